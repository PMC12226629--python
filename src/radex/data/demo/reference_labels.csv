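id,Thyroid examination,Lymph node examination,Thyroid nodule(s),Multiple thyroid nodules,Altered thyroid echotexture,Goitre,Previous thyroid surgery,BTA U1,BTA U2,BTA U3,BTA U4,BTA U5,Solitary thyroid nodule,Normal thyroid
D001,True,True,False,False,False,False,False,False,False,False,False,False,False,True
D002,True,False,True,False,False,False,False,False,False,True,False,False,True,False
D003,True,True,True,True,False,True,False,False,False,False,False,False,False,False
D004,True,False,False,False,True,False,False,False,False,False,False,False,False,False
D005,True,True,False,False,False,False,True,False,False,False,False,False,False,False
D006,True,False,False,False,False,False,False,False,False,False,False,False,False,True
D007,True,False,True,False,False,False,False,False,False,False,False,False,True,False
D008,True,False,False,False,True,True,False,False,False,False,False,False,False,False
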