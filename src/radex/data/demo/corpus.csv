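id,text,exam_date,age,exam_code
D001,Clinical history: Neck lump. Findings: The thyroid is normal in size. There are no thyroid nodules. No cervical lymphadenopathy.,2018-03-12,52,UTHYD
D002,Clinical history: Palpable swelling. Findings: The thyroid is normal in size apart from a single nodule in the right lobe measuring 14 mm. Graded u3 by BTA criteria.,2017-11-02,61,UTHYD
D003,Clinical history: Goitre on examination. Findings: The thyroid is enlarged with multiple nodules in both lobes. Appearances of a multinodular goitre. No abnormal cervical lymph nodes.,2019-06-21,47,UNECK
D004,"Clinical history: Hypothyroid, tired. Findings: The thyroid is diffusely heterogeneous in echotexture, in keeping with thyroiditis. No discrete nodule.",2016-01-30,39,UTHYD
D005,Clinical history: Previous total thyroidectomy. Findings: No residual tissue in the thyroid bed. No abnormal cervical lymph nodes.,2015-09-14,66,UTHPY
D006,Clinical history: Lump in the left side of the neck. Findings: A simple left parotid cyst is noted. The thyroid appears normal.,2018-08-05,29,UNECK
D007,Clinical history: Nodule on CT. Findings: The thyroid contains a colloid cyst in the left lobe. Graded u2/u3 by BTA criteria.,2019-02-17,55,UTHYD
D008,"Clinical history: Thyrotoxicosis. Findings: The thyroid is diffusely enlarged and heterogeneous in echotexture, consistent with graves disease.",2017-05-09,34,UTHYD
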