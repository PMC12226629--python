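# Negation trigger lexicon, seeded with the standard NegEx trigger set.
# Format: <TAG> <phrase>   TAG in {PRE, POST, PSEUDO, TERM, UNC, SCOPE}
# PRE    — negation phrase occurring before the finding
# POST   — negation phrase occurring after the finding
# PSEUDO — looks like a trigger but never negates
# TERM   — scope terminator (conjunctions that end a negation's reach)
# UNC    — uncertainty/hypothetical cue: flags a match, never suppresses it
# SCOPE  — maximum tokens between trigger and finding (NegEx window)

SCOPE 5

PRE no
PRE not
PRE without
PRE absence of
PRE absent
PRE no evidence of
PRE no evidence for
PRE no sign of
PRE no signs of
PRE no suggestion of
PRE nil
PRE denies
PRE denied
PRE negative for
PRE free of
PRE clear of
PRE rules out
PRE ruled out
PRE cannot see
PRE no new
PRE no abnormal
PRE fails to reveal
PRE rather than
PRE with no
PRE unremarkable for

POST not observed
POST not seen
POST not identified
POST not demonstrated
POST not evident
POST not present
POST not detected
POST not appreciated
POST not visualised
POST not visualized
POST was ruled out
POST were ruled out
POST has resolved
POST have resolved
POST is absent
POST are absent
POST excluded
POST unlikely

PSEUDO no increase
PSEUDO no change
PSEUDO no interval change
PSEUDO no significant change
PSEUDO no significant interval change
PSEUDO no further action
PSEUDO not only
PSEUDO not certain
PSEUDO not necessarily
PSEUDO gram negative
PSEUDO cannot be excluded
PSEUDO can not be excluded
PSEUDO cannot exclude

TERM but
TERM however
TERM although
TERM though
TERM apart from
TERM aside from
TERM yet
TERM nevertheless
TERM other than

UNC possible
UNC possibly
UNC probable
UNC likely
UNC query
UNC questionable
UNC suspicious for
UNC may represent
UNC cannot exclude
UNC cannot be excluded
UNC cannot rule out
UNC differential
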