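# physical health theme lexicon v1
mobility
fall
pain
chronic
diabetes
hypertension
medication
incontinence
unable
immobile
fracture
wound
catheter
swallow
breathless
dizzy
frail
stairs
wheelchair
continence
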