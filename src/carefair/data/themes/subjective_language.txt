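# subjective language theme lexicon v1
dirty
excessive
rude
unwise
difficult
demanding
uncooperative
stubborn
pleasant
charming
hostile
aggressive
vocal
reluctant
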