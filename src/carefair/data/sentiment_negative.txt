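# negative sentiment lemma list v1
unhappy
distressed
anxious
agitated
dirty
pain
unable
poor
risk
concern
confusion
deteriorate
difficult
unsafe
unwell
worried
tearful
rude
aggressive
isolated
neglect
decline
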