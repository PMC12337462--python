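# mental health theme lexicon v1
anxious
agitated
tearful
memory
confusion
confused
depression
mood
distressed
dementia
delirium
paranoid
hallucination
withdrawn
forgetful
disorientated
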