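# physical appearance theme lexicon v1
dishevelled
scruffy
unkempt
thin
underweight
overweight
pale
gaunt
smart
presentable
clothes
appearance
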