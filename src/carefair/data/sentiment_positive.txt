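# positive sentiment lemma list v1
happy
settled
content
cheerful
comfortable
enjoy
good
well
independent
pleasant
safe
supportive
improve
warm
kind
calm
stable
engaged
friendly
positive
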