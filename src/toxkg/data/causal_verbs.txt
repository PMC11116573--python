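# Default causal-verb lemma list, one per line.
# Duplicates are removed at load time ("lead" appears twice below).
increase
produce
cause
induce
generate
effect
provoke
arouse
elicit
lead
trigger
derive
associate
relate
link
stem
originate
lead
bring
result
inhibit
elevate
diminish
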