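# Negation cues, one per line. Clitic "n't" is produced by the tokenizer
# (didn't -> did + n't), so a single entry covers all -n't contractions.
not
no
never
n't
none
nobody
nothing
without
hardly
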