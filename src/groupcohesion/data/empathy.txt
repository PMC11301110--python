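# Empathy cue phrases, matched case-insensitively over tokenized text.
i can relate
i feel the same
i feel the same way
sending hugs
be strong
thinking of you
i am with you
i'm with you
i hear you
that must have been
you are not alone
you're not alone
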