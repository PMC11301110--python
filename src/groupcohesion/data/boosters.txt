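# Degree-adverb intensity boosters (the VADER booster word list).
# Multi-word entries are matched greedily, longest first.
absolutely
amazingly
awfully
completely
considerably
decidedly
deeply
enormously
entirely
especially
exceptionally
extremely
fabulously
fully
greatly
highly
hugely
incredibly
intensely
majorly
more
most
particularly
purely
quite
really
remarkably
so
so much
substantially
thoroughly
totally
tremendously
unbelievably
unusually
utterly
very
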