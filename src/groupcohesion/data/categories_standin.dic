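# Open stand-in category dictionaries for the five-category cohesion rule.
# NOT the proprietary LIWC dictionaries: small word lists compiled from public
# lexical resources, following the same category names and wildcard semantics
# (trailing "*" = prefix match). Users holding a real .dic file in this format
# can point the baseline at it instead.
%CAT we
we
us
our
ours
ourselves
lets
we'd
we'll
we're
we've
let's
%CAT positive_emotion
good
great
happy
glad
love*
hope*
support*
thank*
wonderful
amazing
nice
better
best
comfort*
encourag*
joy*
warm*
appreciat*
help*
kind
care
caring
positive
fond
strong
%CAT family
famil*
mother*
father*
mom
moms
dad
dads
husband*
wife
wives
sister*
brother*
son
sons
daughter*
parent*
child*
kids
grandm*
grandp*
%CAT friend
friend*
buddy
buddies
pal
pals
neighbor*
neighbour*
companion*
roommate*
bestie*
mate
mates
%CAT affiliation
group*
together
member*
team*
communit*
belong*
join*
connect*
shar*
circle*
social*
everyone
peer*
ally
allies
help*
we
us
our
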