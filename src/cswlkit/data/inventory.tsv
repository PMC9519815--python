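p	consonant
b	consonant
t	consonant
d	consonant
k	consonant
g	consonant
f	consonant
v	consonant
s	consonant
z	consonant
ʃ	consonant
ʒ	consonant
m	consonant
n	consonant
ɲ	consonant
l	consonant
ʎ	consonant
ɾ	consonant
ʁ	consonant
t͡ʃ	consonant
d͡ʒ	consonant
a	vowel
e	vowel
i	vowel
o	vowel
u	vowel
ɛ	vowel
ɔ	vowel
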