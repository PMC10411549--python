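# German verbal fillers / hesitation markers, v1.
# One token per line, matched case-insensitively after edge-punctuation stripping.
ehm
äh
ähm
öhm
hm
hmm
mhm
mhmm
mh
tja
naja
ähhh
ehh
öh
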