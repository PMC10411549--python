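# Coordinating conjunctions that separate main clauses (automatic splitter
# breaks at a comma directly followed by one of these), v1.
und
aber
oder
denn
sondern
and
but
or
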