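# Negation and hedge cues: surface<TAB>type
# type "negation": determiner cues (no, not) negate their own noun group;
# prepositional cues (without, absence of, ...) negate the following one.
# type "hedge": non-exclusion constructions whose scope is marked
# negative (hedged findings never contribute to labels).  Hedge patterns
# tolerate intervening adverbs ("cannot be completely excluded").
no	negation
not	negation
without	negation
absence of	negation
free of	negation
negative for	negation
no evidence of	negation
cannot be excluded	hedge
cannot be completely excluded	hedge
cannot exclude	hedge
is not excluded	hedge
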