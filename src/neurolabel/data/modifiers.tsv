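# Modifier lexicon: surface<TAB>type[<TAB>mode]
# Location (deep vs cortical) and recency (old vs recent) qualifiers.
# Entries that also carry observation meaning (POCI etc.) appear in both
# lexicons and yield nested entities.
deep	loc:deep
thalamic	loc:deep
thalamus	loc:deep
lacunar	loc:deep
subcortical	loc:deep
basal ganglia	loc:deep
internal capsule	loc:deep
brainstem	loc:deep
pontine	loc:deep
periventricular	loc:deep
LACI	loc:deep	literal
cortical	loc:cortical
lobar	loc:cortical
frontal	loc:cortical
parietal	loc:cortical
temporal	loc:cortical
occipital	loc:cortical
cortex	loc:cortical
MCA territory	loc:cortical	literal
POCI	loc:cortical	literal
TACI	loc:cortical	literal
PACI	loc:cortical	literal
old	time:old
previous	time:old
established	time:old
chronic	time:old
longstanding	time:old
mature	time:old
acute	time:recent
recent	time:recent
new	time:recent
fresh	time:recent
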