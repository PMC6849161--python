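# Observation lexicon: surface<TAB>type[<TAB>mode]
# mode defaults to "lemma" (entry tokens matched against token lemmas or
# lowercased surfaces); "literal" entries match the surface form only,
# case-insensitively, and are meant for abbreviations.
# The starter inventory covers the standard vocabulary of brain-scan
# reporting plus common synonyms; replace with a site-specific lexicon
# via --obs-lexicon for production use.
infarct	ischaemic stroke
infarction	ischaemic stroke
ischaemic stroke	ischaemic stroke
ischaemic change	ischaemic stroke
ischaemic event	ischaemic stroke
lacunar event	ischaemic stroke
lacune	ischaemic stroke
POCI	ischaemic stroke	literal
TACI	ischaemic stroke	literal
PACI	ischaemic stroke	literal
LACI	ischaemic stroke	literal
haemorrhage	haemorrhagic stroke
haematoma	haemorrhagic stroke
hemorrhage	haemorrhagic stroke
intracerebral haemorrhage	haemorrhagic stroke
bleed	haemorrhagic stroke
stroke	stroke unknown
cerebrovascular accident	stroke unknown
CVA	stroke unknown	literal
meningioma	tumour:meningioma
metastasis	tumour:metastasis
metastatic deposit	tumour:metastasis
glioma	tumour:glioma
glioblastoma	tumour:glioma
tumour	tumour
tumor	tumour
mass	tumour
lesion	tumour
space-occupying lesion	tumour
subdural haematoma	subdural haematoma
subdural collection	subdural haematoma
extra-axial collection	subdural haematoma
small vessel disease	small vessel disease
small vessel change	small vessel disease
microangiopathy	small vessel disease
microvascular change	small vessel disease
atrophy	atrophy
volume loss	atrophy
inter-cerebral volume loss	atrophy
involutional change	atrophy
microbleed	microbleed
microhaemorrhage	microbleed
subarachnoid haemorrhage	subarachnoid haemorrhage
SAH	subarachnoid haemorrhage	literal
haemorrhagic transformation	haemorrhagic transformation
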