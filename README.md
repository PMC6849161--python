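# neurolabel

Rule-based text mining of CT/MRI brain-scan radiology reports.

Radiologists' free-text reports hold structured facts — did the scan
show an ischaemic stroke, where, how old is it? — that epidemiologists
and audit teams need as discrete codes.  `neurolabel` reads a report
and produces:

* **observation entities** (13 types: ischaemic/haemorrhagic stroke,
  stroke of unknown type, tumour subtypes, subdural haematoma, small
  vessel disease, atrophy, microbleed, subarachnoid haemorrhage,
  haemorrhagic transformation) and **modifier entities** (`loc:deep`,
  `loc:cortical`, `time:old`, `time:recent`);
* a **negation attribute** on each entity — explicit negation ("No
  acute haemorrhage, masses or extra-axial collections" negates all
  three observations through the coordinated noun group) and hedged
  non-exclusions ("… cannot be completely excluded"), which count as
  negative because only clearly positive findings should drive coding;
* **mod-loc / mod-time relations** linking stroke and microbleed
  observations to their modifiers within a sentence;
* **24 report-level phenotype labels** (e.g. *Ischaemic stroke, deep,
  old*; *Small vessel disease*; *Microbleed, lobar*) derived from the
  non-negated entities and relations in the findings body and
  conclusion, with an auditable evidence trace per label.

The pipeline is entirely rule-based — document zoning, tokenisation,
dual POS tagging with a reconciliation stage, lemmatisation, gazetteer
entity lookup, shallow chunking, negation scoping, relation attachment,
label rules — and every resource (lexicons, cue lists, header table,
label rules) is a declarative file the user can replace.

An evaluation module scores system-vs-gold or annotator-vs-annotator
agreement with per-type and micro-averaged precision, recall and F1
(P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R), reported on the 0–100
scale; zero-denominator ratios print as NaN), and a seedable synthetic
report generator provides gold-annotated test data, since real stroke
registry corpora are access-restricted.

## Worked example

```python
from neurolabel import annotate, explain

doc = annotate("Clinical details: sudden weakness.\n"
               "Report:\nOld thalamic infarcts. No acute infarction.\n"
               "Conclusion:\nEstablished deep infarct.")
for e in doc.entities:
    print(e.entity_id, e.etype.value, doc.text_of(e), e.negated)
print([la.label for la in doc.labels if la.selected])
print(explain(doc, "Ischaemic stroke, deep, old"))
```

prints

```
T1 time_old Old False
T2 loc_deep thalamic False
T3 ischaemic_stroke infarcts False
T4 time_recent acute True
T5 ischaemic_stroke infarction True
T6 time_old Established False
T7 loc_deep deep False
T8 ischaemic_stroke infarct False
['Ischaemic stroke, deep, old']
Ischaemic stroke, deep, old: selected
  T3 ischaemic_stroke [56,64) 'infarcts'
    mod-time(T3, T1)
    mod-loc(T3, T2)
  T1 time_old [43,46) 'Old'
    mod-time(T3, T1)
  ...
```

The first stroke mention is linked to a time and a location modifier;
the second is negated by the determiner *No* and contributes nothing;
the report-level label *Ischaemic stroke, deep, old* is selected with
the entities and relations that justify it.

From a shell:

```sh
neurolabel annotate report.txt --out out/          # BRAT .ann/.txt
neurolabel synth --seed 1 --n 25 --out gold/       # synthetic gold data
neurolabel score --gold gold/ --pred out/ [--iaa]  # P/R/F1 tables
neurolabel explain report.txt                      # evidence traces
```

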