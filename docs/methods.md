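# Methods

## Problem and model

`neurolabel` converts a free-text CT/MRI brain-scan report into a
structured annotation in four layers, each computed over the previous
ones:

1. **entities** — spans naming a radiological observation (13 types)
   or a location/recency modifier (4 types);
2. **negation** — a boolean attribute on entities, never a relation;
3. **relations** — `mod-loc` and `mod-time` links from stroke and
   microbleed observations to modifiers, within one sentence;
4. **labels** — 24 report-level phenotypes selected from the
   non-negated evidence in the findings body and conclusion.

The model is deliberately shallow and rule-based: radiology prose is
short, formulaic and dominated by a small technical vocabulary, so a
gazetteer plus noun-group-scoped negation recovers most of the signal,
and every decision remains auditable — a property clinical users weigh
heavily against opaque learned models.  The annotation discipline is
*linguistically explicit evidence only*: a label is selected only when
a non-negated observation (plus modifiers where required) appears in
the report body or conclusion.  Hedged statements ("a small focus of
acute infarct cannot be completely excluded") are marked negative,
because an unexcludable finding is not a clearly positive one.

## Pipeline stages and their parameters

**Zoning.**  Line-initial headers (case-insensitive, optional colon)
open sections of kind clinical-details / report-body / conclusion /
other; the header line belongs to the section it opens; text before the
first header is treated as the referral preamble (clinical details); a
headerless report is a single body section.  The header table is a
TSV file (`data/headers.tsv`); hospital dialects vary, so it is
configurable.  Section kind follows the header, not its position.

**Tokenisation and sentence splitting.**  Regex tokenisation keeps
hyphenated compounds ("extra-axial") and dotted abbreviations ("e.g.")
as single tokens and emits punctuation as standalone tokens.  Newlines
end sentences (dictated reports put one statement per line), as do
standalone `.`/`!`/`?` tokens; because abbreviations retain their
periods, they never split.

**POS tagging.**  Two rule-based Penn-Treebank-style taggers run in
parallel: a general-English heuristic tagger (closed-class word lists
plus suffix rules) and a clinical override tagger that pins the tags of
a radiological vocabulary (`lacunar` → JJ, `event` → NN, …).  A
reconciliation table resolves disagreements; the default policy
prefers the clinical tagger on clinical-vocabulary tokens and the
general tagger elsewhere.  Both taggers are plain functions from token
sequences to tag sequences, so external taggers can be substituted;
with a single tagger configured its output passes through unchanged.

**Lemmatisation.**  A small irregular table plus suffix stripping
(plural nouns, inflected verbs), lowercase throughout.  Lemma accuracy
matters chiefly for gazetteer lookup ("infarcts" must match the entry
"infarct"); lexicon matching therefore accepts either the lemma or the
lowercased surface, which makes it robust to tagger errors upstream.

**Entity recognition.**  Two gazetteer passes — observations first,
then modifiers.  Entries are TSV rows `surface<TAB>type[<TAB>mode]`;
`lemma` mode (default) matches lemmas/lowercased surfaces, `literal`
mode matches surfaces only and serves abbreviations (POCI, SAH, CVA).
Within a pass, selection is greedy by (token length descending, start
ascending): the longest match wins, ties go leftmost, selected matches
never overlap.  A modifier match co-extensive with an observation
creates a **nested pair** (POCI is simultaneously an ischaemic stroke
and a cortical location); a partially overlapping modifier match is
suppressed — observations drive labelling, so they take precedence.
The shipped lexicons cover the standard reporting vocabulary plus
common synonyms and are user-replaceable; coverage of any particular
hospital's dialect is necessarily approximate.

**Chunking.**  Maximal noun groups absorb determiners, premodifying
adjectives and coordinated head nouns joined by commas/"and"/"or"
("but" opens a new group); verb groups absorb modals, auxiliaries,
adverbs and a predicative adjective after a copula ("may not be
visible" is one group).

**Negation.**  Cue semantics (cues in `data/cues.tsv`):

* determiner cues (*no*, *not*) negate their own noun group, so one
  *No* propagates through an entire coordination;
* prepositional cues (*without*, *absence of*, *free of*, *negative
  for*, *no evidence of*) negate the following noun group;
* hedge patterns (*cannot (be) excluded*, *cannot exclude*, *is not
  excluded*; intervening adverbs tolerated) negate the noun groups
  before the hedge's verb group and the object noun group after it;
* a verb-group *not* negates the subject noun group immediately before
  it and a copular complement immediately after it ("is not a
  tumour"); this is computed with the relation rules but produces an
  attribute, never a relation object.

The scope of a negative determiner is its own noun group only.
Long-range negation ("…with no convincing evidence, on this limited
study, of infarction") is a known limitation: the cue list is
NegEx-style and configurable, but no cross-clause scope rules are
attempted.  Double negation is out of scope.  Nested pairs always
share one negation value, and negation is monotone — adding a cue can
only negate more entities.

**Relations.**  Location modifiers may attach to ischaemic,
haemorrhagic or unknown-type strokes and to microbleeds; time
modifiers to strokes only (microbleeds carry no time dimension).  Each
modifier attaches to at most one observation: the nearest compatible
one in its own noun group, else the nearest in the sentence (ties go
leftward); one observation may hold several relations (one time + one
location is the typical pattern).  Cross-chunk attachment is blocked
when the endpoints disagree in negation polarity; same-chunk
attachment is unconditional.  Nested pairs are never linked explicitly
— the nesting implies the relation, and the labeller consults
`nested_with` directly.  Conflicting same-type values on one
observation (old + recent) keep only the nearest modifier, with a
warning; agreeing duplicates may all attach.  One modifier never links
to two observations — with coordinated strokes sharing a modifier the
nearer one wins; the alternative (fan-out) was rejected as the more
speculative reading.

**Labelling.**  The rule table is data (`data/label_rules.yaml`), not
code, so the entity→label mapping can be audited and replaced.  Rule
semantics: presence labels fire on any non-negated observation of
their type (a generic tumour mention selects *Tumour, other*); stroke
labels combine type × location × time, where location/time come from
explicit relations or nesting and negated modifiers never contribute;
a **deep ischaemic stroke with no time value is assumed old** (an
untreated deep infarct on imaging is overwhelmingly chronic); a
cortical ischaemic stroke without a time value falls back to
*underspecified* — the assumed-old default is deliberately restricted
to the deep case, and the table makes this choice visible and
editable; haemorrhagic strokes have no time default; an unknown-type
stroke selects *Stroke, underspecified*; microbleed labels use
location only; subarachnoid haemorrhage is *aneurysmal* only when an
"aneurysm"-prefixed lemma occurs in the same sentence (the cue is
ours; no published criterion exists), else *other*.  Labels are not
mutually exclusive.  Clinical-details evidence never contributes.

## Evaluation conventions

An entity matches on exact span and exact type; no partial credit.
Negation scoring is restricted to negated entities (a gold-negated
entity whose span/type match is also pred-negated is a TP).  Relation
matching requires the same relation type and entity-matched endpoints;
in inter-annotator mode a relation is excluded from the counts
entirely unless both endpoints are entity matches between the two
sides.  Label scoring counts each selected (report, label) pair as one
unit.  Micro-averaged TOTAL rows are computed from summed counts,
never by averaging per-type F1s.  Ratios with zero denominators are
NaN; F1 is NaN whenever precision or recall is undefined, and
otherwise computed as 2TP/(2TP+FP+FN).  Displayed values are rounded
to two decimals with round-half-even, which reproduces the published
reference rows exactly (e.g. 58/64 → 90.62); unrounded values are kept
internally.  Which annotator serves as reference in agreement scoring
is arbitrary — swapping sides swaps precision and recall and preserves
F1, a property the test suite checks.

## Synthetic data: what it shows and what it does not

Real stroke-register corpora are access-restricted, so the test bed is
a seedable generator (`synthetic.py`).  Templates instantiate sentence
skeletons — affirmative findings with optional modifiers, negated
coordinations up to three heads wide, hedged non-exclusions, verbal
negation, nested POCI mentions, aneurysmal subarachnoid haemorrhage —
only from shipped lexicon surface forms, and the generator records the
gold annotation (entities, negation, relations, labels) as it writes
the text.  Default conditions: 25 reports per batch; observation
frequencies follow a stroke-register case mix (ischaemic disease,
small vessel disease and atrophy dominant); about a quarter of finding
sentences negated plus ~8% hedges and ~6% verbal negation, so roughly
a third of observation mentions end up negative, matching the
positive/negative balance of annotated register reports; report length
a handful of body sentences (order of 90 words), the scale of short
dictated reports.

Because templates stay inside the rule coverage, the pipeline
re-annotates generated reports to their gold standard with F1 = 100 in
all four categories (the *closure property*).  This demonstrates
internal consistency — generator, rules and scorer agree — and guards
every stage against regression; it does **not** estimate real-world
accuracy, since real prose contains out-of-lexicon vocabulary,
long-range negation, typographical noise and syntax the templates do
not produce.  A corruption operator (drop entity, shift span, flip
negation, retype, drop relation, toggle label) perturbs documents by
counted single units so the scorer's counting can be verified against
predicted deltas and brute-force recounts.

## Numerical and degenerate-input choices

Character offsets are 0-based half-open over the raw text everywhere,
including BRAT output.  Entity ids are assigned in reading order, an
observation before its co-extensive nested modifier; relations
reference ids, never offsets.  The BRAT dialect adds `L` lines for
selected report-level labels so they survive round trips; the
"microhaemorrhage" spelling is accepted as an alias for the microbleed
type on input.  Empty or whitespace-only report text is rejected with
an explicit "empty report" error; a batch continues past a failed
report, logging the error.  Matching is insensitive to lexicon file
order (entries are sorted internally), and the whole pipeline is a
pure function of (text, configuration).

## Verification problem sizes

The test suite runs the matcher-vs-enumeration oracle on 1000 random
synthetic sentences, scorer recounts on corrupted batches of 15–20
reports, and the closure loop on a 30-report batch; the acceptance
script uses a 60-report closure batch and a 300-sentence oracle
sample.  These sizes give full coverage of every template and entity
type while keeping the whole suite in the seconds-to-a-minute range on
one CPU.
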