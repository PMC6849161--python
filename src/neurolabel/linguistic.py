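"""Tokenisation, sentence splitting, POS tagging and lemmatisation.

The linguistic layer is deliberately light-weight and rule-based, in
keeping with the rest of the pipeline.  Two Penn-Treebank-style taggers
are shipped — a general-English heuristic tagger and a clinical override
tagger keyed on a radiological vocabulary — combined through a
reconciliation table whose default policy is: where the taggers
disagree, trust the clinical tagger on terms from the clinical
vocabulary and the general tagger otherwise.  Any callable from a token
sequence to an equal-length tag sequence can be substituted for either
tagger.

Sentence splitting treats newlines as boundaries (dictated reports put
one statement per line) and splits inside lines at standalone
terminators; abbreviations such as "e.g." are kept as single tokens and
therefore never end a sentence.  Hyphenated medical compounds
("extra-axial") stay single tokens; all other punctuation is emitted as
standalone tokens.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

from .model import ReportDocument, Sentence, Token

__all__ = [
    "TaggerContractError",
    "TOKEN_RE",
    "tokenize_text",
    "tokenize",
    "general_tagger",
    "clinical_tagger",
    "is_clinical_term",
    "ReconciliationRule",
    "ReconciliationTable",
    "DEFAULT_RECONCILIATION",
    "pos_tag",
    "lemma_of",
    "lemmatise",
]


class TaggerContractError(RuntimeError):
    """A tagger returned a tag sequence of the wrong length."""


# ---------------------------------------------------------------------------
# Tokenisation and sentence splitting
# ---------------------------------------------------------------------------

#: Abbreviation-style tokens like "e.g." or "i.e." keep their periods, so a
#: standalone "." token is always a genuine sentence terminator.
TOKEN_RE = re.compile(
    r"""
    [A-Za-z]\.(?:[A-Za-z]\.)+          # dotted abbreviations: e.g. i.e.
  | \d+(?:\.\d+)?                      # numbers, incl. decimals
  | [A-Za-z0-9]+(?:[-'/][A-Za-z0-9]+)* # words; hyphenated compounds intact
  | \S                                 # any other character on its own
    """,
    re.VERBOSE,
)

_TERMINATORS = {".", "!", "?"}


def tokenize_text(text: str, offset: int = 0) -> list[Token]:
    """Tokenise a string into :class:`Token` objects with absolute offsets."""
    return [
        Token(m.group(0), offset + m.start(), offset + m.end())
        for m in TOKEN_RE.finditer(text)
    ]


def _split_sentences(tokens: list[Token], text: str, offset: int) -> list[Sentence]:
    """Group tokens into sentences at terminators and newline gaps."""
    sentences: list[Sentence] = []
    current: list[Token] = []

    def flush() -> None:
        if current:
            sentences.append(
                Sentence(current[0].start, current[-1].end, tokens=list(current))
            )
            current.clear()

    prev_end: Optional[int] = None
    for tok in tokens:
        if prev_end is not None and "\n" in text[prev_end - offset : tok.start - offset]:
            flush()
        current.append(tok)
        if tok.surface in _TERMINATORS:
            flush()
        prev_end = tok.end
    flush()
    return sentences


def tokenize(doc: ReportDocument) -> ReportDocument:
    """Populate the sentence/token layer, one section at a time.

    Sections must already be assigned (sentences never cross section
    boundaries).
    """
    if not doc.sections:
        raise ValueError("tokenize requires a zoned document (sections present)")
    sentences: list[Sentence] = []
    for sec in doc.sections:
        sec_text = doc.raw_text[sec.start : sec.end]
        toks = tokenize_text(sec_text, offset=sec.start)
        sentences.extend(_split_sentences(toks, sec_text, sec.start))
    doc.sentences = sentences
    return doc


# ---------------------------------------------------------------------------
# POS tagging
# ---------------------------------------------------------------------------

TaggerContract = Callable[[Sequence[str]], Sequence[str]]

_DETERMINERS = {"the", "a", "an", "no", "this", "that", "these", "those",
                "some", "any", "both", "each"}
_CONJUNCTIONS = {"and", "or", "but", "nor"}
_PREPOSITIONS = {"of", "in", "on", "at", "by", "with", "within", "without",
                 "for", "from", "into", "over", "under", "through", "after",
                 "before", "during", "between", "near", "against", "around",
                 "across", "since", "as", "than"}
_MODALS = {"may", "might", "can", "could", "must", "shall", "should", "will",
           "would", "cannot"}
_BE_FORMS = {"be", "is", "are", "was", "were", "been", "being", "am"}
_HAVE_FORMS = {"have", "has", "had", "having"}
_COMMON_VERBS = {"show", "shows", "showed", "shown", "see", "seen", "sees",
                 "appear", "appears", "appeared", "demonstrate",
                 "demonstrates", "demonstrated", "note", "noted", "notes",
                 "suggest", "suggests", "suggested", "reveal", "reveals",
                 "revealed", "exclude", "excluded", "excludes", "identify",
                 "identified", "involve", "involves", "involving", "involved",
                 "affect", "affects", "affecting", "affected", "lie", "lies",
                 "visualised", "visualized", "represent", "represents",
                 "suspected", "confirmed", "reported", "performed",
                 "compared", "keeping"}
_ADVERBS = {"not", "very", "too", "quite", "rather", "so", "now", "also",
            "again", "however", "probably", "possibly", "likely", "there"}
_COMMON_ADJECTIVES = {"old", "new", "small", "large", "acute", "recent",
                      "deep", "mild", "moderate", "severe", "marked", "early",
                      "late", "left", "right", "bilateral", "extensive",
                      "subtle", "previous", "prior", "multiple", "single",
                      "low", "high", "diffuse", "focal", "widespread",
                      "generalised", "generalized", "established",
                      "longstanding", "chronic", "fresh", "mature",
                      "underlying", "significant", "normal", "abnormal",
                      "unremarkable", "prominent"}
_JJ_SUFFIXES = ("al", "ic", "ous", "ive", "able", "ible", "ar", "ary",
                "ical", "ial", "ial", "oid", "ior", "ent")

#: Clinical vocabulary for the override tagger and the reconciliation
#: table's surface class.  Nouns and adjectives commonly found in brain
#: imaging reports; the clinical tagger pins their tags where the general
#: heuristics would mis-tag them.
CLINICAL_NOUNS = {
    "infarct", "infarction", "infarcts", "infarctions", "ischaemia",
    "haemorrhage", "haemorrhages", "hemorrhage", "haematoma", "haematomas",
    "hematoma", "bleed", "bleeds", "microbleed", "microbleeds",
    "microhaemorrhage", "microhaemorrhages", "mass", "masses", "lesion",
    "lesions", "tumour", "tumours", "tumor", "meningioma", "meningiomas",
    "metastasis", "metastases", "glioma", "gliomas", "glioblastoma",
    "atrophy", "stroke", "strokes", "collection", "collections", "aneurysm",
    "aneurysms", "oedema", "edema", "gliosis", "disease", "vessel",
    "vessels", "ventricle", "ventricles", "thalamus", "cortex", "matter",
    "territory", "focus", "foci", "event", "events", "change", "changes",
    "transformation", "loss", "volume", "ganglia", "capsule", "brainstem",
    "cerebellum", "midline", "shift", "hydrocephalus", "encephalomalacia",
}
CLINICAL_ADJECTIVES = {
    "acute", "chronic", "old", "recent", "new", "established", "previous",
    "deep", "cortical", "subcortical", "lobar", "lacunar", "thalamic",
    "frontal", "parietal", "temporal", "occipital", "cerebral", "cerebellar",
    "pontine", "basal", "subdural", "extradural", "subarachnoid",
    "extra-axial", "intra-axial", "ischaemic", "ischemic", "haemorrhagic",
    "hemorrhagic", "intracranial", "intracerebral", "periventricular",
    "involutional", "vascular", "microvascular", "aneurysmal", "embolic",
    "atrophic", "mature", "longstanding", "petechial",
}


def is_clinical_term(surface: str) -> bool:
    s = surface.lower()
    return s in CLINICAL_NOUNS or s in CLINICAL_ADJECTIVES


def _tag_one_general(surface: str, sentence_initial: bool) -> str:
    s = surface.lower()
    if not surface[0].isalnum() and len(surface) == 1:
        return surface  # punctuation tags are the characters themselves
    if re.fullmatch(r"\d+(\.\d+)?", surface):
        return "CD"
    if s in _DETERMINERS:
        return "DT"
    if s in _CONJUNCTIONS:
        return "CC"
    if s == "to":
        return "TO"
    if s in _PREPOSITIONS:
        return "IN"
    if s in _MODALS:
        return "MD"
    if s in _BE_FORMS:
        return "VBZ" if s in {"is", "was"} else "VB"
    if s in _HAVE_FORMS:
        return "VB"
    if s in _ADVERBS or s.endswith("ly"):
        return "RB"
    if s in _COMMON_ADJECTIVES:
        return "JJ"
    if s in _COMMON_VERBS:
        if s.endswith("ing"):
            return "VBG"
        if s.endswith(("ed", "en")):
            return "VBN"
        return "VBZ" if s.endswith("s") else "VB"
    if s.endswith(_JJ_SUFFIXES) and len(s) > 4:
        return "JJ"
    if s.endswith("ing") and len(s) > 4:
        return "VBG"
    if s.endswith("ed") and len(s) > 3:
        return "VBN"
    if surface.isupper() and len(surface) >= 2:
        return "NNP"
    if surface[0].isupper() and not sentence_initial:
        return "NNP"
    if s.endswith("s") and len(s) > 3 and not s.endswith(("ss", "us", "is")):
        return "NNS"
    return "NN"


def general_tagger(tokens: Sequence[str]) -> list[str]:
    """Heuristic Penn-Treebank tagger for general English."""
    return [
        _tag_one_general(tok, sentence_initial=(i == 0))
        for i, tok in enumerate(tokens)
    ]


def clinical_tagger(tokens: Sequence[str]) -> list[str]:
    """Override tagger pinning tags of known radiological vocabulary.

    Falls back to the general heuristics outside the clinical vocabulary.
    """
    tags = general_tagger(tokens)
    for i, tok in enumerate(tokens):
        s = tok.lower()
        if s in CLINICAL_ADJECTIVES:
            tags[i] = "JJ"
        elif s in CLINICAL_NOUNS:
            tags[i] = "NNS" if s.endswith("s") and not s.endswith("ss") else "NN"
    return tags


@dataclass(frozen=True)
class ReconciliationRule:
    """One preference rule; ``"*"`` matches any tag or surface class.

    ``resolved`` is either a literal tag or one of the references
    ``"general"`` / ``"clinical"``.
    """

    tag_general: str
    tag_clinical: str
    surface_class: str  # "clinical" | "other" | "*"
    resolved: str


class ReconciliationTable:
    """Total resolution of tagger disagreements.

    Rules are tried in order; an implicit final rule resolves to the
    general tagger's tag, so every disagreement resolves to exactly one
    tag.
    """

    def __init__(self, rules: Sequence[ReconciliationRule] = ()) -> None:
        self.rules = list(rules)

    def resolve(self, tag_general: str, tag_clinical: str, surface: str) -> str:
        sclass = "clinical" if is_clinical_term(surface) else "other"
        for rule in self.rules:
            if rule.tag_general not in ("*", tag_general):
                continue
            if rule.tag_clinical not in ("*", tag_clinical):
                continue
            if rule.surface_class not in ("*", sclass):
                continue
            if rule.resolved == "general":
                return tag_general
            if rule.resolved == "clinical":
                return tag_clinical
            return rule.resolved
        return tag_general


#: Default policy: prefer the clinical tagger on clinical-vocabulary
#: tokens, the general tagger elsewhere.
DEFAULT_RECONCILIATION = ReconciliationTable(
    [
        ReconciliationRule("*", "*", "clinical", "clinical"),
        ReconciliationRule("*", "*", "other", "general"),
    ]
)


def pos_tag(
    doc: ReportDocument,
    tagger_general: Optional[TaggerContract] = None,
    tagger_clinical: Optional[TaggerContract] = None,
    table: Optional[ReconciliationTable] = None,
) -> ReportDocument:
    """Tag every token, reconciling two taggers where they disagree.

    With ``tagger_clinical`` absent the first tagger's output passes
    through unchanged.  Defaults: the shipped general and clinical
    taggers with the default reconciliation table.
    """
    if tagger_general is None and tagger_clinical is None:
        tagger_general, tagger_clinical = general_tagger, clinical_tagger
    if tagger_general is None:
        raise ValueError("a primary tagger is required")
    table = table if table is not None else DEFAULT_RECONCILIATION

    for sent in doc.sentences:
        surfaces = [t.surface for t in sent.tokens]
        tags_a = list(tagger_general(surfaces))
        if len(tags_a) != len(surfaces):
            raise TaggerContractError(
                f"general tagger returned {len(tags_a)} tags for "
                f"{len(surfaces)} tokens"
            )
        if tagger_clinical is None:
            tags = tags_a
        else:
            tags_b = list(tagger_clinical(surfaces))
            if len(tags_b) != len(surfaces):
                raise TaggerContractError(
                    f"clinical tagger returned {len(tags_b)} tags for "
                    f"{len(surfaces)} tokens"
                )
            tags = [
                a if a == b else table.resolve(a, b, s)
                for a, b, s in zip(tags_a, tags_b, surfaces)
            ]
        for tok, tag in zip(sent.tokens, tags):
            tok.pos_tag = tag
    return doc


# ---------------------------------------------------------------------------
# Lemmatisation
# ---------------------------------------------------------------------------

_IRREGULAR_LEMMAS = {
    "is": "be", "are": "be", "was": "be", "were": "be", "been": "be",
    "being": "be", "am": "be",
    "has": "have", "had": "have", "having": "have",
    "seen": "see", "saw": "see", "shown": "show", "showed": "show",
    "found": "find", "done": "do", "did": "do", "taken": "take",
    "given": "give", "made": "make", "noted": "note", "excluded": "exclude",
    "performed": "perform", "demonstrated": "demonstrate",
    "foci": "focus", "metastases": "metastasis", "ganglia": "ganglion",
    "men": "man", "women": "woman", "children": "child",
}

_SIBILANT_ENDINGS = ("s", "x", "z", "ch", "sh")


def _noun_lemma(s: str) -> str:
    if s.endswith("ies") and len(s) > 4:
        return s[:-3] + "y"
    if s.endswith("es") and len(s) > 3:
        stem = s[:-2]
        if stem.endswith(_SIBILANT_ENDINGS):
            return stem  # masses -> mass, abscesses -> abscess
    if s.endswith("s") and len(s) > 3 and not s.endswith(("ss", "us", "is")):
        return s[:-1]
    return s


def _verb_lemma(s: str) -> str:
    if s.endswith("ied") and len(s) > 4:
        return s[:-3] + "y"
    if s.endswith("ies") and len(s) > 4:
        return s[:-3] + "y"
    if s.endswith("ing") and len(s) > 4:
        return s[:-3]
    if s.endswith("ed") and len(s) > 3:
        if s.endswith(("ated", "uted", "ited", "osed", "ised", "ized",
                       "ured", "ined", "ided", "uded")):
            return s[:-1]  # keep final e: demonstrated -> demonstrate
        return s[:-2]
    if s.endswith("es") and len(s) > 3 and s[:-2].endswith(_SIBILANT_ENDINGS):
        return s[:-2]
    if s.endswith("s") and len(s) > 3 and not s.endswith(("ss", "us", "is")):
        return s[:-1]
    return s


def lemma_of(surface: str, pos_tag: str = "NN") -> str:
    """Lowercase morphological stem for one token."""
    s = surface.lower()
    if s in _IRREGULAR_LEMMAS:
        return _IRREGULAR_LEMMAS[s]
    if pos_tag.startswith("NN"):
        out = _noun_lemma(s) if pos_tag == "NNS" else s
    elif pos_tag.startswith("VB"):
        out = _verb_lemma(s)
    else:
        out = s
    return out or s


def lemmatise(doc: ReportDocument) -> ReportDocument:
    """Fill in lowercase lemmas for every token (POS tags must be present)."""
    for sent in doc.sentences:
        for tok in sent.tokens:
            tok.lemma = lemma_of(tok.surface, tok.pos_tag or "NN")
    return doc
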