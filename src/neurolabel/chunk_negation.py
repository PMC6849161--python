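"""Shallow chunking and negation assignment.

Sentences are segmented into noun groups and verb groups.  Noun groups
are maximal: they absorb determiners, premodifying adjectives and
coordinated head nouns joined by commas, "and" or "or" — which is what
lets a single negative article at the front of *No acute haemorrhage,
masses or extra-axial collections* negate every observation in the
group.  Verb groups absorb auxiliaries, modals, adverbs and (after a
copula) a predicative adjective, so *may not be visible* is one group.

Negation is an attribute on entities, never a relation:

* a determiner cue ("no", "not") negates its own noun group;
* a prepositional cue ("without", "absence of", "no evidence of", ...)
  negates the following noun group;
* a hedged non-exclusion ("... cannot be completely excluded") negates
  the noun groups before its verb group and, for transitive forms
  ("cannot exclude X"), the object noun group after it.

A negative determiner's scope is its own noun group only; long-range
negation across clause boundaries is a documented limitation.  Nested
entity pairs always share one negation value.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

from .model import Chunk, ReportDocument, Sentence
from .resources import open_data

__all__ = [
    "chunk",
    "load_cues",
    "apply_noun_group_negation",
    "apply_hedge_negation",
    "negate_entity",
]

_NG_MOD_TAGS = {"DT", "JJ", "JJR", "JJS", "CD", "PRP$"}
_NG_HEAD_TAGS = {"NN", "NNS", "NNP", "NNPS"}
_NG_TAGS = _NG_MOD_TAGS | _NG_HEAD_TAGS
_VG_TAGS = {"MD", "VB", "VBZ", "VBD", "VBP", "VBN", "VBG", "TO"}
_COORD_SURFACES = {"and", "or"}  # "but" opens a new group


def _starts_ng(tags: list[str], surfaces: list[str], i: int) -> bool:
    if i >= len(tags):
        return False
    if tags[i] in _NG_TAGS:
        return True
    # degree adverb immediately before an adjective opens the group
    return tags[i] == "RB" and i + 1 < len(tags) and tags[i + 1] in _NG_TAGS \
        and surfaces[i].lower() not in {"not"}


def _consume_ng_body(tags: list[str], surfaces: list[str], i: int) -> int:
    """Consume one noun-group core starting at i; return the end index."""
    n = len(tags)
    while i < n:
        if tags[i] in _NG_TAGS:
            i += 1
        elif tags[i] == "RB" and surfaces[i].lower() != "not" \
                and i + 1 < n and tags[i + 1] in _NG_TAGS:
            i += 1
        else:
            break
    return i


def _chunk_sentence(sent: Sentence) -> list[Chunk]:
    tags = [t.pos_tag for t in sent.tokens]
    surfaces = [t.surface for t in sent.tokens]
    n = len(tags)
    chunks: list[Chunk] = []
    i = 0
    while i < n:
        if _starts_ng(tags, surfaces, i):
            start = i
            i = _consume_ng_body(tags, surfaces, i)
            # coordination: ", X" / "and X" / "or X" extends the group
            while i < n:
                sep_end = None
                if surfaces[i] == "," and _starts_ng(tags, surfaces, i + 1):
                    sep_end = i + 1
                elif (tags[i] == "CC"
                      and surfaces[i].lower() in _COORD_SURFACES
                      and _starts_ng(tags, surfaces, i + 1)):
                    sep_end = i + 1
                elif (surfaces[i] == ","
                      and i + 1 < n and tags[i + 1] == "CC"
                      and surfaces[i + 1].lower() in _COORD_SURFACES
                      and _starts_ng(tags, surfaces, i + 2)):
                    sep_end = i + 2
                if sep_end is None:
                    break
                i = _consume_ng_body(tags, surfaces, sep_end)
            chunks.append(Chunk("ng", start, i))
        elif tags[i] in _VG_TAGS or (
            tags[i] == "RB" and i + 1 < n and tags[i + 1] in _VG_TAGS
        ):
            start = i
            saw_be = False
            while i < n and (tags[i] in _VG_TAGS or tags[i] == "RB"):
                if surfaces[i].lower() in {"be", "is", "are", "was", "were",
                                           "been", "being", "am"}:
                    saw_be = True
                i += 1
            # predicative adjective after a copula stays in the group
            if saw_be and i < n and tags[i] == "JJ" and not _starts_ng(
                tags, surfaces, i + 1
            ):
                i += 1
            chunks.append(Chunk("vg", start, i))
        else:
            chunks.append(Chunk("other", i, i + 1))
            i += 1
    return chunks


def chunk(doc: ReportDocument) -> ReportDocument:
    """Populate per-sentence chunks (POS tags must be present)."""
    for sent in doc.sentences:
        sent.chunks = _chunk_sentence(sent)
    return doc


# ---------------------------------------------------------------------------
# Cue loading
# ---------------------------------------------------------------------------

#: Cues acting on the following noun group rather than their own.
_PREPOSITIONAL_CUES = {
    ("without",),
    ("absence", "of"),
    ("free", "of"),
    ("negative", "for"),
    ("no", "evidence", "of"),
}


def _parse_cue_lines(lines: Iterable[str], source: str
                     ) -> tuple[list[tuple[str, ...]], list[tuple[str, ...]]]:
    from .ner import _entry_tokens  # same tokenisation as lexicon entries

    negation: list[tuple[str, ...]] = []
    hedges: list[tuple[str, ...]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{source} line {lineno}: expected "
                             "surface<TAB>type")
        surface, kind = parts[0].strip(), parts[1].strip().lower()
        toks = _entry_tokens(surface)
        if kind == "negation":
            negation.append(toks)
        elif kind == "hedge":
            hedges.append(toks)
        else:
            raise ValueError(f"{source} line {lineno}: unknown cue type "
                             f"{kind!r}")
    return negation, hedges


def load_cues(path: Optional[str | Path] = None
              ) -> tuple[list[tuple[str, ...]], list[tuple[str, ...]]]:
    """Load (negation_cues, hedge_patterns) from a cue TSV file."""
    if path is None:
        with open_data("cues.tsv") as fh:
            return _parse_cue_lines(fh.read().splitlines(), "cues.tsv")
    path = Path(path)
    return _parse_cue_lines(path.read_text(encoding="utf-8").splitlines(),
                            str(path))


# ---------------------------------------------------------------------------
# Negation assignment
# ---------------------------------------------------------------------------


def negate_entity(doc: ReportDocument, entity_id: str) -> None:
    """Set an entity negative, keeping its nested partner in step."""
    ent = doc.entity_by_id(entity_id)
    ent.negated = True
    if ent.nested_with is not None:
        doc.entity_by_id(ent.nested_with).negated = True


def _negate_chunk(doc: ReportDocument, sent: Sentence, ch: Chunk) -> None:
    ch.polarity = "neg"
    c_start, c_end = sent.chunk_char_span(ch)
    for ent in doc.entities:
        if c_start <= ent.start and ent.end <= c_end:
            negate_entity(doc, ent.entity_id)


def _cue_occurrences(sent: Sentence, cues: Sequence[tuple[str, ...]]
                     ) -> list[tuple[int, int, tuple[str, ...]]]:
    """Non-overlapping cue matches, longest first, on lemma or surface."""
    found: list[tuple[int, int, tuple[str, ...]]] = []
    taken: set[int] = set()
    for cue in sorted(cues, key=len, reverse=True):
        k = len(cue)
        for i in range(len(sent.tokens) - k + 1):
            if any(j in taken for j in range(i, i + k)):
                continue
            if all(
                sent.tokens[i + j].surface.lower() == cue[j]
                or sent.tokens[i + j].lemma == cue[j]
                for j in range(k)
            ):
                found.append((i, i + k, cue))
                taken.update(range(i, i + k))
    return sorted(found)


def apply_noun_group_negation(
    doc: ReportDocument,
    negation_cues: Optional[Sequence[tuple[str, ...]]] = None,
) -> ReportDocument:
    """Propagate negative cues through their noun groups.

    Chunks and entities must be present.  Determiner cues negate the
    noun group they open (coordinated heads included); prepositional
    cues negate the next noun group after the cue.
    """
    if negation_cues is None:
        negation_cues, _ = load_cues()
    for sent in doc.sentences:
        ngs = [c for c in sent.chunks if c.kind == "ng"]
        for start, end, cue in _cue_occurrences(sent, negation_cues):
            if cue in _PREPOSITIONAL_CUES:
                nxt = next((c for c in ngs if c.tok_start >= end), None)
                if nxt is not None:
                    _negate_chunk(doc, sent, nxt)
                continue
            own = next(
                (c for c in ngs if c.tok_start <= start and end <= c.tok_end),
                None,
            )
            if own is not None:
                _negate_chunk(doc, sent, own)
            # a bare "not" outside any noun group is verbal negation and
            # is handled during relation extraction
    return doc


def _hedge_matches(sent: Sentence, pattern: tuple[str, ...]
                   ) -> list[tuple[int, int]]:
    """Pattern occurrences, tolerating interleaved adverbs (RB tokens)."""
    out: list[tuple[int, int]] = []
    toks = sent.tokens
    n = len(toks)
    for i in range(n):
        j, k = i, 0
        while j < n and k < len(pattern):
            if (toks[j].surface.lower() == pattern[k]
                    or toks[j].lemma == pattern[k]):
                j += 1
                k += 1
            elif k > 0 and toks[j].pos_tag == "RB":
                j += 1
            else:
                break
        if k == len(pattern):
            out.append((i, j))
    return out


def apply_hedge_negation(
    doc: ReportDocument,
    hedge_patterns: Optional[Sequence[tuple[str, ...]]] = None,
) -> ReportDocument:
    """Mark entities in the scope of non-exclusion hedges as negative."""
    if hedge_patterns is None:
        _, hedge_patterns = load_cues()
    for sent in doc.sentences:
        ngs = [c for c in sent.chunks if c.kind == "ng"]
        for pattern in hedge_patterns:
            for m_start, m_end in _hedge_matches(sent, pattern):
                # leftward: noun groups wholly before the hedge
                for ch in ngs:
                    if ch.tok_end <= m_start:
                        _negate_chunk(doc, sent, ch)
                # rightward: the object noun group starting at the match end
                obj = next((c for c in ngs if c.tok_start == m_end), None)
                if obj is not None:
                    _negate_chunk(doc, sent, obj)
    return doc
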