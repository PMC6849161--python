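"""Lexicon-driven recognition of observation and modifier entities.

Recognition is gazetteer lookup over lemmas: an entry matches a token
run when each entry token equals the token's lemma or lowercased
surface; ``literal`` entries (abbreviations such as "POCI") match the
surface form only, case-insensitively.  Within each lexicon pass,
selection is greedy by (token length descending, start ascending), so
the longest match wins and ties go leftmost, and selected matches never
overlap.

The observation pass runs first; the modifier pass may then lay a
co-extensive modifier over an observation span, producing a nested
entity pair ("POCI" is both an ischaemic stroke and a cortical
location).  A modifier match that only partially overlaps an
observation is suppressed — observations drive the labelling and take
precedence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .linguistic import TOKEN_RE
from .model import (
    Entity,
    ModifierType,
    ObservationType,
    ReportDocument,
    Sentence,
)
from .resources import open_data

__all__ = [
    "LexiconError",
    "LexiconEntry",
    "parse_lexicon",
    "load_lexicon",
    "load_lexicons",
    "candidate_matches",
    "select_matches",
    "match_entities",
]


class LexiconError(ValueError):
    """Raised on a malformed lexicon file; message names the line."""


#: Accepted spellings of entity types in lexicon files (and BRAT input),
#: covering the colon-delimited field notation and plain enum values.
TYPE_NAMES: dict[str, ObservationType | ModifierType] = {
    "ischaemic stroke": ObservationType.ISCHAEMIC_STROKE,
    "haemorrhagic stroke": ObservationType.HAEMORRHAGIC_STROKE,
    "stroke unknown": ObservationType.STROKE_UNKNOWN,
    "stroke (unknown type)": ObservationType.STROKE_UNKNOWN,
    "tumour:meningioma": ObservationType.TUMOUR_MENINGIOMA,
    "tumour:metastasis": ObservationType.TUMOUR_METASTASIS,
    "tumour:glioma": ObservationType.TUMOUR_GLIOMA,
    "tumour": ObservationType.TUMOUR,
    "subdural haematoma": ObservationType.SUBDURAL_HAEMATOMA,
    "small vessel disease": ObservationType.SMALL_VESSEL_DISEASE,
    "atrophy": ObservationType.ATROPHY,
    "microbleed": ObservationType.MICROBLEED,
    "microhaemorrhage": ObservationType.MICROBLEED,
    "subarachnoid haemorrhage": ObservationType.SUBARACHNOID_HAEMORRHAGE,
    "haemorrhagic transformation": ObservationType.HAEMORRHAGIC_TRANSFORMATION,
    "loc:deep": ModifierType.LOC_DEEP,
    "loc:cortical": ModifierType.LOC_CORTICAL,
    "time:old": ModifierType.TIME_OLD,
    "time:recent": ModifierType.TIME_RECENT,
}
for _t in list(ObservationType) + list(ModifierType):
    TYPE_NAMES.setdefault(_t.value, _t)


@dataclass(frozen=True)
class LexiconEntry:
    """One gazetteer entry: a token sequence mapped to an entity type."""

    tokens: tuple[str, ...]
    etype: ObservationType | ModifierType
    mode: str = "lemma"  # "lemma" | "literal"

    def __post_init__(self) -> None:
        if not self.tokens:
            raise LexiconError("empty match sequence")
        if self.mode not in ("lemma", "literal"):
            raise LexiconError(f"unknown match mode {self.mode!r}")


def _entry_tokens(surface: str) -> tuple[str, ...]:
    return tuple(m.group(0).lower() for m in TOKEN_RE.finditer(surface))


def parse_lexicon(lines: Iterable[str], source: str = "<lexicon>",
                  category: Optional[str] = None) -> list[LexiconEntry]:
    """Parse TSV lexicon lines: ``surface<TAB>type[<TAB>mode]``.

    ``category`` restricts entries to ``"observation"`` or ``"modifier"``
    types; a violation or an unknown type raises :class:`LexiconError`
    naming the line.
    """
    entries: list[LexiconEntry] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) not in (2, 3):
            raise LexiconError(f"{source} line {lineno}: expected "
                               "surface<TAB>type[<TAB>mode]")
        surface, type_s = parts[0].strip(), parts[1].strip().lower()
        mode = parts[2].strip().lower() if len(parts) == 3 else "lemma"
        if type_s not in TYPE_NAMES:
            raise LexiconError(f"{source} line {lineno}: unknown entity type "
                               f"{parts[1]!r}")
        etype = TYPE_NAMES[type_s]
        if category == "observation" and not isinstance(etype, ObservationType):
            raise LexiconError(f"{source} line {lineno}: {parts[1]!r} is not "
                               "an observation type")
        if category == "modifier" and not isinstance(etype, ModifierType):
            raise LexiconError(f"{source} line {lineno}: {parts[1]!r} is not "
                               "a modifier type")
        tokens = _entry_tokens(surface)
        if not tokens:
            raise LexiconError(f"{source} line {lineno}: empty surface")
        if mode not in ("lemma", "literal"):
            raise LexiconError(f"{source} line {lineno}: unknown mode {mode!r}")
        entries.append(LexiconEntry(tokens, etype, mode))
    # sorted internally: matching is insensitive to file ordering
    return sorted(entries, key=lambda e: (e.tokens, e.etype.value, e.mode))


def load_lexicon(path: str | Path, category: Optional[str] = None) -> list[LexiconEntry]:
    path = Path(path)
    return parse_lexicon(path.read_text(encoding="utf-8").splitlines(),
                         source=str(path), category=category)


def load_lexicons(
    observations_path: Optional[str | Path] = None,
    modifiers_path: Optional[str | Path] = None,
) -> tuple[list[LexiconEntry], list[LexiconEntry]]:
    """Load the observation and modifier lexicons (packaged defaults)."""
    if observations_path is None:
        with open_data("observations.tsv") as fh:
            obs = parse_lexicon(fh.read().splitlines(), "observations.tsv",
                                category="observation")
    else:
        obs = load_lexicon(observations_path, category="observation")
    if modifiers_path is None:
        with open_data("modifiers.tsv") as fh:
            mods = parse_lexicon(fh.read().splitlines(), "modifiers.tsv",
                                 category="modifier")
    else:
        mods = load_lexicon(modifiers_path, category="modifier")
    return obs, mods


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


def _token_matches(entry_tok: str, surface: str, lemma: str, mode: str) -> bool:
    if mode == "literal":
        return surface.lower() == entry_tok
    return lemma == entry_tok or surface.lower() == entry_tok


def candidate_matches(
    sentence: Sentence, entries: Sequence[LexiconEntry]
) -> list[tuple[int, int, LexiconEntry]]:
    """All (tok_start, tok_end, entry) runs where an entry matches."""
    toks = sentence.tokens
    out: list[tuple[int, int, LexiconEntry]] = []
    for entry in entries:
        k = len(entry.tokens)
        for i in range(len(toks) - k + 1):
            if all(
                _token_matches(entry.tokens[j], toks[i + j].surface,
                               toks[i + j].lemma, entry.mode)
                for j in range(k)
            ):
                out.append((i, i + k, entry))
    return out


def select_matches(
    candidates: Sequence[tuple[int, int, LexiconEntry]]
) -> list[tuple[int, int, LexiconEntry]]:
    """Greedy non-overlapping selection: longest first, then leftmost."""
    ranked = sorted(
        candidates,
        key=lambda c: (-(c[1] - c[0]), c[0], c[2].etype.value, c[2].mode),
    )
    chosen: list[tuple[int, int, LexiconEntry]] = []
    taken: set[int] = set()
    for start, end, entry in ranked:
        span = range(start, end)
        if any(i in taken for i in span):
            continue
        # one entity per token run: skip duplicate-span candidates too
        if any(c[0] == start and c[1] == end for c in chosen):
            continue
        chosen.append((start, end, entry))
        taken.update(span)
    return sorted(chosen, key=lambda c: c[0])


def match_entities(
    doc: ReportDocument,
    observations: Optional[Sequence[LexiconEntry]] = None,
    modifiers: Optional[Sequence[LexiconEntry]] = None,
) -> ReportDocument:
    """Run the two lexicon passes and populate ``doc.entities``.

    Lemmas must be present.  Entity ids are assigned in reading order
    (T1, T2, ...), an observation preceding its co-extensive nested
    modifier.
    """
    if observations is None or modifiers is None:
        default_obs, default_mods = load_lexicons()
        observations = observations if observations is not None else default_obs
        modifiers = modifiers if modifiers is not None else default_mods

    records: list[Entity] = []
    for sent in doc.sentences:
        obs_sel = select_matches(candidate_matches(sent, observations))
        mod_sel = select_matches(candidate_matches(sent, modifiers))

        obs_spans = [(s, e) for s, e, _ in obs_sel]
        sent_entities: list[Entity] = []
        for s, e, entry in obs_sel:
            ent = _make_entity(doc, sent, s, e, entry)
            sent_entities.append(ent)
            for tok in sent.tokens[s:e]:
                tok.lookup_flags.add(f"obs:{entry.etype.value}")
        for s, e, entry in mod_sel:
            overlapping = [
                (os, oe) for os, oe in obs_spans if os < e and s < oe
            ]
            if overlapping and (s, e) not in overlapping:
                continue  # partial overlap: observation wins
            ent = _make_entity(doc, sent, s, e, entry)
            if (s, e) in overlapping:
                partner = next(
                    o for o in sent_entities
                    if (o.start, o.end) == (ent.start, ent.end)
                    and o.is_observation
                )
                ent.nested_with = partner.entity_id
                partner.nested_with = ent.entity_id
            sent_entities.append(ent)
            for tok in sent.tokens[s:e]:
                tok.lookup_flags.add(f"mod:{entry.etype.value}")
        records.extend(sent_entities)

    records.sort(key=lambda e: (e.start, e.end, not e.is_observation))
    rename = {e.entity_id: f"T{i}" for i, e in enumerate(records, start=1)}
    for ent in records:
        ent.entity_id = rename[ent.entity_id]
        if ent.nested_with is not None:
            ent.nested_with = rename[ent.nested_with]
    doc.entities = records
    return doc


_counter = 0


def _make_entity(doc: ReportDocument, sent: Sentence, tok_start: int,
                 tok_end: int, entry: LexiconEntry) -> Entity:
    global _counter
    _counter += 1
    start = sent.tokens[tok_start].start
    end = sent.tokens[tok_end - 1].end
    return Entity(
        entity_id=f"tmp{_counter}",
        etype=entry.etype,
        start=start,
        end=end,
        section_kind=doc.section_kind_at(start),
    )
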