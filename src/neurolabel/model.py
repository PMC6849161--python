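"""Shared data model for annotated brain-scan radiology reports.

A :class:`ReportDocument` carries a report through the pipeline: the raw
text, its sections (clinical details / findings body / conclusion), the
sentence and token layer, recognised observation and modifier entities
with negation attributes, modifier-attachment relations, and the fixed
inventory of 24 report-level phenotype labels, each with a ``selected``
flag and evidence pointers.

All spans are 0-based, half-open character intervals over ``raw_text``.
Serialisation is provided to/from JSON, BRAT standoff (.ann/.txt pairs)
and an inline XML dump (dialect ``neurolabel-xml-1``).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from lxml import etree

__all__ = [
    "ObservationType",
    "ModifierType",
    "SectionKind",
    "RelationType",
    "Section",
    "Token",
    "Chunk",
    "Sentence",
    "Entity",
    "Relation",
    "LabelAssignment",
    "ReportDocument",
    "LABELS",
    "STROKE_TYPES",
    "MOD_LOC_OBSERVATIONS",
    "MOD_TIME_OBSERVATIONS",
    "ReportError",
    "EmptyReportError",
    "ValidationError",
    "BratParseError",
    "read_report",
    "validate_document",
    "doc_to_json",
    "doc_from_json",
    "write_brat",
    "parse_brat",
    "write_xml",
]


class ReportError(ValueError):
    """Base error for document construction and serialisation problems."""


class EmptyReportError(ReportError):
    """Raised when a report text is empty after whitespace stripping."""


class ValidationError(ReportError):
    """Raised when a document violates a structural invariant."""


class BratParseError(ReportError):
    """Raised on malformed standoff input; message names the bad line."""


class ObservationType(str, Enum):
    """Radiological findings recognised as observation entities."""

    ISCHAEMIC_STROKE = "ischaemic_stroke"
    HAEMORRHAGIC_STROKE = "haemorrhagic_stroke"
    STROKE_UNKNOWN = "stroke_unknown"
    TUMOUR_MENINGIOMA = "tumour_meningioma"
    TUMOUR_METASTASIS = "tumour_metastasis"
    TUMOUR_GLIOMA = "tumour_glioma"
    TUMOUR = "tumour"
    SUBDURAL_HAEMATOMA = "subdural_haematoma"
    SMALL_VESSEL_DISEASE = "small_vessel_disease"
    ATROPHY = "atrophy"
    MICROBLEED = "microbleed"
    SUBARACHNOID_HAEMORRHAGE = "subarachnoid_haemorrhage"
    HAEMORRHAGIC_TRANSFORMATION = "haemorrhagic_transformation"


class ModifierType(str, Enum):
    """Location and recency qualifiers attachable to observations."""

    LOC_DEEP = "loc_deep"
    LOC_CORTICAL = "loc_cortical"
    TIME_OLD = "time_old"
    TIME_RECENT = "time_recent"


class SectionKind(str, Enum):
    CLINICAL_DETAILS = "clinical_details"
    REPORT_BODY = "report_body"
    CONCLUSION = "conclusion"
    OTHER = "other"


class RelationType(str, Enum):
    MOD_LOC = "mod-loc"
    MOD_TIME = "mod-time"


STROKE_TYPES = frozenset(
    {
        ObservationType.ISCHAEMIC_STROKE,
        ObservationType.HAEMORRHAGIC_STROKE,
        ObservationType.STROKE_UNKNOWN,
    }
)

#: Observation types permitted as the left end of a mod-loc relation.
MOD_LOC_OBSERVATIONS = STROKE_TYPES | {ObservationType.MICROBLEED}

#: Observation types permitted as the left end of a mod-time relation
#: (microbleeds take a location but never a time).
MOD_TIME_OBSERVATIONS = STROKE_TYPES

#: The closed inventory of 24 report-level phenotype labels.
LABELS: tuple[str, ...] = (
    "Ischaemic stroke, deep, recent",
    "Ischaemic stroke, deep, old",
    "Ischaemic stroke, cortical, recent",
    "Ischaemic stroke, cortical, old",
    "Ischaemic stroke, underspecified",
    "Haemorrhagic stroke, deep, recent",
    "Haemorrhagic stroke, deep, old",
    "Haemorrhagic stroke, lobar, recent",
    "Haemorrhagic stroke, lobar, old",
    "Haemorrhagic stroke, underspecified",
    "Stroke, underspecified",
    "Tumour, meningioma",
    "Tumour, metastasis",
    "Tumour, glioma",
    "Tumour, other",
    "Small vessel disease",
    "Atrophy",
    "Subdural haematoma",
    "Subarachnoid haemorrhage, aneurysmal",
    "Subarachnoid haemorrhage, other",
    "Microbleed, deep",
    "Microbleed, lobar",
    "Microbleed, underspecified",
    "Haemorrhagic transformation",
)


@dataclass
class Section:
    kind: SectionKind
    start: int
    end: int


@dataclass
class Token:
    surface: str
    start: int
    end: int
    pos_tag: str = ""
    lemma: str = ""
    lookup_flags: set[str] = field(default_factory=set)


@dataclass
class Chunk:
    """Shallow syntactic group over a token index range of one sentence."""

    kind: str  # "ng" | "vg" | "other"
    tok_start: int
    tok_end: int  # half-open token index range within the sentence
    polarity: str = "pos"  # "pos" | "neg"


@dataclass
class Sentence:
    start: int
    end: int
    tokens: list[Token] = field(default_factory=list)
    chunks: list[Chunk] = field(default_factory=list)

    def chunk_char_span(self, chunk: Chunk) -> tuple[int, int]:
        toks = self.tokens[chunk.tok_start : chunk.tok_end]
        return toks[0].start, toks[-1].end


@dataclass
class Entity:
    entity_id: str
    etype: ObservationType | ModifierType
    start: int
    end: int
    negated: bool = False
    nested_with: Optional[str] = None
    section_kind: Optional[SectionKind] = None

    @property
    def is_observation(self) -> bool:
        return isinstance(self.etype, ObservationType)

    @property
    def span(self) -> tuple[int, int]:
        return self.start, self.end


@dataclass
class Relation:
    rtype: RelationType
    observation: str  # entity_id
    modifier: str  # entity_id


@dataclass
class LabelAssignment:
    label: str
    selected: bool = False
    evidence: list[str] = field(default_factory=list)


@dataclass
class ReportDocument:
    report_id: str
    raw_text: str
    sections: list[Section] = field(default_factory=list)
    sentences: list[Sentence] = field(default_factory=list)
    entities: list[Entity] = field(default_factory=list)
    relations: list[Relation] = field(default_factory=list)
    labels: list[LabelAssignment] = field(default_factory=list)

    # -- convenience accessors -------------------------------------------

    def entity_by_id(self, entity_id: str) -> Entity:
        for ent in self.entities:
            if ent.entity_id == entity_id:
                return ent
        raise KeyError(entity_id)

    def text_of(self, obj: Entity | Section | Sentence) -> str:
        return self.raw_text[obj.start : obj.end]

    def section_kind_at(self, pos: int) -> Optional[SectionKind]:
        for sec in self.sections:
            if sec.start <= pos < sec.end:
                return sec.kind
        return None

    def sentence_index_at(self, pos: int) -> Optional[int]:
        for i, sent in enumerate(self.sentences):
            if sent.start <= pos < sent.end:
                return i
        return None

    def label_assignment(self, label: str) -> LabelAssignment:
        for la in self.labels:
            if la.label == label:
                return la
        raise KeyError(label)

    def observations(self) -> list[Entity]:
        return [e for e in self.entities if e.is_observation]

    def modifiers(self) -> list[Entity]:
        return [e for e in self.entities if not e.is_observation]

    def copy(self) -> "ReportDocument":
        return copy.deepcopy(self)


def _fresh_labels() -> list[LabelAssignment]:
    return [LabelAssignment(label=name) for name in LABELS]


def read_report(text: str, report_id: str = "report") -> ReportDocument:
    """Wrap raw report text in a document with the full unselected label list."""
    if not isinstance(text, str) or not text.strip():
        raise EmptyReportError("empty report")
    return ReportDocument(report_id=report_id, raw_text=text, labels=_fresh_labels())


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


def validate_document(doc: ReportDocument) -> ReportDocument:
    """Check every structural invariant; raise :class:`ValidationError` on failure.

    Returns the document unchanged so the call can be chained.
    """
    n = len(doc.raw_text)

    if doc.sections:
        prev_end = None
        for sec in doc.sections:
            _check(0 <= sec.start < sec.end <= n, f"section span out of range: {sec}")
            if prev_end is not None:
                _check(sec.start >= prev_end, "sections overlap or are unordered")
            prev_end = sec.end

    for sent in doc.sentences:
        _check(0 <= sent.start <= sent.end <= n, "sentence span out of range")
        prev = None
        for tok in sent.tokens:
            _check(sent.start <= tok.start < tok.end <= sent.end,
                   f"token {tok.surface!r} outside its sentence")
            if prev is not None:
                _check(tok.start >= prev.end, "tokens overlap or are unordered")
            if tok.surface and tok.lemma:
                _check(bool(tok.lemma), "empty lemma on non-empty token")
            prev = tok

    ids = [e.entity_id for e in doc.entities]
    _check(len(ids) == len(set(ids)), "duplicate entity ids")
    by_id = {e.entity_id: e for e in doc.entities}

    for ent in doc.entities:
        _check(0 <= ent.start < ent.end <= n, f"entity span out of range: {ent}")
        if ent.nested_with is not None:
            _check(ent.nested_with in by_id, f"nested_with dangles: {ent.entity_id}")
            partner = by_id[ent.nested_with]
            _check(partner.nested_with == ent.entity_id, "nested_with not symmetric")
            _check((partner.start, partner.end) == (ent.start, ent.end),
                   "nested pair not co-extensive")
            _check(partner.is_observation != ent.is_observation,
                   "nested pair must span both categories")
            _check(partner.negated == ent.negated,
                   "nested pair negation flags differ")

    for cat in (True, False):
        same = sorted(
            (e for e in doc.entities if e.is_observation is cat),
            key=lambda e: e.start,
        )
        for a, b in zip(same, same[1:]):
            _check(b.start >= a.end, f"same-category entities overlap: "
                   f"{a.entity_id}/{b.entity_id}")

    for rel in doc.relations:
        _check(rel.observation in by_id, f"relation references missing entity "
               f"{rel.observation}")
        _check(rel.modifier in by_id, f"relation references missing entity "
               f"{rel.modifier}")
        obs, mod = by_id[rel.observation], by_id[rel.modifier]
        _check(obs.is_observation and not mod.is_observation,
               "relation endpoints have wrong categories")
        if rel.rtype is RelationType.MOD_LOC:
            _check(obs.etype in MOD_LOC_OBSERVATIONS,
                   f"mod-loc does not permit observation {obs.etype.value}")
            _check(mod.etype in (ModifierType.LOC_DEEP, ModifierType.LOC_CORTICAL),
                   "mod-loc requires a location modifier")
        else:
            _check(obs.etype in MOD_TIME_OBSERVATIONS,
                   f"mod-time does not permit observation {obs.etype.value}")
            _check(mod.etype in (ModifierType.TIME_OLD, ModifierType.TIME_RECENT),
                   "mod-time requires a time modifier")
        if doc.sentences:
            si_obs = doc.sentence_index_at(obs.start)
            si_mod = doc.sentence_index_at(mod.start)
            _check(si_obs is not None and si_obs == si_mod,
                   "relation endpoints span sentences")

    _check([la.label for la in doc.labels] == list(LABELS),
           "label list must contain the 24-label inventory exactly once, in order")
    for la in doc.labels:
        if la.selected:
            _check(bool(la.evidence), f"selected label {la.label!r} lacks evidence")
            for ref in la.evidence:
                if ref in by_id:
                    _check(not by_id[ref].negated,
                           f"selected label {la.label!r} cites negated entity {ref}")
    return doc


# ---------------------------------------------------------------------------
# JSON serialisation
# ---------------------------------------------------------------------------


def _etype_to_str(etype: ObservationType | ModifierType) -> str:
    return etype.value


def _etype_from_str(value: str) -> ObservationType | ModifierType:
    try:
        return ObservationType(value)
    except ValueError:
        return ModifierType(value)


def doc_to_json(doc: ReportDocument) -> str:
    """Serialise a document to a JSON string (lossless for all layers)."""
    payload = {
        "report_id": doc.report_id,
        "raw_text": doc.raw_text,
        "sections": [
            {"kind": s.kind.value, "start": s.start, "end": s.end}
            for s in doc.sections
        ],
        "sentences": [
            {
                "start": s.start,
                "end": s.end,
                "tokens": [
                    {
                        "surface": t.surface,
                        "start": t.start,
                        "end": t.end,
                        "pos_tag": t.pos_tag,
                        "lemma": t.lemma,
                        "lookup_flags": sorted(t.lookup_flags),
                    }
                    for t in s.tokens
                ],
                "chunks": [
                    {
                        "kind": c.kind,
                        "tok_start": c.tok_start,
                        "tok_end": c.tok_end,
                        "polarity": c.polarity,
                    }
                    for c in s.chunks
                ],
            }
            for s in doc.sentences
        ],
        "entities": [
            {
                "entity_id": e.entity_id,
                "etype": _etype_to_str(e.etype),
                "start": e.start,
                "end": e.end,
                "negated": e.negated,
                "nested_with": e.nested_with,
                "section_kind": e.section_kind.value if e.section_kind else None,
            }
            for e in doc.entities
        ],
        "relations": [
            {"rtype": r.rtype.value, "observation": r.observation,
             "modifier": r.modifier}
            for r in doc.relations
        ],
        "labels": [
            {"label": la.label, "selected": la.selected, "evidence": la.evidence}
            for la in doc.labels
        ],
    }
    return json.dumps(payload, indent=1)


def doc_from_json(text: str) -> ReportDocument:
    payload = json.loads(text)
    doc = ReportDocument(
        report_id=payload["report_id"],
        raw_text=payload["raw_text"],
        sections=[
            Section(SectionKind(s["kind"]), s["start"], s["end"])
            for s in payload["sections"]
        ],
        sentences=[
            Sentence(
                s["start"],
                s["end"],
                tokens=[
                    Token(
                        t["surface"], t["start"], t["end"], t["pos_tag"],
                        t["lemma"], set(t["lookup_flags"]),
                    )
                    for t in s["tokens"]
                ],
                chunks=[
                    Chunk(c["kind"], c["tok_start"], c["tok_end"], c["polarity"])
                    for c in s["chunks"]
                ],
            )
            for s in payload["sentences"]
        ],
        entities=[
            Entity(
                e["entity_id"], _etype_from_str(e["etype"]), e["start"], e["end"],
                e["negated"], e["nested_with"],
                SectionKind(e["section_kind"]) if e["section_kind"] else None,
            )
            for e in payload["entities"]
        ],
        relations=[
            Relation(RelationType(r["rtype"]), r["observation"], r["modifier"])
            for r in payload["relations"]
        ],
        labels=[
            LabelAssignment(la["label"], la["selected"], list(la["evidence"]))
            for la in payload["labels"]
        ],
    )
    return doc


# ---------------------------------------------------------------------------
# BRAT standoff serialisation
# ---------------------------------------------------------------------------

#: Type-tag spellings accepted on input, beyond the canonical value names.
#: "microhaemorrhage" is a printed synonym for the microbleed observation.
_BRAT_TYPE_ALIASES: dict[str, ObservationType | ModifierType] = {
    "microhaemorrhage": ObservationType.MICROBLEED,
}


def _brat_type_tag(etype: ObservationType | ModifierType) -> str:
    return etype.value


def _parse_brat_type(tag: str, lineno: int) -> ObservationType | ModifierType:
    key = tag.strip().lower()
    if key in _BRAT_TYPE_ALIASES:
        return _BRAT_TYPE_ALIASES[key]
    try:
        return _etype_from_str(key)
    except ValueError:
        raise BratParseError(f"line {lineno}: unknown entity type tag {tag!r}")


def write_brat(doc: ReportDocument) -> tuple[str, str]:
    """Render the annotation layers as a BRAT standoff (.ann, .txt) pair.

    T-lines carry entities, A-lines the negation attribute, R-lines
    modifier relations.  Selected labels are emitted as ``L`` lines — a
    dialect extension (``L<k>\\t<label>\\t<evidence ids>``) so that
    report-level labels survive the round trip.  Entity ids are reassigned
    in reading order (observation before a co-extensive modifier).
    """
    by_id = {e.entity_id: e for e in doc.entities}
    for rel in doc.relations:
        if rel.observation not in by_id or rel.modifier not in by_id:
            raise ReportError(
                f"dangling relation endpoint: {rel.observation}->{rel.modifier}"
            )

    ordered = sorted(doc.entities, key=lambda e: (e.start, e.end, not e.is_observation))
    new_id = {e.entity_id: f"T{i}" for i, e in enumerate(ordered, start=1)}

    lines: list[str] = []
    for ent in ordered:
        surface = doc.raw_text[ent.start : ent.end]
        if "\n" in surface:
            raise ReportError(f"entity {ent.entity_id} spans a newline")
        lines.append(
            f"{new_id[ent.entity_id]}\t{_brat_type_tag(ent.etype)} "
            f"{ent.start} {ent.end}\t{surface}"
        )
    a_count = 0
    for ent in ordered:
        if ent.negated:
            a_count += 1
            lines.append(f"A{a_count}\tNegated {new_id[ent.entity_id]}")
    for i, rel in enumerate(doc.relations, start=1):
        lines.append(
            f"R{i}\t{rel.rtype.value} Arg1:{new_id[rel.observation]} "
            f"Arg2:{new_id[rel.modifier]}"
        )
    l_count = 0
    for la in doc.labels:
        if la.selected:
            l_count += 1
            evidence = " ".join(new_id.get(ref, ref) for ref in la.evidence)
            lines.append(f"L{l_count}\t{la.label}\t{evidence}")
    return "\n".join(lines) + ("\n" if lines else ""), doc.raw_text


def parse_brat(ann_text: str, txt_text: str,
               report_id: str = "report") -> ReportDocument:
    """Parse a standoff (.ann, .txt) pair into a document.

    Inverse of :func:`write_brat` on its image (entity ids are taken from
    the file).  Malformed lines raise :class:`BratParseError` naming the
    offending line number.
    """
    doc = read_report(txt_text, report_id=report_id)
    entities: dict[str, Entity] = {}
    relations: list[Relation] = []
    selected_labels: list[tuple[str, list[str]]] = []
    negated_ids: list[tuple[str, int]] = []

    for lineno, raw in enumerate(ann_text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        tag = fields[0]
        if tag.startswith("T"):
            if len(fields) < 3:
                raise BratParseError(f"line {lineno}: malformed T-line")
            try:
                type_tag, start_s, end_s = fields[1].split(" ")
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise BratParseError(f"line {lineno}: malformed T-line spec")
            if not (0 <= start < end <= len(txt_text)):
                raise BratParseError(
                    f"line {lineno}: offsets [{start},{end}) outside text"
                )
            etype = _parse_brat_type(type_tag, lineno)
            surface = fields[2]
            if txt_text[start:end] != surface:
                raise BratParseError(
                    f"line {lineno}: surface {surface!r} does not match text "
                    f"slice {txt_text[start:end]!r}"
                )
            if tag in entities:
                raise BratParseError(f"line {lineno}: duplicate id {tag}")
            entities[tag] = Entity(tag, etype, start, end)
        elif tag.startswith("A"):
            if len(fields) < 2:
                raise BratParseError(f"line {lineno}: malformed A-line")
            parts = fields[1].split(" ")
            if len(parts) != 2 or parts[0].lower() != "negated":
                raise BratParseError(f"line {lineno}: unsupported attribute")
            negated_ids.append((parts[1], lineno))
        elif tag.startswith("R"):
            if len(fields) < 2:
                raise BratParseError(f"line {lineno}: malformed R-line")
            parts = fields[1].split(" ")
            if len(parts) != 3:
                raise BratParseError(f"line {lineno}: malformed R-line spec")
            try:
                rtype = RelationType(parts[0])
            except ValueError:
                raise BratParseError(
                    f"line {lineno}: unknown relation type {parts[0]!r}"
                )
            args = {}
            for part in parts[1:]:
                if ":" not in part:
                    raise BratParseError(f"line {lineno}: malformed argument")
                k, v = part.split(":", 1)
                args[k] = v
            if set(args) != {"Arg1", "Arg2"}:
                raise BratParseError(f"line {lineno}: R-line needs Arg1 and Arg2")
            relations.append(Relation(rtype, args["Arg1"], args["Arg2"]))
        elif tag.startswith("L"):
            if len(fields) < 2:
                raise BratParseError(f"line {lineno}: malformed L-line")
            label = fields[1]
            if label not in LABELS:
                raise BratParseError(f"line {lineno}: unknown label {label!r}")
            evidence = fields[2].split() if len(fields) > 2 and fields[2] else []
            selected_labels.append((label, evidence))
        else:
            raise BratParseError(f"line {lineno}: unrecognised line prefix {tag!r}")

    for eid, lineno in negated_ids:
        if eid not in entities:
            raise BratParseError(f"line {lineno}: attribute references missing "
                                 f"entity {eid}")
        entities[eid].negated = True
    for rel in relations:
        for eid in (rel.observation, rel.modifier):
            if eid not in entities:
                raise BratParseError(f"relation references missing entity {eid}")

    # reconstruct nesting from co-extensive observation/modifier pairs
    by_span: dict[tuple[int, int], list[Entity]] = {}
    for ent in entities.values():
        by_span.setdefault((ent.start, ent.end), []).append(ent)
    for group in by_span.values():
        obs = [e for e in group if e.is_observation]
        mods = [e for e in group if not e.is_observation]
        if len(obs) == 1 and len(mods) == 1:
            obs[0].nested_with = mods[0].entity_id
            mods[0].nested_with = obs[0].entity_id

    doc.entities = sorted(
        entities.values(), key=lambda e: (e.start, e.end, not e.is_observation)
    )
    doc.relations = relations
    for label, evidence in selected_labels:
        la = doc.label_assignment(label)
        la.selected = True
        la.evidence = evidence
    return doc


# ---------------------------------------------------------------------------
# Inline XML writer (dialect neurolabel-xml-1)
# ---------------------------------------------------------------------------


def write_xml(doc: ReportDocument) -> str:
    """Serialise a document as inline XML.

    Sections are elements wrapping their tokenised sentences; the 24
    labels appear as attributed metadata elements; entities and relations
    are standoff elements referencing character offsets and entity ids.
    """
    root = etree.Element("report", id=doc.report_id, schema="neurolabel-xml-1")
    labels_el = etree.SubElement(root, "labels")
    for la in doc.labels:
        etree.SubElement(
            labels_el, "label", name=la.label,
            selected="true" if la.selected else "false",
        )
    for sec in doc.sections or [Section(SectionKind.OTHER, 0, len(doc.raw_text))]:
        sec_el = etree.SubElement(root, "section", kind=sec.kind.value,
                                  start=str(sec.start), end=str(sec.end))
        for sent in doc.sentences:
            if not (sec.start <= sent.start < sec.end):
                continue
            s_el = etree.SubElement(sec_el, "s", start=str(sent.start),
                                    end=str(sent.end))
            for tok in sent.tokens:
                w = etree.SubElement(s_el, "w", start=str(tok.start),
                                     end=str(tok.end))
                if tok.pos_tag:
                    w.set("p", tok.pos_tag)
                if tok.lemma:
                    w.set("l", tok.lemma)
                w.text = tok.surface
        if not doc.sentences:
            sec_el.text = doc.raw_text[sec.start : sec.end]
    ents_el = etree.SubElement(root, "entities")
    for ent in doc.entities:
        e = etree.SubElement(
            ents_el, "entity", id=ent.entity_id, type=ent.etype.value,
            start=str(ent.start), end=str(ent.end),
            negated="true" if ent.negated else "false",
        )
        if ent.nested_with:
            e.set("nested", ent.nested_with)
    rels_el = etree.SubElement(root, "relations")
    for rel in doc.relations:
        etree.SubElement(rels_el, "relation", type=rel.rtype.value,
                         observation=rel.observation, modifier=rel.modifier)
    return etree.tostring(root, pretty_print=True, encoding="unicode")
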