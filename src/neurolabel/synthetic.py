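"""Seedable generator of radiology-style reports with gold annotations.

The real corpora this package targets are access-restricted hospital
records, so every pipeline stage and the scorer are exercised against
synthetic reports instead: short multi-sentence documents with a
clinical-details preamble, a findings body and a conclusion, containing
observation mentions, location/time modifiers, coordinated negated noun
groups and hedged non-exclusions.  The default scale (a handful of
sentences, on the order of 90 words per report) mirrors the short
dictated reports typical of stroke registries.

Templates are sentence skeletons with slots instantiated only from the
shipped lexicon surface forms, so generated constructions stay within
what the rules cover, while still exercising coordination, nesting and
hedging; the generator records the gold annotation as it writes the
text.  What the generator does **not** emulate: typographical noise,
out-of-lexicon synonyms, long-range negation and free dictated prose —
perfect scores on synthetic data therefore demonstrate internal
consistency of rules and scorer, not real-world accuracy.

A corruption operator applies counted single-unit perturbations to a
document (drop an entity, shift a span, flip a negation, ...), which is
how the scorer's counting is tested against predicted deltas.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .model import (
    Entity,
    LabelAssignment,
    LABELS,
    ModifierType,
    ObservationType,
    Relation,
    RelationType,
    ReportDocument,
    Section,
    SectionKind,
    STROKE_TYPES,
    validate_document,
)

__all__ = ["GeneratorSpec", "GeneratedReport", "generate", "corruption",
           "CorruptionError"]


class CorruptionError(ValueError):
    """More corruptions requested than units available."""


# ---------------------------------------------------------------------------
# Surface inventories (all drawn from the shipped lexicons)
# ---------------------------------------------------------------------------

_OBS_SURFACES: dict[ObservationType, list[str]] = {
    ObservationType.ISCHAEMIC_STROKE: ["infarct", "infarction"],
    ObservationType.HAEMORRHAGIC_STROKE: ["haemorrhage", "haematoma"],
    ObservationType.STROKE_UNKNOWN: ["stroke"],
    ObservationType.TUMOUR_MENINGIOMA: ["meningioma"],
    ObservationType.TUMOUR_METASTASIS: ["metastasis"],
    ObservationType.TUMOUR_GLIOMA: ["glioma"],
    ObservationType.TUMOUR: ["mass", "lesion", "tumour"],
    ObservationType.SUBDURAL_HAEMATOMA: ["subdural haematoma",
                                         "extra-axial collection"],
    ObservationType.SMALL_VESSEL_DISEASE: ["small vessel disease"],
    ObservationType.ATROPHY: ["atrophy", "volume loss"],
    ObservationType.MICROBLEED: ["microbleed", "microhaemorrhage"],
    ObservationType.SUBARACHNOID_HAEMORRHAGE: ["subarachnoid haemorrhage"],
    ObservationType.HAEMORRHAGIC_TRANSFORMATION: ["haemorrhagic transformation"],
}

_LOC_SURFACES = {
    "deep": [("deep", ModifierType.LOC_DEEP),
             ("thalamic", ModifierType.LOC_DEEP),
             ("lacunar", ModifierType.LOC_DEEP)],
    "cortical": [("cortical", ModifierType.LOC_CORTICAL),
                 ("frontal", ModifierType.LOC_CORTICAL),
                 ("parietal", ModifierType.LOC_CORTICAL),
                 ("occipital", ModifierType.LOC_CORTICAL)],
}

_TIME_SURFACES = {
    "old": [("old", ModifierType.TIME_OLD),
            ("previous", ModifierType.TIME_OLD),
            ("established", ModifierType.TIME_OLD),
            ("chronic", ModifierType.TIME_OLD)],
    "recent": [("acute", ModifierType.TIME_RECENT),
               ("recent", ModifierType.TIME_RECENT),
               ("new", ModifierType.TIME_RECENT)],
}

_COMPLAINTS = [
    "Sudden onset weakness",
    "Left sided weakness",
    "Confusion and reduced mobility",
    "Collapse at home",
    "Worsening headache",
    "Speech disturbance",
]

_NOISE_SENTENCES = [
    "The ventricles are of normal size.",
    "No midline shift.",
    "Scan quality is limited by movement.",
    "Normal intracranial appearances otherwise.",
]

#: Observation types selectable by bare presence (no modifier slots).
_PRESENCE_TYPES = (
    ObservationType.TUMOUR_MENINGIOMA,
    ObservationType.TUMOUR_METASTASIS,
    ObservationType.TUMOUR_GLIOMA,
    ObservationType.TUMOUR,
    ObservationType.SUBDURAL_HAEMATOMA,
    ObservationType.SMALL_VESSEL_DISEASE,
    ObservationType.ATROPHY,
    ObservationType.SUBARACHNOID_HAEMORRHAGE,
    ObservationType.HAEMORRHAGIC_TRANSFORMATION,
)

_ALL_TEMPLATES = ("affirmative", "coordination", "hedge", "verbal",
                  "nested", "aneurysmal")


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for report generation.

    Frequencies approximate a stroke-register case mix: ischaemic
    disease, small vessel disease and atrophy dominate; tumour subtypes
    and rarities are infrequent.  Roughly a third of observation
    mentions are negated, matching the positive/negative balance seen
    in annotated stroke-register reports.
    """

    seed: int = 0
    n_reports: int = 25
    obs_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "ischaemic_stroke": 0.28,
            "small_vessel_disease": 0.15,
            "atrophy": 0.13,
            "haemorrhagic_stroke": 0.10,
            "stroke_unknown": 0.06,
            "tumour": 0.06,
            "subdural_haematoma": 0.05,
            "tumour_meningioma": 0.03,
            "tumour_metastasis": 0.03,
            "tumour_glioma": 0.02,
            "microbleed": 0.04,
            "subarachnoid_haemorrhage": 0.03,
            "haemorrhagic_transformation": 0.02,
        }
    )
    p_negated_group: float = 0.25
    p_hedge: float = 0.08
    p_verbal: float = 0.06
    coordination_weights: tuple[float, float, float] = (0.6, 0.25, 0.15)
    p_loc: float = 0.55
    p_time: float = 0.6
    p_clinical_details: float = 0.9
    p_conclusion: float = 0.8
    p_noise_sentence: float = 0.25
    sentences_per_body: tuple[int, int] = (3, 6)
    templates: tuple[str, ...] = _ALL_TEMPLATES

    def __post_init__(self) -> None:
        for name, p in (
            ("p_negated_group", self.p_negated_group),
            ("p_hedge", self.p_hedge),
            ("p_verbal", self.p_verbal),
            ("p_loc", self.p_loc),
            ("p_time", self.p_time),
            ("p_clinical_details", self.p_clinical_details),
            ("p_conclusion", self.p_conclusion),
            ("p_noise_sentence", self.p_noise_sentence),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be within [0, 1]")
        weights = dict(self.obs_weights)
        if any(w < 0 for w in weights.values()) or not any(weights.values()):
            raise ValueError("obs_weights must be non-negative, not all zero")
        unknown = set(self.templates) - set(_ALL_TEMPLATES)
        if unknown:
            raise ValueError(f"unknown templates: {sorted(unknown)}")


@dataclass
class GeneratedReport:
    report_id: str
    text: str
    gold: ReportDocument


# ---------------------------------------------------------------------------
# Document builder
# ---------------------------------------------------------------------------


class _Builder:
    def __init__(self, report_id: str) -> None:
        self.report_id = report_id
        self.parts: list[str] = []
        self.pos = 0
        self.entities: list[Entity] = []
        self.relations: list[tuple[RelationType, int, int]] = []  # (obs, mod) idx
        self.section_marks: list[tuple[SectionKind, int]] = []
        self.selected: dict[str, list[int]] = {}  # label -> entity indexes

    def write(self, s: str) -> None:
        self.parts.append(s)
        self.pos += len(s)

    def start_section(self, kind: SectionKind) -> None:
        self.section_marks.append((kind, self.pos))

    def entity(self, surface: str, etype, negated: bool = False,
               nested_with: Optional[int] = None) -> int:
        idx = len(self.entities)
        ent = Entity(
            entity_id=f"T{idx + 1}",
            etype=etype,
            start=self.pos,
            end=self.pos + len(surface),
            negated=negated,
            section_kind=self.section_marks[-1][0] if self.section_marks else None,
        )
        if nested_with is not None:
            partner = self.entities[nested_with]
            ent.nested_with = partner.entity_id
            partner.nested_with = ent.entity_id
            ent.start, ent.end = partner.start, partner.end
        else:
            self.write(surface)
        self.entities.append(ent)
        return idx

    def relation(self, rtype: RelationType, obs_idx: int, mod_idx: int) -> None:
        self.relations.append((rtype, obs_idx, mod_idx))

    def select(self, label: str, evidence: Sequence[int]) -> None:
        slot = self.selected.setdefault(label, [])
        for idx in evidence:
            if idx not in slot:
                slot.append(idx)

    def finish(self) -> ReportDocument:
        text = "".join(self.parts)
        sections = []
        for i, (kind, start) in enumerate(self.section_marks):
            end = (self.section_marks[i + 1][1]
                   if i + 1 < len(self.section_marks) else len(text))
            sections.append(Section(kind, start, end))
        labels = []
        for name in LABELS:
            evidence_idx = self.selected.get(name)
            labels.append(
                LabelAssignment(
                    label=name,
                    selected=evidence_idx is not None,
                    evidence=[self.entities[i].entity_id
                              for i in evidence_idx] if evidence_idx else [],
                )
            )
        doc = ReportDocument(
            report_id=self.report_id,
            raw_text=text,
            sections=sections,
            entities=list(self.entities),
            relations=[
                Relation(rtype, self.entities[o].entity_id,
                         self.entities[m].entity_id)
                for rtype, o, m in self.relations
            ],
            labels=labels,
        )
        return doc


def _label_for(otype: ObservationType, loc: Optional[str],
               time: Optional[str], aneurysmal: bool = False) -> Optional[str]:
    """Template semantics: which label a positive observation selects."""
    if otype is ObservationType.ISCHAEMIC_STROKE:
        if loc == "deep":
            return f"Ischaemic stroke, deep, {time or 'old'}"
        if loc == "cortical" and time:
            return f"Ischaemic stroke, cortical, {time}"
        return "Ischaemic stroke, underspecified"
    if otype is ObservationType.HAEMORRHAGIC_STROKE:
        side = {"deep": "deep", "cortical": "lobar"}.get(loc or "")
        if side and time:
            return f"Haemorrhagic stroke, {side}, {time}"
        return "Haemorrhagic stroke, underspecified"
    if otype is ObservationType.STROKE_UNKNOWN:
        return "Stroke, underspecified"
    if otype is ObservationType.MICROBLEED:
        side = {"deep": "deep", "cortical": "lobar"}.get(loc or "")
        return f"Microbleed, {side}" if side else "Microbleed, underspecified"
    if otype is ObservationType.SUBARACHNOID_HAEMORRHAGE:
        return ("Subarachnoid haemorrhage, aneurysmal" if aneurysmal
                else "Subarachnoid haemorrhage, other")
    return {
        ObservationType.TUMOUR_MENINGIOMA: "Tumour, meningioma",
        ObservationType.TUMOUR_METASTASIS: "Tumour, metastasis",
        ObservationType.TUMOUR_GLIOMA: "Tumour, glioma",
        ObservationType.TUMOUR: "Tumour, other",
        ObservationType.SUBDURAL_HAEMATOMA: "Subdural haematoma",
        ObservationType.SMALL_VESSEL_DISEASE: "Small vessel disease",
        ObservationType.ATROPHY: "Atrophy",
        ObservationType.HAEMORRHAGIC_TRANSFORMATION: "Haemorrhagic transformation",
    }[otype]


# ---------------------------------------------------------------------------
# Sentence templates
# ---------------------------------------------------------------------------


def _pick_obs(rng: random.Random, spec: GeneratorSpec,
              pool: Optional[Sequence[ObservationType]] = None) -> ObservationType:
    weights = dict(spec.obs_weights)
    types = [ObservationType(k) for k in sorted(weights)]
    if pool is not None:
        types = [t for t in types if t in pool]
    if not types:
        types = list(pool or ObservationType)
    w = [weights.get(t.value, 0.0) or 1e-9 for t in types]
    return rng.choices(types, weights=w, k=1)[0]


def _modifier_slots(rng: random.Random, spec: GeneratorSpec,
                    otype: ObservationType) -> tuple[
                        Optional[tuple[str, ModifierType, str]],
                        Optional[tuple[str, ModifierType, str]]]:
    """(time_slot, loc_slot), each (surface, mtype, value) or None."""
    time_slot = loc_slot = None
    if otype in STROKE_TYPES and rng.random() < spec.p_time:
        value = rng.choice(["old", "recent"])
        surface, mtype = rng.choice(_TIME_SURFACES[value])
        time_slot = (surface, mtype, value)
    if (otype in STROKE_TYPES or otype is ObservationType.MICROBLEED) \
            and rng.random() < spec.p_loc:
        value = rng.choice(["deep", "cortical"])
        surface, mtype = rng.choice(_LOC_SURFACES[value])
        loc_slot = (surface, mtype, value)
    return time_slot, loc_slot


def _capitalise(word: str) -> str:
    return word[0].upper() + word[1:]


def _sentence_affirmative(b: _Builder, rng: random.Random,
                          spec: GeneratorSpec) -> None:
    otype = _pick_obs(rng, spec)
    surface = rng.choice(_OBS_SURFACES[otype])
    time_slot, loc_slot = _modifier_slots(rng, spec, otype)
    frame = rng.choice(["noted", "there_is"])

    first = True
    if frame == "there_is":
        b.write("There is ")
        first = False
    obs_idx = None
    evidence: list[int] = []
    if time_slot:
        word = _capitalise(time_slot[0]) if first else time_slot[0]
        t_idx = b.entity(word, time_slot[1])
        evidence.append(t_idx)
        b.write(" ")
        first = False
    if loc_slot:
        word = _capitalise(loc_slot[0]) if first else loc_slot[0]
        l_idx = b.entity(word, loc_slot[1])
        evidence.append(l_idx)
        b.write(" ")
        first = False
    word = _capitalise(surface) if first else surface
    obs_idx = b.entity(word, otype)
    if time_slot:
        b.relation(RelationType.MOD_TIME, obs_idx, evidence[0])
    if loc_slot:
        b.relation(RelationType.MOD_LOC, obs_idx,
                   evidence[1] if time_slot else evidence[0])
    if frame == "noted":
        b.write(" noted")
    b.write(".")
    label = _label_for(otype, loc_slot[2] if loc_slot else None,
                       time_slot[2] if time_slot else None)
    if label:
        used = [obs_idx]
        if loc_slot and label.split(", ")[-1] != "underspecified":
            used.append(evidence[1] if time_slot else evidence[0])
        if time_slot and "underspecified" not in label:
            used.append(evidence[0])
        b.select(label, used)


def _sentence_coordination(b: _Builder, rng: random.Random,
                           spec: GeneratorSpec) -> None:
    width = rng.choices([1, 2, 3], weights=spec.coordination_weights, k=1)[0]
    types: list[ObservationType] = []
    while len(types) < width:
        t = _pick_obs(rng, spec)
        if t not in types:
            types.append(t)
    with_time = types[0] in STROKE_TYPES and rng.random() < spec.p_time
    b.write("No ")
    time_idx = None
    if with_time:
        value = rng.choice(["old", "recent"])
        surface, mtype = rng.choice(_TIME_SURFACES[value])
        time_idx = b.entity(surface, mtype, negated=True)
        b.write(" ")
    obs_indexes = []
    for i, t in enumerate(types):
        if i == 1 and width == 3:
            b.write(", ")
        elif i > 0:
            b.write(" or ")
        obs_indexes.append(b.entity(rng.choice(_OBS_SURFACES[t]), t,
                                    negated=True))
    if time_idx is not None:
        b.relation(RelationType.MOD_TIME, obs_indexes[0], time_idx)
    b.write(" " + rng.choice(["seen", "identified"]) + ".")


def _sentence_hedge(b: _Builder, rng: random.Random,
                    spec: GeneratorSpec) -> None:
    otype = _pick_obs(rng, spec, pool=tuple(STROKE_TYPES) + _PRESENCE_TYPES)
    surface = rng.choice(_OBS_SURFACES[otype])
    form = rng.choice(["focus", "object"])
    if form == "focus":
        b.write("A small focus of ")
        time_idx = None
        if otype in STROKE_TYPES and rng.random() < spec.p_time:
            value = rng.choice(["old", "recent"])
            t_surface, mtype = rng.choice(_TIME_SURFACES[value])
            time_idx = b.entity(t_surface, mtype, negated=True)
            b.write(" ")
        obs_idx = b.entity(surface, otype, negated=True)
        if time_idx is not None:
            b.relation(RelationType.MOD_TIME, obs_idx, time_idx)
        b.write(" cannot be completely excluded.")
    else:
        b.write("Cannot exclude ")
        b.entity(surface, otype, negated=True)
        b.write(".")


def _sentence_verbal(b: _Builder, rng: random.Random,
                     spec: GeneratorSpec) -> None:
    otype = _pick_obs(rng, spec, pool=tuple(STROKE_TYPES))
    surface = rng.choice(_OBS_SURFACES[otype])
    time_idx = None
    if rng.random() < spec.p_time:
        value = rng.choice(["old", "recent"])
        t_surface, mtype = rng.choice(_TIME_SURFACES[value])
        b.write("Very ")
        time_idx = b.entity(t_surface, mtype, negated=True)
        b.write(" ")
        obs_idx = b.entity(surface, otype, negated=True)
    else:
        obs_idx = b.entity(_capitalise(surface), otype, negated=True)
    if time_idx is not None:
        b.relation(RelationType.MOD_TIME, obs_idx, time_idx)
    b.write(" may not be visible on CT.")


def _sentence_nested(b: _Builder, rng: random.Random,
                     spec: GeneratorSpec) -> None:
    time_slot = None
    t_idx = None
    if rng.random() < spec.p_time:
        value = rng.choice(["old", "recent"])
        surface, mtype = rng.choice(_TIME_SURFACES[value])
        time_slot = (surface, mtype, value)
        t_idx = b.entity(_capitalise(surface), mtype)
        b.write(" ")
    obs_idx = b.entity("POCI", ObservationType.ISCHAEMIC_STROKE)
    mod_idx = b.entity("POCI", ModifierType.LOC_CORTICAL, nested_with=obs_idx)
    b.write(".")
    if time_slot:
        b.relation(RelationType.MOD_TIME, obs_idx, t_idx)
        label = _label_for(ObservationType.ISCHAEMIC_STROKE, "cortical",
                           time_slot[2])
        b.select(label, [obs_idx, mod_idx, t_idx])
    else:
        b.select("Ischaemic stroke, underspecified", [obs_idx])


def _sentence_aneurysmal(b: _Builder, rng: random.Random,
                         spec: GeneratorSpec) -> None:
    surface = "Subarachnoid haemorrhage"
    obs_idx = b.entity(surface, ObservationType.SUBARACHNOID_HAEMORRHAGE)
    b.write(" with underlying aneurysm.")
    b.select("Subarachnoid haemorrhage, aneurysmal", [obs_idx])


def _sentence_conclusion(b: _Builder, rng: random.Random,
                         spec: GeneratorSpec) -> None:
    otype = _pick_obs(rng, spec, pool=_PRESENCE_TYPES)
    surface = rng.choice(_OBS_SURFACES[otype])
    b.write("Appearances are in keeping with ")
    obs_idx = b.entity(surface, otype)
    b.write(".")
    label = _label_for(otype, None, None)
    if label:
        b.select(label, [obs_idx])


def _finding_sentence(b: _Builder, rng: random.Random,
                      spec: GeneratorSpec) -> None:
    enabled = spec.templates
    if "hedge" in enabled and rng.random() < spec.p_hedge:
        _sentence_hedge(b, rng, spec)
        return
    if "verbal" in enabled and rng.random() < spec.p_verbal:
        _sentence_verbal(b, rng, spec)
        return
    if "coordination" in enabled and rng.random() < spec.p_negated_group:
        _sentence_coordination(b, rng, spec)
        return
    pool = [t for t in ("affirmative", "nested", "aneurysmal") if t in enabled]
    if not pool:
        # only negated templates enabled: fall back deterministically
        for name in ("coordination", "hedge", "verbal"):
            if name in enabled:
                {"coordination": _sentence_coordination,
                 "hedge": _sentence_hedge,
                 "verbal": _sentence_verbal}[name](b, rng, spec)
                return
        raise ValueError("no templates enabled")
    choice = rng.choices(pool, weights=[0.85, 0.1, 0.05][: len(pool)], k=1)[0]
    {"affirmative": _sentence_affirmative,
     "nested": _sentence_nested,
     "aneurysmal": _sentence_aneurysmal}[choice](b, rng, spec)


# ---------------------------------------------------------------------------
# Report generation
# ---------------------------------------------------------------------------


def _generate_one(report_id: str, rng: random.Random,
                  spec: GeneratorSpec) -> GeneratedReport:
    b = _Builder(report_id)
    if rng.random() < spec.p_clinical_details:
        b.start_section(SectionKind.CLINICAL_DETAILS)
        b.write(f"Clinical details: {rng.choice(_COMPLAINTS)}.\n")
    b.start_section(SectionKind.REPORT_BODY)
    b.write("Report:\n")
    lo, hi = spec.sentences_per_body
    for _ in range(rng.randint(lo, hi)):
        if rng.random() < spec.p_noise_sentence:
            b.write(rng.choice(_NOISE_SENTENCES))
        else:
            _finding_sentence(b, rng, spec)
        b.write("\n")
    if rng.random() < spec.p_conclusion:
        b.start_section(SectionKind.CONCLUSION)
        b.write("Conclusion:\n")
        _sentence_conclusion(b, rng, spec)
        b.write("\n")
    gold = validate_document(b.finish())
    return GeneratedReport(report_id, gold.raw_text, gold)


def generate(spec: GeneratorSpec) -> list[GeneratedReport]:
    """Deterministic collection of (text, gold document) pairs."""
    rng = random.Random(spec.seed)
    return [
        _generate_one(f"synthetic-{i:04d}", rng, spec)
        for i in range(spec.n_reports)
    ]


# ---------------------------------------------------------------------------
# Corruption operator (for scorer testing)
# ---------------------------------------------------------------------------

_CORRUPTION_OPS = ("drop_entity", "shift_span", "flip_negation", "retype",
                   "drop_relation", "toggle_label")


def _retype(ent: Entity) -> None:
    family = ObservationType if ent.is_observation else ModifierType
    members = list(family)
    i = members.index(ent.etype)
    ent.etype = members[(i + 1) % len(members)]


def corruption(doc: ReportDocument, ops: Mapping[str, int],
               seed: int = 0) -> ReportDocument:
    """Apply counted single-unit perturbations to a copy of ``doc``.

    ``ops`` maps operation names (drop_entity, shift_span, flip_negation,
    retype, drop_relation, toggle_label) to counts.  Raises
    :class:`CorruptionError` when more corruptions are requested than
    units exist.
    """
    unknown = set(ops) - set(_CORRUPTION_OPS)
    if unknown:
        raise CorruptionError(f"unknown corruption ops: {sorted(unknown)}")
    out = doc.copy()
    rng = random.Random(seed)

    entity_budget = (ops.get("drop_entity", 0) + ops.get("shift_span", 0)
                     + ops.get("flip_negation", 0) + ops.get("retype", 0))
    if entity_budget > len(out.entities):
        raise CorruptionError(
            f"{entity_budget} entity corruptions requested but only "
            f"{len(out.entities)} entities available"
        )
    if ops.get("drop_relation", 0) > len(out.relations):
        raise CorruptionError("not enough relations to drop")
    if ops.get("toggle_label", 0) > len(out.labels):
        raise CorruptionError("not enough labels to toggle")

    # each entity is perturbed at most once, so deltas stay predictable
    pool = list(range(len(out.entities)))
    rng.shuffle(pool)

    def take_entities(n: int) -> list[Entity]:
        return [out.entities[pool.pop()] for _ in range(n)]

    for ent in take_entities(ops.get("shift_span", 0)):
        if ent.end + 1 <= len(out.raw_text):
            ent.start, ent.end = ent.start + 1, ent.end + 1
        else:
            ent.start, ent.end = ent.start - 1, ent.end - 1
    for ent in take_entities(ops.get("flip_negation", 0)):
        ent.negated = not ent.negated
    for ent in take_entities(ops.get("retype", 0)):
        _retype(ent)
    for ent in take_entities(ops.get("drop_entity", 0)):
        out.entities = [e for e in out.entities if e.entity_id != ent.entity_id]
        out.relations = [
            r for r in out.relations
            if ent.entity_id not in (r.observation, r.modifier)
        ]
        for la in out.labels:
            la.evidence = [ref for ref in la.evidence if ref != ent.entity_id]
        if ent.nested_with is not None:
            try:
                out.entity_by_id(ent.nested_with).nested_with = None
            except KeyError:
                pass

    rel_idx = list(range(len(out.relations)))
    rng.shuffle(rel_idx)
    drop = set(rel_idx[: ops.get("drop_relation", 0)])
    out.relations = [r for i, r in enumerate(out.relations) if i not in drop]

    lab_idx = list(range(len(out.labels)))
    rng.shuffle(lab_idx)
    for i in lab_idx[: ops.get("toggle_label", 0)]:
        la = out.labels[i]
        la.selected = not la.selected
        if not la.selected:
            la.evidence = []
        elif not la.evidence:
            la.evidence = ["corrupted"]
    return out
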