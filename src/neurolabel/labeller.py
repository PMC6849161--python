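"""Report-level phenotype labelling.

Labels are derived only from non-negated observation entities found in
the findings body or the conclusion — never from the clinical-details
preamble, and never from hedged or negated mentions, because only
clearly positive observations should contribute.

The rule table is declarative (packaged ``label_rules.yaml``) so the
mapping from entities to labels can be audited and replaced without
touching code.  Rule semantics per label family:

* simple-presence labels (small vessel disease, atrophy, subdural
  haematoma, haemorrhagic transformation, tumour subtypes) fire on a
  non-negated observation of the type; a generic tumour mention selects
  "Tumour, other";
* stroke labels combine observation type × location value (deep /
  cortical, the latter printed "lobar" for haemorrhagic stroke) × time
  value, where location and time come from explicit relations or from a
  co-extensive nested modifier; a deep ischaemic stroke without an
  explicit time relation defaults to old; anything unresolvable falls
  back to that type's underspecified label, and a stroke of unknown
  type selects "Stroke, underspecified";
* microbleed labels use the location value only (deep / lobar /
  underspecified) — microbleeds carry no time dimension;
* subarachnoid haemorrhage is "aneurysmal" only when an aneurysm cue
  occurs in the same sentence, else "other".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .model import (
    Entity,
    LABELS,
    ModifierType,
    ObservationType,
    RelationType,
    ReportDocument,
    SectionKind,
)
from .resources import read_data

__all__ = ["LabelRule", "LabelRuleTable", "load_label_rules", "assign_labels",
           "explain"]

_LABEL_SECTIONS = {SectionKind.REPORT_BODY, SectionKind.CONCLUSION}

_LOC_VALUE = {ModifierType.LOC_DEEP: "deep", ModifierType.LOC_CORTICAL: "cortical"}
_TIME_VALUE = {ModifierType.TIME_OLD: "old", ModifierType.TIME_RECENT: "recent"}


@dataclass(frozen=True)
class LabelRule:
    label: str
    observation: ObservationType
    location: Optional[str] = None  # "deep" | "cortical"
    time: Optional[str] = None  # "old" | "recent"
    default_when_no_time: bool = False
    presence: bool = False
    underspecified: bool = False
    context_cue: Optional[str] = None
    context_cue_absent: Optional[str] = None


@dataclass
class LabelRuleTable:
    rules: list[LabelRule] = field(default_factory=list)

    def for_observation(self, otype: ObservationType) -> list[LabelRule]:
        return [r for r in self.rules if r.observation is otype]


def load_label_rules(path: Optional[str | Path] = None) -> LabelRuleTable:
    """Load the declarative rule table (packaged default when no path)."""
    text = read_data("label_rules.yaml") if path is None else Path(path).read_text()
    payload = yaml.safe_load(text)
    rules = []
    for row in payload["rules"]:
        row = dict(row)
        label = row.pop("label")
        if label not in LABELS:
            raise ValueError(f"unknown label in rule table: {label!r}")
        observation = ObservationType(row.pop("observation"))
        rules.append(LabelRule(label=label, observation=observation, **row))
    return LabelRuleTable(rules)


def _resolved_values(doc: ReportDocument, obs: Entity
                     ) -> tuple[Optional[str], Optional[str], list[str]]:
    """(location, time, supporting modifier ids) for one observation.

    Values come from explicit relations or the nested partner; negated
    modifiers never contribute.
    """
    loc = time = None
    support: list[str] = []
    for rel in doc.relations:
        if rel.observation != obs.entity_id:
            continue
        mod = doc.entity_by_id(rel.modifier)
        if mod.negated:
            continue
        if rel.rtype is RelationType.MOD_LOC and loc is None:
            loc = _LOC_VALUE[mod.etype]
            support.append(mod.entity_id)
        elif rel.rtype is RelationType.MOD_TIME and time is None:
            time = _TIME_VALUE[mod.etype]
            support.append(mod.entity_id)
    if obs.nested_with is not None:
        partner = doc.entity_by_id(obs.nested_with)
        if not partner.negated:
            if partner.etype in _LOC_VALUE and loc is None:
                loc = _LOC_VALUE[partner.etype]
                support.append(partner.entity_id)
            elif partner.etype in _TIME_VALUE and time is None:
                time = _TIME_VALUE[partner.etype]
                support.append(partner.entity_id)
    return loc, time, support


def _sentence_has_cue(doc: ReportDocument, obs: Entity, cue: str) -> bool:
    si = doc.sentence_index_at(obs.start)
    if si is None:
        return False
    return any(
        tok.lemma.startswith(cue) or tok.surface.lower().startswith(cue)
        for tok in doc.sentences[si].tokens
    )


def _rule_for(doc: ReportDocument, obs: Entity, rules: LabelRuleTable
              ) -> tuple[Optional[LabelRule], list[str]]:
    """Pick the single rule an observation satisfies, with its evidence."""
    loc, time, support = _resolved_values(doc, obs)
    fallback = None
    for rule in rules.for_observation(obs.etype):
        if rule.underspecified:
            fallback = rule
            continue
        if rule.presence:
            return rule, [obs.entity_id]
        if rule.context_cue is not None:
            if _sentence_has_cue(doc, obs, rule.context_cue):
                return rule, [obs.entity_id]
            continue
        if rule.context_cue_absent is not None:
            if not _sentence_has_cue(doc, obs, rule.context_cue_absent):
                return rule, [obs.entity_id]
            continue
        if rule.location is not None and loc != rule.location:
            continue
        if rule.time is not None:
            if time == rule.time:
                return rule, [obs.entity_id] + support
            if time is None and rule.default_when_no_time:
                return rule, [obs.entity_id] + support
            continue
        # location-only rule (microbleed family)
        if rule.location is not None:
            return rule, [obs.entity_id] + support
    if fallback is not None:
        return fallback, [obs.entity_id] + support
    return None, []


def assign_labels(doc: ReportDocument,
                  rules: Optional[LabelRuleTable] = None) -> ReportDocument:
    """Set the selected flag and evidence on each of the 24 labels."""
    if rules is None:
        rules = load_label_rules()
    for la in doc.labels:
        la.selected = False
        la.evidence = []
    for obs in doc.observations():
        if obs.negated:
            continue
        if obs.section_kind not in _LABEL_SECTIONS:
            continue
        rule, evidence = _rule_for(doc, obs, rules)
        if rule is None:
            continue
        la = doc.label_assignment(rule.label)
        la.selected = True
        for ref in evidence:
            if ref not in la.evidence:
                la.evidence.append(ref)
    return doc


def explain(doc: ReportDocument, label: str) -> str:
    """Human-readable evidence trace for one label."""
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}")
    la = doc.label_assignment(label)
    if not la.selected:
        return f"{label}: not selected — no evidence"
    lines = [f"{label}: selected"]
    for ref in la.evidence:
        ent = doc.entity_by_id(ref)
        lines.append(
            f"  {ent.entity_id} {ent.etype.value} "
            f"[{ent.start},{ent.end}) {doc.text_of(ent)!r}"
        )
        for rel in doc.relations:
            if ref in (rel.observation, rel.modifier):
                lines.append(
                    f"    {rel.rtype.value}({rel.observation}, {rel.modifier})"
                )
    return "\n".join(lines)
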