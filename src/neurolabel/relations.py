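"""Relation extraction and verbal negation.

Each location/time modifier is attached to at most one type-compatible
observation: strokes (ischaemic, haemorrhagic or unknown type) may take
both a location and a time modifier; microbleeds take a location only.
Attachment prefers the nearest compatible observation inside the
modifier's own noun group, falling back to the nearest in the sentence
(ties go to the leftward neighbour).  Co-extensive nested pairs are
never linked explicitly — the nesting already implies the relation.

Verbal negation ("may not be visible") is handled here because the
rules that find the scope of *not* mirror the attachment rules, but the
result is an attribute on the in-scope entities, never a relation.
"""

from __future__ import annotations

import logging
from typing import Optional

from .chunk_negation import negate_entity
from .model import (
    Entity,
    ModifierType,
    MOD_LOC_OBSERVATIONS,
    MOD_TIME_OBSERVATIONS,
    Relation,
    RelationType,
    ReportDocument,
    Sentence,
)

__all__ = ["apply_verbal_negation", "extract_relations"]

logger = logging.getLogger(__name__)

_LOC_MODIFIERS = {ModifierType.LOC_DEEP, ModifierType.LOC_CORTICAL}


def apply_verbal_negation(doc: ReportDocument) -> ReportDocument:
    """Negate entities in the scope of a verb-group *not*.

    Scope is the subject noun group immediately before the verb group
    and, for copular complements ("is not a tumour"), the noun group
    starting immediately after it.  No relation object is created.
    """
    for sent in doc.sentences:
        ngs = [c for c in sent.chunks if c.kind == "ng"]
        for vg in (c for c in sent.chunks if c.kind == "vg"):
            toks = sent.tokens[vg.tok_start : vg.tok_end]
            if not any(t.surface.lower() == "not" for t in toks):
                continue
            subject = None
            for ch in ngs:
                if ch.tok_end <= vg.tok_start:
                    subject = ch
            for target in filter(None, [
                subject,
                next((c for c in ngs if c.tok_start == vg.tok_end), None),
            ]):
                c_start, c_end = sent.chunk_char_span(target)
                for ent in doc.entities:
                    if c_start <= ent.start and ent.end <= c_end:
                        negate_entity(doc, ent.entity_id)
    return doc


def _chunk_of(sent: Sentence, ent: Entity) -> Optional[int]:
    for idx, ch in enumerate(sent.chunks):
        c_start, c_end = sent.chunk_char_span(ch)
        if c_start <= ent.start and ent.end <= c_end:
            return idx
    return None


def _tok_index(sent: Sentence, ent: Entity) -> int:
    for i, tok in enumerate(sent.tokens):
        if tok.start <= ent.start < tok.end or tok.start == ent.start:
            return i
    return 0


def extract_relations(doc: ReportDocument) -> ReportDocument:
    """Attach modifiers to observations, one relation per modifier.

    Requires entities, chunks and negation flags.  Attachment across
    chunks is blocked when the two endpoints disagree in polarity
    (same-chunk attachment is unconditional).  If one observation ends
    up with conflicting same-type modifier values, only the nearest is
    kept and a warning is logged.
    """
    relations: list[Relation] = []
    for si, sent in enumerate(doc.sentences):
        in_sent = [
            e for e in doc.entities
            if doc.sentence_index_at(e.start) == si
        ]
        obs_list = [e for e in in_sent if e.is_observation]
        for mod in (e for e in in_sent if not e.is_observation):
            if mod.nested_with is not None:
                continue  # the nesting implies the relation
            if mod.etype in _LOC_MODIFIERS:
                rtype = RelationType.MOD_LOC
                allowed = MOD_LOC_OBSERVATIONS
            else:
                rtype = RelationType.MOD_TIME
                allowed = MOD_TIME_OBSERVATIONS
            candidates = [o for o in obs_list if o.etype in allowed]
            if not candidates:
                continue
            mod_chunk = _chunk_of(sent, mod)
            mod_pos = _tok_index(sent, mod)

            def distance(o: Entity) -> tuple[int, int]:
                pos = _tok_index(sent, o)
                return (abs(pos - mod_pos), pos)  # ties: leftward neighbour

            same_chunk = [
                o for o in candidates
                if mod_chunk is not None and _chunk_of(sent, o) == mod_chunk
            ]
            if same_chunk:
                target = min(same_chunk, key=distance)
            else:
                cross = [
                    o for o in candidates
                    if o.negated == mod.negated
                    or _chunk_of(sent, o) == mod_chunk
                ]
                if not cross:
                    continue
                target = min(cross, key=distance)
            relations.append(Relation(rtype, target.entity_id, mod.entity_id))

    doc.relations = _resolve_conflicts(doc, relations)
    return doc


_VALUE_OF = {
    ModifierType.LOC_DEEP: "deep",
    ModifierType.LOC_CORTICAL: "cortical",
    ModifierType.TIME_OLD: "old",
    ModifierType.TIME_RECENT: "recent",
}


def _resolve_conflicts(doc: ReportDocument,
                       relations: list[Relation]) -> list[Relation]:
    """Keep only agreeing same-type modifiers per observation."""
    by_obs: dict[tuple[str, RelationType], list[Relation]] = {}
    for rel in relations:
        by_obs.setdefault((rel.observation, rel.rtype), []).append(rel)
    kept: list[Relation] = []
    for (obs_id, rtype), group in by_obs.items():
        values = {_VALUE_OF[doc.entity_by_id(r.modifier).etype] for r in group}
        if len(values) <= 1:
            kept.extend(group)
            continue
        obs = doc.entity_by_id(obs_id)
        si = doc.sentence_index_at(obs.start)
        sent = doc.sentences[si] if si is not None else None

        def gap(rel: Relation) -> int:
            mod = doc.entity_by_id(rel.modifier)
            if sent is None:
                return abs(mod.start - obs.start)
            return abs(_tok_index(sent, mod) - _tok_index(sent, obs))

        winner = min(group, key=lambda r: (gap(r), doc.entity_by_id(r.modifier).start))
        logger.warning(
            "report %s: conflicting %s modifiers on %s (%s); keeping nearest",
            doc.report_id, rtype.value, obs_id, sorted(values),
        )
        kept.append(winner)
    kept.sort(key=lambda r: (doc.entity_by_id(r.modifier).start, r.rtype.value))
    return kept
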