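"""Scoring of system-vs-gold and annotator-vs-annotator agreement.

Counts true positives, false positives and false negatives per type for
four annotation categories — entities, negation, relations and labels —
and reports precision, recall and F1 on the 0–100 scale, micro-averaged
over summed counts for the TOTAL rows (never by averaging per-type
scores).  An entity matches only on exact span and exact type; there is
no partial credit.  Zero-denominator ratios are reported as NaN.

For inter-annotator agreement on relations (``iaa_mode``), candidate
relations are first filtered to those whose two endpoints are entity
matches between the two sides; a relation over disputed entities is
excluded from the counts entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import (
    Entity,
    LABELS,
    RelationType,
    ReportDocument,
)

__all__ = [
    "Counts",
    "ScoreReport",
    "compute_prf",
    "round2",
    "pair_documents",
    "score_entities",
    "score_negation",
    "score_relations",
    "score_labels",
    "score_all",
]


def compute_prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall, F1 on the 0–100 scale (unrounded; NaN when undefined).

    F1 is the harmonic mean 2TP/(2TP+FP+FN); it is NaN whenever either
    precision or recall is undefined.
    """
    p = 100.0 * tp / (tp + fp) if tp + fp else math.nan
    r = 100.0 * tp / (tp + fn) if tp + fn else math.nan
    if math.isnan(p) or math.isnan(r):
        f1 = math.nan
    else:
        f1 = 100.0 * 2 * tp / (2 * tp + fp + fn)
    return p, r, f1


def round2(x: float) -> float:
    """Round to 2 decimals for display (banker's rounding, NaN-safe)."""
    return x if math.isnan(x) else round(x, 2)


@dataclass
class Counts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "Counts") -> "Counts":
        return Counts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)

    @property
    def prf(self) -> tuple[float, float, float]:
        return compute_prf(self.tp, self.fp, self.fn)


@dataclass
class ScoreReport:
    """Per-type and micro-averaged counts for one or more categories."""

    categories: dict[str, dict[str, Counts]] = field(default_factory=dict)

    def add(self, category: str, type_name: str, delta: Counts) -> None:
        slot = self.categories.setdefault(category, {})
        slot[type_name] = slot.get(type_name, Counts()) + delta

    def total(self, category: str) -> Counts:
        out = Counts()
        for counts in self.categories.get(category, {}).values():
            out = out + counts
        return out

    def total_f1(self, category: str) -> float:
        return self.total(category).prf[2]

    def merge(self, other: "ScoreReport") -> "ScoreReport":
        for cat, slot in other.categories.items():
            for type_name, counts in slot.items():
                self.add(cat, type_name, counts)
        return self

    def to_dataframe(self) -> pd.DataFrame:
        """Tabular view mirroring the Type/TP/FP/FN/P/R/F1 column order."""
        rows = []
        for cat, slot in self.categories.items():
            for type_name, c in slot.items():
                p, r, f1 = c.prf
                rows.append(
                    (cat, type_name, c.tp, c.fp, c.fn,
                     round2(p), round2(r), round2(f1))
                )
            t = self.total(cat)
            p, r, f1 = t.prf
            rows.append((cat, "TOTAL", t.tp, t.fp, t.fn,
                         round2(p), round2(r), round2(f1)))
        return pd.DataFrame(
            rows,
            columns=["Category", "Type", "TP", "FP", "FN",
                     "Precision", "Recall", "F1"],
        )

    def __str__(self) -> str:
        return self.to_dataframe().to_string(index=False, na_rep="NaN")


# ---------------------------------------------------------------------------
# Pairing and keys
# ---------------------------------------------------------------------------


def pair_documents(
    gold: Sequence[ReportDocument], pred: Sequence[ReportDocument]
) -> list[tuple[ReportDocument, ReportDocument]]:
    """Pair documents by report_id; error lists ids missing on either side."""
    gold_by_id = {d.report_id: d for d in gold}
    pred_by_id = {d.report_id: d for d in pred}
    missing_pred = sorted(set(gold_by_id) - set(pred_by_id))
    missing_gold = sorted(set(pred_by_id) - set(gold_by_id))
    if missing_pred or missing_gold:
        raise ValueError(
            "unpaired report ids — missing from pred: "
            f"{missing_pred}; missing from gold: {missing_gold}"
        )
    return [(gold_by_id[rid], pred_by_id[rid]) for rid in sorted(gold_by_id)]


def _entity_key(ent: Entity) -> tuple[int, int, str]:
    return (ent.start, ent.end, ent.etype.value)


def _relation_key(doc: ReportDocument, rel) -> tuple:
    obs = doc.entity_by_id(rel.observation)
    mod = doc.entity_by_id(rel.modifier)
    return (rel.rtype.value, _entity_key(obs), _entity_key(mod))


# ---------------------------------------------------------------------------
# Category scorers
# ---------------------------------------------------------------------------


def score_entities(
    gold: Sequence[ReportDocument], pred: Sequence[ReportDocument]
) -> ScoreReport:
    """Exact span + exact type entity matching, per type and in total."""
    report = ScoreReport()
    for g, p in pair_documents(gold, pred):
        g_keys = {_entity_key(e) for e in g.entities}
        p_keys = {_entity_key(e) for e in p.entities}
        for key in g_keys & p_keys:
            report.add("entities", key[2], Counts(tp=1))
        for key in p_keys - g_keys:
            report.add("entities", key[2], Counts(fp=1))
        for key in g_keys - p_keys:
            report.add("entities", key[2], Counts(fn=1))
    return report


def score_negation(
    gold: Sequence[ReportDocument], pred: Sequence[ReportDocument]
) -> ScoreReport:
    """Agreement restricted to negated entities.

    A TP is a gold-negated entity whose span+type match is also negated
    on the prediction side; a gold-negated entity without such a match
    is an FN, a pred-negated entity without one an FP.
    """
    report = ScoreReport()
    for g, p in pair_documents(gold, pred):
        g_neg = {_entity_key(e) for e in g.entities if e.negated}
        p_neg = {_entity_key(e) for e in p.entities if e.negated}
        for key in g_neg & p_neg:
            report.add("negation", key[2], Counts(tp=1))
        for key in p_neg - g_neg:
            report.add("negation", key[2], Counts(fp=1))
        for key in g_neg - p_neg:
            report.add("negation", key[2], Counts(fn=1))
    return report


def score_relations(
    gold: Sequence[ReportDocument],
    pred: Sequence[ReportDocument],
    iaa_mode: bool = False,
) -> ScoreReport:
    """Relation matching: same type and entity-matched endpoints.

    With ``iaa_mode`` a relation only enters the counts when both of its
    endpoints are entity matches between the two sides.
    """
    report = ScoreReport()
    for g, p in pair_documents(gold, pred):
        matched = {_entity_key(e) for e in g.entities} & {
            _entity_key(e) for e in p.entities
        }

        def keys(doc: ReportDocument) -> set:
            out = set()
            for rel in doc.relations:
                key = _relation_key(doc, rel)
                if iaa_mode and not (key[1] in matched and key[2] in matched):
                    continue
                out.add(key)
            return out

        g_keys, p_keys = keys(g), keys(p)
        for key in g_keys & p_keys:
            report.add("relations", key[0], Counts(tp=1))
        for key in p_keys - g_keys:
            report.add("relations", key[0], Counts(fp=1))
        for key in g_keys - p_keys:
            report.add("relations", key[0], Counts(fn=1))
    return report


def score_labels(
    gold: Sequence[ReportDocument], pred: Sequence[ReportDocument]
) -> ScoreReport:
    """Each (report, label) selected pair is one unit."""
    report = ScoreReport()
    for g, p in pair_documents(gold, pred):
        g_sel = {la.label for la in g.labels if la.selected}
        p_sel = {la.label for la in p.labels if la.selected}
        for label in g_sel & p_sel:
            report.add("labels", label, Counts(tp=1))
        for label in p_sel - g_sel:
            report.add("labels", label, Counts(fp=1))
        for label in g_sel - p_sel:
            report.add("labels", label, Counts(fn=1))
    return report


def score_all(
    gold: Sequence[ReportDocument],
    pred: Sequence[ReportDocument],
    iaa_mode: bool = False,
) -> ScoreReport:
    """All four categories in one report."""
    report = ScoreReport()
    report.merge(score_entities(gold, pred))
    report.merge(score_negation(gold, pred))
    report.merge(score_relations(gold, pred, iaa_mode=iaa_mode))
    report.merge(score_labels(gold, pred))
    # guarantee the four categories exist even when empty
    for cat in ("entities", "negation", "relations", "labels"):
        report.categories.setdefault(cat, {})
    return report
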