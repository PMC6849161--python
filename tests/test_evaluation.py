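"""Scorer: published-row regression, oracle equivalence, symmetry, NaN."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurolabel import (
    GeneratorSpec,
    compute_prf,
    corruption,
    generate,
    score_all,
    score_entities,
    score_labels,
    score_negation,
    score_relations,
)
from neurolabel.evaluation import round2


def _assert_close(got, exp):
    if math.isnan(exp):
        assert math.isnan(got)
    else:
        assert not math.isnan(got)
        assert abs(got - exp) < 1e-9


class TestComputePrf:
    def test_published_entity_row(self):
        p, r, f1 = compute_prf(453, 9, 2)
        assert (round2(p), round2(r), round2(f1)) == (98.05, 99.56, 98.80)

    def test_zero_denominator_row(self):
        p, r, f1 = compute_prf(0, 0, 1)
        assert math.isnan(p)
        assert r == 0.0
        assert math.isnan(f1)

    def test_perfect_agreement(self):
        assert compute_prf(10, 0, 0) == (100.0, 100.0, 100.0)

    def test_label_totals_rows(self):
        p, r, f1 = compute_prf(495, 40, 23)
        assert (round2(p), round2(r), round2(f1)) == (92.52, 95.56, 94.02)
        p, r, f1 = compute_prf(495, 39, 40)
        assert (round2(p), round2(r), round2(f1)) == (92.70, 92.52, 92.61)

    def test_regression_against_all_published_rows(self, prf_rows):
        for _, row in prf_rows.iterrows():
            p, r, f1 = compute_prf(row.tp, row.fp, row.fn)
            _assert_close(round2(p), row.precision)
            _assert_close(round2(r), row.recall)
            _assert_close(round2(f1), row.f1)

    @given(tp=st.integers(0, 500), fp=st.integers(0, 500),
           fn=st.integers(0, 500))
    @settings(derandomize=True, max_examples=200)
    def test_f1_between_p_and_r(self, tp, fp, fn):
        p, r, f1 = compute_prf(tp, fp, fn)
        if not (math.isnan(p) or math.isnan(r)):
            assert min(p, r) - 1e-9 <= f1 <= max(p, r) + 1e-9
            assert 0.0 <= f1 <= 100.0

    @given(tp=st.integers(0, 500), fp=st.integers(0, 500),
           fn=st.integers(0, 500))
    @settings(derandomize=True, max_examples=200)
    def test_swapping_fp_fn_swaps_p_and_r(self, tp, fp, fn):
        p1, r1, f1a = compute_prf(tp, fp, fn)
        p2, r2, f1b = compute_prf(tp, fn, fp)
        for a, b in ((p1, r2), (r1, p2), (f1a, f1b)):
            assert (math.isnan(a) and math.isnan(b)) or abs(a - b) < 1e-9


@pytest.fixture(scope="module")
def gold_batch():
    return [r.gold for r in generate(GeneratorSpec(seed=5, n_reports=20))]


@pytest.fixture(scope="module")
def corrupted_batch(gold_batch):
    rng = random.Random(99)
    pred = []
    for doc in gold_batch:
        ops = {
            "drop_entity": rng.randint(0, min(2, len(doc.entities))),
            "flip_negation": rng.randint(0, 1) if len(doc.entities) > 2 else 0,
            "retype": rng.randint(0, 1) if len(doc.entities) > 3 else 0,
            "drop_relation": rng.randint(0, min(1, len(doc.relations))),
            "toggle_label": rng.randint(0, 2),
        }
        pred.append(corruption(doc, ops, seed=rng.randint(0, 10_000)))
    return pred


class TestScorersAgainstBruteForce:
    """Counts must equal an independent pairwise-matching recount."""

    @staticmethod
    def _recount(gold_units, pred_units):
        tp = 0
        pred_left = list(pred_units)
        for g in gold_units:
            if g in pred_left:
                pred_left.remove(g)
                tp += 1
        return tp, len(pred_units) - tp, len(gold_units) - tp

    def test_entity_counts(self, gold_batch, corrupted_batch):
        report = score_entities(gold_batch, corrupted_batch)
        tp = fp = fn = 0
        for g, p in zip(gold_batch, corrupted_batch):
            d_tp, d_fp, d_fn = self._recount(
                [(e.start, e.end, e.etype.value) for e in g.entities],
                [(e.start, e.end, e.etype.value) for e in p.entities],
            )
            tp, fp, fn = tp + d_tp, fp + d_fp, fn + d_fn
        total = report.total("entities")
        assert (total.tp, total.fp, total.fn) == (tp, fp, fn)

    def test_negation_counts(self, gold_batch, corrupted_batch):
        report = score_negation(gold_batch, corrupted_batch)
        tp = fp = fn = 0
        for g, p in zip(gold_batch, corrupted_batch):
            p_keys = [(e.start, e.end, e.etype.value)
                      for e in p.entities if e.negated]
            g_keys = [(e.start, e.end, e.etype.value)
                      for e in g.entities if e.negated]
            d_tp, d_fp, d_fn = self._recount(g_keys, p_keys)
            tp, fp, fn = tp + d_tp, fp + d_fp, fn + d_fn
        total = report.total("negation")
        assert (total.tp, total.fp, total.fn) == (tp, fp, fn)

    def test_label_counts(self, gold_batch, corrupted_batch):
        report = score_labels(gold_batch, corrupted_batch)
        tp = fp = fn = 0
        for g, p in zip(gold_batch, corrupted_batch):
            d_tp, d_fp, d_fn = self._recount(
                [la.label for la in g.labels if la.selected],
                [la.label for la in p.labels if la.selected],
            )
            tp, fp, fn = tp + d_tp, fp + d_fp, fn + d_fn
        total = report.total("labels")
        assert (total.tp, total.fp, total.fn) == (tp, fp, fn)

    def test_relation_counts(self, gold_batch, corrupted_batch):
        def rel_keys(doc):
            by_id = {e.entity_id: e for e in doc.entities}
            return [
                (r.rtype.value,
                 (by_id[r.observation].start, by_id[r.observation].end,
                  by_id[r.observation].etype.value),
                 (by_id[r.modifier].start, by_id[r.modifier].end,
                  by_id[r.modifier].etype.value))
                for r in doc.relations
            ]

        report = score_relations(gold_batch, corrupted_batch, iaa_mode=False)
        tp = fp = fn = 0
        for g, p in zip(gold_batch, corrupted_batch):
            d_tp, d_fp, d_fn = self._recount(rel_keys(g), rel_keys(p))
            tp, fp, fn = tp + d_tp, fp + d_fp, fn + d_fn
        total = report.total("relations")
        assert (total.tp, total.fp, total.fn) == (tp, fp, fn)


class TestScorerProperties:
    def test_identity_scores_100_everywhere(self, gold_batch):
        report = score_all(gold_batch, gold_batch)
        for cat in ("entities", "negation", "relations", "labels"):
            total = report.total(cat)
            assert total.fp == 0 and total.fn == 0
            assert total.prf[2] == 100.0

    def test_swapping_gold_and_pred_swaps_p_and_r(self, gold_batch,
                                                  corrupted_batch):
        fwd = score_all(gold_batch, corrupted_batch)
        rev = score_all(corrupted_batch, gold_batch)
        for cat in ("entities", "negation", "relations", "labels"):
            p1, r1, f1a = fwd.total(cat).prf
            p2, r2, f1b = rev.total(cat).prf
            for a, b in ((p1, r2), (r1, p2), (f1a, f1b)):
                assert (math.isnan(a) and math.isnan(b)) or abs(a - b) < 1e-9

    def test_span_shift_counts_fp_and_fn(self, gold_batch):
        pred = [d.copy() for d in gold_batch]
        pred[0] = corruption(gold_batch[0], {"shift_span": 1}, seed=1)
        base = score_entities(gold_batch, [d.copy() for d in gold_batch])
        shifted = score_entities(gold_batch, pred)
        assert shifted.total("entities").fp == base.total("entities").fp + 1
        assert shifted.total("entities").fn == base.total("entities").fn + 1

    def test_micro_total_from_summed_counts_not_averaged_f1(self, prf_rows):
        ent = prf_rows[prf_rows.table == "entities_iaa"]
        per_type = ent[ent.type != "TOTAL"]
        total_row = ent[ent.type == "TOTAL"].iloc[0]
        assert per_type.tp.sum() == total_row.tp
        assert per_type.fp.sum() == total_row.fp
        assert per_type.fn.sum() == total_row.fn
        micro = round2(compute_prf(int(total_row.tp), int(total_row.fp),
                                   int(total_row.fn))[2])
        macro = round2(per_type.f1.mean())
        assert micro == total_row.f1
        assert micro != macro

    def test_unpaired_ids_rejected_with_listing(self, gold_batch):
        with pytest.raises(ValueError, match="synthetic-0000"):
            score_entities(gold_batch, gold_batch[1:])

    def test_iaa_mode_excludes_disputed_endpoints(self, gold_batch):
        # shift one relation endpoint's span: in IAA mode the relation
        # disappears from the denominator instead of counting FP+FN
        doc = next(d for d in gold_batch if d.relations)
        pred_doc = doc.copy()
        mod_id = pred_doc.relations[0].modifier
        ent = pred_doc.entity_by_id(mod_id)
        ent.start, ent.end = ent.start + 1, ent.end + 1
        strict = score_relations([doc], [pred_doc], iaa_mode=False)
        iaa = score_relations([doc], [pred_doc], iaa_mode=True)
        assert strict.total("relations").fp == 1
        assert strict.total("relations").fn == 1
        assert iaa.total("relations").fp == 0
        assert iaa.total("relations").fn == 0
        assert iaa.total("relations").tp == strict.total("relations").tp

    def test_dataframe_has_table_column_order(self, gold_batch):
        df = score_all(gold_batch, gold_batch).to_dataframe()
        assert list(df.columns) == ["Category", "Type", "TP", "FP", "FN",
                                    "Precision", "Recall", "F1"]
        assert (df[df.Type == "TOTAL"].F1.dropna() == 100.0).all()
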