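"""Benchmark labelling rules, confusion-matrix metrics and ROC machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hotspotter.benchmarks import (ASEDB_N_HOTSPOT, ASEDB_N_NONHOTSPOT,
                                   BID_N_OTHER, BID_N_STRONG,
                                   make_asedb_like_table, make_bid_like_table)
from hotspotter.evaluation import (EXCLUDED, HOTSPOT, NON_HOTSPOT,
                                   BenchmarkError, ConfusionMatrix,
                                   confusion, elbow_threshold,
                                   evaluate_predictions, label_asedb,
                                   label_bid, metrics, rank_auc, roc_curve)


def ddg_table(values):
    return pd.DataFrame({
        "complex_id": "X", "chain": "A",
        "resnum": range(1, len(values) + 1), "aa": "A", "ddg": values})


class TestLabelRules:
    @pytest.mark.parametrize("ddg,expected", [
        (2.0, HOTSPOT),       # inclusive lower bound for hotspots
        (3.5, HOTSPOT),
        (0.4, EXCLUDED),      # non-hotspot bound is strict
        (1.0, EXCLUDED),
        (1.99, EXCLUDED),
        (0.39, NON_HOTSPOT),
        (-0.2, NON_HOTSPOT),
    ])
    def test_ddg_boundaries(self, ddg, expected):
        out = label_asedb(ddg_table([ddg]))
        assert out.truth.iloc[0] == expected

    def test_every_record_gets_exactly_one_class(self):
        rng = np.random.default_rng(11)
        values = rng.uniform(-1, 6, size=500)
        out = label_asedb(ddg_table(values))
        assert set(out.truth) <= {HOTSPOT, NON_HOTSPOT, EXCLUDED}
        counts = out.truth.value_counts()
        assert counts.sum() == 500
        # permutation invariance of the counts
        out2 = label_asedb(ddg_table(values[::-1]))
        assert out2.truth.value_counts().to_dict() == counts.to_dict()

    def test_missing_ddg_rejected(self):
        with pytest.raises(BenchmarkError):
            label_asedb(ddg_table([1.0, np.nan]))

    @pytest.mark.parametrize("label,expected", [
        ("strong", HOTSPOT), ("intermediate", NON_HOTSPOT),
        ("weak", NON_HOTSPOT), ("insignificant", NON_HOTSPOT)])
    def test_strength_labels(self, label, expected):
        df = pd.DataFrame({"complex_id": ["X"], "chain": ["A"],
                           "resnum": [1], "aa": ["A"], "strength": [label]})
        assert label_bid(df).truth.iloc[0] == expected

    def test_unknown_strength_label_rejected(self):
        df = pd.DataFrame({"complex_id": ["X"], "chain": ["A"],
                           "resnum": [1], "aa": ["A"], "strength": ["moderate"]})
        with pytest.raises(BenchmarkError, match="moderate"):
            label_bid(df)

    def test_synthetic_training_table_composition(self):
        out = label_asedb(make_asedb_like_table(seed=4))
        counts = out.truth.value_counts()
        assert counts[HOTSPOT] == ASEDB_N_HOTSPOT
        assert counts[NON_HOTSPOT] == ASEDB_N_NONHOTSPOT

    def test_synthetic_test_table_composition(self):
        out = label_bid(make_bid_like_table(seed=4))
        assert len(out) == BID_N_STRONG + BID_N_OTHER
        assert (out.truth == HOTSPOT).sum() == BID_N_STRONG


class TestMetrics:
    def test_hand_matrix(self):
        m = metrics(ConfusionMatrix(tp=25, fn=13, tn=75, fp=12))
        assert m.se == pytest.approx(25 / 38, abs=1e-4)
        assert m.acc == pytest.approx(0.80)
        assert m.pr == pytest.approx(25 / 37)
        assert m.sp == pytest.approx(75 / 87)

    def test_perfect_prediction(self):
        m = metrics(ConfusionMatrix(tp=10, fn=0, tn=20, fp=0))
        assert (m.acc, m.se, m.pr, m.sp, m.mcc) == (1, 1, 1, 1, 1)
        assert m.flags == ()

    def test_zero_denominator_flags(self):
        m = metrics(ConfusionMatrix(tp=0, fn=0, tn=5, fp=0))
        assert m.se == 0.0
        assert "SE" in m.flags

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionMatrix(0, 0, 0, 0))

    @settings(max_examples=1000, derandomize=True)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()),
                    min_size=1, max_size=40))
    def test_agrees_with_per_record_recount(self, pairs):
        truth = [t for t, _ in pairs]
        pred = [p for _, p in pairs]
        cm = confusion(truth, pred)
        # independent recount
        tp = sum(1 for t, p in pairs if t and p)
        fp = sum(1 for t, p in pairs if not t and p)
        tn = sum(1 for t, p in pairs if not t and not p)
        fn = sum(1 for t, p in pairs if t and not p)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (tp, fp, tn, fn)
        m = metrics(cm)
        assert 0 <= m.acc <= 1 and 0 <= m.se <= 1
        assert 0 <= m.pr <= 1 and 0 <= m.sp <= 1
        assert -1 <= m.mcc <= 1
        if tp + fn:
            assert m.se == pytest.approx(tp / (tp + fn))
        if (tp + tn) and cm.total:
            assert m.acc == pytest.approx((tp + tn) / cm.total)


def brute_force_roc(scores, truth):
    """Exhaustive threshold enumeration oracle."""
    pts = [(0.0, 0.0, np.inf)]
    n_pos = sum(truth)
    n_neg = len(truth) - n_pos
    for t in sorted(set(scores), reverse=True):
        pred = [s >= t for s in scores]
        tp = sum(1 for y, p in zip(truth, pred) if y and p)
        fp = sum(1 for y, p in zip(truth, pred) if not y and p)
        pts.append((fp / n_neg, tp / n_pos, t))
    return pts


class TestRoc:
    def test_tied_scores_give_degenerate_two_point_curve(self):
        curve = roc_curve([0.5] * 6, [1, 0, 1, 0, 0, 1])
        assert len(curve.thresholds) == 2
        assert curve.fpr.tolist() == [0.0, 1.0]
        assert curve.tpr.tolist() == [0.0, 1.0]

    def test_perfect_separation_passes_through_0_1(self):
        curve = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert any(f == 0.0 and t == 1.0
                   for f, t in zip(curve.fpr, curve.tpr))
        assert curve.auc() == pytest.approx(1.0)

    def test_six_residue_set_matches_enumeration(self):
        scores = [0.9, 0.7, 0.7, 0.5, 0.3, 0.1]
        truth = [1, 1, 0, 1, 0, 0]
        curve = roc_curve(scores, truth)
        expected = brute_force_roc(scores, truth)
        got = list(zip(curve.fpr, curve.tpr, curve.thresholds))
        assert len(got) == len(expected)
        for (f1, t1, th1), (f2, t2, th2) in zip(got, expected):
            assert f1 == pytest.approx(f2)
            assert t1 == pytest.approx(t2)
            assert th1 == pytest.approx(th2) or (np.isinf(th1) and np.isinf(th2))

    def test_monotone_along_curve(self):
        rng = np.random.default_rng(5)
        scores = rng.random(50)
        truth = rng.random(50) < 0.4
        curve = roc_curve(scores, truth)
        assert np.all(np.diff(curve.tpr) >= 0)
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.thresholds) < 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.2], [1, 1])

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_trapezoid_auc_equals_rank_statistic(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        scores = np.round(rng.random(n), 2)  # force ties sometimes
        truth = rng.random(n) < 0.5
        if truth.all() or not truth.any():
            truth[0] = ~truth[0]
        curve = roc_curve(scores, truth)
        assert curve.auc() == pytest.approx(rank_auc(scores, truth), abs=1e-9)


class TestElbow:
    def test_perfect_separation_picks_the_boundary(self):
        curve = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        res = elbow_threshold(curve)
        assert res.threshold == pytest.approx(0.8)
        assert not res.uninformative

    def test_staircase_stops_before_final_flat_step(self):
        # TPR climbs for the first three thresholds, the last step is FPR-only
        scores = [0.9, 0.8, 0.7, 0.2]
        truth = [1, 1, 1, 0]
        res = elbow_threshold(roc_curve(scores, truth))
        assert res.threshold == pytest.approx(0.7)

    def test_diagonal_is_flagged_uninformative(self):
        # equal-sized alternating classes with tied pairs -> diagonal curve
        scores = [0.9, 0.9, 0.5, 0.5, 0.1, 0.1]
        truth = [1, 0, 1, 0, 1, 0]
        res = elbow_threshold(roc_curve(scores, truth))
        assert res.uninformative

    def test_degenerate_curve_rejected(self):
        with pytest.raises(ValueError):
            elbow_threshold(roc_curve([0.5, 0.5], [1, 0]))


class TestEvaluatePredictions:
    def test_perfect_join(self):
        bench = label_bid(make_bid_like_table(seed=2))
        pred = bench[["complex_id", "chain", "resnum"]].copy()
        pred["hotspot"] = (bench.truth == HOTSPOT).astype(int)
        cm, m, unmatched = evaluate_predictions(bench, pred)
        assert unmatched == 0
        assert m.acc == 1.0

    def test_excluded_records_not_counted(self):
        bench = label_asedb(ddg_table([3.0, 1.0, 0.1]))
        pred = bench[["complex_id", "chain", "resnum"]].copy()
        pred["hotspot"] = [1, 1, 0]
        cm, m, _ = evaluate_predictions(bench, pred)
        assert cm.total == 2  # the ddG 1.0 record is excluded
        assert m.acc == 1.0

    def test_disjoint_keys_rejected(self):
        bench = label_bid(make_bid_like_table(seed=2))
        pred = pd.DataFrame({"complex_id": ["nope"], "chain": ["Z"],
                             "resnum": [1], "hotspot": [1]})
        with pytest.raises(BenchmarkError):
            evaluate_predictions(bench, pred)
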