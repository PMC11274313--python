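"""Tests of confusion/metric computation, ROC/AUC, and the quality timeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beatsource import (
    ConfusionMatrix,
    SynthConfig,
    classification_metrics,
    confusion,
    make_recording,
    quality_timeline,
    roc_auc,
)
from beatsource.evaluate import report_percent

from oracles import metric_formulas, pairwise_auc

LABELS = ("fetal", "vessel")


class TestConfusion:
    def test_identical_sequences_have_empty_off_diagonal(self):
        cm = confusion(["fetal", "vessel", "fetal"], ["fetal", "vessel", "fetal"])
        assert (cm.n_ff, cm.n_fv, cm.n_vf, cm.n_vv) == (2, 0, 0, 1)

    def test_cells_match_pair_counting_oracle(self):
        rng = np.random.default_rng(1)
        t = rng.choice(LABELS, 10)
        p = rng.choice(LABELS, 10)
        cm = confusion(t, p)
        for cell, (ti, pi) in (("n_ff", ("fetal", "fetal")), ("n_fv", ("fetal", "vessel")),
                               ("n_vf", ("vessel", "fetal")), ("n_vv", ("vessel", "vessel"))):
            assert getattr(cm, cell) == sum(1 for a, b in zip(t, p) if (a, b) == (ti, pi))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion(["fetal", "maternal"], ["fetal", "fetal"])


class TestClassificationMetrics:
    def test_published_worked_example_with_vessel_positive(self):
        """The study's test confusion matrix (2210, 30, 21, 139) yields
        accuracy 97.9, precision 82.3, recall 86.9, F1 84.5 with the vessel
        class as positive."""
        m = classification_metrics(ConfusionMatrix(2210, 30, 21, 139), "vessel")
        assert (m.accuracy, m.precision, m.recall, m.f1) == (97.9, 82.3, 86.9, 84.5)

    def test_perfect_classifier_scores_100_under_both_conventions(self):
        cm = ConfusionMatrix(7, 0, 0, 5)
        for positive in LABELS:
            m = classification_metrics(cm, positive)
            assert (m.accuracy, m.precision, m.recall, m.f1) == (100.0,) * 4

    @given(cells=st.tuples(*[st.integers(0, 400)] * 4))
    @settings(max_examples=100, deadline=None)
    def test_metrics_match_direct_formula_oracle(self, cells):
        n_ff, n_fv, n_vf, n_vv = cells
        if n_ff + n_fv + n_vf + n_vv == 0:
            return
        m = classification_metrics(ConfusionMatrix(*cells), "vessel")
        acc, prec, rec, f1 = metric_formulas(tp=n_vv, tn=n_ff, fp=n_fv, fn=n_vf)
        assert m.raw["accuracy"] == pytest.approx(acc)
        for got, want in ((m.raw["precision"], prec), (m.raw["recall"], rec),
                          (m.raw["f1"], f1)):
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want)

    def test_harmonic_mean_identity_holds_before_rounding(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            cells = rng.integers(1, 300, 4)
            m = classification_metrics(ConfusionMatrix(*cells), "vessel")
            p, r = m.raw["precision"], m.raw["recall"]
            assert m.raw["f1"] == pytest.approx(2 * p * r / (p + r), rel=1e-12)

    def test_accuracy_invariant_to_positive_class_choice(self):
        cm = ConfusionMatrix(50, 3, 7, 21)
        mv = classification_metrics(cm, "vessel")
        mf = classification_metrics(cm, "fetal")
        assert mv.raw["accuracy"] == mf.raw["accuracy"]
        # precision/recall swap under the complementary mapping
        assert mf.raw["recall"] == pytest.approx(100.0 * 50 / 53)
        assert mv.raw["recall"] == pytest.approx(100.0 * 21 / 28)

    def test_zero_denominator_is_signalled_not_zero(self):
        m = classification_metrics(ConfusionMatrix(5, 0, 3, 0), "vessel")
        assert m.precision is None
        assert "precision" in m.undefined

    def test_percent_reporting_uses_two_stage_half_up_rounding(self):
        assert report_percent(100 * 139 / 169) == 82.3
        assert report_percent(97.875) == 97.9
        assert report_percent(82.24) == 82.2


class TestRocAuc:
    def test_perfect_separation_gives_unit_area(self):
        r = roc_auc(["fetal"] * 3 + ["vessel"] * 3, [3, 2.5, 2, 1, 0.5, 0], "fetal")
        assert r.auc == 1.0

    def test_all_tied_scores_give_half(self):
        r = roc_auc(["fetal", "vessel", "fetal", "vessel"], [1, 1, 1, 1], "fetal")
        assert r.auc == 0.5

    def test_hand_made_tied_scores_match_pairwise_oracle_exactly(self):
        labels = ["fetal", "vessel"] * 6
        scores = [3, 3, 2, 1, 2, 2, 5, 0, 1, 1, 4, 2]
        r = roc_auc(labels, scores, "fetal")
        assert r.auc == pytest.approx(pairwise_auc(labels, scores, "fetal"), abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_instances_match_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 30))
        labels = rng.choice(LABELS, n)
        if len(set(labels)) < 2:
            labels[0], labels[1] = "fetal", "vessel"
        scores = rng.choice([0.0, 0.25, 0.5, 1.0, 2.0], n)
        r = roc_auc(labels, scores, "fetal")
        assert r.auc == pytest.approx(pairwise_auc(labels, scores, "fetal"), abs=1e-12)

    def test_negating_tie_free_scores_complements_the_area(self):
        rng = np.random.default_rng(9)
        labels = rng.choice(LABELS, 20)
        labels[:2] = ["fetal", "vessel"]
        scores = rng.permutation(20).astype(float)  # distinct, hence tie-free
        a = roc_auc(labels, scores, "fetal").auc
        b = roc_auc(labels, -scores, "fetal").auc
        assert a + b == pytest.approx(1.0, abs=1e-12)
        assert roc_auc(labels, scores, "fetal", "lower_is_positive").auc == pytest.approx(b)

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(2)
        labels = rng.choice(LABELS, 30)
        labels[:2] = ["fetal", "vessel"]
        r = roc_auc(labels, rng.normal(size=30), "fetal")
        assert r.fpr[0] == 0.0 and r.tpr[0] == 0.0
        assert r.fpr[-1] == 1.0 and r.tpr[-1] == 1.0
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)

    def test_single_class_input_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(["fetal", "fetal"], [1.0, 2.0], "fetal")


class _ConstantModel:
    def __init__(self, p_fetal):
        self.p = p_fetal

    def predict_proba(self, windows):
        n = len(windows)
        return np.column_stack([np.full(n, self.p), np.full(n, 1 - self.p)])


class TestQualityTimeline:
    def test_always_fetal_model_gives_all_blue(self):
        rec, _ = make_recording(SynthConfig(duration_s=20.0, seed=1))
        tl = quality_timeline(rec, _ConstantModel(1.0))
        assert set(tl.color) == {"blue"}

    def test_window_count_arithmetic(self):
        rec, _ = make_recording(SynthConfig(duration_s=60.0, seed=2))
        tl = quality_timeline(rec, _ConstantModel(0.2), stride_s=2.0)
        assert len(tl.color) == 30
        assert tl.start_s[0] == 0.0 and tl.start_s[-1] == 58.0
        assert set(tl.color) == {"red"}

    def test_csv_round_trip_columns(self, tmp_path):
        rec, _ = make_recording(SynthConfig(duration_s=10.0, seed=3))
        tl = quality_timeline(rec, _ConstantModel(0.7))
        path = tmp_path / "timeline.csv"
        tl.to_csv(path)
        import pandas as pd

        frame = pd.read_csv(path)
        assert list(frame.columns) == ["start_s", "p_fetal", "p_vessel", "color"]
        assert len(frame) == len(tl.color)
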