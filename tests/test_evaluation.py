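"""Classification metrics, calibration, and the bootstrap comparison."""

import numpy as np
import pandas as pd
import pytest

from mcrepeat.evaluation import (
    accuracy,
    bootstrap_compare,
    bootstrap_metric,
    brier,
    calibration_curve,
    quadratic_weighted_kappa,
)
from mcrepeat.scoring import HeadKind


class TestAccuracy:
    def test_examples(self):
        assert accuracy([1, 2, 0], [1, 2, 0]) == 1.0
        assert accuracy([0, 1, 1, 2], [0, 1, 1, 1]) == 0.75

    def test_independent_uniform_predictions_hit_one_in_k(self):
        rng = np.random.default_rng(0)
        n, k = 100_000, 5
        assert accuracy(rng.integers(0, k, n), rng.integers(0, k, n)) == pytest.approx(
            1 / k, abs=0.005)


def kappa_pair_counting_oracle(true, pred, k):
    """O(n^2) pair-counting quadratic kappa: expected disagreement from all
    ordered (true_i, pred_j) pairs, observed from the paired samples."""
    true = np.asarray(true)
    pred = np.asarray(pred)
    n = len(true)
    w = lambda i, j: (i - j) ** 2 / (k - 1) ** 2
    observed = sum(w(t, p) for t, p in zip(true, pred))
    expected = sum(w(t, p) for t in true for p in pred) / n
    if expected == 0:
        return float("nan")
    return 1.0 - observed / expected


class TestQuadraticWeightedKappa:
    def test_perfect_agreement(self):
        y = [0, 1, 2, 3, 1, 2]
        assert quadratic_weighted_kappa(y, y, 4) == pytest.approx(1.0)

    def test_shifted_scale_is_strictly_below_perfect(self):
        true = [0, 1, 2, 3, 0, 1, 2, 3]
        shifted = [min(c + 1, 3) for c in true]
        assert quadratic_weighted_kappa(true, shifted, 4) < 1.0

    def test_matches_pair_counting_oracle_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            k = rng.integers(3, 6)
            n = 200
            true = rng.integers(0, k, n)
            pred = np.clip(true + rng.integers(-1, 2, n), 0, k - 1)
            ours = quadratic_weighted_kappa(true, pred, k)
            oracle = kappa_pair_counting_oracle(true, pred, k)
            assert ours == pytest.approx(oracle, abs=1e-10)

    def test_symmetry_and_class_reversal_invariance(self):
        rng = np.random.default_rng(1)
        k, n = 4, 150
        true = rng.integers(0, k, n)
        pred = rng.integers(0, k, n)
        assert quadratic_weighted_kappa(true, pred, k) == pytest.approx(
            quadratic_weighted_kappa(pred, true, k))
        assert quadratic_weighted_kappa(k - 1 - true, k - 1 - pred, k) == pytest.approx(
            quadratic_weighted_kappa(true, pred, k))

    def test_degenerate_marginals_are_undefined(self):
        assert np.isnan(quadratic_weighted_kappa([1, 1, 1], [1, 1, 1], 3))

    def test_matches_sklearn_reference(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(8)
        k, n = 5, 300
        true = rng.integers(0, k, n)
        pred = np.clip(true + rng.integers(-2, 3, n), 0, k - 1)
        ref = cohen_kappa_score(true, pred, labels=list(range(k)), weights="quadratic")
        assert quadratic_weighted_kappa(true, pred, k) == pytest.approx(ref, abs=1e-12)


class TestBrier:
    def test_perfect_one_hot(self):
        head = HeadKind("multiclass", 3)
        probs = np.eye(3)[[0, 1, 2, 1]]
        assert brier([0, 1, 2, 1], probs, head) == 0.0

    def test_binary_half_everywhere(self):
        head = HeadKind("binary", 2)
        assert brier([0, 1, 0, 1], np.full(4, 0.5), head) == pytest.approx(0.25)

    def test_uniform_three_class_closed_form(self):
        head = HeadKind("multiclass", 3)
        probs = np.full((9, 3), 1 / 3)
        labels = [0, 1, 2] * 3
        assert brier(labels, probs, head) == pytest.approx(2 / 3)

    def test_regression_unsupported(self):
        with pytest.raises(ValueError):
            brier([0, 1], np.array([0.2, 1.4]), HeadKind("regression", 3))

    def test_binary_matches_sklearn_reference(self):
        from sklearn.metrics import brier_score_loss

        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 200)
        p = rng.uniform(0, 1, 200)
        assert brier(y, p, HeadKind("binary", 2)) == pytest.approx(
            brier_score_loss(y, p), abs=1e-12)


class TestCalibrationCurve:
    def test_calibrated_simulation_tracks_identity(self):
        rng = np.random.default_rng(0)
        n = 100_000
        p = rng.uniform(0, 1, n)
        y = (rng.uniform(0, 1, n) < p).astype(int)
        rep = calibration_curve(y, p, HeadKind("binary", 2), n_bins=10)
        for b in rep.bins:
            assert b.count > 0
            se = np.sqrt(b.mean_predicted * (1 - b.mean_predicted) / b.count)
            assert abs(b.observed_frequency - b.mean_predicted) < 5 * se + 1e-3

    def test_all_confident_and_correct(self):
        rep = calibration_curve([1] * 50, np.ones(50), HeadKind("binary", 2))
        top = rep.bins[-1]
        assert top.count == 50
        assert top.observed_frequency == 1.0
        assert sum(b.count for b in rep.bins) == rep.n_pooled

    def test_overconfident_wrong_half(self):
        # one-hot predictions that are wrong half the time: top bin
        # frequency 0.5 at mean prediction 1.0
        y = np.array([1] * 50 + [0] * 50)
        p = np.ones(100)
        rep = calibration_curve(y, p, HeadKind("binary", 2))
        assert rep.bins[-1].observed_frequency == pytest.approx(0.5)

    def test_multiclass_pools_one_vs_rest(self):
        probs = np.array([[0.7, 0.2, 0.1], [0.1, 0.8, 0.1]])
        rep = calibration_curve([0, 1], probs, HeadKind("multiclass", 3))
        assert rep.n_pooled == 6  # (sample, class) pairs
        assert sum(b.count for b in rep.bins) == 6

    def test_brier_decomposition_for_binary(self):
        """Mean square error ~= reliability + refinement from the binned
        curve (equality up to within-bin variation)."""
        rng = np.random.default_rng(3)
        n = 50_000
        p = rng.beta(2, 2, n)
        y = (rng.uniform(0, 1, n) < p**1.3).astype(int)  # miscalibrated
        head = HeadKind("binary", 2)
        rep = calibration_curve(y, p, head, n_bins=20)
        bs = brier(y, p, head)
        rel = sum(b.count * (b.mean_predicted - b.observed_frequency) ** 2
                  for b in rep.bins if b.count) / n
        ref = sum(b.count * b.observed_frequency * (1 - b.observed_frequency)
                  for b in rep.bins if b.count) / n
        assert bs == pytest.approx(rel + ref, abs=0.01)


def frame_from(labels, decisions, patients=None):
    n = len(labels)
    patients = patients if patients is not None else [f"p{i // 2}" for i in range(n)]
    return pd.DataFrame({"patient_id": patients, "label": labels, "decision": decisions,
                         "score": np.asarray(decisions, float)})


def acc_metric(df):
    return float((df["label"].to_numpy() == df["decision"].to_numpy()).mean())


class TestBootstrap:
    def test_identical_models_not_significant(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 3, 80)
        decisions = np.clip(labels + rng.integers(-1, 2, 80), 0, 2)
        df = frame_from(labels, decisions)
        res = bootstrap_compare(df, df.copy(), acc_metric, n_boot=200, seed=1)
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_constant_metric_zero_width_ci(self):
        df = frame_from([1] * 40, [1] * 40)
        value, (lo, hi), reps = bootstrap_metric(df, acc_metric, n_boot=100, seed=0)
        assert value == 1.0 and lo == hi == 1.0

    def test_clearly_separated_models_significant(self):
        """A large true metric gap is detected in every harness repetition."""
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 3, 100)
        good = labels.copy()
        flip = rng.uniform(size=100) < 0.45
        bad = np.where(flip, (labels + 1) % 3, labels)
        for rep in range(10):
            res = bootstrap_compare(frame_from(labels, good), frame_from(labels, bad),
                                    acc_metric, n_boot=200, seed=rep)
            assert res.significant and res.mean_a > res.mean_b

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(4)
        for rep in range(20):
            labels = rng.integers(0, 3, 60)
            decisions = np.clip(labels + rng.integers(-1, 2, 60), 0, 2)
            df = frame_from(labels, decisions)
            value, (lo, hi), _ = bootstrap_metric(df, acc_metric, n_boot=300, seed=rep)
            assert lo <= value <= hi

    def test_mismatched_populations_rejected(self):
        a = frame_from([0, 1], [0, 1], ["a", "a"])
        b = frame_from([0, 1], [0, 1], ["b", "b"])
        with pytest.raises(ValueError):
            bootstrap_compare(a, b, acc_metric)

    def test_shared_resampling_pairs_replicates(self):
        """With identical per-patient metric contributions the paired
        replicate difference is exactly zero in every replicate."""
        rng = np.random.default_rng(9)
        labels = rng.integers(0, 3, 40)
        decisions = np.clip(labels + rng.integers(-1, 2, 40), 0, 2)
        a = frame_from(labels, decisions)
        b = a.copy()
        b["score"] += 10  # different scores, same accuracy contributions
        res = bootstrap_compare(a, b, acc_metric, n_boot=100, seed=3)
        assert res.mean_a == pytest.approx(res.mean_b)
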