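"""Classification metrics, calibration, and bootstrap model comparison.

Implements accuracy, quadratic weighted Cohen's kappa, the Brier score,
binned reliability curves, and the model-comparison procedure: patient-
grouped bootstrap (500 replicates) with a two-sided t-test on the paired
replicate distributions, significance at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mcrepeat.scoring import HeadKind

__all__ = [
    "accuracy",
    "quadratic_weighted_kappa",
    "brier",
    "calibration_curve",
    "CalibrationBin",
    "CalibrationReport",
    "ComparisonResult",
    "bootstrap_metric",
    "bootstrap_compare",
]


def accuracy(true: Sequence[int], pred: Sequence[int]) -> float:
    """Fraction of samples whose predicted class equals the true class."""
    true = np.asarray(true, int)
    pred = np.asarray(pred, int)
    if true.size == 0:
        raise ValueError("empty prediction set")
    if true.shape != pred.shape:
        raise ValueError("true and pred must have the same length")
    return float((true == pred).mean())


def quadratic_weighted_kappa(true: Sequence[int], pred: Sequence[int], k: int) -> float:
    """Quadratic weighted Cohen's kappa.

    kappa = 1 - (sum w_ij O_ij) / (sum w_ij E_ij) with weights
    w_ij = (i - j)^2 / (k - 1)^2, O the observed confusion counts and E
    the outer product of the marginals scaled to n. Returns NaN when the
    marginals are degenerate (a single class on both sides), where chance
    agreement is undefined.
    """
    true = np.asarray(true, int)
    pred = np.asarray(pred, int)
    if true.shape != pred.shape or true.size == 0:
        raise ValueError("true and pred must be equal-length and non-empty")
    if true.min() < 0 or true.max() >= k or pred.min() < 0 or pred.max() >= k:
        raise ValueError(f"classes must lie in 0..{k - 1}")
    O = np.zeros((k, k))
    np.add.at(O, (true, pred), 1.0)
    n = true.size
    E = np.outer(O.sum(axis=1), O.sum(axis=0)) / n
    i, j = np.indices((k, k))
    w = (i - j) ** 2 / (k - 1) ** 2
    denom = (w * E).sum()
    if denom == 0:
        return float("nan")
    return float(1.0 - (w * O).sum() / denom)


def brier(true: Sequence[int], probs: np.ndarray, head: HeadKind) -> float:
    """Brier score (0 = perfectly calibrated).

    Binary: mean (p_pos - y)^2. Multi-class (and ordinal scored as a
    k-class distribution): mean over samples of sum_c (p_c - 1{y=c})^2,
    range [0, 2]. Regression heads have no probabilities and are
    unsupported.
    """
    if head.kind == "regression":
        raise ValueError("Brier score is undefined for regression heads (no probabilities)")
    true = np.asarray(true, int)
    probs = np.asarray(probs, float)
    if head.kind == "binary":
        p = probs.ravel()
        if p.shape != true.shape:
            raise ValueError("binary Brier needs one probability per sample")
        return float(((p - true) ** 2).mean())
    if probs.ndim != 2 or probs.shape != (true.size, head.k):
        raise ValueError(f"expected probabilities of shape {(true.size, head.k)}")
    onehot = np.zeros_like(probs)
    onehot[np.arange(true.size), true] = 1.0
    return float(((probs - onehot) ** 2).sum(axis=1).mean())


@dataclass(frozen=True)
class CalibrationBin:
    lo: float
    hi: float
    count: int
    mean_predicted: float  # NaN when the bin is empty
    observed_frequency: float  # NaN when the bin is empty
    predicted_ci: tuple[float, float]  # 2.5/97.5 percentile span of predictions


@dataclass
class CalibrationReport:
    brier: float
    bins: list[CalibrationBin]
    n_pooled: int


def calibration_curve(true: Sequence[int], probs: np.ndarray, head: HeadKind,
                      n_bins: int = 10) -> CalibrationReport:
    """Reliability curve with per-bin predicted-value 95% CI spans.

    Multi-class predictions are pooled one-vs-rest over (sample, class)
    pairs; binary models contribute their positive-class probability per
    sample. Probabilities are partitioned into ``n_bins`` equal-width bins
    on [0, 1]; empty bins are emitted with count 0 and NaN statistics.
    """
    true = np.asarray(true, int)
    probs = np.asarray(probs, float)
    if head.kind == "binary":
        p = probs.ravel()
        y = true.astype(float)
    else:
        if probs.ndim != 2:
            raise ValueError("multi-class calibration needs a (n, k) probability matrix")
        p = probs.ravel()
        y = (true[:, None] == np.arange(probs.shape[1])[None, :]).astype(float).ravel()
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    bins = []
    for b in range(n_bins):
        mask = idx == b
        cnt = int(mask.sum())
        if cnt == 0:
            bins.append(CalibrationBin(edges[b], edges[b + 1], 0, float("nan"), float("nan"),
                                       (float("nan"), float("nan"))))
            continue
        pb = p[mask]
        ci = tuple(np.percentile(pb, [2.5, 97.5]))
        bins.append(CalibrationBin(edges[b], edges[b + 1], cnt, float(pb.mean()),
                                   float(y[mask].mean()), (float(ci[0]), float(ci[1]))))
    return CalibrationReport(brier=brier(true, probs, head), bins=bins, n_pooled=p.size)


@dataclass
class ComparisonResult:
    metric: str
    mean_a: float
    ci_a: tuple[float, float]
    mean_b: float
    ci_b: tuple[float, float]
    p_value: float
    significant: bool
    n_replicates: int
    n_dropped: int = 0


def _grouped_indices(patient_ids: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    patients, inverse = np.unique(patient_ids, return_inverse=True)
    rows = [np.flatnonzero(inverse == i) for i in range(len(patients))]
    return patients, rows


def bootstrap_metric(df: pd.DataFrame, metric: Callable[[pd.DataFrame], float],
                     n_boot: int = 500, seed: int = 0) -> tuple[float, tuple[float, float], np.ndarray]:
    """Patient-grouped bootstrap of a metric: point estimate, percentile
    95% CI, and the replicate values."""
    reps = _bootstrap_replicates(df, metric, n_boot, seed)
    reps_ok = reps[np.isfinite(reps)]
    lo, hi = np.percentile(reps_ok, [2.5, 97.5])
    return float(metric(df)), (float(lo), float(hi)), reps


def _bootstrap_replicates(df: pd.DataFrame, metric, n_boot: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    _, rows = _grouped_indices(df["patient_id"].to_numpy())
    n_pat = len(rows)
    out = np.empty(n_boot)
    for b in range(n_boot):
        chosen = rng.integers(0, n_pat, size=n_pat)
        take = np.concatenate([rows[c] for c in chosen])
        try:
            out[b] = metric(df.iloc[take])
        except (ValueError, ZeroDivisionError):
            out[b] = np.nan
    return out


def bootstrap_compare(preds_a: pd.DataFrame, preds_b: pd.DataFrame,
                      metric: Callable[[pd.DataFrame], float], metric_name: str = "metric",
                      n_boot: int = 500, seed: int = 0) -> ComparisonResult:
    """Compare two models' metric by grouped bootstrap + paired t-test.

    Both prediction frames must cover the same patient population (same
    ``patient_id`` values). Patients are resampled with replacement using
    the SAME resample indices for both models in each of the ``n_boot``
    replicates; the p value is a two-sided t-test on the paired replicate
    distributions, and each model's 95% CI is the percentile interval of
    its replicates. Replicates where the metric is undefined for either
    model are dropped (and counted).
    """
    pats_a, rows_a = _grouped_indices(preds_a["patient_id"].to_numpy())
    pats_b, rows_b = _grouped_indices(preds_b["patient_id"].to_numpy())
    if not np.array_equal(pats_a, pats_b):
        raise ValueError("prediction sets cover different patient populations")
    rng = np.random.default_rng(seed)
    n_pat = len(pats_a)
    reps_a = np.empty(n_boot)
    reps_b = np.empty(n_boot)
    for b in range(n_boot):
        chosen = rng.integers(0, n_pat, size=n_pat)
        for reps, df, rows in ((reps_a, preds_a, rows_a), (reps_b, preds_b, rows_b)):
            take = np.concatenate([rows[c] for c in chosen])
            try:
                reps[b] = metric(df.iloc[take])
            except (ValueError, ZeroDivisionError):
                reps[b] = np.nan
    ok = np.isfinite(reps_a) & np.isfinite(reps_b)
    n_dropped = int(n_boot - ok.sum())
    ra, rb = reps_a[ok], reps_b[ok]
    if ra.size < 2:
        raise ValueError("too few valid bootstrap replicates for comparison")
    diffs = ra - rb
    if np.allclose(diffs, 0.0):
        p_value = 1.0
    else:
        p_value = float(stats.ttest_rel(ra, rb).pvalue)
    ci_a = tuple(float(v) for v in np.percentile(ra, [2.5, 97.5]))
    ci_b = tuple(float(v) for v in np.percentile(rb, [2.5, 97.5]))
    return ComparisonResult(
        metric=metric_name,
        mean_a=float(ra.mean()), ci_a=ci_a,
        mean_b=float(rb.mean()), ci_b=ci_b,
        p_value=p_value, significant=p_value < 0.05,
        n_replicates=int(ok.sum()), n_dropped=n_dropped,
    )
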