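"""Tabular outputs and MC-vs-conventional comparison reports.

Writers for the per-model metric table (disagreement rate, normalized 95%
LoA, quadratic weighted kappa, accuracy, each with a patient-grouped
bootstrap 95% CI), the Bland-Altman point cloud, the per-bin calibration
curve, and the pairwise MC-vs-conventional comparison (bootstrap + paired
t-test) in machine-readable JSON. The reporter only consumes stage output
files; it never recomputes predictions.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from mcrepeat.evaluation import bootstrap_compare, bootstrap_metric
from mcrepeat.pipeline import ModelEvaluation, groups_from_frame
from mcrepeat.repeatability import bland_altman_points, disagreement_rate, loa95
from mcrepeat.scoring import HeadKind, score_range

__all__ = [
    "metric_functions",
    "write_evaluation",
    "load_predictions",
    "compare_models",
    "write_comparison",
]

logger = logging.getLogger(__name__)


def metric_functions(head: HeadKind) -> dict:
    """Metric name -> callable(prediction frame) -> float.

    Each callable accepts a per-image prediction frame (patient_id, label,
    score, decision) so it can be used directly by the grouped bootstrap.
    """
    sr = score_range(head)

    def _disag(df: pd.DataFrame) -> float:
        return disagreement_rate(groups_from_frame(df, sr))

    def _loa(df: pd.DataFrame) -> float:
        return loa95(bland_altman_points(groups_from_frame(df, sr)), sr)

    def _acc(df: pd.DataFrame) -> float:
        return float((df["label"].to_numpy() == df["decision"].to_numpy()).mean())

    def _kappa(df: pd.DataFrame) -> float:
        from mcrepeat.evaluation import quadratic_weighted_kappa

        v = quadratic_weighted_kappa(df["label"].to_numpy(), df["decision"].to_numpy(), head.k)
        if np.isnan(v):
            raise ValueError("kappa undefined on degenerate marginals")
        return v

    return {"disagreement_rate": _disag, "loa95": _loa, "kappa": _kappa, "accuracy": _acc}


def write_evaluation(ev: ModelEvaluation, out_dir: str | Path, model_name: str,
                     n_boot: int = 500, seed: int = 0) -> dict:
    """Write metrics/Bland-Altman/calibration/prediction CSVs for one model.

    Returns the metric rows as a dict for convenience. The metrics CSV has
    one row per metric with the point value and a patient-grouped
    bootstrap percentile 95% CI.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = ev.predictions
    rows = []
    for name, fn in metric_functions(ev.head).items():
        try:
            value, (lo, hi), _ = bootstrap_metric(frame, fn, n_boot=n_boot, seed=seed)
        except ValueError as exc:
            logger.warning("metric %s omitted for %s: %s", name, model_name, exc)
            continue
        rows.append({"model": model_name, "metric": name, "value": value,
                     "ci_lower": lo, "ci_upper": hi})
    if ev.calibration is not None:
        rows.append({"model": model_name, "metric": "brier",
                     "value": ev.calibration.brier, "ci_lower": np.nan, "ci_upper": np.nan})
    else:
        logger.info("Brier omitted for %s: regression head has no probabilities", model_name)
    metrics = pd.DataFrame(rows)
    metrics.to_csv(out / f"{model_name}_metrics.csv", index=False)

    pts = ev.repeatability.points
    pd.DataFrame({"mean": [p.mean_score for p in pts],
                  "difference": [p.difference for p in pts]}).to_csv(
        out / f"{model_name}_bland_altman.csv", index=False)

    if ev.calibration is not None:
        pd.DataFrame([{
            "bin_lo": b.lo, "bin_hi": b.hi, "count": b.count,
            "mean_predicted": b.mean_predicted, "observed_frequency": b.observed_frequency,
            "predicted_ci_lower": b.predicted_ci[0], "predicted_ci_upper": b.predicted_ci[1],
        } for b in ev.calibration.bins]).to_csv(out / f"{model_name}_calibration.csv", index=False)

    frame.drop(columns=["output"]).to_csv(out / f"{model_name}_predictions.csv", index=False)
    return {r["metric"]: r["value"] for r in rows}


def load_predictions(path: str | Path) -> pd.DataFrame:
    """Read a predictions CSV written by :func:`write_evaluation`."""
    df = pd.read_csv(path, dtype={"patient_id": str, "image_id": str})
    required = {"patient_id", "label", "score", "decision"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"predictions file {path} lacks columns {sorted(missing)}")
    return df


#: metrics where a smaller value is better
LOWER_IS_BETTER = {"disagreement_rate", "loa95", "brier"}


def compare_models(preds_mc: pd.DataFrame, preds_plain: pd.DataFrame, head: HeadKind,
                   n_boot: int = 500, seed: int = 0) -> list[dict]:
    """Pairwise MC-vs-conventional comparison over all metrics.

    Runs the shared-resample grouped bootstrap with a two-sided t-test per
    metric and marks the significant winner (p < 0.05), mirroring a
    bold-the-winner results table.
    """
    results = []
    for name, fn in metric_functions(head).items():
        try:
            cmp_ = bootstrap_compare(preds_mc, preds_plain, fn, metric_name=name,
                                     n_boot=n_boot, seed=seed)
        except ValueError as exc:
            logger.warning("comparison for %s skipped: %s", name, exc)
            continue
        if not cmp_.significant:
            winner = None
        else:
            mc_better = cmp_.mean_a < cmp_.mean_b if name in LOWER_IS_BETTER else cmp_.mean_a > cmp_.mean_b
            winner = "mc" if mc_better else "conventional"
        results.append({
            "metric": name,
            "mc_mean": cmp_.mean_a, "mc_ci": list(cmp_.ci_a),
            "conventional_mean": cmp_.mean_b, "conventional_ci": list(cmp_.ci_b),
            "p_value": cmp_.p_value, "significant": cmp_.significant,
            "winner": winner, "n_replicates": cmp_.n_replicates,
            "n_dropped": cmp_.n_dropped,
        })
    return results


def write_comparison(results: list[dict], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps({"comparisons": results}, indent=2))
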