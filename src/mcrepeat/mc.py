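"""Test-time Monte Carlo dropout: sampling, aggregation, iteration sweep.

At inference the dropout layers are re-enabled while everything else stays
in evaluation mode, and N stochastic forward passes are drawn per image
(default N = 50). The final prediction is the element-wise average of the
draws in probability space, an approximate Bayesian posterior predictive
mean. A dropout-disabled single pass is the conventional baseline.

The dropout-mask RNG is restarted from the configured seed at every
inference call, so the N mask realizations are a frozen, reproducible
sequence shared by all images: a prediction depends only on (model,
image, seed) — never on batch composition or iteration order — identical
inputs receive identical MC predictions, and the test-retest difference
between two views of a patient is free of evaluation-side mask noise
(common random numbers). The first n draws of a larger sample are a valid
n-draw sample, which the iteration sweep exploits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from mcrepeat.scoring import HeadKind, decide_class, score_from_binary, score_from_ordinal, score_from_probs

__all__ = [
    "MCConfig",
    "MCPredictionSet",
    "mc_forward",
    "aggregate",
    "deterministic_forward",
    "score_output",
    "sweep_iterations",
]


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo sampling configuration (N draws, seed, mean aggregate)."""

    n_samples: int = 50
    seed: int = 0
    aggregate: str = "mean"

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be >= 1, got {self.n_samples}")
        if self.aggregate != "mean":
            raise ValueError(f"unsupported aggregate {self.aggregate!r}")


@dataclass(frozen=True)
class MCPredictionSet:
    """The N raw head outputs of one input under test-time dropout."""

    draws: np.ndarray  # (N, output_width)
    head: HeadKind
    seed: int

    def __post_init__(self) -> None:
        if self.draws.ndim != 2 or len(self.draws) < 1:
            raise ValueError("draws must be a non-empty (N, width) array")


def mc_forward(model, image: np.ndarray, cfg: MCConfig) -> MCPredictionSet:
    """Draw ``cfg.n_samples`` stochastic forward passes for one image.

    The model must contain dropout layers; running MC on a dropout-free
    model would silently equal a single deterministic pass, so it is an
    error. The mask RNG restarts from ``cfg.seed`` for every call, so the
    same seed yields bitwise-identical draw sequences and identical images
    receive identical predictions.
    """
    if not model.has_dropout:
        raise ValueError("model has no dropout layers; MC sampling would equal a single pass")
    x = np.asarray(image, dtype=float)
    if x.ndim == 3:
        x = x[None]
    if x.shape[0] != 1:
        raise ValueError("mc_forward operates on a single image")
    # one batched pass: the N draws are rows of a tiled batch. Each dropout
    # layer gets its own child stream so the first n rows are identical
    # across different N (prefix/common-random-number property).
    tiled = np.repeat(x, cfg.n_samples, axis=0)
    layers = model.net.dropout_layers
    children = np.random.SeedSequence(cfg.seed).spawn(len(layers))
    try:
        for layer, child in zip(layers, children):
            layer.mask_rng = np.random.default_rng(child)
        draws = model.predict(tiled, stochastic=True)
    finally:
        for layer in layers:
            layer.mask_rng = None
    return MCPredictionSet(draws=draws, head=model.head, seed=cfg.seed)


def aggregate(preds: MCPredictionSet) -> np.ndarray:
    """Element-wise mean of the draws (the final MC prediction).

    For a multiclass head the mean of probability vectors is itself a
    valid probability vector; for regression it is the mean scalar.
    """
    if len(preds.draws) == 0:
        raise ValueError("empty prediction set")
    return preds.draws.mean(axis=0)


def deterministic_forward(model, image: np.ndarray) -> np.ndarray:
    """Single forward pass with dropout disabled (the non-MC baseline)."""
    x = np.asarray(image, dtype=float)
    if x.ndim == 3:
        x = x[None]
    return model.predict(x, stochastic=False)[0]


def score_output(output: np.ndarray, head: HeadKind) -> float:
    """Continuous severity score of an aggregated head output."""
    output = np.asarray(output, dtype=float)
    if head.kind == "multiclass":
        return score_from_probs(output)
    if head.kind == "ordinal":
        return score_from_ordinal(output)
    if head.kind == "binary":
        return score_from_binary(output.reshape(()).item() if output.ndim == 0 else output.ravel()[0])
    return float(output.ravel()[0])


def sweep_iterations(
    model,
    records: Iterable[tuple[str, str, np.ndarray]],
    n_grid: Sequence[int],
    cfg: MCConfig,
    score_range: tuple[float, float] | None = None,
) -> dict:
    """Repeatability (normalized 95% LoA) as a function of MC iterations.

    ``records`` yields ``(patient_id, image_id, image)`` with >= 2 images
    per patient. One N_max-draw MC sample is taken per image
    (N_max = max(n_grid)); the prediction at grid point n aggregates the
    FIRST n draws, so all grid points share the same random draws and the
    curve is free of resampling noise. The dropout-disabled single-pass
    baseline is reported separately.

    Returns ``{"loa_by_n": {n: loa}, "disagreement_by_n": {n: rate},
    "baseline_loa": float, "baseline_disagreement": float}``.
    """
    from mcrepeat.repeatability import (
        TestRetestGroup,
        bland_altman_points,
        decide_loa_path,
        disagreement_rate,
        loa95,
    )

    n_grid = sorted(int(n) for n in n_grid)
    if n_grid[0] < 1:
        raise ValueError("n_grid entries must be >= 1")
    n_max = n_grid[-1]
    if n_max > cfg.n_samples:
        raise ValueError(f"n_grid maximum {n_max} exceeds configured n_samples {cfg.n_samples}")
    head = model.head
    if score_range is None:
        from mcrepeat.scoring import score_range as _default_range

        score_range = _default_range(head)
    rng_range = score_range

    per_patient: dict[str, list[np.ndarray]] = {}
    baseline: dict[str, list[np.ndarray]] = {}
    order: list[str] = []
    for patient_id, image_id, image in records:
        preds = mc_forward(model, image, MCConfig(n_samples=n_max, seed=cfg.seed))
        # prefix means over draws: cumulative sum / n
        cums = np.cumsum(preds.draws, axis=0) / np.arange(1, n_max + 1)[:, None]
        if patient_id not in per_patient:
            per_patient[patient_id] = []
            baseline[patient_id] = []
            order.append(patient_id)
        per_patient[patient_id].append(cums)
        baseline[patient_id].append(deterministic_forward(model, image))

    def _points(outputs_by_patient: dict[str, list[np.ndarray]]):
        groups = []
        for pid in order:
            outs = outputs_by_patient[pid]
            if len(outs) < 2:
                continue
            scores = [score_output(o, head) for o in outs]
            decisions = [decide_class(o, head, rng_range) for o in outs]
            groups.append(TestRetestGroup(patient_id=pid, scores=scores, decisions=decisions,
                                          score_range=rng_range))
        return bland_altman_points(groups), groups

    # one normality decision (taken at the full sample size) covers every
    # grid point, so the curve cannot jump between LoA conventions
    at_full = {pid: [c[n_max - 1] for c in cums_list] for pid, cums_list in per_patient.items()}
    pts_full, _ = _points(at_full)
    path = decide_loa_path(np.asarray([p.difference for p in pts_full]))

    loa_by_n: dict[int, float] = {}
    dis_by_n: dict[int, float] = {}
    for n in n_grid:
        at_n = {pid: [c[n - 1] for c in cums_list] for pid, cums_list in per_patient.items()}
        pts, groups = _points(at_n)
        loa_by_n[n] = loa95(pts, rng_range, path=path)
        dis_by_n[n] = disagreement_rate(groups)
    pts_b, groups_b = _points(baseline)
    base_loa, base_dis = loa95(pts_b, rng_range, path=path), disagreement_rate(groups_b)
    return {
        "loa_by_n": loa_by_n,
        "disagreement_by_n": dis_by_n,
        "baseline_loa": base_loa,
        "baseline_disagreement": base_dis,
    }
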