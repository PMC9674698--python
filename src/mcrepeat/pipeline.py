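"""End-to-end benchmark orchestration.

Glue between the synthetic benchmark, the model zoo, MC inference and the
metric modules: train a dropout / no-dropout variant pair per head kind on
one dataset, predict the test split (MC-averaged or single-pass), and
summarize repeatability, classification and calibration per model.

The reference benchmark conditions (k=3 classes, 300 patients, 2 views
per patient, boundary noise SD 0.25) are the package defaults in
:class:`mcrepeat.synthetic.GeneratorConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mcrepeat import mc as mcmod
from mcrepeat.evaluation import CalibrationReport, accuracy, calibration_curve, quadratic_weighted_kappa
from mcrepeat.models import ModelSpec, SmallCNN, TrainConfig, TrainHistory, build_model, train
from mcrepeat.repeatability import RepeatabilityReport, TestRetestGroup, repeatability_report
from mcrepeat.scoring import HeadKind, decide_class, score_range
from mcrepeat.synthetic import GeneratorConfig, SyntheticDataset, generate_dataset

__all__ = [
    "BenchmarkConfig",
    "ModelEvaluation",
    "binarize_labels",
    "labels_for_head",
    "train_variant",
    "predict_split",
    "evaluate_predictions",
    "groups_from_frame",
    "run_variant_pair",
    "sweep_mc_model",
    "plateau_iterations",
    "run_reference_benchmark",
]

logger = logging.getLogger(__name__)

DEFAULT_MC_GRID = (1, 2, 5, 10, 20, 30, 40, 50)


@dataclass(frozen=True)
class BenchmarkConfig:
    """One benchmark run: dataset conditions + training + MC settings."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    dropout_rate: float = 0.1
    mc_samples: int = 50
    binary_cut: int = 1  # positive class: label >= cut


def binarize_labels(labels: np.ndarray, cut: int = 1) -> np.ndarray:
    """Collapse k ordinal classes to binary: positive iff label >= cut."""
    return (np.asarray(labels, int) >= cut).astype(int)


def labels_for_head(labels: np.ndarray, head: HeadKind, cut: int = 1) -> np.ndarray:
    return binarize_labels(labels, cut) if head.kind == "binary" else np.asarray(labels, int)


def head_for_kind(kind: str, k: int) -> HeadKind:
    return HeadKind(kind, 2 if kind == "binary" else k)


def train_variant(ds: SyntheticDataset, head: HeadKind, dropout_rate: float | None,
                  train_cfg: TrainConfig, binary_cut: int = 1) -> tuple[SmallCNN, TrainHistory]:
    """Train one model variant on the dataset's train/val splits."""
    x_tr, y_tr, _ = ds.split("train")
    x_va, y_va, _ = ds.split("val")
    y_tr = labels_for_head(y_tr, head, binary_cut)
    y_va = labels_for_head(y_va, head, binary_cut)
    spec = ModelSpec(head=head, dropout_rate=dropout_rate,
                     input_size=ds.config.image_size, seed=train_cfg.seed)
    model = build_model(spec)
    hist = train(model, x_tr.astype(float), y_tr, x_va.astype(float), y_va, train_cfg)
    return model, hist


def predict_split(model: SmallCNN, ds: SyntheticDataset, split: str, *,
                  use_mc: bool, mc_cfg: mcmod.MCConfig | None = None,
                  binary_cut: int = 1) -> pd.DataFrame:
    """Per-image predictions on one split.

    Columns: patient_id, image_id, label (head-specific), score, decision,
    output (the raw aggregated head output as a list). MC predictions
    average ``mc_cfg.n_samples`` dropout draws per image with per-image
    RNG substreams; otherwise a single dropout-disabled pass is used.
    """
    head = model.head
    x, y, man = ds.split(split)
    y = labels_for_head(y, head, binary_cut)
    sr = score_range(head)
    rows = []
    for i in range(len(x)):
        img = x[i].astype(float)
        image_id = man["image_id"].iloc[i]
        if use_mc:
            preds = mcmod.mc_forward(model, img, mc_cfg or mcmod.MCConfig())
            out = mcmod.aggregate(preds)
        else:
            out = mcmod.deterministic_forward(model, img)
        if head.kind == "binary":
            out_for_decision = out.ravel()[0]
        else:
            out_for_decision = out
        rows.append({
            "patient_id": man["patient_id"].iloc[i],
            "image_id": image_id,
            "label": int(y[i]),
            "score": mcmod.score_output(out, head),
            "decision": decide_class(out_for_decision, head, sr),
            "output": out.tolist(),
        })
    return pd.DataFrame(rows)


def groups_from_frame(frame: pd.DataFrame, sr: tuple[float, float]) -> list[TestRetestGroup]:
    """Assemble per-patient test-retest groups from a prediction frame."""
    groups = []
    for pid, sub in frame.groupby("patient_id", sort=False):
        groups.append(TestRetestGroup(
            patient_id=str(pid),
            scores=sub["score"].tolist(),
            decisions=sub["decision"].tolist(),
            score_range=sr,
        ))
    return groups


@dataclass
class ModelEvaluation:
    """All reported quantities for one model on one test split."""

    head: HeadKind
    use_mc: bool
    predictions: pd.DataFrame
    repeatability: RepeatabilityReport
    accuracy: float
    kappa: float
    calibration: CalibrationReport | None  # None for regression heads
    history: TrainHistory | None = None


def evaluate_predictions(frame: pd.DataFrame, head: HeadKind, *, use_mc: bool,
                         history: TrainHistory | None = None) -> ModelEvaluation:
    sr = score_range(head)
    groups = groups_from_frame(frame, sr)
    rep = repeatability_report(groups, sr)
    true = frame["label"].to_numpy()
    pred = frame["decision"].to_numpy()
    acc = accuracy(true, pred)
    kap = quadratic_weighted_kappa(true, pred, head.k)
    cal = None
    if head.kind != "regression":
        probs = _probs_matrix(frame, head)
        cal = calibration_curve(true, probs, head)
    return ModelEvaluation(head=head, use_mc=use_mc, predictions=frame,
                           repeatability=rep, accuracy=acc, kappa=kap,
                           calibration=cal, history=history)


def _probs_matrix(frame: pd.DataFrame, head: HeadKind) -> np.ndarray:
    out = np.stack([np.asarray(o, dtype=float) for o in frame["output"]])
    if head.kind == "binary":
        return out.ravel()
    if head.kind == "ordinal":
        # score the ordinal output as a k-class distribution: adjacent
        # differences of the cumulative P(class > j) curve
        q = np.clip(out, 0.0, 1.0)
        cum = np.hstack([np.ones((len(q), 1)), q, np.zeros((len(q), 1))])
        cum = np.minimum.accumulate(cum, axis=1)  # enforce monotone cumulative curve
        return np.clip(cum[:, :-1] - cum[:, 1:], 0.0, None)
    return out


def sweep_mc_model(model: SmallCNN, ds: SyntheticDataset, n_grid, seed: int,
                   split: str = "test") -> dict:
    """MC-iteration sweep of a trained dropout model on one split."""
    x, _, man = ds.split(split)
    records = ((man["patient_id"].iloc[i], man["image_id"].iloc[i], x[i].astype(np.float32))
               for i in range(len(x)))
    cfg = mcmod.MCConfig(n_samples=max(int(n) for n in n_grid), seed=seed)
    return mcmod.sweep_iterations(model, records, n_grid, cfg)


def plateau_iterations(loa_by_n: dict[int, float], rel_tol: float = 0.05) -> int:
    """Smallest grid n from which repeatability matches the full sample.

    Returns the smallest n whose LoA is at most ``(1 + rel_tol)`` times
    the LoA at the largest grid n. One-sided on purpose: the sweep asks
    when further MC iterations stop improving repeatability, and a grid
    point whose LoA is already below the full-sample value has nothing
    left to gain.
    """
    ns = sorted(loa_by_n)
    ref = loa_by_n[ns[-1]]
    for n in ns:
        if loa_by_n[n] <= ref * (1.0 + rel_tol):
            return n
    return ns[-1]


def run_reference_benchmark(seeds, kind: str = "multiclass",
                            n_grid=DEFAULT_MC_GRID, sweep: bool = True) -> list[dict]:
    """Run the packaged reference benchmark for several seeds.

    Per seed: generate the default synthetic dataset, train the dropout
    and conventional variants of ``kind``, evaluate both on the test
    split, and (optionally) sweep MC iterations for the dropout model.
    Returns one dict per seed with the headline metrics.
    """
    out = []
    for seed in seeds:
        seed = int(seed)
        ds = generate_dataset(GeneratorConfig(seed=seed))
        bench = BenchmarkConfig(generator=ds.config, train=TrainConfig(seed=seed))
        head = head_for_kind(kind, ds.config.k)
        mc_cfg = mcmod.MCConfig(n_samples=bench.mc_samples, seed=seed)
        model_mc, hist_mc = train_variant(ds, head, bench.dropout_rate, bench.train)
        model_plain, hist_plain = train_variant(ds, head, None, bench.train)
        frame_mc = predict_split(model_mc, ds, "test", use_mc=True, mc_cfg=mc_cfg)
        frame_plain = predict_split(model_plain, ds, "test", use_mc=False)
        ev_mc = evaluate_predictions(frame_mc, head, use_mc=True, history=hist_mc)
        ev_plain = evaluate_predictions(frame_plain, head, use_mc=False, history=hist_plain)
        rec = {
            "seed": seed,
            "mc": ev_mc,
            "plain": ev_plain,
            "mc_disagreement": ev_mc.repeatability.disagreement_rate,
            "plain_disagreement": ev_plain.repeatability.disagreement_rate,
            "mc_loa95": ev_mc.repeatability.loa95,
            "plain_loa95": ev_plain.repeatability.loa95,
            "mc_brier": ev_mc.calibration.brier if ev_mc.calibration else float("nan"),
            "plain_brier": ev_plain.calibration.brier if ev_plain.calibration else float("nan"),
            "mc_accuracy": ev_mc.accuracy,
            "plain_accuracy": ev_plain.accuracy,
        }
        if sweep:
            sw = sweep_mc_model(model_mc, ds, n_grid, seed)
            rec["sweep"] = sw
            rec["plateau_n"] = plateau_iterations(sw["loa_by_n"])
        out.append(rec)
        logger.info("benchmark seed %d done", seed)
    return out


def run_variant_pair(ds: SyntheticDataset, kind: str, bench: BenchmarkConfig,
                     split: str = "test") -> tuple[ModelEvaluation, ModelEvaluation]:
    """Train and evaluate the MC (dropout) and conventional variants of one
    head kind on a dataset. Returns ``(mc_eval, plain_eval)``."""
    head = head_for_kind(kind, ds.config.k)
    mc_cfg = mcmod.MCConfig(n_samples=bench.mc_samples, seed=bench.train.seed)
    model_mc, hist_mc = train_variant(ds, head, bench.dropout_rate, bench.train, bench.binary_cut)
    model_plain, hist_plain = train_variant(ds, head, None, bench.train, bench.binary_cut)
    frame_mc = predict_split(model_mc, ds, split, use_mc=True, mc_cfg=mc_cfg,
                             binary_cut=bench.binary_cut)
    frame_plain = predict_split(model_plain, ds, split, use_mc=False,
                                binary_cut=bench.binary_cut)
    ev_mc = evaluate_predictions(frame_mc, head, use_mc=True, history=hist_mc)
    ev_plain = evaluate_predictions(frame_plain, head, use_mc=False, history=hist_plain)
    logger.info("%s: MC disag=%.3f loa=%.3f | plain disag=%.3f loa=%.3f", kind,
                ev_mc.repeatability.disagreement_rate, ev_mc.repeatability.loa95,
                ev_plain.repeatability.disagreement_rate, ev_plain.repeatability.loa95)
    return ev_mc, ev_plain
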