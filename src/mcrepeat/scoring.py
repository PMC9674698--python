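"""Severity-score mappings and class decisions for the four head types.

Every head's raw output is summarized as a continuous severity score so
predictions can be compared on a common scale:

* multi-class: the probability-weighted class index, ``s = sum_i p_i (i-1)``
  with one-based ``i`` (equivalently ``sum_c p_c * c`` over zero-based
  classes) — lies in ``[0, k-1]``;
* ordinal (CORAL decode): the sum of the ``k-1`` per-threshold sigmoid
  outputs — lies in ``[0, k-1]``;
* binary: the positive-class probability, used directly;
* regression: the raw scalar output, used directly (not clamped).

Discrete class decisions are derived deterministically from the same
outputs; regression scores are binned by equal-range thresholds (for a
3-class problem on [0, 2]: s <= 0.67 -> class 0, 0.67 < s <= 1.33 ->
class 1, s >= 1.33 -> class 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "HeadKind",
    "score_from_probs",
    "score_from_ordinal",
    "score_from_binary",
    "encode_ordinal_label",
    "equal_range_thresholds",
    "decide_class",
    "score_range",
]

_KINDS = ("binary", "multiclass", "ordinal", "regression")

#: tolerance on probability-vector normalization
_SIMPLEX_ATOL = 1e-6


@dataclass(frozen=True)
class HeadKind:
    """Model head type and number of ordinal classes.

    Parameters
    ----------
    kind:
        One of ``"binary"``, ``"multiclass"``, ``"ordinal"``,
        ``"regression"``.
    k:
        Number of ordinal classes. Binary heads have ``k == 2``;
        multi-class and ordinal heads require ``k >= 3`` (a 2-class
        multi-class model is just a binary model).
    """

    kind: str
    k: int

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown head kind {self.kind!r}; expected one of {_KINDS}")
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        if self.kind == "binary" and self.k != 2:
            raise ValueError("binary head requires k == 2")
        if self.kind in ("multiclass", "ordinal") and self.k < 3:
            raise ValueError(f"{self.kind} head requires k >= 3 to be distinct from binary")

    @property
    def output_width(self) -> int:
        """Width of the raw head output vector."""
        if self.kind == "multiclass":
            return self.k
        if self.kind == "ordinal":
            return self.k - 1
        return 1


def score_range(head: HeadKind) -> tuple[float, float]:
    """Possible range ``(lo, hi)`` of the severity score for ``head``.

    Binary scores are probabilities in [0, 1]; multi-class and ordinal
    scores lie in [0, k-1]. Regression outputs are unbounded in principle,
    but since targets are the class indices the nominal reporting range is
    also [0, k-1] (used to normalize limits of agreement).
    """
    if head.kind == "binary":
        return (0.0, 1.0)
    return (0.0, float(head.k - 1))


def _validate_probs(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError(f"probability vector must be 1-D with k >= 2, got shape {p.shape}")
    if np.any(p < -_SIMPLEX_ATOL) or np.any(p > 1 + _SIMPLEX_ATOL):
        raise ValueError("probabilities must lie in [0, 1]")
    if abs(p.sum() - 1.0) > _SIMPLEX_ATOL:
        raise ValueError(f"probabilities must sum to 1 (got {p.sum():.8f})")
    return p


def score_from_probs(p: Sequence[float]) -> float:
    """Probability-weighted severity score ``sum_i p_i * (i - 1)``.

    ``i`` runs one-based over the ``k`` classes, so the score is the
    expected zero-based class index and lies in ``[0, k-1]``.
    """
    p = _validate_probs(p)
    return float(np.dot(p, np.arange(p.size)))


def score_from_ordinal(q: Sequence[float]) -> float:
    """Ordinal severity score: the sum of the k-1 per-threshold outputs."""
    q = np.asarray(q, dtype=float)
    if q.ndim != 1 or q.size < 1:
        raise ValueError(f"ordinal output must be 1-D with k-1 >= 1 entries, got shape {q.shape}")
    if np.any(q < 0) or np.any(q > 1):
        raise ValueError("ordinal outputs must lie in [0, 1]")
    return float(q.sum())


def score_from_binary(p_pos: float) -> float:
    """Binary severity score: the positive-class probability, unchanged."""
    p_pos = float(p_pos)
    if not 0.0 <= p_pos <= 1.0:
        raise ValueError(f"binary probability must lie in [0, 1], got {p_pos}")
    return p_pos


def encode_ordinal_label(c: int, k: int) -> np.ndarray:
    """Cumulative (CORAL) encoding of class ``c`` as ``k-1`` bits.

    Bit ``j`` (one-based over the k-1 threshold tasks) is 1 iff ``j <= c``,
    i.e. the encoding is a prefix of ones whose length is the zero-based
    class index: for k=3, class 0 -> [0, 0], class 1 -> [1, 0],
    class 2 -> [1, 1].
    """
    c = int(c)
    if k < 2:
        raise ValueError("k must be >= 2")
    if not 0 <= c <= k - 1:
        raise ValueError(f"class {c} out of range 0..{k - 1}")
    return (np.arange(1, k) <= c).astype(float)


def equal_range_thresholds(k: int, lo: float, hi: float) -> np.ndarray:
    """Thresholds splitting ``[lo, hi]`` into ``k`` equal-width intervals.

    Returns the ``k-1`` interior cut points ``t_j = lo + j (hi - lo) / k``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not hi > lo:
        raise ValueError(f"degenerate range [{lo}, {hi}]")
    j = np.arange(1, k)
    return lo + j * (hi - lo) / k


def _decide_regression(s: float, k: int, lo: float, hi: float) -> int:
    # interior intervals left-open/right-closed; outermost inequalities
    # closed, covering the whole real line (scores are not clamped)
    t = equal_range_thresholds(k, lo, hi)
    if s <= t[0]:
        return 0
    if s >= t[-1]:
        return k - 1
    return int(np.searchsorted(t, s, side="left"))


def decide_class(output, head: HeadKind, score_range_: tuple[float, float] | None = None) -> int:
    """Discrete class decision from a raw head output.

    * multiclass: argmax of the probability vector (ties break toward the
      lower class index);
    * binary: 1 iff the positive probability is >= 0.5;
    * ordinal: the count of per-threshold outputs >= 0.5 (standard CORAL
      decode);
    * regression: the equal-range-threshold bin of the scalar over
      ``score_range_`` (defaults to ``(0, k-1)``), with interior intervals
      left-open/right-closed and closed outer intervals.
    """
    if head.kind == "multiclass":
        p = _validate_probs(output)
        if p.size != head.k:
            raise ValueError(f"expected {head.k} probabilities, got {p.size}")
        return int(np.argmax(p))
    if head.kind == "binary":
        return int(score_from_binary(np.asarray(output).reshape(()).item()) >= 0.5)
    if head.kind == "ordinal":
        q = np.asarray(output, dtype=float)
        if q.shape != (head.k - 1,):
            raise ValueError(f"expected {head.k - 1} ordinal outputs, got shape {q.shape}")
        if np.any(q < 0) or np.any(q > 1):
            raise ValueError("ordinal outputs must lie in [0, 1]")
        return int(np.count_nonzero(q >= 0.5))
    # regression
    s = float(np.asarray(output).reshape(()).item())
    lo, hi = score_range_ if score_range_ is not None else score_range(head)
    return _decide_regression(s, head.k, lo, hi)
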