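"""Segmentation and classification evaluation.

Boundary metrics (Hausdorff and its 95th-percentile variant) are computed on
mask boundary pixels in physical units. The dual-annotator agreement gate
implements the consensus protocol used when two radiologists outline the same
lesion: if their Dice similarity exceeds 0.95 either outline is accepted,
otherwise a consensus re-annotation is required.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import rankdata

__all__ = [
    "SegScore",
    "ConfusionCounts",
    "ClassificationMetrics",
    "AgreementDecision",
    "dsc",
    "boundary_points",
    "hausdorff",
    "agreement_gate",
    "clf_metrics",
    "auc",
    "bootstrap_ci",
    "evaluate_segmentation",
]


@dataclass(frozen=True)
class SegScore:
    """Dice plus boundary distances for one predicted/reference mask pair."""

    dsc: float
    hd: float
    hd95: float

    def __post_init__(self) -> None:
        if np.isfinite(self.hd) and np.isfinite(self.hd95) and self.hd95 > self.hd + 1e-12:
            raise ValueError("hd95 cannot exceed hd")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, pred: Sequence[int], truth: Sequence[int]) -> "ConfusionCounts":
        pred = np.asarray(pred, dtype=bool)
        truth = np.asarray(truth, dtype=bool)
        if pred.shape != truth.shape:
            raise ValueError("pred/truth shape mismatch")
        return cls(
            tp=int(np.sum(pred & truth)),
            tn=int(np.sum(~pred & ~truth)),
            fp=int(np.sum(pred & ~truth)),
            fn=int(np.sum(~pred & truth)),
        )


@dataclass(frozen=True)
class ClassificationMetrics:
    """Accuracy/precision/recall/F1; a field is None when its denominator is zero."""

    accuracy: float | None
    precision: float | None
    recall: float | None
    f1: float | None


@dataclass(frozen=True)
class AgreementDecision:
    accept_either: bool
    dsc: float
    threshold: float

    @property
    def outcome(self) -> str:
        return "accept_either" if self.accept_either else "needs_consensus"


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A n B| / (|A| + |B|).

    Defined as 1.0 when both masks are empty and 0.0 when exactly one is.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.sum(a & b))
    return 2.0 * inter / (na + nb)


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """Coordinates (pixels) of the mask's inner boundary: mask minus its erosion."""
    mask = np.asarray(mask).astype(bool)
    if mask.sum() == 0:
        return np.empty((0, mask.ndim), dtype=np.int64)
    eroded = ndimage.binary_erosion(mask, border_value=0)
    return np.argwhere(mask & ~eroded)


def _directed_min_distances(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    tree = cKDTree(pb)
    d, _ = tree.query(pa, k=1)
    return np.atleast_1d(d)


def hausdorff(
    a: np.ndarray,
    b: np.ndarray,
    spacing: float = 1.0,
    points: bool = False,
) -> tuple[float, float]:
    """Hausdorff distance and HD95 between two masks (or point sets).

    Distances are Euclidean between boundary pixels scaled by ``spacing``.
    HD = max of the two directed maxima; HD95 = max of the two directed
    95th percentiles (linear-interpolation percentile). Raises on empty input,
    where both quantities are undefined.

    With ``points=True`` the inputs are (n, d) coordinate arrays instead of masks.
    """
    if points:
        pa = np.asarray(a, dtype=np.float64)
        pb = np.asarray(b, dtype=np.float64)
    else:
        pa = boundary_points(a).astype(np.float64)
        pb = boundary_points(b).astype(np.float64)
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("Hausdorff distance undefined for empty set")
    d_ab = _directed_min_distances(pa, pb) * spacing
    d_ba = _directed_min_distances(pb, pa) * spacing
    hd = max(float(d_ab.max()), float(d_ba.max()))
    hd95 = max(float(np.percentile(d_ab, 95)), float(np.percentile(d_ba, 95)))
    return hd, hd95


def agreement_gate(mask_a: np.ndarray, mask_b: np.ndarray, threshold: float = 0.95) -> AgreementDecision:
    """Dual-annotator consistency gate: accept either annotation iff DSC strictly exceeds the threshold."""
    score = dsc(mask_a, mask_b)
    return AgreementDecision(accept_either=score > threshold, dsc=score, threshold=threshold)


def clf_metrics(c: ConfusionCounts) -> ClassificationMetrics:
    """Accuracy, precision, recall and F1 from confusion counts.

    Metrics with a zero denominator come back as None rather than raising.
    """
    accuracy = (c.tp + c.tn) / c.total if c.total > 0 else None
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    else:
        f1 = None
    return ClassificationMetrics(accuracy=accuracy, precision=precision, recall=recall, f1=f1)


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the tie-corrected Mann-Whitney rank statistic."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores/labels shape mismatch")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)  # average ranks handle ties
    u = float(np.sum(ranks[labels == 1])) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def bootstrap_ci(
    values: Sequence[float],
    stat: Callable[[np.ndarray], float] = np.mean,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Seeded percentile bootstrap interval for a statistic of per-sample values."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        return (float("nan"), float("nan"))
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for i in range(n_boot):
        stats[i] = stat(values[rng.integers(0, values.size, values.size)])
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def evaluate_segmentation(
    pred_masks: Sequence[np.ndarray],
    true_masks: Sequence[np.ndarray],
    spacing: float = 1.0,
    method: str = "",
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Per-slice DSC and HD95 with bootstrap intervals; one report row per method.

    Slices where HD is undefined (an empty mask on either side) contribute to
    the DSC average but are dropped from the HD95 average; the row records how
    many were dropped.
    """
    if len(pred_masks) != len(true_masks):
        raise ValueError("pred/true mask count mismatch")
    dscs, hd95s, n_missing = [], [], 0
    for p, t in zip(pred_masks, true_masks):
        dscs.append(dsc(p, t))
        try:
            _, h95 = hausdorff(p, t, spacing=spacing)
            hd95s.append(h95)
        except ValueError:
            n_missing += 1
    dsc_lo, dsc_hi = bootstrap_ci(dscs, n_boot=n_boot, seed=seed)
    if hd95s:
        hd_lo, hd_hi = bootstrap_ci(hd95s, n_boot=n_boot, seed=seed + 1)
        hd_mean = float(np.mean(hd95s))
    else:
        hd_lo = hd_hi = hd_mean = float("nan")
    return {
        "method": method,
        "dsc": float(np.mean(dscs)),
        "dsc_lo": dsc_lo,
        "dsc_hi": dsc_hi,
        "hd95": hd_mean,
        "hd95_lo": hd_lo,
        "hd95_hi": hd_hi,
        "n_slices": len(pred_masks),
        "n_hd_missing": n_missing,
    }
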