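"""Object-level and pixel-level segmentation evaluation.

Object-level: predicted nuclei are matched one-to-one to ground-truth
nuclei greedily by descending Dice coefficient, a pair counting as a true
positive only when its Dice strictly exceeds 0.2. Precision, recall and F1
follow from the TP/FP/FN counts; ADC is the mean Dice over matched pairs.

Pixel-level: the aggregated Jaccard index (AJI) accumulates, over ground-
truth nuclei, the intersection and union with their best-Jaccard predicted
nucleus, then adds every unused predicted nucleus's pixels to the union —
so both missed nuclei and spurious detections pull the score down.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io_formats import MetricRow, canonicalize_mask, validate_mask

__all__ = [
    "ConfusionCounts",
    "dice",
    "match_instances",
    "precision_recall_f1",
    "adc",
    "aji",
    "evaluate_pair",
]

DC_THRESHOLD = 0.2  # true-positive criterion: Dice strictly greater


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    """Object-level confusion: TP/FP/FN plus the matched (gt, pred, dice) pairs."""

    TP: int
    FP: int
    FN: int
    matched_pairs: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        if self.TP != len(self.matched_pairs):
            raise ValueError("TP must equal the number of matched pairs")
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")


def dice(x: np.ndarray, y: np.ndarray) -> float:
    """Dice coefficient 2|X∩Y| / (|X|+|Y|) of two pixel sets.

    Accepts boolean masks or flat index arrays; raises if both are empty.
    """
    ix = _as_indices(x)
    iy = _as_indices(y)
    if ix.size == 0 and iy.size == 0:
        raise ValueError("Dice coefficient undefined for two empty sets")
    inter = np.intersect1d(ix, iy, assume_unique=True).size
    return 2.0 * inter / (ix.size + iy.size)


def _as_indices(pixels: np.ndarray) -> np.ndarray:
    arr = np.asarray(pixels)
    if arr.dtype == bool:
        return np.flatnonzero(arr)
    return np.unique(arr.ravel())


def _contingency(gt: np.ndarray, pred: np.ndarray):
    """Intersection counts and instance sizes for two canonical masks."""
    g = canonicalize_mask(validate_mask(gt))
    p = canonicalize_mask(validate_mask(pred))
    if g.shape != p.shape:
        raise ValueError(f"shape mismatch: gt {g.shape} vs pred {p.shape}")
    n_g, n_p = int(g.max()), int(p.max())
    joint = np.bincount(
        g.ravel().astype(np.int64) * (n_p + 1) + p.ravel(),
        minlength=(n_g + 1) * (n_p + 1),
    ).reshape(n_g + 1, n_p + 1)
    gt_sizes = joint.sum(axis=1)  # index 0 = background
    pred_sizes = joint.sum(axis=0)
    return joint, gt_sizes, pred_sizes, n_g, n_p


def match_instances(
    gt: np.ndarray, pred: np.ndarray, dc_threshold: float = DC_THRESHOLD
) -> ConfusionCounts:
    """Greedy one-to-one instance matching under the Dice > threshold rule.

    Candidate (gt, pred) pairs with Dice strictly above ``dc_threshold``
    are matched in descending Dice order (ties: smaller gt label, then
    smaller pred label); matched pairs are TP, leftover predictions FP,
    leftover ground-truth instances FN.
    """
    joint, gt_sizes, pred_sizes, n_g, n_p = _contingency(gt, pred)
    inter = joint[1:, 1:]
    denom = gt_sizes[1:, None] + pred_sizes[None, 1:]
    with np.errstate(invalid="ignore"):
        dmat = np.where(denom > 0, 2.0 * inter / denom, 0.0)

    gi, pj = np.nonzero(dmat > dc_threshold)
    candidates = sorted(
        zip(dmat[gi, pj], gi + 1, pj + 1), key=lambda t: (-t[0], t[1], t[2])
    )
    gt_used = np.zeros(n_g + 1, dtype=bool)
    pred_used = np.zeros(n_p + 1, dtype=bool)
    matched: list[tuple[int, int, float]] = []
    for d, g_label, p_label in candidates:
        if gt_used[g_label] or pred_used[p_label]:
            continue
        gt_used[g_label] = pred_used[p_label] = True
        matched.append((int(g_label), int(p_label), float(d)))

    tp = len(matched)
    return ConfusionCounts(
        TP=tp, FP=n_p - tp, FN=n_g - tp, matched_pairs=tuple(matched)
    )


def precision_recall_f1(c: ConfusionCounts) -> tuple[float, float, float]:
    """precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2TP/(2TP+FP+FN); 0/0 -> 0."""
    precision = c.TP / (c.TP + c.FP) if c.TP + c.FP else 0.0
    recall = c.TP / (c.TP + c.FN) if c.TP + c.FN else 0.0
    f1_denom = 2 * c.TP + c.FP + c.FN
    f1 = 2 * c.TP / f1_denom if f1_denom else 0.0
    return precision, recall, f1


def adc(c: ConfusionCounts) -> float:
    """Average Dice coefficient over matched pairs; 0 when nothing matched."""
    if not c.matched_pairs:
        return 0.0
    return float(np.mean([d for _, _, d in c.matched_pairs]))


def aji(gt: np.ndarray, pred: np.ndarray) -> float:
    """Aggregated Jaccard index of a prediction against ground truth.

    For each ground-truth nucleus (ascending label) the predicted nucleus
    with the highest Jaccard is taken (ties: smaller predicted label);
    intersections and unions with these best matches accumulate into C and
    U, ground-truth nuclei with no overlap contribute their own size to U,
    and every predicted nucleus never used as a best match adds its size to
    U. Returns C/U. Ground truth must contain at least one nucleus; an
    empty prediction scores 0.
    """
    joint, gt_sizes, pred_sizes, n_g, n_p = _contingency(gt, pred)
    if n_g == 0:
        raise ValueError("AJI undefined for empty ground truth")
    C = 0
    U = 0
    used = np.zeros(n_p + 1, dtype=bool)
    for g in range(1, n_g + 1):
        inter = joint[g, 1:]
        union = gt_sizes[g] + pred_sizes[1:] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            jac = np.where(union > 0, inter / union, 0.0)
        if n_p and jac.max() > 0:
            j_star = int(np.argmax(jac)) + 1  # argmax ties -> smaller label
            C += int(joint[g, j_star])
            U += int(gt_sizes[g] + pred_sizes[j_star] - joint[g, j_star])
            used[j_star] = True
        else:
            U += int(gt_sizes[g])
    U += int(pred_sizes[1:][~used[1:]].sum())
    return C / U


def evaluate_pair(
    gt: np.ndarray,
    pred: np.ndarray,
    image_id: str = "",
    dc_threshold: float = DC_THRESHOLD,
) -> MetricRow:
    """All five metrics for one (ground truth, prediction) mask pair."""
    counts = match_instances(gt, pred, dc_threshold)
    precision, recall, f1 = precision_recall_f1(counts)
    return MetricRow(
        image_id=image_id,
        precision=precision,
        recall=recall,
        f1=f1,
        adc=adc(counts),
        aji=aji(gt, pred),
    )
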