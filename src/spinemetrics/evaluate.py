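"""Accuracy metrics: boundary F1 (BF-score), landmark errors, intra-rater
variation, and herniation-category agreement."""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .imaging import PixelSpacing, validate_label_image
from .landmarks import CATEGORIES, LandmarkSet

#: Landmark names scored against a reference placement.
SCORED_POINTS = ("T_L", "B_L", "T_R", "B_R", "B_M", "D_C")


@dataclass(frozen=True)
class BFScoreResult:
    """Contour precision, recall and their harmonic mean at tolerance d_T."""

    precision: float
    recall: float
    score: float
    d_T: float


def contour_points(label: np.ndarray, class_id: int) -> np.ndarray:
    """Pixels of ``class_id`` with a differing 4-neighbor or on the border.

    Returns an (n, 2) integer array of (row, col); empty (with a warning)
    if the class is absent.
    """
    lab = validate_label_image(label)
    mask = lab == class_id
    if not mask.any():
        _warnings.warn(f"class {class_id} absent from label image", stacklevel=2)
        return np.empty((0, 2), dtype=int)
    interior = np.zeros_like(mask)
    interior[1:-1, 1:-1] = (
        mask[1:-1, 1:-1]
        & mask[:-2, 1:-1]
        & mask[2:, 1:-1]
        & mask[1:-1, :-2]
        & mask[1:-1, 2:]
    )
    return np.argwhere(mask & ~interior)


def bf_score(pred, gt, d_T: float) -> BFScoreResult:
    """Boundary F1 between two contour point sets at distance tolerance d_T.

    Precision is the fraction of predicted points whose nearest
    ground-truth point is strictly closer than d_T; recall is symmetric;
    the score is their harmonic mean.  Two empty sets score 1 (class
    absence correctly predicted); exactly one empty set scores 0.
    """
    if not d_T > 0:
        raise ValueError(f"d_T must be positive, got {d_T}")
    p = np.asarray(list(pred) if not isinstance(pred, np.ndarray) else pred, float)
    g = np.asarray(list(gt) if not isinstance(gt, np.ndarray) else gt, float)
    p = p.reshape(-1, 2)
    g = g.reshape(-1, 2)
    if len(p) == 0 and len(g) == 0:
        return BFScoreResult(1.0, 1.0, 1.0, d_T)
    if len(p) == 0 or len(g) == 0:
        return BFScoreResult(0.0, 0.0, 0.0, d_T)
    precision = float((cKDTree(g).query(p)[0] < d_T).mean())
    recall = float((cKDTree(p).query(g)[0] < d_T).mean())
    if precision + recall > 0:
        score = 2.0 * precision * recall / (precision + recall)
    else:
        score = 0.0
    return BFScoreResult(precision, recall, score, d_T)


def landmark_errors(
    pred: LandmarkSet, ref: LandmarkSet, spacing: PixelSpacing
) -> dict[str, float]:
    """Per-landmark Euclidean error in mm, plus absolute errors of the
    derived foraminal widths and AP diameter."""
    mm = spacing.mm_per_pixel
    out: dict[str, float] = {}
    for name in SCORED_POINTS:
        delta = np.asarray(getattr(pred, name)) - np.asarray(getattr(ref, name))
        out[f"eps_{name}"] = float(np.hypot(*delta)) * mm

    def dist(lm: LandmarkSet, a: str, b: str) -> float:
        return float(np.hypot(*(getattr(lm, a) - getattr(lm, b)))) * mm

    out["eps_dL"] = abs(dist(pred, "T_L", "B_L") - dist(ref, "T_L", "B_L"))
    out["eps_dR"] = abs(dist(pred, "T_R", "B_R") - dist(ref, "T_R", "B_R"))
    out["eps_dAP"] = abs(dist(pred, "B_M", "q_prime") - dist(ref, "B_M", "q_prime"))
    return out


def intra_variation(samples, spacing: PixelSpacing) -> float:
    """Mean distance (mm) of repeated placements of one point to their mean.

    This is the repeatability statistic used to quantify how consistently
    a rater re-places the same landmark.
    """
    pts = np.asarray(list(samples), dtype=np.float64).reshape(-1, 2)
    if len(pts) < 2:
        raise ValueError("intra_variation needs at least two placements")
    center = pts.mean(axis=0)
    return float(np.sqrt(((pts - center) ** 2).sum(axis=1)).mean()) * spacing.mm_per_pixel


def category_agreement(pred, ref) -> float:
    """Percentage of positions where the two category sequences agree."""
    pred = list(pred)
    ref = list(ref)
    if len(pred) != len(ref):
        raise ValueError(f"length mismatch: {len(pred)} vs {len(ref)}")
    if len(pred) == 0:
        raise ValueError("empty category sequences")
    for c in (*pred, *ref):
        if c not in CATEGORIES:
            raise ValueError(f"unknown category {c!r}")
    matches = sum(a == b for a, b in zip(pred, ref))
    return 100.0 * matches / len(pred)
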