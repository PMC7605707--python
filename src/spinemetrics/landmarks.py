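"""Anatomical landmark location and stenosis measurements.

From the important IVD boundary (A2: disc pixels adjacent to PE, TS or
AAP) and the important PE boundary (A3: posterior-element pixels adjacent
to IVD, TS or AAP) this module locates nine points:

* T_L, B_L / T_R, B_R — endpoints of the shortest segment bridging the
  left / right foramen (T on the disc side, B on the posterior-element
  side);
* B_M — the most posterior point of the PE top boundary between B_L and
  B_R (the canal-arch apex; image top is anterior);
* D_C — centroid of the largest connected IVD component;
* q — the point of the disc boundary between T_L and T_R that maximizes
  (perpendicular distance to the T_L-T_R line) - (distance to B_M);
* p — intersection of the T_L-T_R and B_M-D_C lines;
* q' — orthogonal projection of q onto the B_M-D_C line.

The foraminal widths are d(T_L,B_L) and d(T_R,B_R); the AP diameter is
d(B_M, q'); the herniation ratio r = d(B_M, q') / d(B_M, p) grades the
disc: normal if r >= 1.1, severe if r <= 0.8, minor in between.

All coordinates are 0-based (row, column) floats in the original image
frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import (
    CanalNotFoundError,
    EmptyBoundaryError,
    ForamenNotFoundError,
    RegionAbsentError,
)
from .evolve import (
    BoundarySequence,
    SmoothingConfig,
    adaptive_smooth,
    order_boundary,
    second_derivative_feature,
)
from .grid import IVD_PAIRS, PE_PAIRS, canonical_pair
from .imaging import PixelSpacing, validate_label_image

#: Herniation thresholds: severe iff r <= SEVERE, normal iff r >= NORMAL.
SEVERE_THRESHOLD = 0.8
NORMAL_THRESHOLD = 1.1

CATEGORIES = ("normal", "minor", "severe")

POINT_NAMES = ("T_L", "T_R", "B_L", "B_R", "B_M", "D_C", "p", "q", "q_prime")


@dataclass
class ImportantBoundaries:
    """Ordered, smoothed important IVD (A2) and PE (A3) boundary curves."""

    A2: BoundarySequence
    A3: BoundarySequence


@dataclass
class LandmarkSet:
    """The nine measurement landmarks, (row, col) in sub-pixel coordinates."""

    T_L: np.ndarray
    T_R: np.ndarray
    B_L: np.ndarray
    B_R: np.ndarray
    B_M: np.ndarray
    D_C: np.ndarray
    p: np.ndarray
    q: np.ndarray
    q_prime: np.ndarray

    def __post_init__(self) -> None:
        for name in POINT_NAMES:
            value = np.asarray(getattr(self, name), dtype=np.float64).reshape(2)
            if not np.isfinite(value).all():
                raise ValueError(f"landmark {name} is not finite: {value}")
            setattr(self, name, value)

    def to_dict(self) -> dict[str, list[float]]:
        return {name: [float(v) for v in getattr(self, name)] for name in POINT_NAMES}

    @classmethod
    def from_dict(cls, payload: dict) -> "LandmarkSet":
        return cls(**{name: np.asarray(payload[name], dtype=np.float64)
                      for name in POINT_NAMES})


@dataclass
class Measurements:
    """Distances (mm), herniation ratio and category for one slice."""

    d_L: float
    d_R: float
    d_AP: float
    d_qprime: float  # d(B_M, q'), working pixel units
    d_p: float       # d(B_M, p), working pixel units
    r: float
    category: str
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "d_L_mm": self.d_L,
            "d_R_mm": self.d_R,
            "d_AP_mm": self.d_AP,
            "d_qprime_px": self.d_qprime,
            "d_p_px": self.d_p,
            "r": self.r,
            "category": self.category,
            "warnings": list(self.warnings),
        }


def classify_herniation(
    r,
    severe_threshold: float = SEVERE_THRESHOLD,
    normal_threshold: float = NORMAL_THRESHOLD,
):
    """Grade the herniation ratio: severe iff r <= 0.8, normal iff r >= 1.1,
    minor otherwise.  The severe boundary is inclusive.

    Accepts a scalar (returns a string) or an array of ratios (returns an
    array of category strings).
    """
    arr = np.asarray(r, dtype=np.float64)
    if not np.isfinite(arr).all() or (arr < 0).any():
        raise ValueError(f"herniation ratio must be finite and >= 0, got {r}")
    cats = np.select(
        [arr <= severe_threshold, arr >= normal_threshold],
        ["severe", "normal"],
        default="minor",
    )
    return str(cats) if np.isscalar(r) or arr.ndim == 0 else cats


def extract_important_boundaries(
    pair_points: dict[tuple[int, int], np.ndarray],
    label: np.ndarray,
    image: np.ndarray | None = None,
    smoothing: SmoothingConfig | None = None,
) -> ImportantBoundaries:
    """Union, order and smooth the important IVD and PE boundary points.

    ``pair_points`` maps region pairs to boundary point arrays (as
    returned by the evolution); A2 unions the pairs (2,3), (2,4), (2,5)
    and A3 the pairs (2,3), (3,4), (3,5).  ``label`` is only used to
    distinguish "region absent" from "region present but important
    boundary empty".  If ``image`` is given, the curves are smoothed with
    the adaptive moving average driven by its second derivative; without
    an image the points are ordered but left unsmoothed.
    """
    lab = validate_label_image(label)
    present = set(np.unique(lab).tolist())
    for region, name in ((2, "IVD"), (3, "PE")):
        if region not in present:
            raise RegionAbsentError(f"region {region} ({name}) absent from label image")

    pair_points = {canonical_pair(a, b): np.asarray(pts, dtype=np.float64)
                   for (a, b), pts in pair_points.items()}

    def union(pairs, which: str) -> np.ndarray:
        chunks = [pair_points[p] for p in sorted(pairs) if p in pair_points
                  and len(pair_points[p])]
        if not chunks:
            raise EmptyBoundaryError(f"important {which} boundary is empty")
        return np.concatenate(chunks, axis=0)

    smoothing = smoothing or SmoothingConfig()
    feature = None
    if image is not None:
        feature = second_derivative_feature(image, smoothing.sigma2)

    out = []
    for pairs, which in ((IVD_PAIRS, "IVD"), (PE_PAIRS, "PE")):
        seq = order_boundary(union(pairs, which))
        if feature is not None:
            seq = adaptive_smooth(seq, feature, smoothing)
        seq.source_pairs = frozenset(p for p in pairs if p in pair_points)
        out.append(seq)
    return ImportantBoundaries(A2=out[0], A3=out[1])


def centroid_IVD(label: np.ndarray) -> np.ndarray:
    """Centroid (row, col) of the largest connected component of region 2.

    Smaller fragments are treated as segmentation noise; component ties
    resolve to the first component in scan order.
    """
    lab = validate_label_image(label)
    mask = lab == 2
    if not mask.any():
        raise RegionAbsentError("region 2 (IVD) absent from label image")
    comps, n = ndimage.label(mask)
    sizes = ndimage.sum_labels(np.ones_like(comps), comps, index=range(1, n + 1))
    biggest = int(np.argmax(sizes)) + 1  # argmax keeps the first (topmost) tie
    rows, cols = np.nonzero(comps == biggest)
    return np.array([rows.mean(), cols.mean()], dtype=np.float64)


def ts_column_extent(label: np.ndarray, pad: float = 1.0) -> tuple[float, float] | None:
    """Column interval spanned by the thecal sac (region 4), padded by
    ``pad`` pixels; ``None`` if the region is absent."""
    lab = validate_label_image(label)
    cols = np.nonzero((lab == 4).any(axis=0))[0]
    if len(cols) == 0:
        return None
    return float(cols.min() - pad), float(cols.max() + pad)


def locate_foraminal_points(
    A2: BoundarySequence | np.ndarray,
    A3: BoundarySequence | np.ndarray,
    side: str,
    ts_extent: tuple[float, float] | None,
    midline_col: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Endpoints (T, B) of the shortest segment bridging one foramen.

    Candidates are A2 points (for T) and A3 points (for B) on the given
    side of ``midline_col`` whose column lies outside ``ts_extent`` (the
    thecal-sac column interval, which would otherwise dominate the
    minimum-distance search).  Ties on distance prefer the pair with the
    smaller column offset |T.col - B.col|, then the smaller T row.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    a2 = np.asarray(A2.points if isinstance(A2, BoundarySequence) else A2, float)
    a3 = np.asarray(A3.points if isinstance(A3, BoundarySequence) else A3, float)

    def candidates(pts: np.ndarray) -> np.ndarray:
        if side == "left":
            keep = pts[:, 1] < midline_col
        else:
            keep = pts[:, 1] > midline_col
        if ts_extent is not None:
            lo, hi = ts_extent
            keep &= (pts[:, 1] < lo) | (pts[:, 1] > hi)
        return pts[keep]

    top, bottom = candidates(a2), candidates(a3)
    if len(top) == 0 or len(bottom) == 0:
        raise ForamenNotFoundError(f"no {side} foramen candidates outside the canal")

    diff = top[:, None, :] - bottom[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    dmin = dist.min()
    ti, bi = np.nonzero(dist <= dmin + 1e-9)
    col_off = np.abs(top[ti, 1] - bottom[bi, 1])
    order = np.lexsort((top[ti, 0], col_off))
    pick = order[0]
    return top[ti[pick]].copy(), bottom[bi[pick]].copy()


def locate_BM(
    A3: BoundarySequence | np.ndarray, B_L: np.ndarray, B_R: np.ndarray
) -> np.ndarray:
    """Most posterior (max-row) A3 point with column strictly between B_L
    and B_R; ties prefer the column closest to the interval midpoint."""
    a3 = np.asarray(A3.points if isinstance(A3, BoundarySequence) else A3, float)
    lo, hi = float(B_L[1]), float(B_R[1])
    if not lo < hi:
        raise ValueError(f"need B_L.col < B_R.col, got {lo} >= {hi}")
    sel = a3[(a3[:, 1] > lo) & (a3[:, 1] < hi)]
    if len(sel) == 0:
        raise CanalNotFoundError("no PE boundary point between B_L and B_R")
    rmax = sel[:, 0].max()
    ties = sel[sel[:, 0] >= rmax - 1e-9]
    mid = 0.5 * (lo + hi)
    return ties[np.argmin(np.abs(ties[:, 1] - mid))].copy()


def _m_ivd(A2: BoundarySequence, T_L: np.ndarray, T_R: np.ndarray,
           B_M: np.ndarray) -> np.ndarray:
    """Sub-sequence of the ordered A2 curve bounded laterally by T_L and T_R.

    The two landmarks split the closed/open curve into two arcs; the arc
    closer to B_M (the posterior one) is the measurement arc M_IVD.
    """
    pts = A2.points
    iL = int(np.argmin(((pts - T_L) ** 2).sum(axis=1)))
    iR = int(np.argmin(((pts - T_R) ** 2).sum(axis=1)))
    a, b = sorted((iL, iR))
    inner = pts[a : b + 1]
    outer = np.concatenate([pts[b:], pts[: a + 1]], axis=0)
    if len(inner) == 0:
        return outer
    if len(outer) == 0:
        return inner
    d_inner = np.sqrt(((inner - B_M) ** 2).sum(axis=1)).mean()
    d_outer = np.sqrt(((outer - B_M) ** 2).sum(axis=1)).mean()
    return inner if d_inner <= d_outer else outer


def locate_q(
    M_IVD: np.ndarray, T_L: np.ndarray, T_R: np.ndarray, B_M: np.ndarray
) -> np.ndarray:
    """argmax over the disc arc of (perpendicular distance to the T_L-T_R
    line) - (Euclidean distance to B_M); first index wins ties."""
    pts = np.asarray(M_IVD, dtype=np.float64)
    if pts.ndim != 2 or len(pts) == 0:
        raise ValueError("M_IVD must be a nonempty (n, 2) array")
    chord = np.asarray(T_R, float) - np.asarray(T_L, float)
    norm = np.hypot(*chord)
    if norm <= 0:
        raise ValueError("degenerate T_L-T_R line (identical endpoints)")
    normal = np.array([-chord[1], chord[0]]) / norm
    perp = np.abs((pts - T_L) @ normal)
    d_bm = np.sqrt(((pts - B_M) ** 2).sum(axis=1))
    return pts[int(np.argmax(perp - d_bm))].copy()


def derive_p_qprime(
    q: np.ndarray,
    T_L: np.ndarray,
    T_R: np.ndarray,
    B_M: np.ndarray,
    D_C: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Intersection p of the T_L-T_R and B_M-D_C lines and projection q'
    of q onto the B_M-D_C line.

    Both are computed on the infinite lines; if p falls outside either
    segment, or q' outside B_M-D_C, a warning is recorded rather than an
    error (pathological segmentations degrade, they do not halt).
    """
    T_L, T_R = np.asarray(T_L, float), np.asarray(T_R, float)
    B_M, D_C = np.asarray(B_M, float), np.asarray(D_C, float)
    q = np.asarray(q, float)
    u = T_R - T_L
    v = D_C - B_M
    if np.hypot(*v) <= 0:
        raise ValueError("B_M and D_C coincide; bisecting line undefined")
    det = u[0] * (-v[0]) - (-v[1]) * u[1]  # cross of direction vectors
    det = u[1] * v[0] - u[0] * v[1]
    if abs(det) < 1e-12:
        raise ValueError("T_L-T_R and B_M-D_C lines are parallel")
    # T_L + t*u == B_M + s*v
    rhs = B_M - T_L
    t = (rhs[1] * v[0] - rhs[0] * v[1]) / det
    p = T_L + t * u

    s_q = ((q - B_M) @ v) / (v @ v)
    q_prime = B_M + s_q * v

    warnings = []
    if not 0.0 <= t <= 1.0:
        warnings.append("p lies outside the T_L-T_R segment")
    s_p = ((p - B_M) @ v) / (v @ v)
    if not 0.0 <= s_p <= 1.0:
        warnings.append("p lies outside the B_M-D_C segment")
    if not 0.0 <= s_q <= 1.0:
        warnings.append("q' lies outside the B_M-D_C segment")
    return p, q_prime, warnings


def locate_landmarks(
    boundaries: ImportantBoundaries,
    ivd_centroid: np.ndarray,
    ts_extent: tuple[float, float] | None,
) -> tuple[LandmarkSet, list[str]]:
    """Locate all nine landmarks from the important boundary curves.

    ``ivd_centroid`` and ``ts_extent`` must be in the same (original)
    frame as the boundary curves.
    """
    midline = float(ivd_centroid[1])
    T_L, B_L = locate_foraminal_points(boundaries.A2, boundaries.A3, "left",
                                       ts_extent, midline)
    T_R, B_R = locate_foraminal_points(boundaries.A2, boundaries.A3, "right",
                                       ts_extent, midline)
    B_M = locate_BM(boundaries.A3, B_L, B_R)
    arc = _m_ivd(boundaries.A2, T_L, T_R, B_M)
    q = locate_q(arc, T_L, T_R, B_M)
    p, q_prime, warnings = derive_p_qprime(q, T_L, T_R, B_M, ivd_centroid)
    lm = LandmarkSet(T_L=T_L, T_R=T_R, B_L=B_L, B_R=B_R, B_M=B_M,
                     D_C=np.asarray(ivd_centroid, float), p=p, q=q, q_prime=q_prime)
    return lm, warnings


def measure(
    lm: LandmarkSet,
    spacing: PixelSpacing,
    severe_threshold: float = SEVERE_THRESHOLD,
    normal_threshold: float = NORMAL_THRESHOLD,
    warnings: list[str] | None = None,
) -> Measurements:
    """Foraminal widths, AP diameter (mm) and herniation grade."""
    mm = spacing.mm_per_pixel

    def dist(a, b) -> float:
        return float(np.hypot(*(np.asarray(a, float) - np.asarray(b, float))))

    d_qprime = dist(lm.B_M, lm.q_prime)
    d_p = dist(lm.B_M, lm.p)
    if d_p <= 0:
        raise ValueError("d(B_M, p) is zero; herniation ratio undefined")
    r = d_qprime / d_p
    return Measurements(
        d_L=dist(lm.T_L, lm.B_L) * mm,
        d_R=dist(lm.T_R, lm.B_R) * mm,
        d_AP=d_qprime * mm,
        d_qprime=d_qprime,
        d_p=d_p,
        r=r,
        category=classify_herniation(r, severe_threshold, normal_threshold),
        warnings=list(warnings or ()),
    )
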