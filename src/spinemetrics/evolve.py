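"""Sub-pixel contour evolution on the Modified Boundary Grid.

The evolution relocates each selected interface cell perpendicular to the
interface, to the candidate position (within a search width of ±w label
pixels) whose stored gradient feature has the largest magnitude, and
rewrites the label cells crossed by the move.  Sweeps repeat until the
number of changed label cells, averaged over the last n sweeps, drops
below a threshold tau.  Upsampling the image (bilinear) and label
(nearest-neighbor) by 2 between evolution rounds refines the boundary to
the nearest 2^-(k+1) of an original pixel after k rounds.

Boundary curves are then ordered into sequences by a greedy
nearest-neighbor chain and smoothed with a variable-width moving average
whose half-width tracks the magnitude of the image second derivative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import (
    ModifiedBoundaryGrid,
    SparseBoundaryRep,
    build_boundary_grid,
    build_sparse,
    canonical_pair,
    compute_gradients,
    select_boundary,
    subscript_to_point,
)
from .imaging import validate_label_image


@dataclass(frozen=True)
class EvolutionConfig:
    """Parameters of the boundary evolution.

    w          search width in label pixels (positive integer);
    tau        convergence threshold in changed cells per sweep; ``None``
               ties it to the working image size as max(1, 0.001 * H * W),
               which absorbs the small steady-state churn of corner cells
               that flip between two equally supported configurations;
    n          number of sweeps the change count is averaged over;
    k          number of x2 upsampling rounds (precision 2^-(k+1) px);
    sigma      Gaussian width for the gradient features, in pixels of the
               current working resolution;
    max_sweeps safety cap on sweeps per resolution level.
    """

    w: int = 2
    tau: float | None = None
    n: int = 3
    k: int = 1
    sigma: float = 1.0
    max_sweeps: int = 100

    def __post_init__(self) -> None:
        if int(self.w) != self.w or self.w < 1:
            raise ValueError(f"search width w must be a positive integer, got {self.w}")
        if self.tau is not None and self.tau < 0:
            raise ValueError(f"tau must be non-negative, got {self.tau}")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"averaging window n must be >= 1, got {self.n}")
        if int(self.k) != self.k or self.k < 0:
            raise ValueError(f"upsampling rounds k must be >= 0, got {self.k}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.max_sweeps < self.n:
            raise ValueError("max_sweeps must be at least n")


@dataclass(frozen=True)
class SmoothingConfig:
    """Variable-width moving-average smoothing parameters.

    The half-width is w_min where the sampled feature is smallest along
    the curve and w_max where it is largest, linearly interpolated and
    rounded in between.
    """

    w_min: int = 2
    w_max: int = 7
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        if not (1 <= self.w_min <= self.w_max):
            raise ValueError(
                f"need 1 <= w_min <= w_max, got ({self.w_min}, {self.w_max})"
            )
        if self.sigma2 <= 0:
            raise ValueError(f"sigma2 must be positive, got {self.sigma2}")


@dataclass
class EvolutionHistory:
    """Per-level record of label-cell changes per sweep."""

    changes_per_sweep: list[list[int]] = field(default_factory=list)
    converged: list[bool] = field(default_factory=list)

    @property
    def warning(self) -> bool:
        """True if any level hit the sweep cap without converging."""
        return not all(self.converged)


@dataclass
class BoundarySequence:
    """An ordered boundary curve in original-frame sub-pixel coordinates."""

    points: np.ndarray  # (n, 2) float, (row, col)
    source_pairs: frozenset[tuple[int, int]] = frozenset()

    def __len__(self) -> int:
        return len(self.points)


def has_converged(history, n: int, tau: float) -> bool:
    """True iff at least n sweeps are recorded and the mean of the last n
    change counts is strictly below tau."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(history) < n:
        return False
    return float(np.mean(list(history)[-n:])) < tau


def _candidate_deltas(w: int) -> list[int]:
    # 0 first, then by |delta| with the negative direction preferred
    out = [0]
    for d in range(1, w + 1):
        out.extend((-d, d))
    return out


def evolve_sweep(
    grid: ModifiedBoundaryGrid, S, w: int
) -> int:
    """Run one evolution sweep over the boundary cells in S (in place).

    Cells are processed in ascending (i, j) subscript order against a
    snapshot of S; label edits are applied immediately.  Each cell moves
    along its movement axis (perpendicular to the interface) to the
    candidate interface with maximal absolute gradient feature within ±w
    pixels; ties prefer the smallest move, then the negative direction.
    Candidates whose crossed label cells include a label outside the
    cell's flanking pair are discarded.  Returns the number of label
    cells whose value changed.
    """
    if int(w) != w or w < 1:
        raise ValueError(f"search width w must be a positive integer, got {w}")
    lab = grid.labels
    h, wid = lab.shape
    changed = 0
    for i, j in sorted(S):
        kind = grid.cell_kind(i, j)
        if kind == "v-interface":
            r0, c = i // 2 - 1, (j - 1) // 2  # interface between rows r0, r0+1
            a, b = int(lab[r0, c]), int(lab[r0 + 1, c])
            if a == b:
                continue  # no longer a boundary (edited earlier this sweep)
            best_delta, best_score = 0, abs(grid.gv[r0, c])
            for delta in _candidate_deltas(int(w)):
                if delta == 0:
                    continue
                r_new = r0 + delta
                if not (0 <= r_new <= h - 2):
                    continue
                if delta > 0:
                    crossed = lab[r0 + 1 : r0 + delta + 1, c]
                else:
                    crossed = lab[r0 + delta + 1 : r0 + 1, c]
                if not np.isin(crossed, (a, b)).all():
                    continue
                score = abs(grid.gv[r_new, c])
                if score > best_score:
                    best_delta, best_score = delta, score
            if best_delta > 0:
                seg = lab[r0 + 1 : r0 + best_delta + 1, c]
                changed += int(np.count_nonzero(seg != a))
                seg[:] = a
            elif best_delta < 0:
                seg = lab[r0 + best_delta + 1 : r0 + 1, c]
                changed += int(np.count_nonzero(seg != b))
                seg[:] = b
        elif kind == "h-interface":
            r, c0 = (i - 1) // 2, j // 2 - 1  # interface between cols c0, c0+1
            a, b = int(lab[r, c0]), int(lab[r, c0 + 1])
            if a == b:
                continue
            best_delta, best_score = 0, abs(grid.gh[r, c0])
            for delta in _candidate_deltas(int(w)):
                if delta == 0:
                    continue
                c_new = c0 + delta
                if not (0 <= c_new <= wid - 2):
                    continue
                if delta > 0:
                    crossed = lab[r, c0 + 1 : c0 + delta + 1]
                else:
                    crossed = lab[r, c0 + delta + 1 : c0 + 1]
                if not np.isin(crossed, (a, b)).all():
                    continue
                score = abs(grid.gh[r, c_new])
                if score > best_score:
                    best_delta, best_score = delta, score
            if best_delta > 0:
                seg = lab[r, c0 + 1 : c0 + best_delta + 1]
                changed += int(np.count_nonzero(seg != a))
                seg[:] = a
            elif best_delta < 0:
                seg = lab[r, c0 + best_delta + 1 : c0 + 1]
                changed += int(np.count_nonzero(seg != b))
                seg[:] = b
        else:
            raise ValueError(f"({i}, {j}) is not an interface cell")
    return changed


def upsample_image(image: np.ndarray) -> np.ndarray:
    """Bilinear x2 upsampling under the pixel-area convention."""
    return ndimage.zoom(
        np.asarray(image, dtype=np.float64), 2, order=1, mode="nearest", grid_mode=True
    )


def upsample_label(label: np.ndarray) -> np.ndarray:
    """Nearest-neighbor x2 upsampling (each pixel becomes a 2x2 block)."""
    return np.repeat(np.repeat(label, 2, axis=0), 2, axis=1)


def to_original_frame(coords: np.ndarray, level: int) -> np.ndarray:
    """Map 0-based pixel-frame coordinates at upsampling ``level`` back to
    the original image frame (one (u-0.5)/2 per level)."""
    out = np.asarray(coords, dtype=np.float64).copy()
    for _ in range(level):
        out = (out - 0.5) / 2.0
    return out


def boundary_points_by_pair(
    rep: SparseBoundaryRep, pairs, level: int = 0
) -> dict[tuple[int, int], np.ndarray]:
    """Per-pair boundary-cell positions mapped to the original frame."""
    out: dict[tuple[int, int], np.ndarray] = {}
    for a, b in pairs:
        pair = canonical_pair(a, b)
        cells = rep.entries.get(pair)
        if not cells:
            continue
        pts = np.array([subscript_to_point(i, j) for i, j in cells], dtype=np.float64)
        out[pair] = to_original_frame(pts, level)
    return out


def subpixel_boundary_evolution(
    image: np.ndarray,
    label: np.ndarray,
    pairs,
    cfg: EvolutionConfig | None = None,
):
    """Evolve the selected region boundaries to sub-pixel precision.

    For each resolution level 0..k the gradients and the grid are rebuilt,
    the boundary set S is constructed from ``pairs``, and sweeps run until
    convergence (or ``max_sweeps``, recorded as a warning in the history).
    Between levels the image is upsampled bilinearly and the label by
    nearest neighbor, both by a factor of 2.

    Returns ``(label_highres, pair_points, history)`` where
    ``label_highres`` is the final-level label image, ``pair_points`` maps
    each evolved region pair to an (n, 2) array of boundary positions in
    the original frame (quantized no coarser than 2^-(k+1) px), and
    ``history`` records changes per sweep per level.
    """
    cfg = cfg or EvolutionConfig()
    img = np.asarray(image, dtype=np.float64)
    lab = validate_label_image(label).copy()
    if img.shape != lab.shape:
        raise ValueError(f"image {img.shape} and label {lab.shape} shapes differ")
    pairs = {canonical_pair(a, b) for a, b in pairs}
    if not pairs:
        raise ValueError("at least one region pair is required")

    history = EvolutionHistory()
    grid = None
    for level in range(cfg.k + 1):
        grads = compute_gradients(img, cfg.sigma)
        grid = build_boundary_grid(lab, grads)
        changes: list[int] = []
        tau = cfg.tau if cfg.tau is not None else max(1.0, 0.001 * img.size)
        converged = False
        while len(changes) < cfg.max_sweeps:
            rep = build_sparse(grid)
            S = select_boundary(rep, pairs)
            changes.append(evolve_sweep(grid, S, cfg.w))
            if has_converged(changes, cfg.n, tau):
                converged = True
                break
        history.changes_per_sweep.append(changes)
        history.converged.append(converged)
        lab = grid.labels
        if level < cfg.k:
            img = upsample_image(img)
            lab = upsample_label(lab)

    final_rep = build_sparse(grid)
    pair_points = boundary_points_by_pair(final_rep, pairs, level=cfg.k)
    return lab, pair_points, history


def order_boundary(points) -> BoundarySequence:
    """Order an unordered boundary point set into a curve.

    Greedy nearest-neighbor chain starting from the point with the
    smallest (row, column); ties in distance resolve to the
    lexicographically smallest candidate for determinism.
    """
    pts = np.asarray(list(points) if not isinstance(points, np.ndarray) else points,
                     dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise ValueError("order_boundary needs a nonempty set of (row, col) points")
    pts = np.unique(pts, axis=0)  # lexicographic sort, drops duplicates
    n = len(pts)
    used = np.zeros(n, dtype=bool)
    order = np.empty(n, dtype=np.intp)
    current = 0  # lexicographic minimum
    used[0] = True
    order[0] = 0
    for step in range(1, n):
        d2 = np.einsum("ij,ij->i", pts - pts[current], pts - pts[current])
        d2[used] = np.inf
        nearest = int(np.argmin(d2))  # first index wins ties (lexicographic)
        used[nearest] = True
        order[step] = nearest
        current = nearest
    return BoundarySequence(points=pts[order])


def second_derivative_feature(image: np.ndarray, sigma2: float = 1.0) -> np.ndarray:
    """Magnitude of the Laplacian of the Gaussian-smoothed image.

    Computed as central second differences of the smoothed image (border
    values replicated), which vanish exactly on constant and linear
    images.
    """
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be positive, got {sigma2}")
    from .grid import _smooth

    smoothed = _smooth(np.asarray(image, dtype=np.float64), sigma2)
    p = np.pad(smoothed, 1, mode="edge")
    lap = (p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:]
           - 4.0 * smoothed)
    return np.abs(lap)


def adaptive_smooth(
    seq: BoundarySequence,
    feature: np.ndarray | None,
    cfg: SmoothingConfig | None = None,
) -> BoundarySequence:
    """Variable-width moving average along an ordered boundary curve.

    The half-width w_p at each point is w_min where the feature image
    (sampled at the nearest integer pixel of the point, min-max normalized
    over the curve) is smallest and w_max where it is largest, rounded to
    the nearest integer in between.  Only indices i with
    ``w_p < i < card(A) - w_p`` are replaced by the mean of their
    2*w_p + 1 neighbors from the unsmoothed curve; endpoints pass through.
    A constant (or missing) feature yields w_p = w_min everywhere.
    """
    cfg = cfg or SmoothingConfig()
    pts = np.asarray(seq.points, dtype=np.float64)
    n = len(pts)
    if n == 0:
        raise ValueError("cannot smooth an empty sequence")

    if feature is None:
        widths = np.full(n, cfg.w_min, dtype=int)
    else:
        feat = np.asarray(feature, dtype=np.float64)
        rows = np.clip(np.rint(pts[:, 0]).astype(int), 0, feat.shape[0] - 1)
        cols = np.clip(np.rint(pts[:, 1]).astype(int), 0, feat.shape[1] - 1)
        sampled = feat[rows, cols]
        span = sampled.max() - sampled.min()
        if span <= 0:
            widths = np.full(n, cfg.w_min, dtype=int)
        else:
            t = (sampled - sampled.min()) / span
            widths = np.rint(cfg.w_min + t * (cfg.w_max - cfg.w_min)).astype(int)

    out = pts.copy()
    for i in range(n):
        w = int(widths[i])
        if w < i < n - w:
            out[i] = pts[i - w : i + w + 1].mean(axis=0)
    return BoundarySequence(points=out, source_pairs=seq.source_pairs)
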