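"""Modified Boundary Grid and Sparse Boundary Representation.

A label image of shape H x W is embedded in a (2H-1) x (2W-1) grid whose
cells are addressed by 1-based subscripts (i, j):

* ``i`` odd and ``j`` odd   -> a label cell (the pixel at ((i-1)/2, (j-1)/2)
  in 0-based image coordinates);
* ``i`` even and ``j`` odd  -> a vertical-interface cell between two
  vertically adjacent pixels; it stores the vertical image gradient there;
* ``i`` odd and ``j`` even  -> a horizontal-interface cell storing the
  horizontal gradient;
* both even                 -> empty (no information).

The sparse boundary representation indexes, for each unordered pair of
neighboring regions {a, b}, the grid subscripts of all interface cells
whose two flanking label cells carry exactly the labels a and b.

Pixel-frame coordinates used elsewhere in the package are 0-based floats
with pixel centers at integers; an interface cell (i, j) sits at
((i-1)/2, (j-1)/2), i.e. halfway between its two flanking pixel centers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imaging import validate_label_image

#: Region pairs whose union forms the important IVD boundary A2.
IVD_PAIRS = frozenset({(2, 3), (2, 4), (2, 5)})
#: Region pairs whose union forms the important PE boundary A3.
PE_PAIRS = frozenset({(2, 3), (3, 4), (3, 5)})
#: All pairs evolved by the default pipeline (A2 union A3).
IMPORTANT_PAIRS = IVD_PAIRS | PE_PAIRS


def canonical_pair(a: int, b: int) -> tuple[int, int]:
    """Return the unordered region pair (a, b) with a < b."""
    if a == b:
        raise ValueError(f"a region pair needs two distinct labels, got ({a}, {b})")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class GradientPair:
    """Gaussian-smoothed forward-difference gradients of an image.

    ``gh`` has shape H x (W-1) (differences along columns) and ``gv`` has
    shape (H-1) x W (differences along rows), so each entry sits exactly
    on one pixel interface.
    """

    gh: np.ndarray
    gv: np.ndarray
    sigma: float


def _smooth(image: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing with a truncated kernel of radius ceil(3*sigma),
    renormalized at the borders (normalized convolution)."""
    radius = max(1, math.ceil(3.0 * sigma))
    num = ndimage.gaussian_filter(image, sigma, mode="constant", cval=0.0, radius=radius)
    den = ndimage.gaussian_filter(
        np.ones_like(image), sigma, mode="constant", cval=0.0, radius=radius
    )
    return num / den


def compute_gradients(image: np.ndarray, sigma: float = 1.0) -> GradientPair:
    """Forward-difference gradients of the Gaussian-smoothed image."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] < 2 or img.shape[1] < 2:
        raise ValueError(f"image must be at least 2 x 2, got shape {img.shape}")
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    smoothed = _smooth(img, sigma)
    gh = smoothed[:, 1:] - smoothed[:, :-1]
    gv = smoothed[1:, :] - smoothed[:-1, :]
    return GradientPair(gh=gh, gv=gv, sigma=float(sigma))


@dataclass
class ModifiedBoundaryGrid:
    """The (2H-1) x (2W-1) grid of labels and interface gradient features.

    Physically stored as the label matrix plus the two gradient matrices;
    the grid view is provided through the subscript accessors.
    """

    labels: np.ndarray
    gh: np.ndarray
    gv: np.ndarray

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def shape(self) -> tuple[int, int]:
        h, w = self.labels.shape
        return (2 * h - 1, 2 * w - 1)

    def _check(self, i: int, j: int) -> None:
        gh_, gw_ = self.shape
        if not (1 <= i <= gh_ and 1 <= j <= gw_):
            raise IndexError(f"grid subscript ({i}, {j}) outside 1..{gh_} x 1..{gw_}")

    def cell_kind(self, i: int, j: int) -> str:
        """One of 'label', 'v-interface', 'h-interface', 'empty'."""
        self._check(i, j)
        io, jo = i % 2 == 1, j % 2 == 1
        if io and jo:
            return "label"
        if not io and jo:
            return "v-interface"
        if io and not jo:
            return "h-interface"
        return "empty"

    def label_at(self, i: int, j: int) -> int:
        if self.cell_kind(i, j) != "label":
            raise ValueError(f"({i}, {j}) is not a label cell")
        return int(self.labels[(i - 1) // 2, (j - 1) // 2])

    def feature_at(self, i: int, j: int) -> float:
        kind = self.cell_kind(i, j)
        if kind == "v-interface":
            return float(self.gv[i // 2 - 1, (j - 1) // 2])
        if kind == "h-interface":
            return float(self.gh[(i - 1) // 2, j // 2 - 1])
        raise ValueError(f"({i}, {j}) is not an interface cell")

    def flanking_labels(self, i: int, j: int) -> tuple[int, int]:
        """Labels of the two pixels separated by interface cell (i, j),
        in reading order (top, bottom) or (left, right)."""
        kind = self.cell_kind(i, j)
        if kind == "v-interface":
            r, c = i // 2 - 1, (j - 1) // 2
            return int(self.labels[r, c]), int(self.labels[r + 1, c])
        if kind == "h-interface":
            r, c = (i - 1) // 2, j // 2 - 1
            return int(self.labels[r, c]), int(self.labels[r, c + 1])
        raise ValueError(f"({i}, {j}) is not an interface cell")


def build_boundary_grid(label: np.ndarray, grads: GradientPair) -> ModifiedBoundaryGrid:
    """Assemble the Modified Boundary Grid from a label image and its gradients."""
    lab = validate_label_image(label)
    h, w = lab.shape
    if h < 2 or w < 2:
        raise ValueError(f"label image must be at least 2 x 2, got {lab.shape}")
    if grads.gh.shape != (h, w - 1) or grads.gv.shape != (h - 1, w):
        raise ValueError(
            f"gradient shapes {grads.gh.shape}/{grads.gv.shape} do not match "
            f"a {h} x {w} label image"
        )
    return ModifiedBoundaryGrid(labels=lab.copy(), gh=grads.gh, gv=grads.gv)


def grid_to_label(grid: ModifiedBoundaryGrid) -> np.ndarray:
    """Downsample the grid at odd/odd subscripts, recovering the label image."""
    return grid.labels.copy()


@dataclass
class SparseBoundaryRep:
    """Mapping from unordered region pairs to boundary-cell grid subscripts."""

    entries: dict[tuple[int, int], list[tuple[int, int]]] = field(default_factory=dict)

    def pairs(self) -> set[tuple[int, int]]:
        return set(self.entries)

    def cells(self, a: int, b: int) -> list[tuple[int, int]]:
        return list(self.entries.get(canonical_pair(a, b), ()))

    def total_cells(self) -> int:
        return sum(len(v) for v in self.entries.values())

    def to_json(self) -> str:
        payload = {
            "pairs": [
                {"a": a, "b": b, "cells": [list(c) for c in cells]}
                for (a, b), cells in sorted(self.entries.items())
            ]
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "SparseBoundaryRep":
        payload = json.loads(text)
        entries: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for item in payload["pairs"]:
            pair = canonical_pair(int(item["a"]), int(item["b"]))
            entries[pair] = [(int(i), int(j)) for i, j in item["cells"]]
        return cls(entries=entries)


def build_sparse(grid: ModifiedBoundaryGrid) -> SparseBoundaryRep:
    """Parse the grid once, collecting every interface cell whose flanking
    labels differ, keyed by the canonicalized region pair."""
    lab = grid.labels
    entries: dict[tuple[int, int], list[tuple[int, int]]] = {}

    # vertical interfaces: pixel (r, c) vs (r+1, c) -> subscript (2r+2, 2c+1)
    top, bot = lab[:-1, :], lab[1:, :]
    for r, c in np.argwhere(top != bot):
        pair = canonical_pair(int(top[r, c]), int(bot[r, c]))
        entries.setdefault(pair, []).append((2 * int(r) + 2, 2 * int(c) + 1))
    # horizontal interfaces: pixel (r, c) vs (r, c+1) -> subscript (2r+1, 2c+2)
    left, right = lab[:, :-1], lab[:, 1:]
    for r, c in np.argwhere(left != right):
        pair = canonical_pair(int(left[r, c]), int(right[r, c]))
        entries.setdefault(pair, []).append((2 * int(r) + 1, 2 * int(c) + 2))

    for cells in entries.values():
        cells.sort()
    return SparseBoundaryRep(entries=entries)


def select_boundary(rep: SparseBoundaryRep, pairs) -> set[tuple[int, int]]:
    """Union of boundary-cell subscripts over the requested region pairs.

    Pairs absent from the representation contribute nothing.
    """
    out: set[tuple[int, int]] = set()
    for a, b in pairs:
        out.update(rep.entries.get(canonical_pair(a, b), ()))
    return out


def subscript_to_point(i: int, j: int) -> tuple[float, float]:
    """Map a 1-based grid subscript to 0-based pixel-frame coordinates."""
    return ((i - 1) / 2.0, (j - 1) / 2.0)
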