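"""Synthetic axial-slice phantoms with analytically known ground truth.

The phantom emulates the six-region layout of an axial lumbar slice at
disc level: a rectangular Unregistered frame (class 1), a kidney-shaped
intervertebral disc (class 2, anterior = image top), a posterior-element
band whose top boundary dips into a central canal arch (class 3), an
elliptical thecal sac inside the canal (class 4), the AAP space between
disc and posterior elements (class 5), and Other background (class 6).

The disc's posterior boundary is an ellipse arc with a cosine indentation
(the healthy kidney shape) plus an optional posterior-directed Gaussian
bump of amplitude ``hern_amp`` that models herniation.  The posterior
band's top boundary carries two lateral horns (the superior articular
processes bounding the foramina) whose tips approach the disc's
posterior-lateral lobes; the band is anchored so that the closest
approach between disc and horn on each side equals the designed
foraminal gap, and the horns make that closest approach sharply
localized.  Every landmark, distance and the herniation ratio are derived from
these analytic curves (sampled at 0.01 px) with the same geometric rules
the measurement pipeline uses, but computed independently of it, so the
phantom provides an oracle for end-to-end tests.

Two pseudo-modality intensity images (per-class means, Gaussian noise, a
smooth bias field) stand in for registered T1/T2; their default means
give the IVD/AAP boundary low contrast and the PE/AAP boundary high
contrast.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .errors import GeometryError
from .imaging import PixelSpacing, build_composite, validate_label_image
from .landmarks import (
    NORMAL_THRESHOLD,
    SEVERE_THRESHOLD,
    LandmarkSet,
    Measurements,
)

#: The three disc levels measured per study.
DEFAULT_LEVELS = ("L3-L4", "L4-L5", "L5-S1")

_DEFAULT_T1_MEANS = {1: 0.03, 2: 0.52, 3: 0.15, 4: 0.78, 5: 0.40, 6: 0.08}
_DEFAULT_T2_MEANS = {1: 0.03, 2: 0.66, 3: 0.12, 4: 0.88, 5: 0.50, 6: 0.06}

_REFERENCE_HEIGHT = 320.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and noise parameters of one synthetic slice.

    Lengths are in pixels of the canvas; defaults describe a 320 x 320
    slice.  ``scaled`` produces a proportionally shrunk spec for fast
    tests.  ``hern_amp`` > 0 pushes the posterior disc boundary toward
    the canal (herniation); 0 is the healthy kidney shape.
    """

    shape: tuple[int, int] = (320, 320)
    frame_width: int = 10
    mm_per_pixel: float = 0.5
    seed: int = 0

    ivd_row: float = 110.0          # disc center row r0
    ivd_col: float | None = None    # disc center column (None -> canvas middle)
    ivd_halfwidth: float = 96.0     # lateral semi-axis a_c
    ivd_top: float = 46.0           # anterior semi-axis
    ivd_bot: float = 48.0           # posterior semi-axis (before indentation)
    indent: float = 42.0            # kidney indentation depth at the midline
    hern_amp: float = 0.0           # herniation bump amplitude h (px, posterior)
    hern_width: float = 0.18        # bump sigma as a fraction of ivd_halfwidth

    gap_left: float = 8.0           # designed left foraminal gap (px)
    gap_right: float = 8.0          # designed right foraminal gap (px)
    horn_height: float = 14.0       # articular-process horn height above the base
    horn_sigma: float = 5.0         # horn Gaussian width (px)
    horn_pos: float = 0.55          # horn center, fraction of ivd_halfwidth
    lobe_height: float = 6.0        # posterolateral disc lobe depth (px)
    lobe_sigma: float = 6.0         # lobe Gaussian width (px)
    canal_depth: float = 18.0       # canal-arch depth below the horn base line
    canal_halfwidth: float | None = None  # None -> ts_halfwidth + 8
    pe_thickness: float = 40.0

    ts_halfwidth: float = 26.0
    ts_halfheight: float = 5.0

    t1_means: dict[int, float] = field(default_factory=lambda: dict(_DEFAULT_T1_MEANS))
    t2_means: dict[int, float] = field(default_factory=lambda: dict(_DEFAULT_T2_MEANS))
    noise_sd: float = 0.02
    bias_amp: float = 0.05

    @property
    def center_col(self) -> float:
        return (self.shape[1] - 1) / 2.0 if self.ivd_col is None else self.ivd_col

    @property
    def canal_hw(self) -> float:
        return (self.ts_halfwidth + 8.0 * self.shape[0] / _REFERENCE_HEIGHT
                if self.canal_halfwidth is None else self.canal_halfwidth)

    @classmethod
    def scaled(cls, height: int, **overrides) -> "PhantomSpec":
        """Proportionally scaled spec on a square ``height`` canvas."""
        s = height / _REFERENCE_HEIGHT
        base = cls()
        spec = dataclasses.replace(
            base,
            shape=(height, height),
            frame_width=max(3, round(base.frame_width * s)),
            mm_per_pixel=base.mm_per_pixel / s,
            ivd_row=base.ivd_row * s,
            ivd_halfwidth=base.ivd_halfwidth * s,
            ivd_top=base.ivd_top * s,
            ivd_bot=base.ivd_bot * s,
            indent=base.indent * s,
            hern_amp=base.hern_amp * s,
            gap_left=max(2.5, base.gap_left * s),
            gap_right=max(2.5, base.gap_right * s),
            horn_height=max(3.0, base.horn_height * s),
            horn_sigma=max(2.0, base.horn_sigma * s),
            lobe_height=max(2.0, base.lobe_height * s),
            lobe_sigma=max(2.5, base.lobe_sigma * s),
            canal_depth=max(3.0, base.canal_depth * s),
            pe_thickness=max(6.0, base.pe_thickness * s),
            ts_halfwidth=max(4.0, base.ts_halfwidth * s),
            ts_halfheight=max(2.0, base.ts_halfheight * s),
        )
        return dataclasses.replace(spec, **overrides) if overrides else spec


@dataclass
class PhantomStudy:
    """One synthetic slice plus its analytic ground truth."""

    spec: PhantomSpec
    label: np.ndarray
    t1: np.ndarray
    t2: np.ndarray
    composite: np.ndarray
    truth_landmarks: LandmarkSet
    truth_measurements: Measurements

    @property
    def truth_category(self) -> str:
        return self.truth_measurements.category


@dataclass(frozen=True)
class PerturbationSpec:
    """Annotation-noise model: boundary jitter plus 1x1 hole injection."""

    jitter_px: int = 1
    hole_rate: float = 0.0        # holes per 100 boundary pixels
    hole_classes: tuple[int, ...] = (6,)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_px < 0 or self.hole_rate < 0:
            raise ValueError("jitter amplitude and hole rate must be >= 0")


class _Geometry:
    """Analytic boundary curves of a phantom spec (0-based pixel frame)."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        self.c_mid = spec.center_col
        self.hw = spec.ivd_halfwidth
        # Articular-process horns rise under the sloping posterolateral
        # disc margin (the slope keeps the closest approach laterally
        # localized after rasterization); each horn tip sits the designed
        # foraminal gap below the disc boundary at its column.
        if not 0.0 < spec.horn_pos < 1.0:
            raise GeometryError("horn_pos must lie strictly inside (0, 1)")
        cl = self.c_mid - spec.horn_pos * self.hw
        cr = self.c_mid + spec.horn_pos * self.hw
        if cl > self.c_mid - spec.ts_halfwidth - 3.0:
            raise GeometryError("thecal sac is too wide for the foramina")
        # (horn center column, PE base row at that column)
        self.anchor_left = (
            float(cl),
            float(self.b_ivd(np.array([cl]))[0]) + spec.gap_left + spec.horn_height,
        )
        self.anchor_right = (
            float(cr),
            float(self.b_ivd(np.array([cr]))[0]) + spec.gap_right + spec.horn_height,
        )
        self.pe_bottom = max(self.anchor_left[1], self.anchor_right[1]) + spec.pe_thickness
        mid = np.array([self.c_mid])
        self.canal_gap = float(self.t_pe(mid)[0] - self.b_ivd(mid)[0])
        self.ts_center_row = float(self.b_ivd(mid)[0]) + 0.5 * self.canal_gap
        # a herniated disc narrows the canal; the thecal sac compresses
        # rather than overlapping its neighbors
        self.ts_halfheight = min(spec.ts_halfheight, 0.5 * (self.canal_gap - 2.5))
        self._validate()

    def _u(self, cols: np.ndarray) -> np.ndarray:
        return (np.asarray(cols, float) - self.c_mid) / self.hw

    def t_ivd(self, cols: np.ndarray) -> np.ndarray:
        u = np.clip(self._u(cols), -1.0, 1.0)
        return self.spec.ivd_row - self.spec.ivd_top * np.sqrt(1.0 - u * u)

    def b_ivd(self, cols: np.ndarray) -> np.ndarray:
        """Posterior disc boundary: ellipse arc - kidney indentation
        + posterolateral lobes + herniation bump."""
        s = self.spec
        cols = np.asarray(cols, float)
        u = np.clip(self._u(cols), -1.0, 1.0)
        curve = s.ivd_row + s.ivd_bot * np.sqrt(1.0 - u * u)
        curve -= s.indent * np.cos(np.pi * u / 2.0)
        two_sig2 = 2.0 * s.lobe_sigma**2
        for sign in (-1.0, 1.0):
            center = self.c_mid + sign * s.horn_pos * self.hw
            curve += s.lobe_height * np.exp(-((cols - center) ** 2) / two_sig2)
        curve += s.hern_amp * np.exp(-(u * u) / (2.0 * s.hern_width**2))
        return curve

    def t_pe(self, cols: np.ndarray) -> np.ndarray:
        """Posterior-element top boundary: line through the two horn-base
        anchors, minus the two articular horns, plus the canal arch."""
        cols = np.asarray(cols, float)
        s = self.spec
        (cl, rl), (cr, rr) = self.anchor_left, self.anchor_right
        base = rl + (rr - rl) * (cols - cl) / (cr - cl)
        two_sig2 = 2.0 * s.horn_sigma**2
        horns = s.horn_height * (
            np.exp(-((cols - cl) ** 2) / two_sig2)
            + np.exp(-((cols - cr) ** 2) / two_sig2)
        )
        v = (cols - self.c_mid) / s.canal_hw
        bump = np.where(np.abs(v) < 1.0,
                        np.cos(np.pi * np.clip(v, -1, 1) / 2.0) ** 2, 0.0)
        return base - horns + s.canal_depth * bump

    def aap_top(self, cols: np.ndarray) -> np.ndarray:
        """Top boundary of the AAP space: the posterior disc boundary where
        the disc exists, its equator row laterally beyond the disc."""
        cols = np.asarray(cols, float)
        inside = np.abs(self._u(cols)) <= 1.0
        return np.where(inside, self.b_ivd(cols), self.spec.ivd_row)

    @property
    def lateral_extent(self) -> tuple[float, float]:
        """Column extent of the posterior-element band and the AAP space."""
        fw = self.spec.frame_width
        return (fw + 4.0, self.spec.shape[1] - fw - 5.0)

    def _validate(self) -> None:
        s = self.spec
        h, w = s.shape
        lo, hi = self.lateral_extent
        cols = np.linspace(lo, hi, 4097)
        t_pe, a_top = self.t_pe(cols), self.aap_top(cols)
        disc_cols = np.linspace(self.c_mid - self.hw, self.c_mid + self.hw, 2049)
        t_ivd, b_ivd = self.t_ivd(disc_cols), self.b_ivd(disc_cols)
        fw = s.frame_width
        if t_ivd.min() < fw + 1:
            raise GeometryError("disc extends into the unregistered frame (top)")
        if self.c_mid - self.hw < lo + 1 or self.c_mid + self.hw > hi - 1:
            raise GeometryError("disc is wider than the posterior-element band")
        if self.pe_bottom > h - fw - 2:
            raise GeometryError("posterior elements extend into the frame (bottom)")
        if (b_ivd < t_ivd - 0.01).any():  # tolerance: both axes vanish at the tips
            raise GeometryError("posterior disc boundary crosses the anterior one")
        if (t_pe - a_top < 1.0).any():
            raise GeometryError("disc touches the posterior elements")
        if self.ts_halfheight < 1.0:
            raise GeometryError(
                f"canal gap {self.canal_gap:.1f} px cannot host the thecal sac"
            )


def rasterize_label(spec: PhantomSpec) -> np.ndarray:
    """Rasterize the analytic phantom geometry into a six-class label image."""
    geo = _Geometry(spec)
    h, w = spec.shape
    cols = np.arange(w, dtype=float)
    rows = np.arange(h, dtype=float)[:, None]
    in_disc_cols = np.abs(geo._u(cols)) <= 1.0

    t_ivd, b_ivd = geo.t_ivd(cols), geo.b_ivd(cols)
    t_pe, a_top = geo.t_pe(cols), geo.aap_top(cols)
    label = np.full((h, w), 6, dtype=np.int16)

    lo, hi = geo.lateral_extent
    pe_cols = (cols >= lo) & (cols <= hi)
    label[(rows >= t_pe) & (rows <= geo.pe_bottom) & pe_cols] = 3
    label[(rows > a_top) & (rows < t_pe) & pe_cols] = 5
    label[(rows >= t_ivd) & (rows <= b_ivd) & in_disc_cols] = 2
    ts_u = (cols - geo.c_mid) / spec.ts_halfwidth
    ts_mask = np.abs(ts_u) < 1.0
    ts_half = geo.ts_halfheight * np.sqrt(np.clip(1.0 - ts_u * ts_u, 0.0, None))
    label[(np.abs(rows - geo.ts_center_row) <= ts_half) & ts_mask] = 4

    fw = spec.frame_width
    label[:fw, :] = 1
    label[-fw:, :] = 1
    label[:, :fw] = 1
    label[:, -fw:] = 1
    return label


def render_modalities(
    spec: PhantomSpec, label: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class mean intensities + smooth bias field + Gaussian noise."""
    h, w = label.shape
    t1 = np.zeros((h, w)); t2 = np.zeros((h, w))
    for c in range(1, 7):
        m = label == c
        t1[m] = spec.t1_means[c]
        t2[m] = spec.t2_means[c]
    rr = np.arange(h)[:, None] / max(h - 1, 1) - 0.5
    cc = np.arange(w)[None, :] / max(w - 1, 1) - 0.5
    bias = spec.bias_amp * (rr * rr + cc * cc)
    rng1 = np.random.default_rng([spec.seed, 0])
    rng2 = np.random.default_rng([spec.seed, 1])
    t1 = t1 + bias + rng1.normal(0.0, spec.noise_sd, (h, w))
    t2 = t2 + 0.7 * bias + rng2.normal(0.0, spec.noise_sd, (h, w))
    return t1, t2


# --- analytic ground truth -------------------------------------------------
# The landmark rules below intentionally mirror the measurement pipeline but
# are evaluated on densely sampled analytic curves, independent of the label
# raster, the boundary grid and the landmarks module's search code.


def _line_intersection(a0, a1, b0, b1):
    u = a1 - a0
    v = b1 - b0
    det = u[1] * v[0] - u[0] * v[1]
    if abs(det) < 1e-12:
        raise GeometryError("chord and bisecting line are parallel")
    rhs = b0 - a0
    t = (rhs[1] * v[0] - rhs[0] * v[1]) / det
    return a0 + t * u


def analytic_truth(
    spec: PhantomSpec, step: float = 0.01
) -> tuple[LandmarkSet, Measurements]:
    """Ground-truth landmarks and measurements from the analytic curves,
    sampled every ``step`` px along the column axis."""
    geo = _Geometry(spec)
    cols = np.arange(geo.c_mid - geo.hw + 0.5, geo.c_mid + geo.hw - 0.5 + step, step)
    a2 = np.column_stack([geo.b_ivd(cols), cols])
    a3 = np.column_stack([geo.t_pe(cols), cols])

    # disc centroid by column-wise integration of the region between curves
    height = geo.b_ivd(cols) - geo.t_ivd(cols)
    area = height.sum()
    d_c = np.array([
        float((0.5 * (geo.b_ivd(cols) + geo.t_ivd(cols)) * height).sum() / area),
        float((cols * height).sum() / area),
    ])

    ts_lo = geo.c_mid - spec.ts_halfwidth - 1.0
    ts_hi = geo.c_mid + spec.ts_halfwidth + 1.0
    midline = d_c[1]

    def foramen(side: str):
        if side == "left":
            sel = (cols < midline) & (cols < ts_lo)
        else:
            sel = (cols > midline) & (cols > ts_hi)
        if not sel.any():
            raise GeometryError(f"no analytic {side} foramen candidates")
        top, bot = a2[sel], a3[sel]
        d, idx = cKDTree(bot).query(top)
        ti = int(np.argmin(d))
        return top[ti].copy(), bot[idx[ti]].copy()

    t_l, b_l = foramen("left")
    t_r, b_r = foramen("right")

    between = (a3[:, 1] > b_l[1]) & (a3[:, 1] < b_r[1])
    canal = a3[between]
    b_m = canal[np.argmax(canal[:, 0])].copy()

    arc = a2[(a2[:, 1] >= t_l[1]) & (a2[:, 1] <= t_r[1])]
    chord = t_r - t_l
    normal = np.array([-chord[1], chord[0]]) / np.hypot(*chord)
    objective = np.abs((arc - t_l) @ normal) - np.sqrt(((arc - b_m) ** 2).sum(axis=1))
    q = arc[int(np.argmax(objective))].copy()

    p = _line_intersection(t_l, t_r, b_m, d_c)
    v = d_c - b_m
    q_prime = b_m + (((q - b_m) @ v) / (v @ v)) * v

    lm = LandmarkSet(T_L=t_l, T_R=t_r, B_L=b_l, B_R=b_r, B_M=b_m, D_C=d_c,
                     p=p, q=q, q_prime=q_prime)
    mm = spec.mm_per_pixel
    d_qprime = float(np.hypot(*(b_m - q_prime)))
    d_p = float(np.hypot(*(b_m - p)))
    r = d_qprime / d_p
    category = ("severe" if r <= SEVERE_THRESHOLD
                else "normal" if r >= NORMAL_THRESHOLD else "minor")
    meas = Measurements(
        d_L=float(np.hypot(*(t_l - b_l))) * mm,
        d_R=float(np.hypot(*(t_r - b_r))) * mm,
        d_AP=d_qprime * mm,
        d_qprime=d_qprime,
        d_p=d_p,
        r=r,
        category=category,
    )
    return lm, meas


def generate_phantom(spec: PhantomSpec | None = None) -> PhantomStudy:
    """Generate one synthetic slice: label, modalities, composite and truth."""
    spec = spec or PhantomSpec()
    label = rasterize_label(spec)
    t1, t2 = render_modalities(spec, label)
    lm, meas = analytic_truth(spec)
    return PhantomStudy(
        spec=spec,
        label=label,
        t1=t1,
        t2=t2,
        composite=build_composite(t1, t2),
        truth_landmarks=lm,
        truth_measurements=meas,
    )


def solve_herniation_amplitude(
    spec: PhantomSpec, target_r: float, step: float = 0.05
) -> PhantomSpec:
    """Return a copy of ``spec`` whose analytic herniation ratio equals
    ``target_r`` (the ratio decreases monotonically with the bump
    amplitude)."""
    def ratio(h: float) -> float:
        trial = dataclasses.replace(spec, hern_amp=h)
        return analytic_truth(trial, step=step)[1].r - target_r

    lo = -0.45 * spec.indent
    # largest bump still leaving room for the (compressed) thecal sac
    geo0 = _Geometry(dataclasses.replace(spec, hern_amp=0.0))
    hi = geo0.canal_gap - 4.7
    while hi > lo:
        try:
            _Geometry(dataclasses.replace(spec, hern_amp=hi))
            break
        except GeometryError:
            hi -= 0.5
    f_lo, f_hi = ratio(lo), ratio(hi)
    if f_lo * f_hi > 0:
        raise GeometryError(
            f"target ratio {target_r} is outside the achievable range "
            f"[{f_hi + target_r:.2f}, {f_lo + target_r:.2f}]"
        )
    h = brentq(ratio, lo, hi, xtol=1e-4)
    return dataclasses.replace(spec, hern_amp=float(h))


def _shift(arr: np.ndarray, dr: int, dc: int) -> np.ndarray:
    h, w = arr.shape
    padded = np.pad(arr, 1, mode="edge")
    return padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]


def _boundary_mask(label: np.ndarray) -> np.ndarray:
    return (
        (label != _shift(label, 1, 0))
        | (label != _shift(label, -1, 0))
        | (label != _shift(label, 0, 1))
        | (label != _shift(label, 0, -1))
    )


def _important_boundary_mask(label: np.ndarray) -> np.ndarray:
    """Pixels of an anatomical class (2-5) 4-adjacent to a different
    anatomical class, i.e. on one of the important IVD/PE boundaries."""
    anatomical = (label >= 2) & (label <= 5)
    out = np.zeros(label.shape, dtype=bool)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nb = _shift(label, dr, dc)
        out |= anatomical & (nb != label) & (nb >= 2) & (nb <= 5)
    return out


def perturb_label(label: np.ndarray, pspec: PerturbationSpec) -> np.ndarray:
    """Simulate annotation error: jitter region boundaries by up to
    ``jitter_px`` pixels and inject 1x1 holes along them."""
    out = validate_label_image(label).copy()
    rng = np.random.default_rng(pspec.seed)
    for _ in range(int(pspec.jitter_px)):
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            neighbor = _shift(out, dr, dc)
            flip = (neighbor != out) & (rng.random(out.shape) < 0.35)
            out[flip] = neighbor[flip]
    if pspec.hole_rate > 0:
        from scipy import ndimage

        boundary = _important_boundary_mask(out)
        # candidate sites: anatomical pixels whose whole 8-neighborhood
        # shares their class (so the defect is a genuine 1x1 hole), within
        # 2 px of an important boundary
        uniform = np.ones(out.shape, dtype=bool)
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (1, -1),
                       (-1, 1), (-1, -1)):
            uniform &= _shift(out, dr, dc) == out
        near = ndimage.binary_dilation(boundary, iterations=2)
        sites = np.argwhere(uniform & near & (out >= 2) & (out <= 5))
        n_holes = int(round(pspec.hole_rate * int(boundary.sum()) / 100.0))
        if n_holes > 0 and len(sites) > 0:
            picks = rng.choice(len(sites), size=min(n_holes, len(sites)),
                               replace=False)
            values = rng.choice(np.asarray(pspec.hole_classes), size=len(picks))
            out[sites[picks, 0], sites[picks, 1]] = values
    return out


@dataclass
class CohortSlice:
    """One slice of a synthetic cohort (study x disc level)."""

    study_index: int
    level: str
    study: PhantomStudy


#: category -> (probability, low r, high r) used when drawing cohort specs.
DEFAULT_CATEGORY_MIX = (
    ("normal", 0.5, 1.15, 1.40),
    ("minor", 0.3, 0.86, 1.04),
    ("severe", 0.2, 0.56, 0.78),
)


def generate_cohort(
    n_studies: int,
    levels=DEFAULT_LEVELS,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
    category_mix=DEFAULT_CATEGORY_MIX,
) -> list[CohortSlice]:
    """Generate ``n_studies`` x ``len(levels)`` synthetic slices.

    Each slice uses an independent substream derived from (seed, study,
    level), so cohorts are reproducible under partial regeneration.  The
    per-slice spec jitters the base geometry and draws a herniation
    category from ``category_mix``, solving the bump amplitude for a
    target ratio drawn within that category's band.
    """
    if n_studies < 1:
        raise ValueError("n_studies must be >= 1")
    base = base_spec or PhantomSpec()
    probs = np.array([m[1] for m in category_mix], dtype=float)
    probs = probs / probs.sum()
    out: list[CohortSlice] = []
    for si in range(n_studies):
        for li, level in enumerate(levels):
            rng = np.random.default_rng([seed, si, li])
            spec = dataclasses.replace(
                base,
                seed=int(rng.integers(2**31 - 1)),
                ivd_row=base.ivd_row * float(rng.uniform(0.98, 1.02)),
                ivd_halfwidth=base.ivd_halfwidth * float(rng.uniform(0.95, 1.05)),
                ivd_top=base.ivd_top * float(rng.uniform(0.95, 1.05)),
                ivd_bot=base.ivd_bot * float(rng.uniform(0.95, 1.05)),
                gap_left=base.gap_left * float(rng.uniform(0.85, 1.2)),
                gap_right=base.gap_right * float(rng.uniform(0.85, 1.2)),
                canal_depth=base.canal_depth * float(rng.uniform(0.9, 1.1)),
            )
            idx = int(rng.choice(len(category_mix), p=probs))
            _, _, r_lo, r_hi = category_mix[idx]
            target_r = float(rng.uniform(r_lo, r_hi))
            spec = solve_herniation_amplitude(spec, target_r)
            out.append(CohortSlice(study_index=si, level=level,
                                   study=generate_phantom(spec)))
    return out


def split_dataset(items, train_fraction: float = 0.8, seed: int = 0):
    """Random disjoint train/test partition with sizes round(n*f) and the
    remainder."""
    items = list(items)
    if not items:
        raise ValueError("cannot split an empty dataset")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(items))
    n_train = int(round(len(items) * train_fraction))
    train = [items[i] for i in perm[:n_train]]
    test = [items[i] for i in perm[n_train:]]
    return train, test


def default_spacing(spec: PhantomSpec) -> PixelSpacing:
    return PixelSpacing(mm_per_pixel=spec.mm_per_pixel)
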