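"""End-to-end single-slice pipeline and batch driver.

Stages (in order): schema validation -> optional morphological closing ->
sub-pixel boundary evolution of the important region pairs -> important
boundary extraction (ordering + adaptive smoothing) -> landmark location
-> measurement and herniation grading.  Warnings from every stage are
propagated, never dropped.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evolve as evolve_mod
from . import imaging as imaging_mod
from . import landmarks as landmarks_mod
from .errors import SpinemetricsError
from .evolve import EvolutionConfig, SmoothingConfig
from .grid import IMPORTANT_PAIRS, build_boundary_grid, build_sparse, compute_gradients
from .imaging import DEFAULT_CLASS_ORDER, PixelSpacing
from .landmarks import NORMAL_THRESHOLD, SEVERE_THRESHOLD


@dataclass(frozen=True)
class RunConfig:
    """All tunables of the slice pipeline in one place."""

    evolution: EvolutionConfig = field(default_factory=EvolutionConfig)
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    evolve: bool = True
    close: bool = True
    class_order: tuple[int, ...] = DEFAULT_CLASS_ORDER
    mm_per_pixel: float = 0.5
    severe_threshold: float = SEVERE_THRESHOLD
    normal_threshold: float = NORMAL_THRESHOLD
    radiological_convention: bool = False
    pairs: frozenset[tuple[int, int]] = IMPORTANT_PAIRS

    @property
    def spacing(self) -> PixelSpacing:
        return PixelSpacing(mm_per_pixel=self.mm_per_pixel)

    def to_flat_dict(self) -> dict[str, object]:
        flat: dict[str, object] = {}
        for section, obj in (("evolution", self.evolution), ("smoothing", self.smoothing)):
            for f in dataclasses.fields(obj):
                flat[f"{section}.{f.name}"] = getattr(obj, f.name)
        flat.update(
            {
                "evolve": self.evolve,
                "close": self.close,
                "class_order": list(self.class_order),
                "mm_per_pixel": self.mm_per_pixel,
                "severe_threshold": self.severe_threshold,
                "normal_threshold": self.normal_threshold,
                "radiological_convention": self.radiological_convention,
                "pairs": sorted(list(p) for p in self.pairs),
            }
        )
        return flat


def load_config(path) -> RunConfig:
    """Build a RunConfig from a flat YAML/JSON document with dotted keys."""
    import yaml

    with open(path) as fh:
        flat = yaml.safe_load(fh) or {}
    return config_from_flat(flat)


def config_from_flat(flat: dict) -> RunConfig:
    evo_kwargs, smo_kwargs, top_kwargs = {}, {}, {}
    for key, value in flat.items():
        if key.startswith("evolution."):
            evo_kwargs[key.split(".", 1)[1]] = value
        elif key.startswith("smoothing."):
            smo_kwargs[key.split(".", 1)[1]] = value
        elif key == "class_order":
            top_kwargs[key] = tuple(value)
        elif key == "pairs":
            top_kwargs[key] = frozenset(tuple(p) for p in value)
        else:
            top_kwargs[key] = value
    return RunConfig(
        evolution=EvolutionConfig(**evo_kwargs),
        smoothing=SmoothingConfig(**smo_kwargs),
        **top_kwargs,
    )


@dataclass
class PipelineResult:
    """Landmarks, measurements and diagnostics for one slice."""

    landmarks: landmarks_mod.LandmarkSet
    measurements: landmarks_mod.Measurements
    boundaries: landmarks_mod.ImportantBoundaries
    pair_points: dict[tuple[int, int], np.ndarray]
    history: evolve_mod.EvolutionHistory | None
    warnings: list[str]
    label_refined: np.ndarray  # final working-resolution label

    def to_dict(self, radiological: bool = False) -> dict:
        lm = self.landmarks.to_dict()
        meas = self.measurements.to_dict()
        if radiological:
            # patient left appears on the image right: swap the side names
            lm = {**lm, "T_L": lm["T_R"], "T_R": lm["T_L"],
                  "B_L": lm["B_R"], "B_R": lm["B_L"]}
            meas = {**meas, "d_L_mm": meas["d_R_mm"], "d_R_mm": meas["d_L_mm"]}
        return {"landmarks": lm, "measurements": meas,
                "warnings": list(self.warnings)}


def read_any_image(path) -> np.ndarray:
    """Read a slice image, trying the composite TIFF layout first."""
    if str(path).lower().endswith((".tif", ".tiff")):
        try:
            return imaging_mod.read_composite(path)
        except Exception:
            pass
    return imaging_mod.read_image(path)


def _reduce_image(image: np.ndarray) -> np.ndarray:
    """Collapse a composite to one working intensity image (mean of the
    T1 and registered-T2 channels)."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] == 3:
        return 0.5 * (arr[:, :, 0] + arr[:, :, 1])
    raise ValueError(f"expected H x W or H x W x 3 image, got shape {arr.shape}")


def run_slice(image: np.ndarray, label: np.ndarray,
              cfg: RunConfig | None = None) -> PipelineResult:
    """Run the full measurement pipeline on one slice."""
    cfg = cfg or RunConfig()
    warnings: list[str] = []
    img = _reduce_image(image)
    lab = imaging_mod.validate_label_image(label)
    if img.shape != lab.shape:
        raise ValueError(f"image {img.shape} and label {lab.shape} shapes differ")

    if cfg.close:
        lab = imaging_mod.close_labels(lab, cfg.class_order)

    if cfg.evolve:
        level = cfg.evolution.k
        lab_hr, pair_points, history = evolve_mod.subpixel_boundary_evolution(
            img, lab, cfg.pairs, cfg.evolution
        )
        if history.warning:
            warnings.append("evolution: sweep cap reached before convergence")
    else:
        level, history, lab_hr = 0, None, lab
        rep = build_sparse(build_boundary_grid(lab, compute_gradients(img)))
        pair_points = evolve_mod.boundary_points_by_pair(rep, cfg.pairs, level=0)

    boundaries = landmarks_mod.extract_important_boundaries(
        pair_points, lab_hr, image=img, smoothing=cfg.smoothing,
    )
    centroid = evolve_mod.to_original_frame(
        landmarks_mod.centroid_IVD(lab_hr), level
    )
    extent_hr = landmarks_mod.ts_column_extent(lab_hr, pad=0.0)
    ts_extent = None
    if extent_hr is not None:
        lo, hi = evolve_mod.to_original_frame(np.array(extent_hr), level)
        ts_extent = (float(lo) - 1.0, float(hi) + 1.0)

    lm, lm_warnings = landmarks_mod.locate_landmarks(boundaries, centroid, ts_extent)
    warnings.extend(lm_warnings)
    meas = landmarks_mod.measure(
        lm, cfg.spacing, cfg.severe_threshold, cfg.normal_threshold,
        warnings=warnings,
    )
    return PipelineResult(
        landmarks=lm,
        measurements=meas,
        boundaries=boundaries,
        pair_points=pair_points,
        history=history,
        warnings=warnings,
        label_refined=lab_hr,
    )


def run_batch(manifest, cfg: RunConfig | None = None,
              out_path=None) -> pd.DataFrame:
    """Run the pipeline over every row of a manifest.

    ``manifest`` is a CSV path or DataFrame with columns ``image`` and
    ``label`` (file paths) and optionally ``spacing_mm``.  Per-row
    failures are recorded and the batch continues.
    """
    cfg = cfg or RunConfig()
    if isinstance(manifest, (str, Path)):
        table = pd.read_csv(manifest)
    else:
        table = manifest.copy()
    for col in ("image", "label"):
        if col not in table.columns:
            raise ValueError(f"manifest lacks required column {col!r}")

    rows = []
    for _, row in table.iterrows():
        record = {"image": row["image"], "label": row["label"]}
        try:
            img = read_any_image(row["image"])
            lab = imaging_mod.read_label_image(row["label"])
            row_cfg = cfg
            if "spacing_mm" in table.columns and not pd.isna(row.get("spacing_mm")):
                row_cfg = dataclasses.replace(cfg, mm_per_pixel=float(row["spacing_mm"]))
            result = run_slice(img, lab, row_cfg)
            payload = result.to_dict(radiological=cfg.radiological_convention)
            record.update(payload["measurements"])
            record["warnings"] = "; ".join(payload["warnings"])
            record["status"] = "ok"
        except (SpinemetricsError, OSError, ValueError) as exc:
            record["status"] = "failed"
            record["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(record)
    result = pd.DataFrame(rows)
    if out_path is not None:
        out_path = Path(out_path)
        if out_path.suffix == ".json":
            out_path.write_text(json.dumps(rows, indent=2, default=str))
        else:
            result.to_csv(out_path, index=False)
    return result
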