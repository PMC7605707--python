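"""Image and label-image I/O for axial lumbar-spine slices.

All images are 2-D numpy arrays in (row, column) order with the anterior
side of the axial slice at row 0.  Label images use the fixed six-class
schema: 1 = Unregistered, 2 = IVD (intervertebral disc), 3 = PE (posterior
elements), 4 = TS (thecal sac), 5 = AAP (area between anterior and
posterior vertebral elements), 6 = Other.

Supported on-disk formats: 8/16-bit grayscale PNG, TIFF, and single-slice
NIfTI.  Label images are stored as 8-bit grayscale PNG with raw values 1-6.
Composites (T1, registered T2, |T1-T2|) are stored as 3-channel TIFF.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import SchemaViolationError

#: Class id -> anatomical name, fixed schema.
CLASS_NAMES = {
    1: "Unregistered",
    2: "IVD",
    3: "PE",
    4: "TS",
    5: "AAP",
    6: "Other",
}

#: Region ids of the six-class schema.
LABEL_SET = frozenset(CLASS_NAMES)

#: Ids of the intervertebral disc and posterior-element regions.
IVD, PE, TS, AAP = 2, 3, 4, 5

#: Default per-class precedence for morphological closing: anatomical
#: classes overwrite background; TS and AAP last because they are smallest.
DEFAULT_CLASS_ORDER = (2, 3, 4, 5)

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


@dataclass(frozen=True)
class PixelSpacing:
    """Isotropic pixel size in millimetres per pixel."""

    mm_per_pixel: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mm_per_pixel) or self.mm_per_pixel <= 0:
            raise ValueError(f"mm_per_pixel must be positive, got {self.mm_per_pixel}")


def validate_label_image(labels: np.ndarray) -> np.ndarray:
    """Check a label array against the six-class schema.

    Returns the array as a small-integer dtype.  Raises
    :class:`SchemaViolationError` naming the first offending value and its
    (row, column) location.
    """
    arr = np.asarray(labels)
    if arr.ndim != 2:
        raise SchemaViolationError(f"label image must be 2-D, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        rounded = np.rint(arr)
        if not np.allclose(arr, rounded, atol=0):
            raise SchemaViolationError("label image contains non-integer values")
        arr = rounded.astype(np.int16)
    bad = (arr < 1) | (arr > 6)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise SchemaViolationError(
            f"label value {int(arr[r, c])} at (row={int(r)}, col={int(c)}) "
            f"is outside the schema {{1..6}}"
        )
    return arr.astype(np.int16, copy=False)


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return any(name.endswith(s) for s in _NIFTI_SUFFIXES)


def read_image(path, slice_index: int | None = None) -> np.ndarray:
    """Read a 2-D intensity image (PNG/TIFF/single-slice NIfTI) as float64.

    NIfTI volumes must either be single-slice or be given an explicit
    ``slice_index`` into the third axis.  Anisotropic in-plane NIfTI
    spacing is rejected.
    """
    import imageio.v3 as iio

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        import nibabel as nib

        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:2]
        if len(zooms) == 2 and not np.isclose(zooms[0], zooms[1]):
            raise ValueError(
                f"anisotropic in-plane spacing {zooms} is not supported"
            )
        data = np.asanyarray(img.dataobj)
        data = np.squeeze(data) if data.ndim > 2 and data.shape[2] == 1 else data
        if data.ndim == 3:
            if slice_index is None:
                raise ValueError(
                    f"{path} has {data.shape[2]} slices; pass slice_index"
                )
            data = data[:, :, slice_index]
        if data.ndim != 2:
            raise ValueError(f"cannot interpret {path} as a 2-D slice")
        return np.asarray(data, dtype=np.float64)
    data = iio.imread(path)
    if data.ndim == 3:  # drop a trivial channel axis if present
        if data.shape[2] == 1:
            data = data[:, :, 0]
        else:
            raise ValueError(f"{path} is multi-channel; expected grayscale")
    return np.asarray(data, dtype=np.float64)


def write_image(path, pixels: np.ndarray) -> None:
    """Write a 2-D image as PNG/TIFF/NIfTI, inferring the format from the suffix."""
    import imageio.v3 as iio

    path = Path(path)
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise ValueError("write_image expects a 2-D array")
    if _is_nifti(path):
        import nibabel as nib

        nib.save(nib.Nifti1Image(arr[:, :, None].astype(np.float64), np.eye(4)), str(path))
        return
    if path.suffix.lower() == ".png":
        if not np.issubdtype(arr.dtype, np.integer) and not arr.dtype == np.uint8:
            if np.allclose(arr, np.rint(arr)):
                arr = np.rint(arr)
            else:
                raise ValueError("PNG output requires integer-valued pixels")
        arr = arr.astype(np.uint16 if arr.max(initial=0) > 255 else np.uint8)
    iio.imwrite(path, arr)


def read_label_image(path) -> np.ndarray:
    """Read and schema-validate a six-class label image."""
    raw = read_image(path)
    return validate_label_image(raw)


def write_label_image(path, labels: np.ndarray) -> None:
    """Write a validated label image as 8-bit grayscale (values 1-6)."""
    arr = validate_label_image(labels)
    write_image(path, arr.astype(np.uint8))


def build_composite(t1: np.ndarray, t2_registered: np.ndarray) -> np.ndarray:
    """Stack (T1, registered T2, |T1 - T2|) into an H x W x 3 composite.

    The third channel is the per-pixel Manhattan (absolute) difference of
    the two modalities.
    """
    t1 = np.asarray(t1, dtype=np.float64)
    t2 = np.asarray(t2_registered, dtype=np.float64)
    if t1.shape != t2.shape:
        raise ValueError(f"shape mismatch: T1 {t1.shape} vs T2 {t2.shape}")
    return np.stack([t1, t2, np.abs(t1 - t2)], axis=-1)


def write_composite(path, composite: np.ndarray) -> None:
    """Persist a composite as a 3-channel 16-bit TIFF (T1, T2, |T1-T2|).

    Intensities are scaled by the largest channel value to use the 16-bit
    range; the scale factor is stored losslessly in the file description.
    """
    import tifffile

    comp = np.asarray(composite, dtype=np.float64)
    if comp.ndim != 3 or comp.shape[2] != 3:
        raise ValueError("composite must be H x W x 3")
    peak = float(comp.max(initial=0.0))
    scale = 65535.0 / peak if peak > 0 else 1.0
    data = np.rint(comp * scale).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="rgb", description=f"scale={scale!r}")


def read_composite(path) -> np.ndarray:
    """Read a composite TIFF written by :func:`write_composite`."""
    import tifffile

    with tifffile.TiffFile(path) as tif:
        data = tif.asarray().astype(np.float64)
        desc = tif.pages[0].tags.get("ImageDescription")
        scale = 1.0
        if desc is not None and str(desc.value).startswith("scale="):
            scale = float(str(desc.value)[len("scale="):])
    return data / scale


def close_labels(labels: np.ndarray, class_order=DEFAULT_CLASS_ORDER) -> np.ndarray:
    """Morphologically close each class mask in turn to fill 1x1 holes/gaps.

    For each class ``c`` in ``class_order`` the binary mask of ``c`` is
    closed with a 3x3 square structuring element; pixels newly claimed by
    the closing overwrite earlier classes, so later classes take
    precedence.  Pixels are never removed from a class, only added.
    """
    out = validate_label_image(labels).copy()
    order = tuple(class_order)
    if len(set(order)) != len(order) or not set(order) <= LABEL_SET:
        raise ValueError(f"class_order must be distinct values in 1..6, got {order}")
    structure = np.ones((3, 3), dtype=bool)
    for c in order:
        mask = out == c
        dilated = ndimage.binary_dilation(mask, structure=structure)
        closed = ndimage.binary_erosion(dilated, structure=structure, border_value=1)
        out[closed] = c
    return out
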