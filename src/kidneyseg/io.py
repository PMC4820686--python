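"""Image/volume data model and readers/writers for CT slice stacks and masks.

Conventions used throughout the package:

* images are 2-D ``float64`` arrays with intensities in ``[0, 1]``; raw inputs
  are rescaled once at load time, volume-wide, by ``(v - min) / (max - min)``
  (a constant-valued volume maps to all zeros);
* coordinates are 0-based ``(row, col)`` with row increasing downward;
* bounding boxes are half-open: ``[row_lo, row_hi) x [col_lo, col_hi)``;
* binary masks are boolean arrays of the same shape as their image.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "BoundingBox",
    "Volume",
    "as_gray_image",
    "as_binary_mask",
    "normalize_volume",
    "read_volume",
    "write_mask_stack",
    "read_mask_stack",
]


@dataclass(frozen=True)
class BoundingBox:
    """Half-open axis-aligned rectangle in (row, col) pixel coordinates."""

    row_lo: int
    col_lo: int
    row_hi: int
    col_hi: int

    def __post_init__(self) -> None:
        if not (self.row_lo < self.row_hi and self.col_lo < self.col_hi):
            raise ValueError(f"degenerate bounding box {self}")
        if self.row_lo < 0 or self.col_lo < 0:
            raise ValueError(f"negative bounding box corner {self}")

    def validate(self, shape: tuple[int, int]) -> None:
        rows, cols = shape
        if self.row_hi > rows or self.col_hi > cols:
            raise ValueError(f"bounding box {self} exceeds image shape {shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_hi - self.row_lo, self.col_hi - self.col_lo)

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row_lo, self.row_hi), slice(self.col_lo, self.col_hi))

    def clamp(self, shape: tuple[int, int]) -> "BoundingBox":
        rows, cols = shape
        return BoundingBox(
            max(self.row_lo, 0),
            max(self.col_lo, 0),
            min(self.row_hi, rows),
            min(self.col_hi, cols),
        )

    def contains_box(self, other: "BoundingBox") -> bool:
        return (
            self.row_lo <= other.row_lo
            and self.col_lo <= other.col_lo
            and self.row_hi >= other.row_hi
            and self.col_hi >= other.col_hi
        )


@dataclass
class Volume:
    """An ordered stack of same-shaped grayscale slices.

    ``slices`` is a ``(n_slices, rows, cols)`` float array with values in
    ``[0, 1]``; ``spacing`` is optional ``(pixel_mm, pixel_mm, slice_mm)``
    metadata carried through from the source format.
    """

    slices: np.ndarray
    spacing: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=np.float64)
        if self.slices.ndim != 3:
            raise ValueError("Volume.slices must be (n_slices, rows, cols)")
        if self.slices.size == 0:
            raise ValueError("empty volume")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.slices.shape[1:]

    def __len__(self) -> int:
        return self.n_slices

    def __getitem__(self, i: int) -> np.ndarray:
        return self.slices[i]


def as_gray_image(image: np.ndarray) -> np.ndarray:
    """Validate and return a 2-D intensity image with finite values in [0,1]."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("image intensities must lie in [0, 1]")
    return img


def as_binary_mask(mask: np.ndarray, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Validate and return a boolean mask, optionally checking its shape."""
    m = np.asarray(mask)
    if m.dtype != bool:
        vals = np.unique(m)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be in {0, 1}")
        m = m.astype(bool)
    if m.ndim != 2:
        raise ValueError(f"expected a 2-D mask, got shape {m.shape}")
    if shape is not None and m.shape != tuple(shape):
        raise ValueError(f"mask shape {m.shape} != expected {tuple(shape)}")
    return m


def normalize_volume(raw: np.ndarray) -> np.ndarray:
    """Rescale a raw stack to [0,1] over the whole volume (constant -> zeros)."""
    raw = np.asarray(raw, dtype=np.float64)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


VolumeFormat = Literal["dicom_dir", "nifti", "image_stack"]
MaskFormat = Literal["png_stack", "nifti"]

_IMAGE_EXTS = {".png", ".tif", ".tiff"}


def read_volume(path: str | os.PathLike, format: VolumeFormat) -> Volume:
    """Read an ordered slice stack from disk.

    ``dicom_dir``: every readable file in the directory, sorted by the z
    component of ImagePositionPatient (fallback: InstanceNumber, filename);
    rescale slope/intercept are applied before normalization.
    ``nifti``: a .nii/.nii.gz volume, slices taken along the last axis.
    ``image_stack``: a directory of PNG/TIFF files in lexicographic order.

    Intensities are rescaled to [0, 1] over the whole volume.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such path: {path}")
    if format == "dicom_dir":
        raw, spacing = _read_dicom_dir(path)
    elif format == "nifti":
        raw, spacing = _read_nifti(path)
    elif format == "image_stack":
        raw, spacing = _read_image_stack(path)
    else:
        raise ValueError(f"unknown volume format: {format!r}")
    return Volume(normalize_volume(raw), spacing=spacing)


def _read_dicom_dir(path: Path) -> tuple[np.ndarray, tuple | None]:
    import pydicom

    if not path.is_dir():
        raise NotADirectoryError(f"dicom_dir expects a directory: {path}")
    datasets = []
    for f in sorted(path.iterdir()):
        if not f.is_file():
            continue
        try:
            ds = pydicom.dcmread(str(f))
            ds.pixel_array  # force decode now so errors name the file
        except Exception as exc:  # pragma: no cover - depends on corrupt input
            raise IOError(f"unreadable DICOM file {f}: {exc}") from exc
        datasets.append((f, ds))
    if not datasets:
        raise IOError(f"no readable DICOM files in {path}")

    def sort_key(item):
        f, ds = item
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None and len(ipp) == 3:
            return (0, float(ipp[2]), str(f))
        inst = getattr(ds, "InstanceNumber", None)
        if inst is not None:
            return (1, float(inst), str(f))
        return (2, 0.0, str(f))

    datasets.sort(key=sort_key)
    arrays = []
    shape = None
    for f, ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ValueError(f"mixed slice shapes: {f} has {arr.shape}, expected {shape}")
        arrays.append(arr)
    ds0 = datasets[0][1]
    spacing = None
    ps = getattr(ds0, "PixelSpacing", None)
    if ps is not None and len(ps) == 2:
        slice_mm = float(getattr(ds0, "SpacingBetweenSlices", getattr(ds0, "SliceThickness", 1.0)))
        spacing = (float(ps[0]), float(ps[1]), slice_mm)
    return np.stack(arrays), spacing


def _read_nifti(path: Path) -> tuple[np.ndarray, tuple | None]:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise IOError(f"unreadable NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D NIfTI volume, got shape {data.shape}")
    # nibabel axis order is (x, y, z): move the slice axis first.
    raw = np.moveaxis(data, 2, 0)
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[0]), float(zooms[1]), float(zooms[2]))
    return raw, spacing


def _read_image_stack(path: Path) -> tuple[np.ndarray, tuple | None]:
    import imageio.v3 as iio

    if not path.is_dir():
        raise NotADirectoryError(f"image_stack expects a directory: {path}")
    files = sorted(f for f in path.iterdir() if f.suffix.lower() in _IMAGE_EXTS)
    if not files:
        raise IOError(f"no PNG/TIFF files in {path}")
    arrays = []
    shape = None
    for f in files:
        try:
            arr = np.asarray(iio.imread(str(f)), dtype=np.float64)
        except Exception as exc:
            raise IOError(f"unreadable image file {f}: {exc}") from exc
        if arr.ndim == 3:  # collapse RGB(A) to luminance-by-mean
            arr = arr[..., :3].mean(axis=2)
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ValueError(f"mixed slice shapes: {f} has {arr.shape}, expected {shape}")
        arrays.append(arr)
    return np.stack(arrays), None


def write_mask_stack(
    masks: Sequence[np.ndarray], path: str | os.PathLike, format: MaskFormat = "png_stack"
) -> None:
    """Write binary masks; ``png_stack`` stores {0,255} PNGs, ``nifti`` {0,1}.

    Round-trip through :func:`read_mask_stack` is bit-exact.
    """
    masks = [as_binary_mask(m) for m in masks]
    if not masks:
        raise ValueError("empty mask list")
    shape = masks[0].shape
    for m in masks:
        if m.shape != shape:
            raise ValueError("masks must share one shape")
    path = Path(path)
    if format == "png_stack":
        import imageio.v3 as iio

        path.mkdir(parents=True, exist_ok=True)
        width = max(4, len(str(len(masks))))
        for i, m in enumerate(masks):
            iio.imwrite(str(path / f"mask_{i:0{width}d}.png"), m.astype(np.uint8) * 255)
    elif format == "nifti":
        import nibabel as nib

        data = np.moveaxis(np.stack(masks).astype(np.uint8), 0, 2)
        nib.save(nib.Nifti1Image(data, affine=np.eye(4)), str(path))
    else:
        raise ValueError(f"unknown mask format: {format!r}")


def read_mask_stack(path: str | os.PathLike, format: MaskFormat = "png_stack") -> list[np.ndarray]:
    """Read a mask stack written by :func:`write_mask_stack`."""
    path = Path(path)
    if format == "png_stack":
        import imageio.v3 as iio

        files = sorted(f for f in path.iterdir() if f.suffix.lower() == ".png")
        if not files:
            raise IOError(f"no PNG masks in {path}")
        return [np.asarray(iio.imread(str(f))) > 0 for f in files]
    if format == "nifti":
        import nibabel as nib

        data = np.asanyarray(nib.load(str(path)).dataobj)
        return [s.astype(bool) for s in np.moveaxis(data, 2, 0)]
    raise ValueError(f"unknown mask format: {format!r}")
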