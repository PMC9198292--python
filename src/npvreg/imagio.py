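"""Image container, file I/O, preprocessing and sample-set construction.

Coordinate convention used throughout the package: images live on a 0-based
integer lattice with axis order (x, y[, z]) mapped directly onto the numpy
array axes, i.e. ``data[x, y]`` / ``data[x, y, z]``.  Gray values lie in
[0, levels-1] (default 256 levels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ChannelError, DegenerateInputError, FormatError, SizeError

logger = logging.getLogger(__name__)

__all__ = [
    "Image",
    "SampleSet",
    "read_image",
    "write_image",
    "normalize_gray",
    "strip_background",
    "intensity_centroid",
    "sample_grid",
]


@dataclass(frozen=True)
class Image:
    """A 2-D or 3-D scalar image on a voxel lattice.

    Parameters
    ----------
    data
        Scalar array, 2 or 3 axes, finite values in [0, levels-1].
    spacing
        Physical units per voxel per axis (metadata only; registration runs
        on the voxel lattice).
    levels
        Number of gray levels L; values are expected in [0, L-1].
    """

    data: np.ndarray
    spacing: tuple = None
    levels: int = 256

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim not in (2, 3):
            raise SizeError(f"image must be 2-D or 3-D, got {data.ndim} axes")
        if not np.all(np.isfinite(data)):
            raise ValueError("image contains non-finite values")
        object.__setattr__(self, "data", data)
        spacing = self.spacing
        if spacing is None:
            spacing = (1.0,) * data.ndim
        spacing = tuple(float(s) for s in spacing)
        if len(spacing) != data.ndim or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing {spacing} invalid for {data.ndim}-D image")
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def with_data(self, data: np.ndarray) -> "Image":
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass(frozen=True)
class SampleSet:
    """The regular sub-lattice of points used to evaluate the similarity.

    ``points`` has shape (N, ndim), row-major over the strided lattice.
    """

    points: np.ndarray
    stride: tuple

    def __post_init__(self):
        object.__setattr__(self, "points", np.asarray(self.points, dtype=np.intp))
        object.__setattr__(self, "stride", tuple(int(s) for s in self.stride))

    def __len__(self) -> int:
        return self.points.shape[0]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_NIFTI_EXT = (".nii", ".nii.gz")
_SLICE_EXT = (".png", ".tif", ".tiff")


def _ext(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def read_image(path) -> Image:
    """Read a NIfTI volume or a PNG/TIFF grayscale slice.

    RGB inputs are rejected: registration operates on scalar intensities.
    Convert to grayscale first (e.g. a single channel or a luminance map).
    """
    import imageio.v3 as iio
    import nibabel as nib

    path = Path(path)
    ext = _ext(path)
    if ext in _NIFTI_EXT:
        nii = nib.load(str(path))
        data = np.asarray(nii.dataobj, dtype=float)
        if data.ndim == 3 and data.shape[-1] == 1:
            data = data[..., 0]
        zooms = nii.header.get_zooms()[: data.ndim]
        return Image(data=data, spacing=tuple(float(z) for z in zooms))
    if ext in _SLICE_EXT:
        arr = iio.imread(path)
        if arr.ndim == 3:
            raise ChannelError(
                f"{path} has {arr.shape[-1]} channels; a scalar grayscale image is "
                "required — extract one channel or convert to grayscale first"
            )
        levels = 65536 if arr.dtype.itemsize > 1 else 256
        return Image(data=arr.astype(float), levels=levels)
    raise FormatError(
        f"unknown image extension {ext!r} (expected .nii/.nii.gz or .png/.tif/.tiff)"
    )


def write_image(img: Image, path) -> None:
    """Write an image; NIfTI for any dimensionality, PNG/TIFF for 2-D only.

    Integer-valued gray data round-trips losslessly through either format.
    """
    import imageio.v3 as iio
    import nibabel as nib

    path = Path(path)
    ext = _ext(path)
    if ext in _NIFTI_EXT:
        affine = np.diag(list(img.spacing) + [1.0] * (4 - img.ndim))
        nii = nib.Nifti1Image(np.asarray(img.data, dtype=np.float64), affine)
        nii.header.set_zooms(img.spacing)
        nib.save(nii, str(path))
        return
    if ext in _SLICE_EXT:
        if img.ndim != 2:
            raise FormatError("PNG/TIFF can only store 2-D slices; use NIfTI")
        dtype = np.uint8 if img.levels <= 256 else np.uint16
        iio.imwrite(path, np.round(img.data).astype(dtype))
        return
    raise FormatError(f"unknown image extension {ext!r}")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def normalize_gray(img: Image, levels: int = 256) -> Image:
    """Linearly rescale intensities so min -> 0 and max -> levels-1 (integers).

    Idempotent on its own output.  A constant image cannot be normalized.
    """
    data = img.data
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        raise DegenerateInputError("cannot normalize a constant image")
    out = np.round((data - lo) * (levels - 1) / (hi - lo))
    return Image(data=out, spacing=img.spacing, levels=levels)


def strip_background(img: Image, threshold: float, keep_largest: bool = False) -> Image:
    """Zero out voxels below ``threshold``; optionally keep only the largest
    above-threshold connected component (removes detached clutter such as a
    scanner bed frame or head mask fragments).
    """
    if not (0 <= threshold < img.levels):
        raise ValueError(f"threshold {threshold} outside [0, {img.levels})")
    if threshold == 0 and not keep_largest:
        return img
    out = np.where(img.data >= threshold, img.data, 0.0)
    if keep_largest:
        labels, n = ndimage.label(out > 0)
        if n > 1:
            sizes = ndimage.sum_labels(np.ones_like(out), labels, index=range(1, n + 1))
            keep = int(np.argmax(sizes)) + 1
            out = np.where(labels == keep, out, 0.0)
    if not np.any(out > 0):
        logger.warning("strip_background produced an empty foreground")
    return img.with_data(out)


def intensity_centroid(img: Image) -> tuple:
    """Gray-value centroid c_a = sum(a * g) / sum(g) per axis, real-valued.

    Serves as the coordinate origin for transform initialization: aligning
    the two centroids is the translation pre-alignment of the coarse stage.
    """
    g = img.data
    total = g.sum()
    if total <= 0:
        raise DegenerateInputError("intensity centroid undefined for an all-zero image")
    coords = np.indices(g.shape)
    return tuple(float((coords[a] * g).sum() / total) for a in range(g.ndim))


def sample_grid(img: Image, stride) -> SampleSet:
    """Every stride-th lattice point per axis, row-major.

    The sample count is the product over axes of ceil(size/stride); a stride
    larger than an axis still yields the origin plane on that axis.
    """
    if np.isscalar(stride):
        stride = (int(stride),) * img.ndim
    stride = tuple(int(s) for s in stride)
    if len(stride) != img.ndim or any(s < 1 for s in stride):
        raise ValueError(f"stride {stride} invalid for {img.ndim}-D image")
    axes = [np.arange(0, n, s) for n, s in zip(img.shape, stride)]
    mesh = np.meshgrid(*axes, indexing="ij")
    points = np.stack([m.ravel() for m in mesh], axis=-1)
    return SampleSet(points=points, stride=stride)
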