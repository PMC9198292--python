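"""Transform hierarchy: affine matrices and cubic B-spline free-form deformation.

Convention: a transform is a callable mapping an (N, ndim) array of
floating-frame points to their (N, ndim) positions in the reference frame.
:func:`warp_image` uses backward-warping semantics — the transform maps
output-frame voxel coordinates to input-frame sample positions — so an image
generated by ``warp_image(img, T)`` lives in the frame T maps *from*.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import SpacingError
from .imagio import Image

__all__ = [
    "AffineTransform",
    "FFDGrid",
    "FFDTransform",
    "ComposedTransform",
    "make_ffd_grid",
    "bspline_basis",
    "ffd_local_coords",
    "ffd_displacement",
    "ffd_weight_matrix",
    "ffd_apply",
    "affine_apply",
    "warp_image",
    "resample_to_reference",
    "export_displacement_field",
]

_ORDER = {"nearest": 0, "linear": 1, "cubic": 3}


# ---------------------------------------------------------------------------
# Affine
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AffineTransform:
    """Homogeneous affine transform; (ndim+1) x (ndim+1) matrix.

    Parameter-vector ordering: linear block row-major, then translation.
    """

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        d = m.shape[0] - 1
        if m.shape != (d + 1, d + 1) or d not in (2, 3):
            raise ValueError(f"affine matrix shape {m.shape} invalid")
        if not np.allclose(m[-1], np.eye(d + 1)[-1]):
            raise ValueError("last homogeneous row must be (0,...,0,1)")
        if abs(np.linalg.det(m[:d, :d])) <= 1e-12:
            raise ValueError("affine linear block is singular")
        object.__setattr__(self, "matrix", m)

    @property
    def ndim(self) -> int:
        return self.matrix.shape[0] - 1

    @property
    def linear(self) -> np.ndarray:
        d = self.ndim
        return self.matrix[:d, :d]

    @property
    def translation(self) -> np.ndarray:
        d = self.ndim
        return self.matrix[:d, d]

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.linear.T + self.translation

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self after other: (self @ other)(p) = self(other(p))."""
        return AffineTransform(self.matrix @ other.matrix)

    # -- constructors -------------------------------------------------------

    @classmethod
    def identity(cls, ndim: int) -> "AffineTransform":
        return cls(np.eye(ndim + 1))

    @classmethod
    def from_translation(cls, t) -> "AffineTransform":
        t = np.asarray(t, dtype=float)
        m = np.eye(len(t) + 1)
        m[: len(t), len(t)] = t
        return cls(m)

    @classmethod
    def rotation_2d(cls, degrees: float, center=(0.0, 0.0)) -> "AffineTransform":
        th = np.deg2rad(degrees)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        c = np.asarray(center, dtype=float)
        m = np.eye(3)
        m[:2, :2] = R
        m[:2, 2] = c - R @ c
        return cls(m)

    @classmethod
    def from_params(cls, params, ndim: int) -> "AffineTransform":
        params = np.asarray(params, dtype=float)
        if params.size != ndim * ndim + ndim:
            raise ValueError(f"expected {ndim * ndim + ndim} parameters")
        m = np.eye(ndim + 1)
        m[:ndim, :ndim] = params[: ndim * ndim].reshape(ndim, ndim)
        m[:ndim, ndim] = params[ndim * ndim :]
        return cls(m)

    def to_params(self) -> np.ndarray:
        return np.concatenate([self.linear.ravel(), self.translation])

    def to_json(self) -> dict:
        return {"kind": "affine", "matrix": self.matrix.tolist()}


def affine_apply(params: AffineTransform, point):
    """Apply an affine transform to one point or an (N, ndim) stack."""
    out = params(point)
    return out[0] if np.asarray(point).ndim == 1 else out


# ---------------------------------------------------------------------------
# B-spline FFD
# ---------------------------------------------------------------------------


def bspline_basis(u):
    """Cubic B-spline basis values (B0..B3) at fractional position u in [0, 1).

    B0=(1-u)^3/6, B1=(3u^3-6u^2+4)/6, B2=(-3u^3+3u^2+3u+1)/6, B3=u^3/6;
    nonnegative and summing to 1 for all u.  Accepts scalars or arrays;
    returns shape ``u.shape + (4,)``.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0) or np.any(u >= 1):
        raise ValueError("u must lie in [0, 1)")
    b0 = (1 - u) ** 3 / 6.0
    b1 = (3 * u**3 - 6 * u**2 + 4) / 6.0
    b2 = (-3 * u**3 + 3 * u**2 + 3 * u + 1) / 6.0
    b3 = u**3 / 6.0
    return np.stack([b0, b1, b2, b3], axis=-1)


@dataclass(frozen=True)
class FFDGrid:
    """Control lattice of a cubic B-spline free-form deformation.

    Control points sit every ``spacing`` voxels; ``control`` holds one
    displacement vector (voxels) per control point, padded by one point on
    each side so every image point has a full 4^ndim support, i.e. the
    storage shape per axis is extent/spacing + 3 and storage index = lattice
    index + 1 (lattice indices run from -1).
    """

    extent: tuple
    spacing: tuple
    control: np.ndarray

    @property
    def ndim(self) -> int:
        return len(self.extent)

    @property
    def n_cells(self) -> tuple:
        return tuple(int(x // s) for x, s in zip(self.extent, self.spacing))

    def with_control(self, control: np.ndarray) -> "FFDGrid":
        control = np.asarray(control, dtype=float).reshape(self.control.shape)
        return replace(self, control=control)

    def to_json(self) -> dict:
        return {
            "kind": "ffd",
            "extent": list(self.extent),
            "spacing": list(self.spacing),
            "control": self.control.tolist(),
        }


def make_ffd_grid(extent, spacing) -> FFDGrid:
    """Zero-displacement FFD grid; ``spacing`` must divide ``extent`` per axis."""
    extent = tuple(int(x) for x in np.atleast_1d(extent))
    if np.isscalar(spacing):
        spacing = (spacing,) * len(extent)
    spacing = tuple(float(s) for s in spacing)
    for x, s in zip(extent, spacing):
        if s <= 0 or x % s != 0:
            divisors = [d for d in range(1, x + 1) if x % d == 0]
            raise SpacingError(
                f"spacing {s} does not divide extent {x}; valid divisors: {divisors}"
            )
    shape = tuple(int(x // s) + 3 for x, s in zip(extent, spacing)) + (len(extent),)
    return FFDGrid(extent=extent, spacing=spacing, control=np.zeros(shape))


def ffd_local_coords(point, grid: FFDGrid, raw_fraction: bool = False):
    """Cell indices i = floor(x/λ) - 1 and fractions u per axis for one point.

    By default the fraction is lattice-normalized, u = x/λ - floor(x/λ), the
    reading consistent with the basis parameterizing position between control
    points; ``raw_fraction=True`` gives the literal x - floor(x).
    """
    point = np.asarray(point, dtype=float)
    if np.any(point < 0) or np.any(point > np.asarray(grid.extent)):
        raise ValueError(f"point {point} outside extent {grid.extent}")
    scaled = point / np.asarray(grid.spacing)
    i = np.floor(scaled).astype(int) - 1
    u = (point - np.floor(point)) if raw_fraction else (scaled - np.floor(scaled))
    return i, u


def ffd_displacement(grid: FFDGrid, points: np.ndarray) -> np.ndarray:
    """Tensor-product B-spline displacement at an (N, ndim) stack of points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = grid.ndim
    scaled = pts / np.asarray(grid.spacing)
    base = np.floor(scaled).astype(np.intp) - 1
    u = scaled - np.floor(scaled)
    # clamp to the padded storage so edge/out-of-domain queries (e.g. during
    # field inversion) extrapolate from the boundary cell instead of failing
    n = np.asarray(grid.n_cells, dtype=np.intp)
    base = np.clip(base, -1, n - 2)
    basis = [bspline_basis(u[:, a]) for a in range(d)]  # each (N, 4)
    disp = np.zeros_like(pts)
    # 4^d support; storage index = lattice index + 1
    for combo in np.ndindex(*(4,) * d):
        w = basis[0][:, combo[0]]
        for a in range(1, d):
            w = w * basis[a][:, combo[a]]
        idx = tuple(base[:, a] + combo[a] + 1 for a in range(d))
        disp += w[:, None] * grid.control[idx]
    return disp


def ffd_weight_matrix(grid: FFDGrid, points: np.ndarray) -> np.ndarray:
    """Dense (N, n_control) matrix W with displacement(points) = W @ control.

    The tensor-product basis weights depend only on the query points, so for
    a fixed sample set they can be computed once and reused across objective
    evaluations while only the control displacements change.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = grid.ndim
    spatial = grid.control.shape[:-1]
    scaled = pts / np.asarray(grid.spacing)
    base = np.floor(scaled).astype(np.intp) - 1
    u = scaled - np.floor(scaled)
    n = np.asarray(grid.n_cells, dtype=np.intp)
    base = np.clip(base, -1, n - 2)
    basis = [bspline_basis(u[:, a]) for a in range(d)]
    N = pts.shape[0]
    W = np.zeros((N, int(np.prod(spatial))))
    rows = np.arange(N)
    for combo in np.ndindex(*(4,) * d):
        w = basis[0][:, combo[0]]
        for a in range(1, d):
            w = w * basis[a][:, combo[a]]
        flat = base[:, 0] + combo[0] + 1
        for a in range(1, d):
            flat = flat * spatial[a] + (base[:, a] + combo[a] + 1)
        W[rows, flat] += w
    return W


def ffd_apply(grid: FFDGrid, point):
    """Displaced position of one point (or an (N, ndim) stack)."""
    pts = np.atleast_2d(np.asarray(point, dtype=float))
    if np.any(pts < 0) or np.any(pts > np.asarray(grid.extent)):
        raise ValueError("point outside FFD extent")
    out = pts + ffd_displacement(grid, pts)
    return out[0] if np.asarray(point).ndim == 1 else out


@dataclass(frozen=True)
class FFDTransform:
    """Callable wrapper: p -> p + FFD displacement(p)."""

    grid: FFDGrid

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts + ffd_displacement(self.grid, pts)

    def to_json(self) -> dict:
        return self.grid.to_json()


@dataclass(frozen=True)
class ComposedTransform:
    """Global affine plus local B-spline displacement: T(p) = A(p) + D(p).

    The local displacement is evaluated at the original point, the standard
    global+local decomposition for FFD refinement of a coarse affine fit.
    """

    affine: AffineTransform
    grid: FFDGrid

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self.affine(pts) + ffd_displacement(self.grid, pts)

    def to_json(self) -> dict:
        return {
            "kind": "affine+ffd",
            "affine": self.affine.to_json(),
            "ffd": self.grid.to_json(),
        }


# ---------------------------------------------------------------------------
# Warping
# ---------------------------------------------------------------------------


def export_displacement_field(transform, shape, path) -> np.ndarray:
    """Write the dense displacement field T(p) - p as a NIfTI vector volume.

    The field has one vector component per trailing axis (shape ``shape +
    (ndim,)``, voxel units); it is also returned.
    """
    import nibabel as nib

    shape = tuple(int(s) for s in shape)
    coords = np.indices(shape).reshape(len(shape), -1).T.astype(float)
    disp = (np.asarray(transform(coords)) - coords).reshape(shape + (len(shape),))
    nib.save(nib.Nifti1Image(disp, np.eye(4)), str(path))
    return disp


def warp_image(img: Image, transform, interpolation: str = "linear") -> Image:
    """Backward-warp: output voxel x gets ``img`` sampled at transform(x).

    Out-of-bounds samples become 0.  ``interpolation`` is nearest, linear or
    cubic (spline) intensity interpolation.
    """
    order = _ORDER[interpolation]
    coords = np.indices(img.shape).reshape(img.ndim, -1).T.astype(float)
    mapped = np.asarray(transform(coords), dtype=float)
    out = ndimage.map_coordinates(
        img.data, mapped.T, order=order, mode="constant", cval=0.0
    )
    return img.with_data(out.reshape(img.shape))


def resample_to_reference(
    flt: Image, transform, shape=None, interpolation: str = "linear", n_iter: int = 10
) -> Image:
    """Resample the floating image into the reference frame.

    ``transform`` maps floating points to reference points; resampling needs
    the inverse map, obtained analytically for affines and by fixed-point
    iteration on the displacement field otherwise (adequate for the small,
    smooth deformations the FFD stage estimates; display/fusion use only).
    """
    shape = tuple(shape) if shape is not None else flt.shape
    if isinstance(transform, AffineTransform):
        inv = transform.inverse()
        coords = np.indices(shape).reshape(len(shape), -1).T.astype(float)
        mapped = inv(coords)
    else:
        coords = np.indices(shape).reshape(len(shape), -1).T.astype(float)
        # solve T(p) = x for p: p <- x - (T(p) - p)
        p = coords.copy()
        for _ in range(n_iter):
            p = coords - (np.asarray(transform(p)) - p)
    if not isinstance(transform, AffineTransform):
        mapped = p
    out = ndimage.map_coordinates(
        flt.data, mapped.T, order=_ORDER[interpolation], mode="constant", cval=0.0
    )
    return Image(data=out.reshape(shape), spacing=flt.spacing, levels=flt.levels)
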