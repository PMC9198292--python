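"""Interpolation kernels for joint-histogram accumulation.

Partial-volume (PV) histogram updates distribute each sample's unit mass over
the integer neighbors of its transformed position.  The classical scheme uses
the linear (triangle) kernel; the improved scheme replaces it with a cubic
kernel that is nonnegative and forms a partition of unity, which removes the
kinks the linear kernel imprints on the similarity surface.

A kernel is valid for histogram accumulation iff

    (1)  f(x) >= 0 everywhere, and
    (2)  sum_m f(m - eta) = 1  for every fractional offset eta in [0, 1),

condition (2) guaranteeing that each sample contributes total mass exactly 1.
Both conditions are enforced numerically at :class:`KernelSpec` construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidKernelError

__all__ = [
    "KernelSpec",
    "NeighborhoodWeights",
    "linear_kernel",
    "cubic_kernel",
    "pv_weights",
    "LINEAR",
    "CUBIC_HERMITE",
    "CUBIC_BSPLINE",
]

#: Coefficients (a, b, c, d) of the default cubic piece a|x|^3 + b|x|^2 + c|x| + d.
#: (2, -3, 0, 1) is the cubic Hermite smoothstep: the even degree-3 kernel on
#: |x| < 1 with f(0) = 1 satisfying both validity conditions.
HERMITE_COEFFS = (2.0, -3.0, 0.0, 1.0)

# eta grid used for the numerical partition-of-unity check.
_POU_GRID = np.linspace(0.0, 1.0, 101, endpoint=False)
_POU_TOL = 1e-12


def linear_kernel(x):
    """Classical PV (triangle) kernel: 1 - |x| for |x| < 1, else 0."""
    x = np.asarray(x, dtype=float)
    ax = np.abs(x)
    return np.where(ax < 1.0, 1.0 - ax, 0.0)


def _bspline3(x):
    """Cubic B-spline kernel, support |x| < 2, C^2, not interpolating."""
    ax = np.abs(np.asarray(x, dtype=float))
    inner = 2.0 / 3.0 - ax**2 + 0.5 * ax**3
    outer = (2.0 - ax) ** 3 / 6.0
    return np.where(ax < 1.0, inner, np.where(ax < 2.0, outer, 0.0))


@dataclass(frozen=True)
class KernelSpec:
    """A validated histogram-interpolation kernel.

    Parameters
    ----------
    kind
        ``"linear"``, ``"cubic_hermite"`` (any a|x|^3+b|x|^2+c|x|+d piece on
        |x|<1 via ``coefficients``) or ``"cubic_bspline"`` (support 2).
    coefficients
        (a, b, c, d) of the cubic piece; only used for ``cubic_hermite``.
    """

    kind: str = "cubic_hermite"
    coefficients: tuple = HERMITE_COEFFS
    support: int = field(default=1)

    def __post_init__(self):
        if self.kind not in ("linear", "cubic_hermite", "cubic_bspline"):
            raise InvalidKernelError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "cubic_bspline":
            object.__setattr__(self, "support", 2)
        else:
            object.__setattr__(self, "support", 1)
        self._validate()

    # -- evaluation ---------------------------------------------------------

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "linear":
            return linear_kernel(x)
        if self.kind == "cubic_bspline":
            return _bspline3(x)
        a, b, c, d = self.coefficients
        ax = np.abs(x)
        val = a * ax**3 + b * ax**2 + c * ax + d
        # cancellation near |x| = 1 can produce ~-1e-19; the valid kernel is
        # nonnegative, so clamp instead of poisoning histogram cells
        val = np.maximum(val, 0.0)
        return np.where(ax < 1.0, val, 0.0)

    @property
    def offsets(self) -> tuple:
        """Integer neighbor offsets with (possibly) nonzero weight for eta in [0,1)."""
        s = self.support
        return tuple(range(1 - s, s + 1))

    def offset_weights(self, frac: np.ndarray) -> np.ndarray:
        """Per-axis neighbor weights for fractional offsets ``frac`` in [0, 1).

        Returns an array of shape ``frac.shape + (len(offsets),)`` where column
        ``j`` holds ``kernel(offsets[j] - frac)``.  For the linear kind the
        closed forms (1 - d, d) are used, matching the textbook PV weight
        products bit-for-bit.
        """
        frac = np.asarray(frac, dtype=float)
        if self.kind == "linear":
            return np.stack([1.0 - frac, frac], axis=-1)
        cols = [self(m - frac) for m in self.offsets]
        return np.stack(cols, axis=-1)

    # -- validation ---------------------------------------------------------

    def _validate(self):
        xs = np.linspace(-self.support, self.support, 801)
        vals = self(xs)
        if np.any(vals < -_POU_TOL):
            raise InvalidKernelError(
                f"kernel {self.kind} with coefficients {self.coefficients} is negative"
            )
        sums = self.offset_weights(_POU_GRID).sum(axis=-1)
        err = np.max(np.abs(sums - 1.0))
        if err > _POU_TOL:
            raise InvalidKernelError(
                f"kernel {self.kind} with coefficients {self.coefficients} violates "
                f"partition of unity (max deviation {err:.3e})"
            )


LINEAR = KernelSpec(kind="linear")
CUBIC_HERMITE = KernelSpec(kind="cubic_hermite")
CUBIC_BSPLINE = KernelSpec(kind="cubic_bspline")


def cubic_kernel(x, spec: KernelSpec = CUBIC_HERMITE):
    """Evaluate a cubic kernel spec at ``x`` (even extension, 0 outside support)."""
    return spec(x)


@dataclass(frozen=True)
class NeighborhoodWeights:
    """PV weights of the integer neighbors of a sub-voxel position.

    ``offsets[i]`` is the lattice offset (each component in {0, 1}) of neighbor
    i relative to the floor of the position, ``weights[i]`` its mass share.
    2-D neighbors follow the conventional corner order (0,0), (1,0), (1,1),
    (0,1) so that ``weights`` is (w1, w2, w3, w4) = ((1-dx)(1-dy), dx(1-dy),
    dx dy, (1-dx)dy).
    """

    offsets: tuple
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("PV weights must be nonnegative")


_CORNER_ORDER_2D = ((0, 0), (1, 0), (1, 1), (0, 1))


def pv_weights(d_x: float, d_y: float, d_z: float | None = None) -> NeighborhoodWeights:
    """Bilinear / trilinear partial-volume weights for fractional offsets in [0, 1).

    2-D: (w1, w2, w3, w4) over the corner order (0,0), (1,0), (1,1), (0,1);
    3-D: 8 trilinear products over ``itertools.product((0, 1), repeat=3)``
    (axis order x, y, z).  The weights always sum to exactly 1.
    """
    fracs = (d_x, d_y) if d_z is None else (d_x, d_y, d_z)
    for d in fracs:
        if not (0.0 <= d < 1.0):
            raise ValueError(f"fractional offset {d} outside [0, 1)")
    if d_z is None:
        w = np.array(
            [
                (1.0 - d_x) * (1.0 - d_y),
                d_x * (1.0 - d_y),
                d_x * d_y,
                (1.0 - d_x) * d_y,
            ]
        )
        return NeighborhoodWeights(offsets=_CORNER_ORDER_2D, weights=w)
    offsets = tuple(itertools.product((0, 1), repeat=3))
    axis_w = [(1.0 - d, d) for d in fracs]
    w = np.array(
        [axis_w[0][o[0]] * axis_w[1][o[1]] * axis_w[2][o[2]] for o in offsets]
    )
    return NeighborhoodWeights(offsets=offsets, weights=w)
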