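"""Synthetic multimodal phantoms with known ground-truth transforms.

Real multimodal pairs (e.g. CT/MRI/PET of one brain) share anatomy but map
tissue classes to unrelated — often non-monotone — intensity ranges, which
is exactly why information-theoretic similarity is needed.  The generator
emulates that situation: a piecewise-constant nested-ellipse anatomy, a
per-class intensity remap (optionally a non-monotone permutation), an
analytic ground-truth warp drawn from the registrar's own model family
(affine matrices or a B-spline FFD with bounded control offsets), and
additive clipped Gaussian noise.

Ground-truth transforms map floating-frame points into the reference frame
(the same direction the registrar fits), and the floating image is produced
by backward warping, so parameter recovery is exact in the noiseless limit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import MappingError, OutOfFrameError, SizeError
from .imagio import Image, read_image, write_image
from .transforms import (
    AffineTransform,
    ComposedTransform,
    FFDTransform,
    make_ffd_grid,
    warp_image,
)

__all__ = [
    "RegistrationCase",
    "make_shape_phantom",
    "simulate_modality",
    "random_class_remap",
    "make_registration_case",
    "save_case",
    "load_case",
]


@dataclass(frozen=True)
class RegistrationCase:
    """A reference/floating phantom pair with exact ground truth.

    ``true_transform`` maps floating-frame points to the reference frame;
    ``modality_remap`` is the per-class intensity lookup applied before
    warping; ``noise_sigma`` is the additive Gaussian noise level in gray
    units.  The same seed reproduces the case bit-identically.
    """

    reference: Image
    floating: Image
    true_transform: object
    transform_kind: str
    modality_remap: dict
    noise_sigma: float
    seed: int


def make_shape_phantom(shape, n_structures: int = 3, seed: int = 0) -> Image:
    """Nested-ellipse anatomy with ``n_structures`` gray classes on [0, 255].

    Background is 0; every structure keeps a visible ring, so the image has
    exactly ``n_structures + 1`` distinct gray values.  Deterministic per seed.
    """
    shape = tuple(int(s) for s in np.atleast_1d(shape))
    if len(shape) not in (2, 3):
        raise SizeError("phantom must be 2-D or 3-D")
    if any(s < 16 for s in shape):
        raise SizeError(f"each dimension must be >= 16, got {shape}")
    if n_structures < 1:
        raise ValueError("n_structures must be >= 1")
    rng = np.random.default_rng(seed)
    ndim = len(shape)
    size = np.asarray(shape, dtype=float)

    # distinct class intensities, brightest innermost
    values = np.round(np.linspace(80, 255, n_structures))
    if len(np.unique(values)) != n_structures:
        raise ValueError(f"too many structures ({n_structures}) for 256 gray levels")

    coords = np.indices(shape).astype(float)

    def paint(data, center, radii, theta, value):
        # rotated (2-D) or axis-aligned (3-D) ellipse/ellipsoid
        rel = [coords[a] - center[a] for a in range(ndim)]
        if ndim == 2 and theta is not None:
            ct, st = np.cos(theta), np.sin(theta)
            rel = [ct * rel[0] + st * rel[1], -st * rel[0] + ct * rel[1]]
        dist = sum((rel[a] / radii[a]) ** 2 for a in range(ndim))
        data[dist <= 1.0] = value

    data = np.zeros(shape)
    # outer structure: clearly eccentric, randomly oriented, off-center —
    # anatomy must not be rotationally symmetric or similarity measures
    # cannot observe rotations and shears
    center0 = size / 2 + rng.uniform(-size / 20, size / 20)
    r_major = size.min() * rng.uniform(0.34, 0.40)
    ratios = np.ones(ndim)
    ratios[1:] = rng.uniform(0.55, 0.75, size=ndim - 1)
    radii0 = r_major * rng.permutation(ratios)
    theta0 = rng.uniform(0, np.pi) if ndim == 2 else None
    paint(data, center0, radii0, theta0, values[0])

    # interior structures: large, eccentric and strongly off-center so that
    # a substantial intensity mass constrains every transform parameter
    for k in range(1, n_structures):
        shrink = 0.6 ** (k - 1)
        r_k = np.maximum(2.0, radii0.min() * 0.65 * shrink)
        r_vec = r_k * rng.uniform(0.5, 1.0, size=ndim)
        margin = radii0.min() - r_vec.max() - 1.0
        c_k = center0 + rng.uniform(0.35, 0.9, size=ndim) * rng.choice(
            [-1.0, 1.0], size=ndim
        ) * max(margin, 0.0)
        theta_k = rng.uniform(0, np.pi) if ndim == 2 else None
        paint(data, c_k, r_vec, theta_k, values[k])
    img = Image(data=data)
    n_found = len(np.unique(data))
    if n_found != n_structures + 1:
        raise ValueError(
            f"phantom degenerate: {n_found - 1} visible classes of {n_structures} "
            f"requested on shape {shape}"
        )
    return img


def random_class_remap(img: Image, seed: int = 0, non_monotone: bool = True) -> dict:
    """A per-class intensity permutation (background 0 fixed).

    Permuting the nonzero class values among themselves yields a bijective,
    typically non-monotone gray mapping — the hard multimodal relationship
    intensity-difference measures cannot handle but mutual information can.
    """
    rng = np.random.default_rng(seed)
    classes = np.unique(img.data)
    nonzero = [v for v in classes if v != 0]
    perm = np.array(nonzero, dtype=float)
    if len(nonzero) > 1 and non_monotone:
        for _ in range(100):
            perm = rng.permutation(nonzero)
            if np.any(np.diff(perm[np.argsort(nonzero)]) < 0):
                break
    remap = {float(v): float(p) for v, p in zip(nonzero, perm)}
    remap[0.0] = 0.0
    return remap


def simulate_modality(
    img: Image, remap: dict, noise_sigma: float = 0.0, seed: int = 0
) -> Image:
    """Apply a per-class intensity remap plus clipped additive Gaussian noise."""
    present = np.unique(img.data)
    missing = [v for v in present if float(v) not in remap]
    if missing:
        raise MappingError(f"remap missing gray classes {missing}")
    out = np.zeros_like(img.data)
    for v in present:
        out[img.data == v] = remap[float(v)]
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sigma, size=out.shape)
        out = np.clip(out, 0.0, img.levels - 1)
    return img.with_data(out)


def _true_transform(kind, magnitude, shape, spacing, rng):
    ndim = len(shape)
    center = (np.asarray(shape, dtype=float) - 1) / 2
    if kind == "translation":
        t = np.broadcast_to(np.asarray(magnitude, dtype=float), (ndim,))
        return AffineTransform.from_translation(t)
    if kind == "rigid":
        if ndim != 2:
            raise NotImplementedError("rigid phantom warps are 2-D")
        return AffineTransform.rotation_2d(float(magnitude), center=center)
    if kind == "affine":
        if ndim != 2:
            raise NotImplementedError("affine phantom warps are 2-D")
        rot = AffineTransform.rotation_2d(
            rng.uniform(-magnitude, magnitude), center=center
        )
        s = 1.0 + rng.uniform(-0.05, 0.05, size=2)
        m = np.eye(3)
        m[:2, :2] = np.diag(s)
        m[:2, 2] = center - np.diag(s) @ center
        scale = AffineTransform(m)
        trans = AffineTransform.from_translation(rng.uniform(-2, 2, size=2))
        return trans.compose(rot.compose(scale))
    if kind == "ffd":
        grid = make_ffd_grid(shape, spacing)
        offsets = rng.uniform(-magnitude, magnitude, size=grid.control.shape)
        return FFDTransform(grid.with_control(offsets))
    if kind == "rigid+ffd":
        # magnitude = (rotation degrees, max control offset in voxels)
        deg, ffd_mag = magnitude
        rigid = _true_transform("rigid", deg, shape, spacing, rng)
        grid = make_ffd_grid(shape, spacing)
        offsets = rng.uniform(-ffd_mag, ffd_mag, size=grid.control.shape)
        return ComposedTransform(rigid, grid.with_control(offsets))
    raise ValueError(f"unknown transform kind {kind!r}")


def make_registration_case(
    shape=(64, 64),
    transform_kind: str = "translation",
    magnitude=2.0,
    noise_sigma: float = 2.0,
    seed: int = 0,
    n_structures: int = 4,
    ffd_spacing: float = 16.0,
) -> RegistrationCase:
    """Build a multimodal phantom pair with a recorded ground-truth warp.

    ``magnitude`` is in voxels (translation: scalar or per-axis vector; ffd:
    maximum control-point offset) or degrees (rigid/affine rotation).  The
    warp must leave all floating-frame content at least 2 voxels inside the
    border, else :class:`OutOfFrameError` is raised.
    """
    rng = np.random.default_rng(seed)
    ref = make_shape_phantom(shape, n_structures=n_structures, seed=seed)
    remap = random_class_remap(ref, seed=seed + 1)
    moving = simulate_modality(ref, remap, noise_sigma=0.0)
    transform = _true_transform(
        transform_kind, magnitude, ref.shape, ffd_spacing, rng
    )
    clean = warp_image(moving, transform, interpolation="linear")
    fg = np.argwhere(clean.data > 0.5)
    if fg.size:
        lo = fg.min(axis=0)
        hi = np.asarray(ref.shape) - 1 - fg.max(axis=0)
        if np.any(lo < 2) or np.any(hi < 2):
            raise OutOfFrameError(
                f"{transform_kind} warp of magnitude {magnitude} pushes content "
                "within 2 voxels of the frame border"
            )
    floating = clean
    if noise_sigma > 0:
        noise_rng = np.random.default_rng(seed + 2)
        noisy = np.clip(
            clean.data + noise_rng.normal(0.0, noise_sigma, size=clean.shape),
            0.0,
            ref.levels - 1,
        )
        floating = clean.with_data(noisy)
    return RegistrationCase(
        reference=ref,
        floating=floating,
        true_transform=transform,
        transform_kind=transform_kind,
        modality_remap=remap,
        noise_sigma=float(noise_sigma),
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_case(case: RegistrationCase, directory, fmt: str = "nii.gz") -> None:
    """Write reference/floating images plus case.json with the ground truth."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_image(case.reference, directory / f"reference.{fmt}")
    write_image(case.floating, directory / f"floating.{fmt}")
    meta = {
        "transform_kind": case.transform_kind,
        "true_transform": case.true_transform.to_json(),
        "modality_remap": {str(k): v for k, v in case.modality_remap.items()},
        "noise_sigma": case.noise_sigma,
        "seed": case.seed,
        "format": fmt,
    }
    (directory / "case.json").write_text(json.dumps(meta, indent=2))


def load_case(directory) -> RegistrationCase:
    directory = Path(directory)
    meta = json.loads((directory / "case.json").read_text())
    fmt = meta["format"]
    tt = meta["true_transform"]
    if tt["kind"] == "affine":
        transform = AffineTransform(np.asarray(tt["matrix"]))
    elif tt["kind"] == "affine+ffd":
        grid = make_ffd_grid(tuple(tt["ffd"]["extent"]), tuple(tt["ffd"]["spacing"]))
        transform = ComposedTransform(
            AffineTransform(np.asarray(tt["affine"]["matrix"])),
            grid.with_control(np.asarray(tt["ffd"]["control"])),
        )
    else:
        grid = make_ffd_grid(tuple(tt["extent"]), tuple(tt["spacing"]))
        transform = FFDTransform(grid.with_control(np.asarray(tt["control"])))
    return RegistrationCase(
        reference=read_image(directory / f"reference.{fmt}"),
        floating=read_image(directory / f"floating.{fmt}"),
        true_transform=transform,
        transform_kind=meta["transform_kind"],
        modality_remap={float(k): v for k, v in meta["modality_remap"].items()},
        noise_sigma=meta["noise_sigma"],
        seed=meta["seed"],
    )
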