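"""End-to-end two-stage registration: preprocess, affine coarse stage,
B-spline FFD fine stage, similarity reporting and false-color fusion.

Both stages maximize normalized mutual information (minimize -NMI) of the
joint histogram accumulated by PV or NPV interpolation over a regular sample
grid, using the DFP quasi-Newton optimizer with central finite-difference
gradients.  The coarse stage is initialized by aligning the two intensity
centroids; no multi-resolution pyramid is used, so the capture range is set
by that initialization plus the coarse sample stride.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from . import __version__ as _version
from .dfp import DFPConfig, dfp_minimize
from .errors import DegenerateInputError
from .histograms import new_histogram, npv_accumulate
from .imagio import Image, intensity_centroid, normalize_gray, sample_grid, strip_background
from .kernels import CUBIC_BSPLINE, CUBIC_HERMITE, LINEAR, KernelSpec
from .phantoms import RegistrationCase
from .similarity import SimilarityReport, nmi, similarity_report
from .transforms import (
    AffineTransform,
    ComposedTransform,
    FFDGrid,
    ffd_weight_matrix,
    make_ffd_grid,
)

__all__ = [
    "RegistrationConfig",
    "RegistrationResult",
    "register",
    "register_affine",
    "register_ffd",
    "fuse_falsecolor",
    "evaluate_case",
    "translation_sweep",
]

_KERNELS = {
    "linear": LINEAR,
    "cubic_hermite": CUBIC_HERMITE,
    "cubic_bspline": CUBIC_BSPLINE,
}


@dataclass(frozen=True)
class RegistrationConfig:
    """Knobs of the two-stage pipeline.

    interpolation: "pv" (linear kernel) or "npv" (cubic kernel); kernel names
    the NPV kernel; fd steps are the finite-difference scales for translation
    (voxels), linear-block entries and control-point displacements (voxels).
    """

    interpolation: str = "npv"
    kernel: str = "cubic_hermite"
    bins: int = 64
    #: coarse-stage histogram bins: the capture pass runs on a smoother,
    #: lower-resolution joint histogram, the refinement passes on ``bins``
    affine_bins: int = 16
    levels: int = 256
    affine_model: str = "affine"  # translation | rigid | affine
    affine_stride: int = 2
    ffd_stride: int = 1
    ffd_spacing: float = 16.0
    strip_background: bool = False
    strip_threshold: float | None = None
    affine_dfp: DFPConfig = field(
        default_factory=lambda: DFPConfig(eps=1e-4, max_iter=100, h0_auto_scale=1.0)
    )
    ffd_dfp: DFPConfig = field(
        default_factory=lambda: DFPConfig(eps=1e-4, max_iter=30, h0_auto_scale=1.0)
    )
    fd_step_translation: float = 0.5
    fd_step_linear: float = 0.01
    fd_step_rotation: float = 0.02  # radians; ~0.5 voxel at mid-radius of 64^2
    fd_step_control: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.interpolation not in ("pv", "npv"):
            raise ValueError("interpolation must be 'pv' or 'npv'")
        if not (8 <= self.bins <= 256):
            raise ValueError("bins must lie in [8, 256]")
        if self.affine_stride < 1 or self.ffd_stride < 1:
            raise ValueError("sample strides must be >= 1")
        if self.kernel not in _KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}")

    @property
    def kernel_spec(self) -> KernelSpec:
        return LINEAR if self.interpolation == "pv" else _KERNELS[self.kernel]


@dataclass
class RegistrationResult:
    """Estimated transforms, stage-wise similarity reports and provenance."""

    affine: AffineTransform
    ffd_grid: FFDGrid | None
    reports: dict  # stage name -> SimilarityReport
    converged: dict
    traces: dict
    config: RegistrationConfig
    seed: int

    @property
    def transform(self):
        if self.ffd_grid is None:
            return self.affine
        return ComposedTransform(self.affine, self.ffd_grid)

    def to_json(self) -> str:
        payload = {
            "affine": self.affine.to_json(),
            "ffd": None if self.ffd_grid is None else self.ffd_grid.to_json(),
            "reports": {k: json.loads(v.to_json()) for k, v in self.reports.items()},
            "converged": self.converged,
            "seed": self.seed,
            "npvreg_version": _version,
            "config": {
                "interpolation": self.config.interpolation,
                "kernel": self.config.kernel,
                "bins": self.config.bins,
                "levels": self.config.levels,
                "affine_model": self.config.affine_model,
                "affine_stride": self.config.affine_stride,
                "ffd_stride": self.config.ffd_stride,
                "ffd_spacing": self.config.ffd_spacing,
            },
        }
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# Objective machinery
# ---------------------------------------------------------------------------


def _measure(ref, flt, transform, samples, spec, bins) -> SimilarityReport:
    hist = npv_accumulate(new_histogram(bins), ref, flt, transform, samples, spec)
    return similarity_report(hist)


def _objective(ref, flt, samples, spec, bins, transform_factory):
    """-NMI of the accumulated histogram; +inf when more than half the
    samples fall out of bounds (prevents trivially high NMI on a shrinking
    overlap)."""
    n_total = len(samples)

    def obj(params):
        t = transform_factory(params)
        hist = npv_accumulate(new_histogram(bins), ref, flt, t, samples, spec)
        if hist.n_samples < 0.5 * n_total or hist.total_mass <= 0:
            return np.inf
        return -nmi(hist)

    return obj


def _check_not_constant(img: Image, name: str) -> None:
    if img.data.max() == img.data.min():
        raise DegenerateInputError(f"{name} image is constant")


def _affine_factory(model: str, ndim: int, center: np.ndarray):
    """Map a stage parameter vector to an AffineTransform.

    Linear blocks act about the image center, decoupling rotation/scale from
    translation for better finite-difference conditioning.
    """
    if model == "translation":
        def factory(p):
            return AffineTransform.from_translation(p)
        n_params = ndim
        x0 = np.zeros(ndim)
    elif model == "rigid":
        if ndim != 2:
            raise NotImplementedError("rigid model is 2-D")
        def factory(p):
            rot = AffineTransform.rotation_2d(np.rad2deg(p[0]), center=center)
            return AffineTransform.from_translation(p[1:]).compose(rot)
        n_params = 3
        x0 = np.zeros(3)
    elif model == "affine":
        def factory(p):
            m = np.eye(ndim + 1)
            M = p[: ndim * ndim].reshape(ndim, ndim)
            m[:ndim, :ndim] = M
            m[:ndim, ndim] = center - M @ center + p[ndim * ndim :]
            return AffineTransform(m)
        n_params = ndim * ndim + ndim
        x0 = np.concatenate([np.eye(ndim).ravel(), np.zeros(ndim)])
    else:
        raise ValueError(f"unknown affine model {model!r}")
    return factory, n_params, x0


def _fd_steps_affine(model: str, ndim: int, config: RegistrationConfig) -> np.ndarray:
    if model == "translation":
        return np.full(ndim, config.fd_step_translation)
    if model == "rigid":
        return np.array([config.fd_step_rotation] + [config.fd_step_translation] * ndim)
    return np.concatenate(
        [
            np.full(ndim * ndim, config.fd_step_linear),
            np.full(ndim, config.fd_step_translation),
        ]
    )


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def register_affine(ref: Image, flt: Image, config: RegistrationConfig):
    """Coarse stage: centroid-initialized affine fit by DFP on -NMI.

    Runs up to two passes: a capture pass on a coarse (``affine_bins``)
    histogram with a low-dimensional model (rigid in 2-D), then a refinement
    pass with the requested ``affine_model`` on the full ``bins`` histogram.
    Optimization runs in scaled parameters — one unit is one natural
    finite-difference step per parameter type — so the (auto-scaled)
    identity H_0 is well conditioned.

    Returns (AffineTransform, info dict with reports/trace/converged).
    """
    _check_not_constant(ref, "reference")
    _check_not_constant(flt, "floating")
    ndim = ref.ndim
    center = (np.asarray(flt.shape, dtype=float) - 1) / 2
    t0 = np.asarray(intensity_centroid(ref)) - np.asarray(intensity_centroid(flt))
    samples = sample_grid(flt, config.affine_stride)
    spec = config.kernel_spec

    capture_model = "rigid" if (ndim == 2 and config.affine_model == "affine") else None
    stages = []
    if capture_model is not None:
        stages.append((capture_model, config.affine_bins))
    elif config.affine_bins < config.bins:
        stages.append((config.affine_model, config.affine_bins))
    stages.append((config.affine_model, config.bins))

    est = AffineTransform.from_translation(t0)  # centroid pre-alignment
    before = _measure(ref, flt, est, samples, spec, config.bins)
    traces = []
    converged = False
    for model, bins in stages:
        base_factory, n_params, x0 = _affine_factory(model, ndim, center)
        scales = _fd_steps_affine(model, ndim, config)
        prev = est

        def factory(z, _base=base_factory, _s=scales, _x0=x0, _prev=prev):
            p = _x0 + _s * np.asarray(z, dtype=float)
            return _base(p).compose(_prev)

        obj = _objective(ref, flt, samples, spec, bins, factory)
        dfp_cfg = replace(config.affine_dfp, fd_step=1.0)
        result = dfp_minimize(obj, None, np.zeros(n_params), dfp_cfg)
        est = factory(result.x)
        traces.extend(result.trace)
        converged = result.converged
    after = _measure(ref, flt, est, samples, spec, config.bins)
    info = {
        "reports": {"affine_before": before, "affine_after": after},
        "trace": traces,
        "converged": converged,
    }
    return est, info


def register_ffd(ref: Image, flt: Image, init_affine: AffineTransform | None, config: RegistrationConfig):
    """Fine stage: B-spline control-point displacements by DFP on -NMI of the
    composed (affine + local displacement) transform.

    Returns (FFDGrid, info dict).
    """
    _check_not_constant(ref, "reference")
    _check_not_constant(flt, "floating")
    if init_affine is None:
        init_affine = AffineTransform.identity(ref.ndim)
    grid0 = make_ffd_grid(flt.shape, config.ffd_spacing)
    samples = sample_grid(flt, config.ffd_stride)
    spec = config.kernel_spec

    scale = config.fd_step_control

    def factory(z):
        return ComposedTransform(init_affine, grid0.with_control(scale * np.asarray(z)))

    # the B-spline tensor weights depend only on the fixed sample points;
    # precompute them so each objective evaluation is one small matmul
    pts = samples.points.astype(float)
    a_pts = init_affine(pts)
    w_mat = ffd_weight_matrix(grid0, pts)
    ndim = ref.ndim
    n_total = len(samples)

    class _Mapped:
        __slots__ = ("q",)

        def __init__(self, q):
            self.q = q

        def __call__(self, _pts):
            return self.q

    def obj(z):
        control = (scale * np.asarray(z, dtype=float)).reshape(-1, ndim)
        q = a_pts + w_mat @ control
        hist = npv_accumulate(
            new_histogram(config.bins), ref, flt, _Mapped(q), samples, spec
        )
        if hist.n_samples < 0.5 * n_total or hist.total_mass <= 0:
            return np.inf
        return -nmi(hist)

    z0 = grid0.control.ravel() / scale
    dfp_cfg = replace(config.ffd_dfp, fd_step=1.0)
    before = _measure(ref, flt, factory(z0), samples, spec, config.bins)
    result = dfp_minimize(obj, None, z0, dfp_cfg)
    grid = grid0.with_control(scale * result.x)
    after = _measure(ref, flt, factory(result.x), samples, spec, config.bins)
    info = {
        "reports": {"ffd_before": before, "ffd_after": after},
        "trace": result.trace,
        "converged": result.converged,
    }
    return grid, info


def preprocess(img: Image, config: RegistrationConfig) -> Image:
    """Gray normalization to config.levels, optional background stripping."""
    out = normalize_gray(img, levels=config.levels)
    if config.strip_background:
        thr = config.strip_threshold
        if thr is None:
            nz = out.data[out.data > 0]
            thr = float(np.percentile(nz, 1)) if nz.size else 0.0
        out = strip_background(out, thr, keep_largest=True)
    return out


def register(ref: Image, flt: Image, config: RegistrationConfig = RegistrationConfig()) -> RegistrationResult:
    """Full pipeline: preprocess -> affine coarse -> FFD fine -> final report."""
    ref_p = preprocess(ref, config)
    flt_p = preprocess(flt, config)
    spec = config.kernel_spec

    samples_fine = sample_grid(flt_p, config.ffd_stride)
    initial = _measure(
        ref_p, flt_p, AffineTransform.identity(ref_p.ndim), samples_fine, spec, config.bins
    )

    affine, a_info = register_affine(ref_p, flt_p, config)
    grid, f_info = register_ffd(ref_p, flt_p, affine, config)

    reports = {"initial": initial}
    reports.update(a_info["reports"])
    reports.update(f_info["reports"])
    reports["final"] = _measure(
        ref_p, flt_p, ComposedTransform(affine, grid), samples_fine, spec, config.bins
    )
    return RegistrationResult(
        affine=affine,
        ffd_grid=grid,
        reports=reports,
        converged={"affine": a_info["converged"], "ffd": f_info["converged"]},
        traces={"affine": a_info["trace"], "ffd": f_info["trace"]},
        config=config,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# Fusion and evaluation
# ---------------------------------------------------------------------------


def fuse_falsecolor(ref: Image, warped_flt: Image) -> np.ndarray:
    """Green/magenta overlay: reference in green, warped floating in red+blue.

    Aligned identical structures appear gray; misaligned structure shows as
    pure green or magenta fringes.  Returns a uint8 array of shape
    ``ref.shape + (3,)``.
    """
    if ref.shape != warped_flt.shape:
        raise ValueError(f"shape mismatch {ref.shape} vs {warped_flt.shape}")

    def scaled(img):
        lo, hi = img.data.min(), img.data.max()
        if hi == lo:
            return np.zeros(img.shape)
        return (img.data - lo) / (hi - lo)

    g = scaled(ref)
    m = scaled(warped_flt)
    rgb = np.stack([m, g, m], axis=-1)
    return np.round(rgb * 255).astype(np.uint8)


def evaluate_case(result: RegistrationResult, case: RegistrationCase) -> dict:
    """Parameter- and field-level errors of a result against phantom truth."""
    if case.true_transform is None:
        raise ValueError("case carries no ground truth")
    ref = case.reference
    est = result.transform
    true = case.true_transform
    coords = np.indices(ref.shape).reshape(ref.ndim, -1).T.astype(float)
    fg = ref.data.ravel() > 0
    diff = np.asarray(est(coords)) - np.asarray(true(coords))
    err = np.linalg.norm(diff, axis=1)
    metrics = {
        "mean_field_error": float(err[fg].mean()),
        "max_field_error": float(err[fg].max()),
        "nmi_initial": result.reports["initial"].NMI if "initial" in result.reports else None,
        "nmi_final": result.reports["final"].NMI if "final" in result.reports else None,
    }
    if isinstance(true, AffineTransform) and isinstance(
        result.affine, AffineTransform
    ):
        center = (np.asarray(ref.shape, dtype=float) - 1) / 2
        t_est = np.asarray(result.affine(center[None])[0]) - center
        t_true = np.asarray(true(center[None])[0]) - center
        metrics["translation_error"] = float(np.linalg.norm(t_est - t_true))
        if ref.ndim == 2:
            def angle(M):
                return np.degrees(np.arctan2(M[1, 0] - M[0, 1], M[0, 0] + M[1, 1]))
            metrics["rotation_error_deg"] = float(
                abs(angle(result.affine.linear) - angle(true.linear))
            )
    return metrics


def translation_sweep(
    ref: Image,
    flt: Image,
    offsets,
    spec: KernelSpec,
    bins: int = 64,
    stride: int = 1,
    axis: int = 0,
):
    """NMI as a function of a pure translation along ``axis``.

    Probes the smoothness of the similarity surface: the linear PV kernel
    imprints kinks at integer offsets, the cubic kernel does not.
    """
    samples = sample_grid(flt, stride)
    values = []
    for off in offsets:
        t = np.zeros(ref.ndim)
        t[axis] = off
        transform = AffineTransform.from_translation(t)
        hist = npv_accumulate(new_histogram(bins), ref, flt, transform, samples, spec)
        values.append(nmi(hist))
    return np.asarray(values)
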