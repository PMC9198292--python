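"""Davidon-Fletcher-Powell quasi-Newton minimizer with Armijo backtracking.

The method maintains an inverse-Hessian approximation H_k updated by the
rank-two DFP formula

    H_{k+1} = H_k - (H_k y y^T H_k) / (y^T H_k y) + (s s^T) / (s^T y),

skipped (H unchanged) whenever the curvature condition s^T y > 0 fails, which
keeps H symmetric positive definite.  Step lengths are alpha = delta^m with m
the smallest nonnegative integer satisfying the Armijo sufficient-decrease
inequality f(x + delta^m d) <= f(x) + sigma delta^m g^T d.

Gradients may be supplied analytically or estimated by central finite
differences (the NMI objective has no closed-form gradient).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EvaluationError, LineSearchError

__all__ = [
    "DFPConfig",
    "DFPResult",
    "finite_diff_gradient",
    "armijo_step",
    "dfp_update",
    "dfp_minimize",
]


@dataclass(frozen=True)
class DFPConfig:
    """Optimizer settings.

    delta: backtracking ratio in (0, 1); sigma: Armijo slope factor in
    (0, 0.5); eps: gradient-norm stopping tolerance; fd_step: central-
    difference step, scalar or per-parameter array; h0: initial inverse-
    Hessian approximation (identity if None); max_m: backtracking budget.
    """

    delta: float = 0.5
    sigma: float = 0.1
    eps: float = 1e-5
    max_iter: int = 200
    fd_step: float | np.ndarray = 1e-4
    h0: np.ndarray | None = None
    max_m: int = 30
    #: if set (and h0 is None), H_0 = (h0_auto_scale / ||g_0||) I so the first
    #: step has roughly this length — useful when the objective's gradient
    #: magnitude is far from the parameters' natural scale (e.g. NMI).
    h0_auto_scale: float | None = None

    def __post_init__(self):
        if not (0.0 < self.delta < 1.0):
            raise ValueError("delta must lie in (0, 1)")
        if not (0.0 < self.sigma < 0.5):
            raise ValueError("sigma must lie in (0, 0.5)")
        if self.eps < 0:
            raise ValueError("eps must be >= 0")
        if self.h0 is not None:
            h0 = np.asarray(self.h0, dtype=float)
            if not np.allclose(h0, h0.T):
                raise ValueError("h0 must be symmetric")
            if np.any(np.linalg.eigvalsh(h0) <= 0):
                raise ValueError("h0 must be positive definite")
            object.__setattr__(self, "h0", h0)


@dataclass
class DFPResult:
    x: np.ndarray
    f: float
    converged: bool
    n_iter: int
    trace: list  # rows (k, f, grad_norm, alpha, m)
    message: str = ""

    def trace_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("k,f,grad_norm,alpha,m\n")
            for row in self.trace:
                fh.write(",".join(f"{v:.12g}" for v in row) + "\n")


def finite_diff_gradient(objective, x, step) -> np.ndarray:
    """Central-difference gradient (f(x+h e_i) - f(x-h e_i)) / 2h per coordinate."""
    x = np.asarray(x, dtype=float)
    h = np.broadcast_to(np.asarray(step, dtype=float), x.shape)
    if np.any(h <= 0):
        raise ValueError("finite-difference steps must be positive")
    g = np.empty_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h[i]
        fp, fm = objective(x + e), objective(x - e)
        if not (np.isfinite(fp) and np.isfinite(fm)):
            raise EvaluationError(f"objective non-finite at coordinate {i}")
        g[i] = (fp - fm) / (2.0 * h[i])
    return g


def armijo_step(objective, x, d, g, delta=0.5, sigma=0.1, max_m=30):
    """Smallest m with f(x + delta^m d) <= f(x) + sigma delta^m g.d; returns (m, alpha)."""
    x = np.asarray(x, dtype=float)
    d = np.asarray(d, dtype=float)
    gd = float(np.dot(g, d))
    if gd >= 0:
        raise ValueError(f"d is not a descent direction (g.d = {gd})")
    fx = objective(x)
    for m in range(max_m + 1):
        alpha = delta**m
        if objective(x + alpha * d) <= fx + sigma * alpha * gd:
            return m, alpha
    raise LineSearchError(f"no Armijo step within {max_m} backtracks")


def dfp_update(H: np.ndarray, s: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Rank-two DFP inverse-Hessian update; H unchanged when s^T y <= 0."""
    H = np.asarray(H, dtype=float)
    s = np.asarray(s, dtype=float)
    y = np.asarray(y, dtype=float)
    sy = float(np.dot(s, y))
    if sy <= 0:
        return H.copy()
    Hy = H @ y
    yHy = float(np.dot(y, Hy))
    if yHy == 0:
        raise EvaluationError("degenerate DFP update: y^T H y = 0 with s^T y > 0")
    return H - np.outer(Hy, Hy) / yHy + np.outer(s, s) / sy


def _simple_decrease(objective, x, fx, d, delta, max_m):
    """Largest backtracked step that strictly decreases f, if any."""
    for m in range(max_m + 1):
        alpha = delta**m
        if float(objective(x + alpha * d)) < fx - 1e-12:
            return m, alpha
    return None


def dfp_minimize(objective, gradient, x0, config: DFPConfig = DFPConfig(), callback=None):
    """Minimize ``objective`` from ``x0``; ``gradient=None`` uses central differences.

    Returns a :class:`DFPResult` holding the best iterate seen, a convergence
    flag and the per-iteration trace.  The f-trace is nonincreasing by the
    Armijo descent guarantee; on line-search failure the best-so-far iterate
    is returned flagged not-converged.
    """
    x = np.asarray(x0, dtype=float).copy()
    f = float(objective(x))
    if not np.isfinite(f):
        raise EvaluationError("objective not finite at x0")
    grad = gradient if gradient is not None else (
        lambda z: finite_diff_gradient(objective, z, config.fd_step)
    )
    n = x.size
    g = np.asarray(grad(x), dtype=float)

    def initial_h():
        if config.h0 is not None:
            return config.h0.copy()
        if config.h0_auto_scale is not None:
            gn = float(np.linalg.norm(g))
            if gn > 0:
                return np.eye(n) * (config.h0_auto_scale / gn)
        return np.eye(n)

    H = initial_h()
    best_x, best_f = x.copy(), f
    trace = []
    message = "max_iter reached"
    converged = False
    fresh_restart = False
    k = 0
    while k < config.max_iter:
        gnorm = float(np.linalg.norm(g))
        if gnorm <= config.eps:
            converged = True
            message = "gradient norm below eps"
            trace.append((k, f, gnorm, 0.0, 0))
            break
        d = -H @ g
        if float(np.dot(g, d)) >= 0:
            # H lost positive definiteness numerically; steepest-descent restart
            H = initial_h()
            d = -H @ g
        try:
            m, alpha = armijo_step(
                lambda z: float(objective(z)), x, d, g,
                delta=config.delta, sigma=config.sigma, max_m=config.max_m,
            )
            fresh_restart = False
        except LineSearchError as exc:
            if not fresh_restart:
                # curvature estimate is unreliable (noisy secant gradients);
                # discard it and retry once from a rescaled steepest descent
                H = initial_h()
                fresh_restart = True
                continue
            # sufficient decrease unattainable on this rough patch of the
            # surface; fall back to simple decrease along the current
            # direction before giving up
            step = _simple_decrease(objective, x, f, d, config.delta, config.max_m)
            if step is None:
                message = str(exc)
                trace.append((k, f, gnorm, 0.0, config.max_m))
                break
            m, alpha = step
            fresh_restart = False
        x_new = x + alpha * d
        f_new = float(objective(x_new))
        g_new = np.asarray(grad(x_new), dtype=float)
        s = x_new - x
        y = g_new - g
        H = dfp_update(H, s, y)
        trace.append((k, f, gnorm, alpha, m))
        x, f, g = x_new, f_new, g_new
        if f < best_f:
            best_x, best_f = x.copy(), f
        if callback is not None:
            callback(k=k, x=x, f=f, g=g, H=H)
        k += 1
    else:
        trace.append((k, f, float(np.linalg.norm(g)), 0.0, 0))
    return DFPResult(
        x=best_x, f=best_f, converged=converged, n_iter=k, trace=trace, message=message
    )
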