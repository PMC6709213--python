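"""Constrained curve fits of model-based representations.

Each pixel-space representation is summarised by an exponentiated-cosine
curve with four parameters:

    f(x) = b + a * (0.5 cos(|x - c| pi / s) + 0.5)^7   for |x - c| < s,
    f(x) = b                                           elsewhere,

center c and size s in scene units, amplitude a >= 0 and baseline b in
response units. Fitting is a two-stage procedure: an exhaustive grid search
over (c, s) — solving the box-constrained linear subproblem for (a, b) in
closed form at every grid point — followed by bounded local refinement of
all four parameters, with c and s each confined to one grid step of the
grid optimum. The refined fit is kept only if it lowers the RMSE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .iem import basis_eval, PixelGrid

__all__ = [
    "CurveParams",
    "FitGridSpec",
    "FitResult",
    "curve_eval",
    "grid_fit",
    "fit_representation",
    "center_error",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CurveParams:
    center: float
    size: float
    amplitude: float
    baseline: float

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("size must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass(frozen=True)
class FitGridSpec:
    """Search ranges of the grid stage (scene/response units)."""

    center_lo: float = -2.75
    center_hi: float = 2.75
    center_step: float = 0.1
    size_lo: float = 1.5
    size_hi: float = 15.0
    size_step: float = 0.1
    baseline_lo: float = -5.0
    baseline_hi: float = 5.0
    refine_halfwidth: float = 0.1

    def __post_init__(self) -> None:
        if self.center_step <= 0 or self.size_step <= 0:
            raise ValueError("grid steps must be positive")
        if self.center_hi < self.center_lo or self.size_hi < self.size_lo:
            raise ValueError("grid ranges must be non-empty")

    @property
    def centers(self) -> np.ndarray:
        n = int(round((self.center_hi - self.center_lo) / self.center_step)) + 1
        return np.round(self.center_lo + self.center_step * np.arange(n), 10)

    @property
    def sizes(self) -> np.ndarray:
        n = int(round((self.size_hi - self.size_lo) / self.size_step)) + 1
        return np.round(self.size_lo + self.size_step * np.arange(n), 10)


@dataclass(frozen=True)
class FitResult:
    params: CurveParams
    rmse: float
    stage: str            # 'grid' or 'refined'
    grid_params: CurveParams
    grid_rmse: float


def curve_eval(x, params: CurveParams):
    """Evaluate the fit curve at pixel coordinates ``x``."""
    return params.baseline + params.amplitude * basis_eval(
        np.asarray(x, dtype=float) - params.center, params.size
    )


def center_error(fit: FitResult, true_position: float) -> float:
    """Absolute error between the fitted center and the true coordinate."""
    return abs(fit.params.center - true_position)


# Cache of precomputed grid-stage design tensors, keyed by (spec, pixel coords).
_engine_cache: dict[tuple, tuple] = {}


def _grid_engine(spec: FitGridSpec, pixels: np.ndarray):
    key = (spec, pixels.shape[0], float(pixels[0]), float(pixels[-1]))
    hit = _engine_cache.get(key)
    if hit is not None:
        return hit
    centers = spec.centers
    sizes = spec.sizes
    cc, ss = np.meshgrid(centers, sizes, indexing="ij")
    cc = cc.ravel()
    ss = ss.ravel()
    # G[k] = unit-amplitude, zero-baseline curve for combo k.
    r = np.abs(pixels[None, :] - cc[:, None])
    G = np.where(r < ss[:, None],
                 (0.5 * np.cos(r * np.pi / ss[:, None]) + 0.5) ** 7,
                 0.0)
    Sg = G.sum(axis=1)
    Sgg = (G * G).sum(axis=1)
    out = (cc, ss, G, Sg, Sgg)
    _engine_cache[key] = out
    return out


def _bounded_linear(Gy, Sg, Sgg, Sy, n, amax, blo, bhi):
    """Closed-form box-constrained (a, b) per combo, vectorized.

    Solves min ||y - (a g + b)||^2 with a in [0, amax], b in [blo, bhi]:
    unconstrained solution first, then clamp the offending coordinate and
    re-solve the other (exact for this 2-parameter box problem).
    """
    denom = n * Sgg - Sg * Sg
    denom = np.where(np.abs(denom) < 1e-300, 1e-300, denom)
    a = (n * Gy - Sg * Sy) / denom
    b = (Sy - a * Sg) / n
    a = np.clip(a, 0.0, amax)
    b = (Sy - a * Sg) / n
    bad = (b < blo) | (b > bhi)
    if np.any(bad):
        b = np.clip(b, blo, bhi)
        with np.errstate(invalid="ignore", divide="ignore"):
            a_re = np.where(Sgg > 0, (Gy - b * Sg) / np.where(Sgg > 0, Sgg, 1.0), 0.0)
        a = np.where(bad, np.clip(a_re, 0.0, amax), a)
    return a, b


def grid_fit(curve: np.ndarray, pixels: np.ndarray | PixelGrid,
             spec: FitGridSpec = FitGridSpec()) -> FitResult:
    """Exhaustive (center, size) grid search with exact linear (a, b) subfits.

    For every (c, s) combination the amplitude is restricted to
    [0, max(curve) - min(curve)] and the baseline to the spec's bounds; the
    globally minimal-RMSE combination wins, ties broken deterministically
    by smallest center then smallest size.
    """
    if isinstance(pixels, PixelGrid):
        pixels = pixels.coords
    y = np.asarray(curve, dtype=float)
    if y.ndim != 1 or y.shape != pixels.shape:
        raise ValueError("curve must be a vector matching the pixel grid")
    if not np.all(np.isfinite(y)):
        raise ValueError("curve contains non-finite values")

    cc, ss, G, Sg, Sgg = _grid_engine(spec, pixels)
    n = float(len(y))
    Sy = y.sum()
    Syy = float(y @ y)
    Gy = G @ y
    amax = float(y.max() - y.min())
    a, b = _bounded_linear(Gy, Sg, Sgg, Sy, n, amax,
                           spec.baseline_lo, spec.baseline_hi)
    sse = (Syy + a * a * Sgg + n * b * b
           - 2.0 * a * Gy - 2.0 * b * Sy + 2.0 * a * b * Sg)
    rmse = np.sqrt(np.maximum(sse, 0.0) / n)
    # combos are ordered center-major, size-minor; argmin's first-hit rule
    # implements the lexicographic tie-break.
    k = int(np.argmin(rmse))
    params = CurveParams(center=float(cc[k]), size=float(ss[k]),
                         amplitude=float(a[k]), baseline=float(b[k]))
    return FitResult(params=params, rmse=float(rmse[k]), stage="grid",
                     grid_params=params, grid_rmse=float(rmse[k]))


def _mse(y: np.ndarray, pixels: np.ndarray, theta) -> float:
    # refinement objective: MSE shares its argmin with RMSE but stays
    # smooth at a perfect fit, where sqrt has a gradient singularity
    c, s, a, b = theta
    pred = b + a * basis_eval(pixels - c, max(s, 1e-9))
    return float(np.mean((y - pred) ** 2))


def fit_representation(curve: np.ndarray, pixels: np.ndarray | PixelGrid,
                       spec: FitGridSpec = FitGridSpec()) -> FitResult:
    """Two-stage fit: grid search then bounded local refinement.

    Refinement minimises the RMSE over (c, s, a, b) with c and s each
    constrained within one grid step of the grid optimum, a within
    [0, max - min] and b within the spec's baseline bounds. If refinement
    fails or does not lower the RMSE, the grid fit is returned.
    """
    if isinstance(pixels, PixelGrid):
        pixels = pixels.coords
    y = np.asarray(curve, dtype=float)
    g = grid_fit(y, pixels, spec)
    p = g.params
    amax = float(y.max() - y.min())
    h = spec.refine_halfwidth
    bounds = [
        (p.center - h, p.center + h),
        (max(p.size - h, 1e-6), p.size + h),
        (0.0, max(amax, 0.0)),
        (spec.baseline_lo, spec.baseline_hi),
    ]
    x0 = np.array([p.center, p.size, p.amplitude, p.baseline])
    try:
        res = minimize(lambda th: _mse(y, pixels, th), x0, method="L-BFGS-B",
                       bounds=bounds, options={"maxiter": 500, "ftol": 1e-16,
                                               "gtol": 1e-14})
        refined = CurveParams(center=float(res.x[0]), size=float(res.x[1]),
                              amplitude=float(res.x[2]), baseline=float(res.x[3]))
        refined_rmse = float(np.sqrt(_mse(y, pixels, res.x)))
    except Exception as exc:  # pragma: no cover - optimizer failure fallback
        log.warning("refinement failed (%s); keeping grid fit", exc)
        return g
    if refined_rmse <= g.rmse:
        return FitResult(params=refined, rmse=refined_rmse, stage="refined",
                         grid_params=g.params, grid_rmse=g.rmse)
    return g
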