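"""Inverted encoding model for spatial position along one scene axis.

A voxel's mean trial response is modelled as a weighted sum of six spatial
"channels" — exponentiated-cosine basis functions tiling the axis of
interest (horizontal x or depth z):

    B = W X,    X = F S

where F (channels x pixels) samples the basis on a fine pixel grid, S
(pixels x trials) is a pixel representation of the stimulus on every trial,
B (voxels x trials) holds the responses and W (voxels x channels) the
channel weights. Weights are estimated on training runs by least squares
via the Moore-Penrose pseudoinverse, and the model is inverted on held-out
runs to yield channel responses X2_hat = (W'W)^-1 W' B2, projected back
through F as pixel-space "model-based representations" of the stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trials import TrialMatrix

__all__ = [
    "PixelGrid",
    "BasisSet",
    "Reconstruction",
    "PositionAverages",
    "basis_eval",
    "channel_activations",
    "build_basis",
    "stimulus_profile",
    "design_matrix",
    "estimate_weights",
    "invert_model",
    "reconstruct",
    "crossval_reconstruct",
    "average_by_position",
    "DEFAULT_CENTERS",
    "DEFAULT_SIZE",
]

#: Default channel centers: the six stimulus row coordinates, scene units.
DEFAULT_CENTERS: tuple[float, ...] = (-1.5, -0.9, -0.3, 0.3, 0.9, 1.5)
#: Default channel size s (half-width of the compact support), scene units.
DEFAULT_SIZE: float = 1.8
#: Exponent of the cosine basis; fixed by the model.
BASIS_EXPONENT: int = 7


class ModelError(ValueError):
    """Ill-posed encoding-model problem (rank deficiency, dimension mismatch)."""


def basis_eval(r, size: float):
    """Exponentiated-cosine basis value at distance ``r`` from the center.

    f(r) = (0.5 cos(r*pi/s) + 0.5)^7 for |r| < s, 0 elsewhere. Compactly
    supported, in [0, 1], with f(0) = 1.
    """
    if size <= 0:
        raise ValueError("basis size must be positive")
    r = np.abs(np.asarray(r, dtype=float))
    out = np.where(r < size, (0.5 * np.cos(r * np.pi / size) + 0.5) ** BASIS_EXPONENT, 0.0)
    return float(out) if out.ndim == 0 else out


def channel_activations(coords, centers=DEFAULT_CENTERS, size: float = DEFAULT_SIZE):
    """Channel responses to point stimuli: (n_channels, n_coords)."""
    coords = np.atleast_1d(np.asarray(coords, dtype=float))
    centers = np.asarray(centers, dtype=float)
    return basis_eval(coords[None, :] - centers[:, None], size)


@dataclass(frozen=True)
class PixelGrid:
    """Evenly spaced sampling of the scene axis used for S, F and curves."""

    lo: float = -2.75
    hi: float = 2.75
    n_pixels: int = 111

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("pixel grid requires lo < hi")
        if self.n_pixels < 2:
            raise ValueError("pixel grid requires at least 2 pixels")

    @property
    def coords(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n_pixels)

    @property
    def spacing(self) -> float:
        return (self.hi - self.lo) / (self.n_pixels - 1)

    def nearest_pixel(self, coord: float) -> int:
        if not self.lo <= coord <= self.hi:
            raise ValueError(f"coordinate {coord} outside pixel domain "
                             f"[{self.lo}, {self.hi}]")
        return int(round((coord - self.lo) / self.spacing))


DEFAULT_PIXEL_GRID = PixelGrid()


@dataclass(frozen=True)
class BasisSet:
    """Six spatial channels sampled on a pixel grid (matrix F)."""

    centers: tuple[float, ...]
    size: float
    pixel_grid: PixelGrid
    F: np.ndarray = field(repr=False)

    @property
    def n_channels(self) -> int:
        return len(self.centers)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.F, index=list(self.centers),
                            columns=np.round(self.pixel_grid.coords, 6))


def build_basis(
    pixel_grid: PixelGrid = DEFAULT_PIXEL_GRID,
    centers=DEFAULT_CENTERS,
    size: float = DEFAULT_SIZE,
    n_channels: int | None = None,
) -> BasisSet:
    """Sample ``len(centers)`` evenly tiling channels on the pixel grid."""
    centers = tuple(float(c) for c in centers)
    if n_channels is not None and n_channels != len(centers):
        raise ValueError(f"n_channels={n_channels} but {len(centers)} centers given")
    if any(b <= a for a, b in zip(centers, centers[1:])):
        raise ValueError("centers must be strictly increasing")
    if centers[0] < pixel_grid.lo or centers[-1] > pixel_grid.hi:
        raise ValueError("centers must lie within the pixel domain")
    F = channel_activations(pixel_grid.coords, centers, size)
    return BasisSet(centers=centers, size=float(size), pixel_grid=pixel_grid, F=F)


def stimulus_profile(
    coord: float,
    pixel_grid: PixelGrid = DEFAULT_PIXEL_GRID,
    mode: str = "delta",
    extent: float | None = None,
) -> np.ndarray:
    """Pixel representation of one stimulus (a column of S); unit mass.

    ``delta`` places all mass on the nearest pixel; ``boxcar`` spreads it
    uniformly over pixels within ``extent`` scene units of the coordinate
    (e.g. the rendered sphere radius).
    """
    p = np.zeros(pixel_grid.n_pixels)
    if mode == "delta":
        p[pixel_grid.nearest_pixel(coord)] = 1.0
        return p
    if mode == "boxcar":
        if extent is None or extent <= 0:
            raise ValueError("boxcar profile requires a positive extent")
        pixel_grid.nearest_pixel(coord)  # domain check
        mask = np.abs(pixel_grid.coords - coord) <= extent + 1e-12
        p[mask] = 1.0 / mask.sum()
        return p
    raise ValueError(f"unknown stimulus profile mode {mode!r}")


def _profile_matrix(coords, pixel_grid, mode, extent) -> np.ndarray:
    return np.column_stack(
        [stimulus_profile(c, pixel_grid, mode, extent) for c in coords]
    )


def design_matrix(F: np.ndarray, S: np.ndarray) -> np.ndarray:
    """X = F S (channels x trials)."""
    F = np.asarray(F, dtype=float)
    S = np.asarray(S, dtype=float)
    if F.ndim != 2 or S.ndim != 2 or F.shape[1] != S.shape[0]:
        raise ModelError(f"pixel dimensions do not match: F {F.shape}, S {S.shape}")
    return F @ S


def _deficient_channels(M: np.ndarray, tol: float) -> list[int]:
    """Channels implicated in the (near-)null space of M (rows = channels)."""
    gram = M @ M.T
    w, v = np.linalg.eigh(gram)
    bad = v[:, w < tol * max(w.max(), 1.0)]
    if bad.size == 0:
        return []
    load = np.abs(bad).max(axis=1)
    return [int(i) for i in np.flatnonzero(load > 0.1)]


def estimate_weights(B1: np.ndarray, X1: np.ndarray, rank_tol: float = 1e-10) -> np.ndarray:
    """Least-squares channel weights W_hat (voxels x channels).

    Solves min ||B1 - W X1||_F via the Moore-Penrose pseudoinverse of the
    design matrix: W_hat = B1 pinv(X1). ``B1`` is voxels x trials, ``X1``
    channels x trials with full row rank and at least as many trials as
    channels.
    """
    B1 = np.asarray(B1, dtype=float)
    X1 = np.asarray(X1, dtype=float)
    if B1.ndim != 2 or X1.ndim != 2 or B1.shape[1] != X1.shape[1]:
        raise ModelError(f"trial dimensions do not match: B1 {B1.shape}, X1 {X1.shape}")
    n_channels, n_trials = X1.shape
    if n_trials < n_channels:
        raise ModelError(f"need at least {n_channels} trials, got {n_trials}")
    if np.linalg.matrix_rank(X1, tol=None) < n_channels:
        bad = _deficient_channels(X1, rank_tol)
        raise ModelError(
            f"design matrix is rank deficient; channels {bad} are linearly "
            "dependent or unstimulated"
        )
    return B1 @ np.linalg.pinv(X1)


def invert_model(W_hat: np.ndarray, B2: np.ndarray, rank_tol: float = 1e-10) -> np.ndarray:
    """Channel responses on test data: X2_hat = (W'W)^-1 W' B2.

    ``W_hat`` is voxels x channels with full column rank (needs at least as
    many voxels as channels); ``B2`` voxels x trials. Returns channels x
    trials.
    """
    W_hat = np.asarray(W_hat, dtype=float)
    B2 = np.asarray(B2, dtype=float)
    if W_hat.ndim != 2 or B2.ndim != 2 or W_hat.shape[0] != B2.shape[0]:
        raise ModelError(f"voxel dimensions do not match: W {W_hat.shape}, B2 {B2.shape}")
    n_voxels, n_channels = W_hat.shape
    if n_voxels < n_channels:
        raise ModelError(f"need at least {n_channels} voxels, got {n_voxels}")
    if np.linalg.matrix_rank(W_hat, tol=None) < n_channels:
        bad = _deficient_channels(W_hat.T, rank_tol)
        raise ModelError(f"weight matrix is rank deficient (channels {bad})")
    gram = W_hat.T @ W_hat
    return np.linalg.solve(gram, W_hat.T @ B2)


def reconstruct(X2_hat: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Model-based representations: curves = X2_hat' F (trials x pixels)."""
    X2_hat = np.asarray(X2_hat, dtype=float)
    F = np.asarray(F, dtype=float)
    if X2_hat.ndim != 2 or F.ndim != 2 or X2_hat.shape[0] != F.shape[0]:
        raise ModelError(f"channel dimensions do not match: X2 {X2_hat.shape}, F {F.shape}")
    return X2_hat.T @ F


@dataclass
class Reconstruction:
    """Cross-validated pixel-space representations with trial labels."""

    curves: np.ndarray          # (n_stim_trials, n_pixels)
    channel_responses: np.ndarray  # (n_channels, n_stim_trials)
    basis: BasisSet
    axis: str
    trials: TrialMatrix         # stimulus trials only, row-aligned with curves

    @property
    def pixel_grid(self) -> PixelGrid:
        return self.basis.pixel_grid

    def to_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "subject": self.trials.subject,
                "run": self.trials.run,
                "position_row": self.trials.row,
                "position_col": self.trials.col,
                "mirrored": self.trials.mirrored.astype(int),
            }
        )
        pix = pd.DataFrame(
            self.curves,
            columns=[f"px_{c:.3f}" for c in self.pixel_grid.coords],
        )
        return pd.concat([meta, pix], axis=1)


def crossval_reconstruct(
    dataset: TrialMatrix,
    basis: BasisSet,
    axis: str = "z",
    profile_mode: str = "delta",
    extent: float | None = None,
) -> Reconstruction:
    """Leave-one-run-out reconstruction of every stimulus trial.

    For each run, channel weights are estimated from all other runs and the
    model is inverted on the held-out run, so each trial is reconstructed
    exactly once from independent training data. Null trials are excluded.
    """
    stim = dataset.stimulus_trials()
    runs = stim.runs
    if len(runs) < 2:
        raise ModelError("leave-one-run-out cross-validation needs >= 2 runs")
    coords = stim.coordinate(axis)
    S = _profile_matrix(coords, basis.pixel_grid, profile_mode, extent)
    X_all = design_matrix(basis.F, S)
    B_all = stim.responses.T  # voxels x trials

    n_pix = basis.pixel_grid.n_pixels
    curves = np.zeros((stim.n_trials, n_pix))
    chan = np.zeros((basis.n_channels, stim.n_trials))
    for run in runs:
        test = stim.run == run
        train = ~test
        W_hat = estimate_weights(B_all[:, train], X_all[:, train])
        X2_hat = invert_model(W_hat, B_all[:, test])
        chan[:, test] = X2_hat
        curves[test] = reconstruct(X2_hat, basis.F)
    return Reconstruction(curves=curves, channel_responses=chan, basis=basis,
                          axis=axis, trials=stim)


@dataclass
class PositionAverages:
    """Mean representation per stimulus position along one axis."""

    curves: np.ndarray       # (n_positions, n_pixels)
    true_coords: np.ndarray  # (n_positions,) scene units
    labels: np.ndarray       # position indices 0..5
    counts: np.ndarray       # trials averaged per position
    axis: str
    pixel_grid: PixelGrid
    subject: str = "s00"

    def to_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "subject": self.subject,
                "axis": self.axis,
                "position": self.labels,
                "true_coord": self.true_coords,
                "n_trials": self.counts,
            }
        )
        pix = pd.DataFrame(self.curves,
                           columns=[f"px_{c:.3f}" for c in self.pixel_grid.coords])
        return pd.concat([meta, pix], axis=1)


def average_by_position(
    recon: Reconstruction,
    axis: str | None = None,
    unmirror: bool = True,
) -> PositionAverages:
    """Average trial reconstructions into six per-position curves.

    For the horizontal axis the grids of mirrored runs were flipped left-
    right; their curves are reflected about the domain midpoint and their
    column labels and x coordinates mapped back to the unmirrored layout
    before averaging, so that equally eccentric positions are pooled. Depth
    rows are unaffected by mirroring, so z curves are averaged as-is.
    """
    axis = axis or recon.axis
    stim = recon.trials
    grid = recon.pixel_grid
    if abs((grid.lo + grid.hi) / 2) > 1e-9 and axis == "x" and unmirror:
        raise ModelError("x-axis unmirroring requires a pixel domain symmetric about 0")

    curves = recon.curves.copy()
    if axis == "z":
        labels = stim.row.copy()
        coord = stim.z.copy()
    else:
        labels = stim.col.copy()
        coord = stim.x.copy()
        if unmirror:
            m = stim.mirrored
            curves[m] = curves[m, ::-1]
            n_cols = labels.max() + 1
            labels[m] = (n_cols - 1) - labels[m]
            coord[m] = -coord[m]

    uniq = np.unique(labels)
    expected = np.arange(labels.max() + 1)
    missing = np.setdiff1d(expected, uniq)
    if missing.size:
        raise ModelError(f"no trials at position(s) {missing.tolist()}")
    n_pos = len(uniq)
    out = np.zeros((n_pos, curves.shape[1]))
    true = np.zeros(n_pos)
    counts = np.zeros(n_pos, dtype=int)
    for k, lab in enumerate(uniq):
        sel = labels == lab
        if not np.any(sel):
            raise ModelError(f"no trials at position {lab}")
        out[k] = curves[sel].mean(axis=0)
        true[k] = coord[sel].mean()
        counts[k] = int(sel.sum())
    return PositionAverages(curves=out, true_coords=true, labels=uniq,
                            counts=counts, axis=axis, pixel_grid=grid,
                            subject=stim.subject)
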