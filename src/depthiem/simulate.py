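"""Synthetic voxel populations with known spatial tuning.

Every downstream stage (encoding model, curve fitting, decoding, group
statistics) is exercised on data generated here, so ground truth is always
available. Voxels respond as weighted sums of generative spatial channels
(the same exponentiated-cosine family the analysis uses, unless configured
otherwise) evaluated at each trial's horizontal (x) and depth (z)
coordinate, plus i.i.d. Gaussian noise. Optionally, trial responses can be
rendered into BOLD-like time series by convolution with a double-gamma
hemodynamic response function and re-extracted the way the trial estimates
are defined: the average of the z-scored signal at the 3rd and 4th volumes
after stimulus onset.

Experiment layout mirrors the study design: 9 subjects, 13 runs each,
36 stimulus trials (one per grid cell) plus 9 randomly interleaved null
trials per run, with the stimulus grid horizontally flipped on even-
numbered runs. Every stochastic operation is a pure function of its inputs
and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from . import iem
from .geometry import StimulusGrid, GridSpacing, ViewerGeometry, DEFAULT_GEOMETRY, make_grid
from .trials import TrialMatrix

__all__ = [
    "HrfParams",
    "VoxelSet",
    "SimConfig",
    "SimulatedExperiment",
    "make_voxels",
    "calibrate_noise",
    "simulate_trial_responses",
    "simulate_experiment",
    "hrf_double_gamma",
    "simulate_timeseries",
    "extract_trial_estimates",
    "RunTimeseries",
    "DEFAULT_NOISE_SCALE",
]

#: Default trial-noise scale, as a multiple of each voxel's peak mean
#: response over the grid. Chosen so that default six-way depth decoding
#: d-prime falls in the empirically plausible 0-0.6 range (see methods note).
DEFAULT_NOISE_SCALE: float = 2.0


@dataclass(frozen=True)
class HrfParams:
    """Canonical double-gamma HRF: response peak 5 s, undershoot peak 15 s,
    response/undershoot amplitude ratio 6, unit dispersions (seconds)."""

    peak_s: float = 5.0
    undershoot_peak_s: float = 15.0
    response_undershoot_ratio: float = 6.0
    response_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0

    def __post_init__(self) -> None:
        for name in ("peak_s", "undershoot_peak_s", "response_undershoot_ratio",
                     "response_dispersion", "undershoot_dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"HRF parameter {name} must be positive")


def hrf_double_gamma(t, params: HrfParams = HrfParams()):
    """Difference-of-gammas hemodynamic response, h(0) = 0, unit-free.

    Each lobe is a gamma density whose mode equals the stated peak time
    (shape = peak/dispersion + 1, scale = dispersion); the undershoot is
    scaled down by the response:undershoot ratio.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("HRF is causal; t must be >= 0")
    a1 = params.peak_s / params.response_dispersion + 1.0
    a2 = params.undershoot_peak_s / params.undershoot_dispersion + 1.0
    h = (gamma_dist.pdf(t, a1, scale=params.response_dispersion)
         - gamma_dist.pdf(t, a2, scale=params.undershoot_dispersion)
         / params.response_undershoot_ratio)
    return float(h) if h.ndim == 0 else h


@dataclass
class VoxelSet:
    """Ground-truth tuning of a simulated voxel population.

    Each voxel carries a weight vector over the generative x channels and
    one over the generative z channels; its noiseless response to a trial
    at (x, z) is w_x . f(x) + w_z . f(z). ``noise_sd`` is the per-voxel
    trial-noise standard deviation (response units).
    """

    weights_x: np.ndarray  # (n_voxels, n_channels)
    weights_z: np.ndarray
    centers: tuple[float, ...] = iem.DEFAULT_CENTERS
    size: float = iem.DEFAULT_SIZE
    noise_sd: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.weights_x = np.atleast_2d(np.asarray(self.weights_x, dtype=float))
        self.weights_z = np.atleast_2d(np.asarray(self.weights_z, dtype=float))
        if self.weights_x.shape != self.weights_z.shape:
            raise ValueError("x and z weight matrices must have the same shape")
        if not (np.all(np.isfinite(self.weights_x)) and np.all(np.isfinite(self.weights_z))):
            raise ValueError("weights must be finite")
        if self.noise_sd is None:
            self.noise_sd = np.zeros(self.n_voxels)
        self.noise_sd = np.broadcast_to(
            np.asarray(self.noise_sd, dtype=float), (self.n_voxels,)
        ).copy()
        if np.any(self.noise_sd < 0):
            raise ValueError("noise_sd must be non-negative")

    @property
    def n_voxels(self) -> int:
        return self.weights_x.shape[0]

    def mean_response(self, x, z) -> np.ndarray:
        """Noiseless response of every voxel to trials at (x, z): (trials, voxels)."""
        fx = iem.channel_activations(x, self.centers, self.size)  # (ch, trials)
        fz = iem.channel_activations(z, self.centers, self.size)
        return (self.weights_x @ fx + self.weights_z @ fz).T


def make_voxels(
    n_voxels: int,
    centers=iem.DEFAULT_CENTERS,
    size: float = iem.DEFAULT_SIZE,
    weight_distribution: str = "halfnorm",
    noise_sd: float = 0.0,
    axis: str = "both",
    seed: int = 0,
) -> VoxelSet:
    """Draw a reproducible voxel population.

    ``weight_distribution``: 'halfnorm' (non-negative half-normal, default)
    or 'uniform' on [0, 1). ``axis`` restricts tuning to a single scene axis
    ('x' or 'z'; the other weight block is zero), which makes the noiseless
    encoding-model round trip exact.
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    rng = np.random.default_rng(seed)
    n_ch = len(centers)
    if weight_distribution == "halfnorm":
        draw = lambda: np.abs(rng.normal(size=(n_voxels, n_ch)))
    elif weight_distribution == "uniform":
        draw = lambda: rng.uniform(size=(n_voxels, n_ch))
    else:
        raise ValueError(f"unknown weight distribution {weight_distribution!r}")
    wx = draw()
    wz = draw()
    if axis == "x":
        wz = np.zeros_like(wz)
    elif axis == "z":
        wx = np.zeros_like(wx)
    elif axis != "both":
        raise ValueError(f"axis must be 'x', 'z' or 'both', got {axis!r}")
    return VoxelSet(weights_x=wx, weights_z=wz, centers=tuple(centers),
                    size=float(size), noise_sd=np.full(n_voxels, float(noise_sd)))


def calibrate_noise(voxels: VoxelSet, grid: StimulusGrid, scale: float) -> VoxelSet:
    """Set each voxel's noise sd to ``scale`` times its peak mean response
    over the stimulus grid."""
    xs = np.array([l.x_scene for l in grid.locations])
    zs = np.array([l.z_scene for l in grid.locations])
    peak = np.abs(voxels.mean_response(xs, zs)).max(axis=0)
    return replace(voxels, noise_sd=scale * peak)


def _default_sequence(grid: StimulusGrid, n_nulls: int, rng: np.random.Generator):
    """One trial per grid cell plus interleaved null trials, shuffled."""
    cells: list[tuple[int, int] | None] = [
        (l.row_index, l.col_index) for l in grid.locations
    ]
    cells += [None] * n_nulls
    rng.shuffle(cells)
    return cells


def simulate_trial_responses(
    voxels: VoxelSet,
    grid: StimulusGrid,
    trial_sequence,
    seed: int = 0,
    run: int = 1,
    subject: str = "s00",
) -> TrialMatrix:
    """Responses for one run: W.f(position) per trial plus Gaussian noise.

    ``trial_sequence`` is a list of (row_index, col_index) grid cells, with
    ``None`` marking null trials (pure noise). Reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = len(trial_sequence)
    rows = np.full(n, -1, dtype=int)
    cols = np.full(n, -1, dtype=int)
    xs = np.full(n, np.nan)
    zs = np.full(n, np.nan)
    signal = np.zeros((n, voxels.n_voxels))
    for t, cell in enumerate(trial_sequence):
        if cell is None:
            continue
        loc = grid.location(*cell)  # raises KeyError for labels outside the grid
        rows[t], cols[t] = cell
        xs[t], zs[t] = loc.x_scene, loc.z_scene
        signal[t] = voxels.mean_response(loc.x_scene, loc.z_scene)[0]
    noise = rng.normal(0.0, 1.0, size=signal.shape) * voxels.noise_sd[None, :]
    return TrialMatrix(
        responses=signal + noise,
        run=np.full(n, run),
        row=rows,
        col=cols,
        x=xs,
        z=zs,
        is_null=rows < 0,
        mirrored=np.full(n, grid.mirrored),
        subject=subject,
    )


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of a simulated experiment."""

    n_subjects: int = 9
    n_runs: int = 13
    n_voxels: int = 60
    n_nulls_per_run: int = 9
    noise_scale: float = DEFAULT_NOISE_SCALE   # sd as multiple of peak response
    weight_distribution: str = "halfnorm"
    gen_centers: tuple[float, ...] = iem.DEFAULT_CENTERS
    gen_size: float = iem.DEFAULT_SIZE
    tuning_axis: str = "both"
    mirror_even_runs: bool = True
    spacing: GridSpacing = GridSpacing()
    geom: ViewerGeometry = DEFAULT_GEOMETRY

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise ValueError("cross-validation requires n_runs >= 2")
        if self.n_subjects < 1 or self.n_voxels < 1:
            raise ValueError("n_subjects and n_voxels must be >= 1")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")


@dataclass
class SubjectSim:
    """One subject's ground truth and concatenated run data."""

    subject: str
    voxels: VoxelSet
    trials: TrialMatrix  # all runs stacked


@dataclass
class SimulatedExperiment:
    config: SimConfig
    seed: int
    grid: StimulusGrid
    grid_mirrored: StimulusGrid
    subjects: list[SubjectSim]

    def trials_frame(self) -> pd.DataFrame:
        return pd.concat([s.trials.to_frame() for s in self.subjects],
                         ignore_index=True)


def _run_is_mirrored(run_number: int, mirror_even_runs: bool) -> bool:
    return (run_number % 2 == 0) == mirror_even_runs


def simulate_experiment(config: SimConfig = SimConfig(), seed: int = 0) -> SimulatedExperiment:
    """Simulate the full multi-subject experiment.

    Each subject gets an independent voxel population; runs alternate
    between the base grid and its horizontal mirror (even-numbered runs
    mirrored by default). Noise sd is ``noise_scale`` times each voxel's
    peak response. Fully reproducible from ``seed``.
    """
    grid = make_grid(config.geom, config.spacing, mirrored=False)
    grid_m = make_grid(config.geom, config.spacing, mirrored=True)
    root = np.random.SeedSequence(seed)
    subject_seeds = root.spawn(config.n_subjects)
    subjects = []
    for s, sseq in enumerate(subject_seeds):
        name = f"s{s:02d}"
        vox_seed, *run_seeds = sseq.spawn(config.n_runs + 1)
        voxels = make_voxels(
            config.n_voxels,
            centers=config.gen_centers,
            size=config.gen_size,
            weight_distribution=config.weight_distribution,
            axis=config.tuning_axis,
            seed=vox_seed,
        )
        voxels = calibrate_noise(voxels, grid, config.noise_scale)
        runs = []
        for r, rseq in enumerate(run_seeds, start=1):
            g = grid_m if _run_is_mirrored(r, config.mirror_even_runs) else grid
            (noise_seed,) = rseq.spawn(1)
            # trial order is part of the design, not the noise: it depends
            # only on (subject, run), so different seeds share labels
            sequence = _default_sequence(
                g, config.n_nulls_per_run, np.random.default_rng([s, r])
            )
            runs.append(
                simulate_trial_responses(voxels, g, sequence, seed=noise_seed,
                                         run=r, subject=name)
            )
        subjects.append(SubjectSim(subject=name, voxels=voxels,
                                   trials=TrialMatrix.concat(runs)))
    return SimulatedExperiment(config=config, seed=seed, grid=grid,
                               grid_mirrored=grid_m, subjects=subjects)


# ---------------------------------------------------------------------------
# Time-series mode
# ---------------------------------------------------------------------------

@dataclass
class RunTimeseries:
    """BOLD-like voxel time series for one run plus its event table."""

    data: np.ndarray      # (n_volumes, n_voxels)
    events: pd.DataFrame  # onset_s, duration_s, row, col, is_null
    tr_s: float
    run: int = 1
    subject: str = "s00"
    mirrored: bool = False

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]


def _schedule_events(
    n_trials: int,
    stim_s: float,
    iti_range: tuple[float, float],
    lead_s: float,
    tail_s: float,
    duration_s: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Jittered onsets that exactly fill the run.

    ITIs are drawn uniformly from ``iti_range`` and then affinely rescaled
    (keeping the lower bound as a floor) so trials plus the lead-in and
    tail fixation periods fill ``duration_s`` exactly.
    """
    lo, hi = iti_range
    itis = rng.uniform(lo, hi, size=n_trials)
    budget = duration_s - lead_s - tail_s - n_trials * stim_s
    if budget < n_trials * lo:
        raise ValueError("run too short for the requested trial count")
    excess = itis.sum() - n_trials * lo
    target = budget - n_trials * lo
    itis = lo + (itis - lo) * (target / excess if excess > 0 else 0.0)
    onsets = lead_s + np.concatenate([[0.0], np.cumsum(stim_s + itis[:-1])])
    return onsets


def simulate_timeseries(
    voxels: VoxelSet,
    grid: StimulusGrid,
    trial_sequence,
    hrf: HrfParams = HrfParams(),
    tr_s: float = 2.0,
    duration_s: float = 300.0,
    stim_s: float = 3.0,
    iti_range: tuple[float, float] = (2.0, 6.0),
    lead_s: float = 2.0,
    tail_s: float = 10.0,
    noise_sd: float = 0.0,
    drift_per_run: float = 0.0,
    seed: int = 0,
    run: int = 1,
    subject: str = "s00",
) -> RunTimeseries:
    """Render one run's trials into an HRF-convolved voxel time series.

    Each stimulus trial contributes its noiseless response amplitude times
    a boxcar of ``stim_s`` seconds convolved with the HRF; null trials
    contribute nothing. A linear drift of ``drift_per_run`` (response units
    over the whole run) and white noise of sd ``noise_sd`` are added. A
    300 s run at TR 2 s yields 150 volumes.
    """
    rng = np.random.default_rng(seed)
    n_vol = int(round(duration_s / tr_s))
    onsets = _schedule_events(len(trial_sequence), stim_s, iti_range,
                              lead_s, tail_s, duration_s, rng)
    if np.any(onsets + stim_s > duration_s):
        raise ValueError("events extend beyond the end of the run")

    dt = 0.1  # fine grid for the neural regressor, seconds
    fine_t = np.arange(0.0, duration_s, dt)
    hrf_kernel = hrf_double_gamma(np.arange(0.0, 32.0, dt), hrf)
    vol_idx = np.round(np.arange(n_vol) * tr_s / dt).astype(int)

    rows = np.full(len(trial_sequence), -1, dtype=int)
    cols = np.full(len(trial_sequence), -1, dtype=int)
    data = np.zeros((n_vol, voxels.n_voxels))
    for t, cell in enumerate(trial_sequence):
        if cell is None:
            continue
        loc = grid.location(*cell)
        rows[t], cols[t] = cell
        boxcar = ((fine_t >= onsets[t]) & (fine_t < onsets[t] + stim_s)).astype(float)
        regressor = np.convolve(boxcar, hrf_kernel)[: len(fine_t)] * dt
        amp = voxels.mean_response(loc.x_scene, loc.z_scene)[0]
        data += regressor[vol_idx, None] * amp[None, :]

    if drift_per_run:
        data += np.linspace(0.0, drift_per_run, n_vol)[:, None]
    if noise_sd:
        data += rng.normal(0.0, noise_sd, size=data.shape)

    events = pd.DataFrame(
        {
            "onset_s": onsets,
            "duration_s": stim_s,
            "row": rows,
            "col": cols,
            "is_null": rows < 0,
        }
    )
    return RunTimeseries(data=data, events=events, tr_s=tr_s, run=run,
                         subject=subject, mirrored=grid.mirrored)


def extract_trial_estimates(
    ts: RunTimeseries,
    grid: StimulusGrid,
    drop_incomplete: bool = True,
) -> TrialMatrix:
    """Single-trial activation estimates from a run's time series.

    Each voxel's series is z-scored within the run, then each trial's
    estimate is the average of the volumes 3 and 4 acquisitions after the
    reference volume (the last volume at or before stimulus onset),
    i.e. roughly 4-8 s post-onset. Trials whose late volumes fall beyond
    the run end are excluded (``drop_incomplete``) or raise otherwise.
    """
    sd = ts.data.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("constant voxel time series cannot be z-scored")
    zdata = (ts.data - ts.data.mean(axis=0)) / sd

    ref = np.floor(ts.events["onset_s"].to_numpy() / ts.tr_s).astype(int)
    ok = ref + 4 < ts.n_volumes
    if not np.all(ok):
        if not drop_incomplete:
            raise ValueError("trial too close to the run end for extraction")
    ref = ref[ok]
    ev = ts.events.loc[ok].reset_index(drop=True)
    est = 0.5 * (zdata[ref + 3] + zdata[ref + 4])

    rows = ev["row"].to_numpy()
    cols = ev["col"].to_numpy()
    xs = np.full(len(ev), np.nan)
    zs = np.full(len(ev), np.nan)
    for t in range(len(ev)):
        if rows[t] >= 0:
            loc = grid.location(int(rows[t]), int(cols[t]))
            xs[t], zs[t] = loc.x_scene, loc.z_scene
    return TrialMatrix(
        responses=est,
        run=np.full(len(ev), ts.run),
        row=rows,
        col=cols,
        x=xs,
        z=zs,
        is_null=rows < 0,
        mirrored=np.full(len(ev), ts.mirrored),
        subject=ts.subject,
    )
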