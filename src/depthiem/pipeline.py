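"""End-to-end orchestration: simulate -> IEM -> fit -> decode -> group stats.

A pipeline run is fully specified by a structured config (YAML-friendly
nested dict) plus an integer seed; identical configs give byte-identical
numeric outputs. Each stage reads its inputs from and writes its outputs
to the run directory as CSV tables, so stages can be run individually on
persisted intermediates or all at once, and a manifest records the config
and content hashes for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import decoding, fitting, groupstats, iem, simulate
from .geometry import GridSpacing, ViewerGeometry, make_grid
from .trials import TrialMatrix

__all__ = ["PipelineConfig", "ConfigError", "load_config", "run_pipeline",
           "report", "stage_simulate", "stage_fit_iem", "stage_fit_curves",
           "stage_decode", "stage_group_stats"]

log = logging.getLogger(__name__)

_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "geometry", "simulation", "iem", "fitting", "decoding", "stats"},
    "geometry": {"eye_offset", "fixation_distance", "vertical_fov_deg",
                 "horizontal_fov_deg", "ecc_max_deg"},
    "simulation": {"n_subjects", "n_runs", "n_voxels", "n_nulls_per_run",
                   "noise_scale", "weight_distribution", "tuning_axis",
                   "mirror_even_runs"},
    "iem": {"centers", "size", "pixel_lo", "pixel_hi", "n_pixels",
            "profile_mode", "profile_extent"},
    "fitting": {"center_lo", "center_hi", "center_step", "size_lo", "size_hi",
                "size_step", "baseline_lo", "baseline_hi", "refine_halfwidth"},
    "decoding": {"C", "n_perm", "q_levels"},
    "stats": {"n_boot", "ci"},
}


class ConfigError(ValueError):
    """Invalid pipeline configuration; message lists every offender."""


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    geometry: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)
    iem: dict = field(default_factory=dict)
    fitting: dict = field(default_factory=dict)
    decoding: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)

    # -- resolved objects -------------------------------------------------
    def viewer_geometry(self) -> ViewerGeometry:
        g = self.geometry
        return ViewerGeometry(
            eye_offset=g.get("eye_offset", 0.4),
            fixation_distance=g.get("fixation_distance", 10.0),
            vertical_fov_deg=g.get("vertical_fov_deg", 25.0),
            horizontal_fov_deg=g.get("horizontal_fov_deg", 33.0),
        )

    def grid_spacing(self) -> GridSpacing:
        return GridSpacing(ecc_max_deg=self.geometry.get("ecc_max_deg", 9.8))

    def sim_config(self) -> simulate.SimConfig:
        s = self.simulation
        return simulate.SimConfig(
            n_subjects=s.get("n_subjects", 9),
            n_runs=s.get("n_runs", 13),
            n_voxels=s.get("n_voxels", 60),
            n_nulls_per_run=s.get("n_nulls_per_run", 9),
            noise_scale=s.get("noise_scale", simulate.DEFAULT_NOISE_SCALE),
            weight_distribution=s.get("weight_distribution", "halfnorm"),
            gen_centers=tuple(self.iem.get("centers", iem.DEFAULT_CENTERS)),
            gen_size=self.iem.get("size", iem.DEFAULT_SIZE),
            tuning_axis=s.get("tuning_axis", "both"),
            mirror_even_runs=s.get("mirror_even_runs", True),
            spacing=self.grid_spacing(),
            geom=self.viewer_geometry(),
        )

    def pixel_grid(self) -> iem.PixelGrid:
        c = self.iem
        return iem.PixelGrid(lo=c.get("pixel_lo", -2.75), hi=c.get("pixel_hi", 2.75),
                             n_pixels=c.get("n_pixels", 111))

    def basis(self) -> iem.BasisSet:
        return iem.build_basis(
            self.pixel_grid(),
            centers=tuple(self.iem.get("centers", iem.DEFAULT_CENTERS)),
            size=self.iem.get("size", iem.DEFAULT_SIZE),
        )

    def fit_spec(self) -> fitting.FitGridSpec:
        f = self.fitting
        defaults = fitting.FitGridSpec()
        return fitting.FitGridSpec(
            **{k: f.get(k, getattr(defaults, k)) for k in _SCHEMA["fitting"]}
        )


def _validate(raw: dict) -> list[str]:
    problems = []
    unknown_top = set(raw) - _SCHEMA[""]
    problems += [f"unknown config key: {k}" for k in sorted(unknown_top)]
    for block, allowed in _SCHEMA.items():
        if not block or block not in raw:
            continue
        if not isinstance(raw[block], dict):
            problems.append(f"config block '{block}' must be a mapping")
            continue
        problems += [f"unknown key: {block}.{k}"
                     for k in sorted(set(raw[block]) - allowed)]
    n_runs = raw.get("simulation", {}).get("n_runs", 13)
    if n_runs < 2:
        problems.append("simulation.n_runs must be >= 2: leave-one-run-out "
                        "cross-validation needs at least two runs")
    return problems


def load_config(source=None, seed: int | None = None) -> PipelineConfig:
    """Build and validate a config from a YAML path, dict, or defaults."""
    if source is None:
        raw = {}
    elif isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text()) or {}
    elif isinstance(source, dict):
        raw = source
    else:
        raise ConfigError(f"unsupported config source {type(source)!r}")
    problems = _validate(raw)
    if problems:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(problems))
    cfg = PipelineConfig(
        seed=int(raw.get("seed", 0)),
        geometry=dict(raw.get("geometry", {})),
        simulation=dict(raw.get("simulation", {})),
        iem=dict(raw.get("iem", {})),
        fitting=dict(raw.get("fitting", {})),
        decoding=dict(raw.get("decoding", {})),
        stats=dict(raw.get("stats", {})),
    )
    if seed is not None:
        cfg = replace(cfg, seed=int(seed))
    return cfg


def _timed(name: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            log.info("stage %-12s %.2f s", name, time.perf_counter() - self.t0)

    return _T()


# ---------------------------------------------------------------------------
# Stages (each reads/writes CSVs in out_dir so subcommands compose)
# ---------------------------------------------------------------------------

def _load_subject_trials(out_dir: Path) -> list[TrialMatrix]:
    df = pd.read_csv(out_dir / "trials.csv")
    return [TrialMatrix.from_frame(g.reset_index(drop=True))
            for _, g in df.groupby("subject", sort=True)]


def stage_simulate(cfg: PipelineConfig, out_dir: Path) -> None:
    with _timed("simulate"):
        exp = simulate.simulate_experiment(cfg.sim_config(), seed=cfg.seed)
        exp.grid.to_csv(out_dir / "grid.csv")
        exp.grid_mirrored.to_csv(out_dir / "grid_mirrored.csv")
        exp.trials_frame().to_csv(out_dir / "trials.csv", index=False)
        log.info("simulated %d subjects x %d runs x %d voxels",
                 exp.config.n_subjects, exp.config.n_runs, exp.config.n_voxels)


def stage_fit_iem(cfg: PipelineConfig, out_dir: Path, axes=("x", "z")) -> None:
    basis = cfg.basis()
    mode = cfg.iem.get("profile_mode", "delta")
    extent = cfg.iem.get("profile_extent")
    with _timed("fit-iem"):
        for axis in axes:
            frames = []
            for tm in _load_subject_trials(out_dir):
                recon = iem.crossval_reconstruct(tm, basis, axis=axis,
                                                 profile_mode=mode, extent=extent)
                frames.append(iem.average_by_position(recon).to_frame())
            pd.concat(frames, ignore_index=True).to_csv(
                out_dir / f"representations_{axis}.csv", index=False)


def stage_fit_curves(cfg: PipelineConfig, out_dir: Path, axes=("x", "z")) -> None:
    spec = cfg.fit_spec()
    grid = cfg.pixel_grid()
    with _timed("fit-curves"):
        rows = []
        for axis in axes:
            path = out_dir / f"representations_{axis}.csv"
            df = pd.read_csv(path)
            pix_cols = [c for c in df.columns if c.startswith("px_")]
            for _, rec in df.iterrows():
                curve = rec[pix_cols].to_numpy(dtype=float)
                fit = fitting.fit_representation(curve, grid, spec)
                rows.append(
                    {
                        "subject": rec["subject"],
                        "axis": axis,
                        "position": int(rec["position"]),
                        "true_coord": float(rec["true_coord"]),
                        "center": fit.params.center,
                        "size": fit.params.size,
                        "amplitude": fit.params.amplitude,
                        "baseline": fit.params.baseline,
                        "rmse": fit.rmse,
                        "stage": fit.stage,
                        "center_error": abs(fit.params.center - float(rec.true_coord)),
                    }
                )
        pd.DataFrame(rows).to_csv(out_dir / "fits.csv", index=False)


def stage_decode(cfg: PipelineConfig, out_dir: Path) -> None:
    C = cfg.decoding.get("C", 1.0)
    n_perm = cfg.decoding.get("n_perm", 0)
    q_levels = cfg.decoding.get("q_levels", [0.05, 0.01])
    scheme = decoding.pairwise_scheme()
    with _timed("decode"):
        subjects = _load_subject_trials(out_dir)
        tables = [decoding.decode_all_pairs(tm, scheme, C=C) for tm in subjects]
        df = pd.concat(tables, ignore_index=True)
        if n_perm > 0:
            pvals = []
            for k, pair in enumerate(scheme):
                real = np.array([t["dprime"].iloc[k] for t in tables])
                null = np.stack([
                    decoding.permutation_null(tm, pair.row_i, pair.row_j,
                                              n_iter=n_perm,
                                              seed=cfg.seed + 1000 + k, C=C)
                    for tm in subjects
                ])
                pvals.append(decoding.group_permutation_pvalue(real, null))
            pair_key = df.apply(lambda r: (r.pair_i, r.pair_j), axis=1)
            pmap = {(p.row_i, p.row_j): pv for p, pv in zip(scheme, pvals)}
            df["p_perm"] = [pmap[k] for k in pair_key]
            for q in q_levels:
                rej = decoding.fdr_bh(list(pmap.values()), q=q)
                rmap = {k: bool(v) for k, v in zip(pmap, rej)}
                df[f"fdr_reject_{str(q).replace('0.', '')}"] = \
                    [rmap[k] for k in pair_key]
        df.to_csv(out_dir / "decoding.csv", index=False)


def stage_group_stats(cfg: PipelineConfig, out_dir: Path) -> None:
    n_boot = cfg.stats.get("n_boot", 1000)
    ci = cfg.stats.get("ci", 95.0)
    with _timed("group-stats"):
        fits = pd.read_csv(out_dir / "fits.csv")
        rows = []
        for axis, sub in fits.groupby("axis"):
            wide = sub.pivot_table(index="subject", columns="position",
                                   values="center", sort=True)
            true = sub.groupby("position")["true_coord"].mean().to_numpy()
            dist = groupstats.bootstrap_center_slope(
                wide.to_numpy(), true, n_iter=n_boot, seed=cfg.seed + 7)
            rows.append({"axis": axis, "metric": "center_slope",
                         "estimate": float(dist.point),
                         "ci_lo": float(dist.ci_lo), "ci_hi": float(dist.ci_hi),
                         "p": groupstats.distribution_pvalue_vs_zero(dist)})
            for metric in ("center_error", "amplitude", "size", "baseline"):
                per_subj = sub.groupby("subject")[metric].mean().to_numpy()
                d = groupstats.bootstrap_subjects(per_subj, n_iter=n_boot,
                                                  seed=cfg.seed + 11, ci=ci)
                rows.append({"axis": axis, "metric": metric,
                             "estimate": float(d.point),
                             "ci_lo": float(d.ci_lo), "ci_hi": float(d.ci_hi),
                             "p": np.nan})
        dec_path = out_dir / "decoding.csv"
        if dec_path.exists():
            dec = pd.read_csv(dec_path)
            wide = dec.pivot_table(index="subject",
                                   columns=["pair_i", "pair_j"],
                                   values="dprime", sort=True)
            deltas = dec.groupby(["pair_i", "pair_j"])[
                "delta_disparity_arcmin"].mean().to_numpy()
            ss = decoding.dprime_disparity_slope(wide.to_numpy(), deltas,
                                                 n_boot=n_boot,
                                                 seed=cfg.seed + 13)
            rows.append({"axis": "z", "metric": "dprime_disparity_slope",
                         "estimate": ss.slope, "ci_lo": ss.ci_lo,
                         "ci_hi": ss.ci_hi, "p": ss.p_ttest})
            rows.append({"axis": "z", "metric": "six_way_dprime",
                         "estimate": float(dec.groupby("subject")["dprime"]
                                           .mean().mean()),
                         "ci_lo": np.nan, "ci_hi": np.nan, "p": np.nan})
        pd.DataFrame(rows).to_csv(out_dir / "group_summary.csv", index=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(cfg: PipelineConfig, out_dir: Path) -> None:
    files = sorted(p.name for p in out_dir.glob("*.csv"))
    manifest = {
        "config": asdict(cfg),
        "seed": cfg.seed,
        "files": {f: _sha256(out_dir / f) for f in files},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))


def run_pipeline(cfg: PipelineConfig, out_dir) -> Path:
    """Run every stage and write the provenance manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_simulate(cfg, out_dir)
    stage_fit_iem(cfg, out_dir)
    stage_fit_curves(cfg, out_dir)
    stage_decode(cfg, out_dir)
    stage_group_stats(cfg, out_dir)
    _write_manifest(cfg, out_dir)
    return out_dir


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def report(out_dir, plots: bool = False) -> str:
    """Human-readable summary of a result bundle; optional figure files.

    Missing tables produce a warning line and their section is omitted.
    """
    out_dir = Path(out_dir)
    lines = [f"depthiem results in {out_dir}", "=" * 40]

    fits_path = out_dir / "fits.csv"
    if fits_path.exists():
        fits = pd.read_csv(fits_path)
        for axis, sub in fits.groupby("axis"):
            lines.append(f"[{axis} axis] mean |center error| = "
                         f"{sub['center_error'].mean():.3f} scene units; "
                         f"mean amplitude = {sub['amplitude'].mean():.3f}")
    else:
        lines.append("warning: fits.csv missing; fit section omitted")

    gs_path = out_dir / "group_summary.csv"
    if gs_path.exists():
        gs = pd.read_csv(gs_path)
        for rec in gs.itertuples():
            p = "" if np.isnan(rec.p) else f", p={rec.p:.4g}"
            ci = ("" if np.isnan(rec.ci_lo)
                  else f" [{rec.ci_lo:.3f}, {rec.ci_hi:.3f}]")
            lines.append(f"[{rec.axis}] {rec.metric}: {rec.estimate:.3f}{ci}{p}")
    else:
        lines.append("warning: group_summary.csv missing; stats section omitted")

    dec_path = out_dir / "decoding.csv"
    if dec_path.exists():
        dec = pd.read_csv(dec_path)
        six = dec.groupby("subject")["dprime"].mean().mean()
        lines.append(f"[decoding] six-way mean d' = {six:.3f} over "
                     f"{dec['subject'].nunique()} subjects")
    else:
        lines.append("warning: decoding.csv missing; decoding section omitted")

    if plots:
        _write_plots(out_dir, lines)
    text = "\n".join(lines)
    (out_dir / "report.txt").write_text(text + "\n")
    return text


def _write_plots(out_dir: Path, lines: list[str]) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for axis in ("x", "z"):
        path = out_dir / f"representations_{axis}.csv"
        if not path.exists():
            continue
        df = pd.read_csv(path)
        pix_cols = [c for c in df.columns if c.startswith("px_")]
        coords = np.array([float(c[3:]) for c in pix_cols])
        fig, ax = plt.subplots(figsize=(6, 4))
        cmap = plt.get_cmap("viridis")
        for pos, sub in df.groupby("position"):
            mean_curve = sub[pix_cols].to_numpy(float).mean(axis=0)
            color = cmap(pos / 5)
            ax.plot(coords, mean_curve, color=color)
            ax.axvline(sub["true_coord"].mean(), color=color, ls=":", lw=1)
        ax.set_xlabel(f"{axis} (scene units)")
        ax.set_ylabel("representation")
        ax.set_title(f"mean model-based representations, {axis} axis")
        fig.tight_layout()
        fig.savefig(out_dir / f"representations_{axis}.png", dpi=120)
        plt.close(fig)
        lines.append(f"wrote representations_{axis}.png")

    fits_path = out_dir / "fits.csv"
    if fits_path.exists():
        fits = pd.read_csv(fits_path)
        fig, axes_ = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
        for ax_, (axis, sub) in zip(axes_, fits.groupby("axis")):
            ax_.scatter(sub["true_coord"], sub["center"], s=12, alpha=0.6)
            t = np.array([sub["true_coord"].min(), sub["true_coord"].max()])
            sl, ic = np.polyfit(sub["true_coord"], sub["center"], 1)
            ax_.plot(t, t, color="gray", lw=1)
            ax_.plot(t, sl * t + ic, "k--", lw=1)
            ax_.set_title(f"{axis}: slope {sl:.2f}")
            ax_.set_xlabel("true position")
        axes_[0].set_ylabel("fitted center")
        fig.tight_layout()
        fig.savefig(out_dir / "center_vs_true.png", dpi=120)
        plt.close(fig)
        lines.append("wrote center_vs_true.png")

    dec_path = out_dir / "decoding.csv"
    if dec_path.exists():
        dec = pd.read_csv(dec_path)
        fig, ax = plt.subplots(figsize=(5, 4))
        grp = dec.groupby("delta_disparity_arcmin")["dprime"].mean()
        ax.plot(grp.index, grp.values, "o-")
        ax.set_xlabel("disparity difference (arcmin)")
        ax.set_ylabel("mean d'")
        fig.tight_layout()
        fig.savefig(out_dir / "dprime_vs_disparity.png", dpi=120)
        plt.close(fig)
        lines.append("wrote dprime_vs_disparity.png")
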