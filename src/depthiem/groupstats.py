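"""Group-level statistics: subject-wise bootstrap and recovery slopes.

Variability across the (small) subject sample is estimated by resampling
subjects with replacement, the standard approach when only a handful of
subjects is available. Accuracy of the encoding-model representations is
summarised by the ordinary least-squares slope of fitted representation
centers on true stimulus coordinates: slope 1 means the representations
track the stimulus perfectly, slope 0 means they carry no positional
information.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "BootstrapDistribution",
    "bootstrap_subjects",
    "center_vs_true_slope",
    "bootstrap_center_slope",
    "distribution_pvalue_vs_zero",
    "pairwise_group_diff",
]


@dataclass
class BootstrapDistribution:
    """Resampled statistic values plus point estimate and percentile CI."""

    values: np.ndarray      # (n_iter, ...) statistic per resample
    point: np.ndarray       # statistic on the original sample
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_iter: int
    seed: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.point = np.asarray(self.point, dtype=float)


def bootstrap_subjects(
    per_subject_values,
    statistic: Callable[[np.ndarray], np.ndarray] | None = None,
    n_iter: int = 1000,
    seed: int = 0,
    ci: float = 95.0,
) -> BootstrapDistribution:
    """Bootstrap a statistic over subjects.

    ``per_subject_values`` has subjects on axis 0; each iteration draws
    n subjects with replacement and applies ``statistic`` (default: mean
    over subjects). The CI is the percentile interval at ``ci``%.
    """
    vals = np.asarray(per_subject_values, dtype=float)
    if vals.shape[0] < 1:
        raise ValueError("at least one subject required")
    if statistic is None:
        statistic = lambda v: np.mean(v, axis=0)
    n_subj = vals.shape[0]
    rng = np.random.default_rng(seed)
    draws = [
        np.asarray(statistic(vals[rng.integers(0, n_subj, size=n_subj)]))
        for _ in range(n_iter)
    ]
    values = np.stack(draws)
    point = np.asarray(statistic(vals))
    alpha = (100.0 - ci) / 2.0
    lo = np.percentile(values, alpha, axis=0)
    hi = np.percentile(values, 100.0 - alpha, axis=0)
    return BootstrapDistribution(values=values, point=point, ci_lo=lo, ci_hi=hi,
                                 n_iter=n_iter, seed=seed)


def center_vs_true_slope(fit_centers, true_positions) -> tuple[float, float]:
    """OLS line of fitted centers on true stimulus coordinates."""
    c = np.asarray(fit_centers, dtype=float)
    t = np.asarray(true_positions, dtype=float)
    if len(np.unique(t)) < 2:
        raise ValueError("need at least two distinct true positions")
    slope, intercept = np.polyfit(t, c, 1)
    return float(slope), float(intercept)


def bootstrap_center_slope(
    per_subject_centers,
    true_positions,
    n_iter: int = 1000,
    seed: int = 0,
) -> BootstrapDistribution:
    """Bootstrap the center-vs-true slope across subjects.

    ``per_subject_centers`` is (n_subjects, n_positions); each iteration
    resamples subjects, averages their fitted centers per position and
    fits a line against the true coordinates.
    """
    centers = np.atleast_2d(np.asarray(per_subject_centers, dtype=float))
    true = np.asarray(true_positions, dtype=float)

    def stat(v):
        return center_vs_true_slope(v.mean(axis=0), true)[0]

    return bootstrap_subjects(centers, statistic=stat, n_iter=n_iter, seed=seed)


def distribution_pvalue_vs_zero(dist: BootstrapDistribution | np.ndarray) -> float:
    """Min of the two tail proportions of a resampled distribution vs zero."""
    values = dist.values if isinstance(dist, BootstrapDistribution) else np.asarray(dist)
    if values.size == 0:
        raise ValueError("empty distribution")
    return float(min(np.mean(values <= 0), np.mean(values >= 0)))


def pairwise_group_diff(
    dist_a: BootstrapDistribution,
    dist_b: BootstrapDistribution,
) -> float:
    """Two-tail min-proportion p for a difference of paired bootstrap
    distributions (same iteration count and seed pairing).

    Exact zeros (e.g. comparing a distribution with itself) are split
    between the tails, so identical distributions give p = 0.5.
    """
    if dist_a.n_iter != dist_b.n_iter:
        raise ValueError("bootstrap distributions have mismatched iteration counts")
    diff = dist_a.values - dist_b.values
    ties = np.mean(diff == 0)
    return float(min(np.mean(diff < 0), np.mean(diff > 0)) + 0.5 * ties)
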