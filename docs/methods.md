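# Methods

`depthiem` implements a complete, simulation-backed version of a
population-code analysis for stimulus position in depth: stereoscopic
stimulus geometry, a generative model of voxel responses, an inverted
encoding model (IEM) for the horizontal (x) and depth (z) scene axes,
constrained curve fits of the recovered representations, pairwise d'
decoding with permutation inference, and subject-wise bootstrap group
statistics. This note records the models, the defaults and why they were
chosen, and what the synthetic data can and cannot establish.

## Stimulus geometry

The scene is rendered in arbitrary "scene units" with the viewer's eyes at
x = ±0.4 in the fixation plane and fixation at distance D = 10 straight
ahead; z = 0 is the fixation plane and positive z is nearer. Relative
binocular disparity of a point (x, z) is the vergence-demand difference

    δ(x, z) = 2 atan(e/D) − [atan((x+e)/(D−z)) − atan((x−e)/(D−z))],

with e = 0.4, expressed in arcminutes; crossed (near) disparity is
negative. On axis this gives −48.44 arcmin at the nearest depth row
(z = +1.5) and +35.82 arcmin at the farthest (z = −1.5). Eccentricity is
measured from the cyclopean point to the target's depth plane,
atan(|x|/(D−z)).

The 36 stimulus locations form a staggered triangular grid: six depth rows
at z ∈ {−1.5, −0.9, −0.3, 0.3, 0.9, 1.5} crossed with six horizontal
columns per row. The exact horizontal offsets of the original display are
not published; the default layout places twelve evenly spaced *angular*
columns spanning ±9.8° of eccentricity, with alternate depth rows taking
alternate column subsets (a half-spacing stagger), and converts angle to
scene units per row via x = (D−z)·tan(angle). This choice is not
arbitrary: it reproduces the published eccentricity range (innermost
column 0.89°, outermost 9.8°), makes the union of a grid and its
horizontal mirror exactly 72 distinct locations, and — as an independent
check — yields per-row mean disparities of (38.6, 25.6, 11.0, −5.3,
−23.7, −44.8) arcmin, within 0.2 arcmin of the published design values
(38.6, 25.6, 11.1, −5.2, −23.6, −44.6). Those published row averages, not
the layout-dependent recomputed ones, are used as the canonical disparity
separations in the decoding module.

The rendered sphere radius is scaled linearly in viewing distance between
the two published anchors (0.73 scene units at d = 11.5, 0.55 at d = 8.5)
so that apparent size is constant across depth; the two published angular
radii (3.4°/3.6°) are mutually inconsistent under simple tangent scaling,
which is why anchored interpolation is used rather than a single angular
constant.

## Generative model of voxel responses

Each simulated voxel carries non-negative half-normal weight vectors over
six generative channels per axis (the same exponentiated-cosine family the
analysis uses, unless configured otherwise). Its mean response to a trial
at (x, z) is w_x·f(x) + w_z·f(z); trial noise is i.i.d. Gaussian with
per-voxel standard deviation expressed as a multiple of that voxel's peak
mean response over the grid (`noise_scale`). Null trials are pure noise.

Defaults emulate the study design: 9 subjects, 13 runs, 60 voxels, 36
stimulus trials (each grid cell once, order shuffled) plus 9 interleaved
null trials per run, with the grid horizontally mirrored on even-numbered
runs. Trial order depends only on (subject, run), so changing the seed
changes noise and tuning but not labels. The published description is
internally inconsistent about whether even- or odd-numbered runs were
mirrored; the mirror parity is a config flag (`mirror_even_runs`, default
true).

The default `noise_scale = 2.0` was calibrated once so that six-way depth
decoding d' on default synthetic data lands near 0.4, inside the 0–0.6
range a real experiment of this kind produces; it is a modelling choice,
not an empirical fact about cortex. The parameter-recovery analyses use
`noise_scale = 0.5` (a high-SNR regime) because their purpose is to verify
the machinery, not to mimic empirical effect sizes.

Optionally, trial responses can be rendered as BOLD-like time series: each
trial's amplitude drives a 3-s boxcar convolved with a canonical
double-gamma HRF (response peak 5 s, undershoot peak 15 s, amplitude
ratio 6, unit dispersions), sampled at TR = 2 s over 300-s runs (150
volumes), plus optional linear drift and white noise. Inter-trial
intervals are drawn from U(2, 6) s and affinely rescaled above the 2-s
floor so the 45 events plus 2-s lead-in and 10-s tail fill the run
exactly; this keeps the printed run length while preserving jitter. Trial
estimates are re-extracted exactly as defined for the real data: z-score
each voxel within the run, then average the volumes 3 and 4 acquisitions
after the last volume at or before stimulus onset (≈4–8 s post-onset).

## Inverted encoding model

Six channels tile each axis. The basis function is
f(r) = (0.5 cos(rπ/s) + 0.5)^7 for |r| < s and 0 elsewhere. Channel
centers and size are not published; defaults place centers at the six
stimulus row coordinates (−1.5 … 1.5, spacing 0.6) with s = 1.8, giving
adjacent-channel overlap 0.75^7 ≈ 0.13 at one spacing. Both are
configurable, and the unit tests exercise a range of sizes. The pixel grid
is 111 points over [−2.75, 2.75] (spacing 0.05, matching the fit search
range), and the default stimulus profile is a delta at the nearest pixel;
a boxcar of the sphere's radius is available by config.

Weights are the least-squares solution of B1 = W·X1 computed as
W = B1·pinv(X1). (The textbook normal-equations form written with the
trials×trials Gram matrix is singular whenever trials exceed channels;
the Moore–Penrose pseudoinverse gives the intended minimum-norm
solution.) Inversion on held-out data is X2 = (WᵀW)⁻¹Wᵀ·B2, which
requires at least as many voxels as channels and a full-column-rank W;
rank deficiencies raise errors naming the offending channels. Training
and testing follow leave-one-run-out cross-validation so every trial is
reconstructed exactly once from independent data. For the x axis, curves
from mirrored runs are reflected about the domain midpoint and their
column labels and coordinates mapped back to the unmirrored layout before
averaging into six per-position representations; depth rows need no such
correction.

Because the columns of a triangular grid sit at slightly different x per
row, an x "position" is a column group whose true coordinate is the mean
scene x of its trials; this blurs x representations slightly relative to
the z case, where every trial in a row shares one exact z.

## Curve fitting

Each representation is fit with f(x) = b + a(0.5 cos(|x−c|π/s) + 0.5)^7.
Stage one is an exhaustive grid over centers −2.75…2.75 and sizes
1.5…15, both in steps of 0.1 (note the center lattice therefore sits at
…−0.05, 0.05, 0.15… offsets). At each (c, s) the box-constrained linear
subproblem for (a, b) — a ∈ [0, max−min of the curve], b ∈ [−5, 5] — is
solved in closed form: unconstrained least squares, then clamp the
offending coordinate and re-solve the other, which is exact for a
two-parameter box problem. Ties in RMSE break lexicographically (smallest
center, then size). Stage two refines all four parameters with L-BFGS-B,
c and s each confined to ±0.1 of the grid optimum; the refined fit is
kept only if its RMSE is no worse. The refinement objective is the mean
squared error (same argmin as RMSE but smooth at zero residual, where the
square root's gradient is singular).

Known limitation: when the true center lies near the edge of the fitting
domain and the size is large, the peak is truncated and (c, s) become
nearly degenerate; the grid can then lock onto a neighbouring lattice
point whose ±0.1 refinement box excludes the truth, leaving center errors
of order 0.01 scene units. Within the identifiable regime (centers in the
stimulus range, sizes ≤ ~6) noiseless recovery is better than 0.006.

## Decoding

Each of the 15 unordered pairs of depth rows is decoded with a linear
maximum-margin classifier (C = 1) under leave-one-run-out
cross-validation, collapsing across horizontal position within a row.
Voxel features are standardized with training-fold statistics. Pooled
test predictions are scored as d' = Φ⁻¹(HR) − Φ⁻¹(FAR) with rates clipped
to [1/2N, 1 − 1/2N]; the mean of the 15 pairwise values is the six-way
score. The permutation null shuffles the pair's row labels across trials
(run structure fixed) and repeats the full decode; the group-level p is
the minimum of the two tail proportions comparing the subject-mean real
d' with the subject-mean null distribution, reported un-doubled (a
doubling option exists but is off by default). Benjamini–Hochberg FDR is
applied over the flattened table of pairwise p values. The d'/disparity
relationship is summarised by an ordinary least-squares slope of d' on
the pairs' disparity separations, bootstrapped over subjects, with both a
t test of the slope distribution against zero (as in the original
procedure, despite its unconventional use of a bootstrap distribution in
a t test) and the proportion-based alternative reported.

## Group statistics

Subject-level variability is estimated by resampling subjects with
replacement (default 1000 iterations) with percentile 95% CIs; the
bootstrap variant behind the published intervals is unstated, and
percentile is the simplest defensible choice. Representation accuracy is
the OLS slope of fitted centers on true coordinates (1 = perfect
tracking, 0 = no positional information), fit once per bootstrap
iteration; p values against zero use the min-of-tails rule, and paired
bootstrap differences split exact ties between tails so identical
distributions give p = 0.5.

## What the synthetic tests do and do not show

Passing tests establish that every computational stage is correct: the
algebra matches independent least-squares oracles to 1e−10, noiseless
round trips are exact, the fitter recovers planted parameters, decoding
recovers planted class structure, and d' grows with disparity separation
when the generative tuning makes nearby depths more similar. They do not
establish anything about real cortex: the generator uses i.i.d. Gaussian
noise (no physiological or spatially correlated noise), additive
separable x/z tuning (no joint receptive fields or attention effects),
noise levels chosen by calibration rather than measurement, and no
vergence drift — the mechanism suspected of flattening empirical depth
slopes. Recovery slopes just below 1 here reflect basis-edge compression
and column-group blurring, not the physiological effects that dominate
real data.

## Problem sizes and determinism

Every stochastic operation is a pure function of its inputs and an
integer seed (NumPy `SeedSequence` spawning per subject and run), and the
pipeline writes a manifest of config and content hashes; identical
configs give byte-identical tables. The bundled verification runs use a
9-subject × 12-run × 60-voxel experiment for slope recovery, twenty
3-subject × 10-run replicates for the d'/disparity monotonicity check,
100-curve samples for fit recovery, and 100 random small instances for
the algebra oracles — sizes chosen to exercise the full design while
keeping a complete run in the low minutes on one CPU.
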