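# depthiem

Inverted encoding models and d′ decoding for stimulus position **in
depth**, on simulated fMRI voxel populations.

When an observer views a stereoscopic stimulus, its depth must be
inferred from binocular disparity — the small angular difference between
the two eyes' images. Visual-cortex voxels carry graded selectivity for
position along both the horizontal (x) and depth (z) axes, and two
complementary multivariate analyses can quantify that selectivity:

* an **inverted encoding model (IEM)**: each voxel's trial response is
  modelled as a weighted sum of six spatial "channels" — exponentiated
  cosines `f(r) = (0.5 cos(rπ/s) + 0.5)^7` tiling one scene axis — via
  `B₁ = W X₁`, with `X₁ = F S` built from a pixel representation of each
  stimulus. Weights are estimated by least squares (`Ŵ = B₁ pinv(X₁)`)
  on training runs and inverted on held-out runs
  (`X̂₂ = (ŴᵀŴ)⁻¹ Ŵᵀ B₂`) to reconstruct a pixel-space representation of
  the viewed position, which is then fit with
  `f(x) = b + a(0.5 cos(|x−c|π/s) + 0.5)^7` by exhaustive grid search
  plus bounded refinement;
* **pairwise decoding**: a linear max-margin classifier discriminates
  every pair of the six depth rows under leave-one-run-out
  cross-validation, scored as `d′ = Φ⁻¹(HR) − Φ⁻¹(FAR)`, with
  label-shuffling permutation nulls, Benjamini–Hochberg FDR, and a
  bootstrapped regression of d′ on the pair's disparity separation.

Because real BOLD data is not required, the package ships a fully
specified synthetic-data generator that emulates the study design
(9 subjects, 13 runs of 36 stimulus + 9 null trials on a staggered
36-location x–z grid, mirrored on alternate runs, optional HRF-convolved
time series at TR = 2 s) with known ground-truth tuning, so every stage
is verifiable against planted parameters. It is aimed at researchers who
want to prototype, validate or teach population-code analyses of depth
encoding.

## Worked example

Write a config and run the pipeline (3 subjects, 8 runs, 40 voxels,
trial noise at 0.5× each voxel's peak response):

```yaml
# example.yaml
seed: 7
simulation: {n_subjects: 3, n_runs: 8, n_voxels: 40, noise_scale: 0.5}
decoding:   {n_perm: 100}
stats:      {n_boot: 1000}
```

```bash
depthiem run-all --config example.yaml --out-dir example_run
depthiem report --out-dir example_run
```

prints

```
[x axis] mean |center error| = 0.083 scene units; mean amplitude = 0.668
[z axis] mean |center error| = 0.022 scene units; mean amplitude = 0.861
[x] center_slope: 0.903 [0.881, 0.916], p=0
[z] center_slope: 0.976 [0.975, 0.977], p=0
[z] dprime_disparity_slope: 0.012 [0.010, 0.016], p=0
[z] six_way_dprime: 2.129
[decoding] six-way mean d' = 2.129 over 3 subjects
```

Reading this: the fitted centers of the model-based representations track
the true stimulus coordinates with slope 0.90 (x) and 0.98 (z) — slope 1
would be perfect tracking, 0 no positional information — with bootstrap
95% CIs in brackets and min-tail p values against zero. Mean absolute
center error is 0.08/0.02 scene units, and d′ rises by 0.012 per
arcminute of disparity separation between the decoded depth rows. The
six-way d′ of 2.1 reflects this high-SNR demo setting; the generator's
default noise (`noise_scale: 2.0`) is calibrated to a realistic
six-way d′ ≈ 0.4. All tables (grid, trial matrices, reconstructions,
fits, decoding, group summaries) land in `example_run/` as CSV with a
provenance manifest; `depthiem report --plots` additionally writes
representation, center-vs-true and d′-vs-disparity figures.

Stages can also run individually (`depthiem simulate | fit-iem |
fit-curves | decode | group-stats`) on a shared `--out-dir`, and
everything is importable as a library (`depthiem.iem`,
`depthiem.fitting`, `depthiem.decoding`, ...).

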