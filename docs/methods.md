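# Methods

## The FWHM edge model

A vessel cross-section on an OCT B-scan is modelled, along a scan line
through its centre, as five intensity plateaus — perivascular tissue, dark
near wall, lumen, dark far wall, tissue — joined by monotone flanks. The
full-width-at-half-maximum rule places a boundary where a flank crosses the
midpoint between the local extremes. The estimator is deliberately simple
and noise-tolerant:

1. **Trough detection.** Local minima of the 3-sample moving mean of the
   profile are candidate walls; a candidate qualifies if its prominence
   (crest-to-minimum contrast) reaches `min_contrast` (default 10 intensity
   units on the 8-bit scale). The two most prominent qualifying minima at
   least `min_separation_um` apart (default 5 µm) are the walls; the lumen
   crest between them splits the profile into two trough segments.
2. **Flank extremes.** Within a trough segment the minimum is the smallest
   mean of three consecutive samples; on each flank the crest is the largest
   such mean between the trough minimum and the flank's bound (profile end,
   or the neighbouring trough's minimum when both walls are measured). The
   half level is the arithmetic midpoint `(crest + minimum)/2`, computed per
   side because the tissue and lumen crests generally differ.
3. **Edge localisation.** Among all runs of `k` consecutive samples on the
   flank (default `k = 3`, matching the granularity of the 3-sample
   averaging; ties resolved to the leftmost run for determinism), the run
   with the largest endpoint difference is fitted by least squares; the edge
   is the continuous position where that line crosses the half level. The
   crossing may extrapolate beyond the run but must stay inside the flank,
   otherwise a typed `EdgeOutOfFlank` error is raised.

Positions are continuous micrometre coordinates (sample *i* at
`origin + i·spacing`); degenerate inputs (flat flanks, zero slopes, missing
troughs) raise typed errors rather than returning NaN, so the quality layer
can log an explicit reason for every rejected image.

Exact symmetries, enforced by tests: translation equivariance, invariance
under affine intensity maps `a·I + b` (a > 0), reflection symmetry, and
resolution invariance on noiseless input.

### Sampling condition

The 3-sample machinery needs three samples on the wall plateau and three on
each flank ramp to be unbiased. For a wall band of thickness WT, ramp
half-width r and sample spacing Δ this requires roughly `2r ≥ 2Δ` and
`WT − 2r ≥ 2Δ`, i.e. **WT ≥ 4Δ**. Below that the trough minimum is
over-estimated by plateau/ramp mixing and the half level shifts; on a
phantom with WT = 3 µm sampled at 1 µm the inner-edge bias is ~0.17 µm and
no choice of ramp width or grid alignment removes it (verified by exhaustive
scan). The segmentation-oracle tests therefore run over the phantom grid
restricted to resolvable combinations; clinically the protocol's "only
images that clearly show the wall" filter plays the same role.

## Measurement protocol

Each vessel is measured on several images (five in the strict protocol),
each image three times; repeats are averaged per image and images averaged
with equal weight. Quality control rejects attempts whose trough detection
failed, whose flank contrast falls below `min_contrast`, or whose boundary
ordering is invalid. Morphometry is computed per patient and then averaged
across patients (the mean of per-patient WCSA is not the WCSA of the mean
diameters — a Jensen gap the pipeline preserves by design). `pi_mode`
selects exact π (default) or the 2-decimal 3.14 used in the reference
tables; the identity `WCSA = π_c·WT·(LD + WT)` holds exactly in either mode.

## Cohort statistics

Group comparisons use two-sample t-tests — pooled (Student) or Welch, with
an `auto` mode that applies a Levene test (centre = mean, α = 0.05) on
samples or a two-sided F-ratio test on summaries. The reference study's
arteriolar rows are numerically consistent with the pooled variant and its
venular rows with Welch; the reproduction harness pins the variant per row
accordingly. Sex uses a Pearson chi-square without continuity correction
(df = 1). Correlations and regressions are computed within the DR group
only (n = 65): the printed p-values of the printed r values are consistent
with df = 63 (e.g. r = 0.271 → p = 0.029). Backward elimination starts from
the full OLS model (stage, duration, age), repeatedly drops the predictor
with the largest p ≥ 0.05, and reports the reduced model; predictors with
numerically negligible contribution (relative to the response scale) are
treated as non-significant so that exact fits eliminate cleanly. Two-sided
p-values throughout, no multiple-testing correction (none is applied in the
reference analysis).

## Synthetic data

**Phantoms.** Piecewise-constant plateaus (defaults tissue 200, wall 50,
lumen 120 on the 8-bit scale — wall/tissue contrast 150) joined by linear
ramps of half-width 1 µm centred on the true boundaries. The analytic edge
is the ramp midpoint, which the FWHM crossing equals exactly in the
noiseless case — the module's oracle. Optional additive zero-mean Gaussian
noise (acquisition noise); multiplicative speckle, shadowing and retinal
layering are *not* modelled, so passing tests demonstrate estimator
correctness and noise tolerance, not performance on real OCT texture. The
2D renderer revolves the radial profile into concentric rings and supplies a
scan line through the centre perpendicular to the requested vessel axis.

**Cohorts.** 75 NDR + 65 DR patients by default, matching the reference
cohort, with sex fractions, age and BMI distributions, and the DR-stage
distribution (37/11/11/4/2 over stages I–V; stage VI absent) taken from the
published summaries. Vessel geometry samples LD and WT and derives
OD = LD + 2·WT, guaranteeing validity and the WT identity; LD–WT
correlation defaults to 0 (no joint distribution is published). Diabetes
duration is not summarised in the reference tables; the default
Normal(10, 5) years truncated at 0.5 is an invented but plausible T2DM
value, configurable. Two presets:

- `table_matched` — LD and WT per group from the published means ± SD
  (truncated normal). Note the published DR arteriolar row is internally
  inconsistent (128.80/147.01/18.29 violate OD = LD + 2·WT), so the
  generating OD mean is 165.38 µm, not the printed 147.01 µm; recovery
  tests compare against generating moments.
- `regression_matched` — DR-group LD and WT follow the published
  stage-regression equations with residual SD solved from the printed R²
  (`σ² = b²·var(stage)(1−R²)/R²`); the venular LD row follows the equation
  slope 20.632 (the printed coefficient column's 33.287 contradicts its own
  equation). The two presets are deliberately distinct because the printed
  group means and the printed regressions cannot both be matched.

**End-to-end mode.** `generate_cohort(..., measure_from_profiles=True)`
renders 5 images × 3 repeats per vessel with noise SD 5 and obtains each
patient's diameters through the full detection → edges → QC → aggregation
path (each repeat is an independently re-acquired noisy profile, since
re-measuring a fixed profile with a deterministic algorithm is a no-op).
Patient-truth sampling and rendering noise use separate seeded streams, so
the same seed yields identical truths with and without measurement; the
resulting mean measurement error is below 0.15 µm. Problem sizes used by
the tests — a full 140-patient measured cohort per seed, 20 seeds for the
direction/significance study, 100 noise replicates, 5 000 draws for the
regression-preset check — keep the whole suite around a minute on one CPU.

Statistical power note: with the published group sizes and SDs the venular
LD comparison has expected |t| ≈ 2.5 and hence ≈ 70 % power at α = 0.05, so
its per-seed significance is *not* expected to reproduce in ≈ 90 % of
seeds; the recovery tests assert its direction, and per-seed significance
only for rows whose generating effect size gives ≥ 95 % power.

## Known limitations

- 1D profiles and circular cross-sections only: no vessel tracking,
  multi-vessel profiles, or elliptical walls.
- Additive noise only; no OCT speckle statistics.
- The upper-wall/tissue ambiguity seen in real B-scans (wall merging with
  the retinal surface) is emulated only as a low-contrast rejection case.
- Scan-line placement, perpendicularity and artery/vein identity are
  caller-supplied metadata, never inferred.
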