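# octmorph

Sub-pixel retinal vessel morphometry on OCT densitometric line profiles.

On a spectral-domain OCT B-scan a retinal vessel cross-section shows two dark
wall bands flanking the lumen. Along a scan line drawn through the vessel,
the intensity profile therefore has two concave-upward troughs. `octmorph`
implements full-width-at-half-maximum (FWHM) segmentation of such profiles:
for each wall trough it estimates the crest and minimum as 3-sample moving
means, sets the half level to their midpoint, fits a least-squares line
through the steepest run of samples on each flank, and takes the wall edge at
the sub-pixel position where that line crosses the half level. The inner
edges of the two troughs delimit the lumen diameter (LD), the outer edges
the outer diameter (OD), and from the aggregated diameters

    WT   = (OD − LD) / 2
    WLR  = (OD − LD) / LD
    WCSA = π (OD² − LD²) / 4

give wall thickness, wall-to-lumen ratio and wall cross-sectional area.

On top of the measurement layer the package provides the cohort analysis of
an NDR-vs-DR study design (type-2 diabetes without / with diabetic
retinopathy): pooled and Welch two-sample t-tests, a sex chi-square,
within-DR Pearson correlations against age, retinopathy stage and diabetes
duration, and multivariate linear regression with backward elimination. A
synthetic module generates ground-truthed vessel phantoms (1D profiles and
2D cross-section images) and whole patient cohorts calibrated to the
published group summaries of the reference clinical cohort, so the entire
pipeline is testable end-to-end with known truth.

Intended users: researchers working on densitometric vessel measurement and
anyone needing a reproducible, fully synthetic test bed for FWHM-style edge
detection and cohort morphometry statistics.

## Worked example

```python
from octmorph import measure_profile, MorphometricParams
from octmorph.synthetic import SyntheticVesselTruth, render_profile

truth = SyntheticVesselTruth(center_um=30, ld_true_um=20, od_true_um=30)
profile, boundaries = render_profile(truth, spacing_um=1.0)
m = measure_profile(profile)
print(boundaries)                      # (15.0, 20.0, 40.0, 45.0)
print(round(m.ld_um, 3), round(m.od_um, 3))   # 20.0 30.0
print(MorphometricParams.from_diameters(m.od_um, m.ld_um))
# MorphometricParams(wt_um=5.000..., wlr=0.5000..., wcsa_um2=392.69...,
#                    pi_mode='exact')
```

The measured LD/OD equal the phantom truth because on a noiseless
linear-ramp phantom the FWHM crossing is analytically the ramp midpoint;
with additive noise (SD 5 at wall contrast 150) the mean absolute LD error
stays near 0.13 µm.

The numbered drivers under `analysis/` run the full study on synthetic
cohorts and write their tables under `results/`:

```
python analysis/01_simulate_cohort.py        # truth-level cohorts (75 NDR + 65 DR)
python analysis/02_measure_cohort.py         # render + FWHM-measure every vessel
python analysis/03_cohort_report.py          # group comparisons, correlations, regressions
python analysis/04_reproduce_reference_stats.py  # recompute printed t / chi2 values
```

For example, `04_reproduce_reference_stats.py` recomputes the arteriolar LD
pooled t as −5.214 and the sex chi-square as 2.875 from the packaged group
summaries, matching the reported values to three decimals, and prints the
venular wall thickness implied by the DR group-mean diameters,
(180.20 − 146.17)/2 = 17.015 µm, against the reported 17.01 µm.

There is also a CLI: `octmorph simulate|measure|cohort|reproduce --help`.

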