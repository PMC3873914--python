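# dscnorm

**DSC-MRI perfusion quantification and reference-region normalization
analysis on synthetic cohorts with known ground truth.**

Group studies of cerebral blood flow (CBF) measured with dynamic
susceptibility contrast (DSC) MRI face a basic obstacle: inter-subject
variability in absolute perfusion values is enormous (coefficients of
variation of 40–50%), swamping the 10–20% regional differences that
distinguish, say, patients with early Alzheimer's disease (AD) from healthy
controls.  The standard remedy is *intensity normalization*: dividing every
regional value by the mean of a reference region assumed free of disease
bias.  But the choice of reference — cerebellum, whole-brain white matter
(WM), or whole-brain cortical gray matter (cGM) — changes which group
differences a study can detect.

`dscnorm` implements the full analysis chain needed to study this question
quantitatively, together with a synthetic phantom generator that emulates
the statistical structure of a three-group clinical cohort (controls,
stable mild cognitive impairment, mild AD), so that every result can be
checked against known ground truth.

## What it computes

**Quantification** (`dscnorm.dsc_quant`).  From a 4D bolus-passage signal
S(t), with baseline S₀ estimated from the pre-bolus frames:

- concentration conversion C(t) = −(k/TE) · ln(S(t)/S₀);
- per-voxel gamma-variate fit C(t) = K·(t−t₀)^α·exp(−(t−t₀)/β) by the
  linearization method (log-domain least squares with a search over the
  arrival time t₀), which denoises the first pass and excludes
  recirculation;
- automatic arterial-input-function (AIF) detection from the fitted
  curves' arrival time, peak height and bolus width;
- truncated-SVD deconvolution of the tissue curves by the AIF on the
  lower-triangular Toeplitz convolution matrix, giving the flow-scaled
  residue function CBF·R(t); CBF is its maximum.

**ROI analysis** (`dscnorm.roi_norm`).  Mean CBF per labelled region,
voxel-weighted aggregation of gyri into hemisphere lobes, the three
reference values (cerebellum mean, WM mean, cGM = unweighted average of
lobe means), and per-subject ratio normalization.

**Group statistics** (`dscnorm.group_stats`).  One-way ANOVA per region,
Dunnett's many-to-one comparisons against the control group (deterministic
quadrature of the multivariate-t rectangle probability), Cohen's d,
coefficients of variation, a two-way random-effects variance decomposition
(diagnosis group vs normalization method), and an age-covaried ANCOVA for
volumetric comparisons.

**Phantom** (`dscnorm.phantom`).  Synthetic cohorts on the acquisition grid
of a 1.5 T echo-planar protocol (TR = 1.439 s, TE = 30 ms, 40 frames, 6
pre-bolus frames): per-region ground-truth CBF, one lognormal global
perfusion factor per subject (~45% CV), small independent regional
fluctuations (~6% CV), Gaussian scanner noise, and group-specific regional
effects (bilateral parietal −15% and right medial temporal +12% in the AD
group).  A 20/15/28 control/MCI/AD cohort is the default.

## Worked example

Run the full pipeline (simulate → quantify → extract → normalize →
compare) on a small nine-subject cohort:

```python
import pandas as pd
from dscnorm import RunConfig, make_fixtures, run_pipeline

cfg = RunConfig(cohort=make_fixtures("tiny", seed=5), seed=5)
rundir = run_pipeline(cfg, "demo_run")
print(pd.read_csv(rundir / "cv_table.tsv", sep="\t").round(2).to_string(index=False))
```

```
            lobe  cv_absolute  cv_cer  cv_wm  cv_cgm
         frontal        47.03    9.19  12.75    5.13
        parietal        54.27   15.06  18.91   10.65
temporal_lateral        49.25    9.23  11.97    7.24
 temporal_medial        47.34   10.49  13.81    8.34
       occipital        47.88   10.28  15.68    6.27
```

Absolute CBF values vary by ~50% across subjects; after normalization the
variability collapses to single digits, and cortical-GM normalization
yields the lowest CV in every lobe — the mechanism that makes normalized
group comparisons possible at all.  The accompanying
`group_comparisons.tsv` holds, per region and normalization, the ANOVA
F/p, Dunnett p values versus controls and effect sizes; at this tiny
cohort size the AD parietal effect shows a large negative effect size
(d ≈ −1.7 for the right parietal lobe under cGM normalization) but is not
yet significant — detection needs the study-sized cohort, as the
simulation studies below show.

The same stages are available as a CLI:

```bash
dscnorm run-all --config config.yaml --out run_dir
dscnorm quantify --pwi sub_pwi.nii.gz --mask mask.nii.gz --out cbf.nii.gz
```

## Limitations

The phantom uses block geometry with pre-aligned labels: registration
error, partial-volume effects, motion, recirculation and arterial signal
saturation are not modelled, so results quantify the behaviour of the
analysis chain itself, not of any specific scanner or population.  CBF is
reported in relative units; absolute calibration (hematocrit, tissue
density, proportionality constant k) is out of scope.  See
`docs/methods.md` for the model details and design choices.
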