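# Methods

## Forward model

A subject's voxel time series is generated by the standard single-pass
tracer-kinetic model of bolus-tracking MRI.  The arterial concentration is
a gamma-variate

    C_a(t) = K (t − t0)^α exp(−(t − t0)/β),   t > t0,

with defaults K = 25, α = 3, β = 1.5 s, t0 = 10 s on a 40-frame grid with
TR = 1.439 s and 6 pre-bolus baseline frames.  Tissue concentration follows
the convolution model

    C_m(t) = CBF_eff · (C_a ⊛ R)(t),

with the discrete convolution step equal to TR and a residue function R
that is either exponential, R(t) = exp(−t/MTT) (default; MTT = 4 s for
gray matter and cerebellum, 6 s for white matter), or a boxcar of width
MTT.  Tissue bolus arrival lags the artery by 2 s (`bolus_delay`).
Signal is obtained from the T2* model

    S(t) = S0 · exp(−TE · C(t) / k),     TE = 30 ms,  k = 1,

plus Gaussian noise with SD equal to `signal_noise_sd` (default 1%) of the
regional baseline S0 = 100.

Ground-truth CBF values are kept in the relative units on which the
reference regions are conventionally tabulated (cortical lobes ≈ 0.11,
cerebellum 0.30, white matter 0.07).  Because such relative values are not
rates, the kinetic simulation multiplies them by a fixed `flow_scale`
(default 0.2 s⁻¹ per relative unit), chosen so that tissue blood volumes
and first-pass signal drops are physiological (≈ 20% peak drop in
cortical GM, > 90% in the artery, artery brighter than any tissue).  The
scale cancels in every ratio the analysis uses.

## Inter-subject variability

Each subject draws one *global perfusion factor* and one *regional factor
per region*, both lognormal with mean 1 and exact coefficients of
variation `global_cv` (default 45%) and `regional_cv` (default 6%).  The
lognormal choice guarantees positivity and makes ratio normalization
behave multiplicatively.  The global factor multiplies every tissue
region of the subject — it is exactly the nuisance that reference-region
normalization is designed to cancel; the regional factors are independent
across regions and set the floor that normalization cannot remove.  The
arterial input is not modulated by either factor: it is the input, not the
flow.  Group effects are fixed per-region multipliers; the defaults encode
the AD pattern (parietal ×0.85 bilaterally, right medial temporal ×1.12)
and no MCI effect.  Ages are drawn from N(73, 7²) truncated at 60 years
and are used only by the ANCOVA stage.

With this structure the expected CV of an absolute regional value is
√(global² + regional²) ≈ 45.4%, the CV of a value normalized by a
single-region reference (cerebellum, WM) is ≈ √2·regional ≈ 8.5%, and the
CV after cGM normalization is ≈ regional·√(1 − 1/L) ≈ 5.7% for L = 10
lobes, because averaging many lobes makes the reference itself nearly
noise-free.  This is the entire mechanism behind the empirical CV ordering
(cGM < cerebellum ≈ WM) that the simulations reproduce; it requires no
tuned coupling between regions.

## Phantom geometry and the region-level simulator

The phantom is a parameterized block layout: one rectangular x–y block per
region through the full slab depth, on a 32×32×8 grid by default (8×8×4
for the tiny fixture).  The default region set is one region per
(cortical lobe, hemisphere) — frontal, parietal, lateral temporal, medial
temporal, occipital × left/right — plus cerebellum, whole-brain WM and an
arterial region.  Cohort-scale simulation studies (hundreds to thousands
of cohorts) use `simulate_roi_tables`, which draws exactly the same
per-subject factors from the same stream as the voxel generator but skips
image synthesis and quantification; those imaging steps act as a common
multiplicative gain per subject and therefore cannot change any normalized
statistic.  A test pins the two paths to identical ground truth.

What the phantom does *not* emulate: anatomy, registration error, partial
volume, motion and susceptibility artifacts, recirculation, arterial
saturation.  Passing tests therefore demonstrate correctness of the
analysis chain under the stated statistical structure, not performance on
clinical data.

## Quantification chain

*Baseline and conversion.*  S0 is the mean of the first 6 frames; voxels
with any nonpositive signal are flagged invalid and excluded (not
zero-filled, which would bias ROI means toward zero).  Negative
concentrations (noise pushing S above S0) are clipped to zero before
fitting.  Because the conversion is a log-ratio, the CBF map is exactly
invariant to any per-subject rescaling of the raw signal.

*Gamma-variate fitting.*  The linearized model
ln C = ln K + α ln(t−t0) − (t−t0)/β is solved by weighted linear least
squares over the first-pass window: from the rise above 10% of the peak
(scanning backwards from the peak so pre-bolus noise spikes are ignored)
to the first post-peak frame below 30% of the peak, which excludes
recirculation and other second-order effects.  The arrival time t0 is
found by a grid search over the frames preceding the window followed by a
golden-section refinement within one frame of the best grid point; all
window points lie beyond every candidate t0, so residual sums of squares
are comparable across candidates.  The refinement is what lets noiseless
refits recover parameters to ~10⁻⁷ relative even when the true t0 falls
between frames.  Fits are rejected when fewer than 4 usable points
remain, when α ≤ 0 or β ≤ 0, or when the implied peak height (outside
[⅓, 3]× the observed maximum) or peak time (off by more than 2 frames)
contradicts the data — the latter two bounds discard the exploding or
degenerate fits that log-domain fitting produces in noise-dominated
voxels.

*AIF detection.*  Candidate arterial voxels are those jointly in the
earliest-arrival decile, highest-peak decile and narrowest-FWHM decile of
the fitted curves, computed within the pool of voxels whose fitted peak
reaches the median (noise-dominated fits would otherwise crowd the
deciles).  Arrival is measured as the time the fitted curve reaches 10%
of its peak — anchored to the observed rise, it is robust to the t0/shape
trade-off of the fit.  When the strict decile intersection yields fewer
voxels than requested (which happens when arterial-like voxels dominate a
small volume and each decile clips into the artery itself), selection
falls back to the combined rank of the same three criteria.  The 10
candidates with the highest fitted peak are averaged into the AIF; ties
break by voxel index for determinism.

*Deconvolution.*  The AIF is assembled into the lower-triangular Toeplitz
matrix A[i,j] = TR·C_a(t_{i−j}) and inverted by truncated SVD, zeroing
singular values below 0.05·σ_max (configurable; the conventional
threshold).  By default the fitted gamma curves, not the raw
concentrations, are deconvolved (configurable with
`--no-gamma-denoise`), consistent with fitting's denoising purpose.  CBF
is the maximum of the deconvolved residue samples, clipped at zero.
Noiseless recovery of an exponential-residue tissue curve is accurate to
≈ 1%; the 2 s arterial-to-tissue delay, which is not a multiple of TR,
costs a further ~10% systematic underestimation that is common to all
tissue regions and cancels in every ratio.

## ROI extraction and normalization

Lobe values are voxel-count-weighted means of their member regions,
identical to the direct mean over the merged label set.  The three
references are: cerebellum mean, whole-brain WM mean, and whole-brain
cortical GM computed as the *unweighted* average of lobe means (hemisphere
lobes averaged first, then the five lobes) — the literal reading of
"average of the lobes"; a voxel-weighted variant is available via
`reference_value`'s inputs.  Normalization divides every region column by
the subject's reference; subjects with a missing or nonpositive reference
are dropped with a warning.

## Statistics

*ANOVA* is the classical between/within mean-square ratio
(scipy.stats.f_oneway behind the module surface).

*Dunnett's test* pools the error variance over all groups
(df = N − g) and computes the family-wise adjusted p for comparison i as
1 − P(max_j |T_j| ≤ |t_i|) under the joint null.  The rectangle
probability of the k-variate t is evaluated by deterministic double
Gaussian quadrature (64 Hermite nodes for the shared control deviate, 64
Legendre nodes on the probability transform of the pooled-SD chi factor),
exploiting that the comparisons are conditionally independent given those
two variables.  This is exact to ~10⁻⁶: with k = 1 it reproduces the
pooled t-test, and at the Monte-Carlo-calibrated 5% critical value of
max|T| (10⁶ seeded draws) it returns 0.050.  An independent cross-check
against scipy.stats.dunnett is part of the test suite.

*Effect size* is Cohen's d with the pooled SD; the sign convention is
patient minus control, so hypoperfusion gives d < 0.

*CV tables* pool all subjects of all groups per region, with left and
right hemisphere values pooled per lobe.

*Variance components* come from the method of moments on the two-way
random-effects ANOVA without interaction: each factor's marginal sum of
squares has expectation (df)·σ_e² + c·σ_factor² with c computed from the
level counts; this is valid here because the layout is crossed (each
subject contributes one value under every normalization), so each
factor's marginal totals are free of the other factor's effects.
Negative estimates are truncated at zero.  The decomposition is run
across the three *normalized* tables, where the large scale differences
between normalization methods (cerebellum-normalized ratios ≈ 0.37,
WM ≈ 1.6, cGM ≈ 1.0) make the normalization component dominate (> 95%),
confirming that the CV reduction reflects lower intra-group variability
rather than erased group differences.  With all-identical data the
components are zero and the residual proportion is reported as 1 by
convention.

*ANCOVA* fits volume ~ intercept + group + age by OLS, tests the group
effect by the extra-sum-of-squares F against the age-only model, and
adjusts the group-vs-control comparisons with the same Dunnett quadrature
using the model residual MSE; the group-size-based correlation structure
is used for the adjustment, a negligible approximation when age
distributions are similar across groups.  Constant or collinear age falls
back to the plain ANOVA with a warning.

*Gating.*  Following standard practice, `compare_all` reports a region as
significant only when the ANOVA is significant at α and the Dunnett p is
below α.  Both raw p values and the gated flag appear in the output, and
the null-calibration studies measure the family-wise Dunnett error (the
quantity with nominal level 0.05); the gated chain is by construction
slightly conservative.

No correction is applied across regions beyond Dunnett's within-region
family — the analysis mirrors the lobe-by-lobe reporting convention of
reference-region studies, and users comparing many regions should apply
their own across-region control.

## Determinism and problem sizes

A single cohort seed fans out to per-subject seeds through
`numpy.random.SeedSequence`; identical configs give byte-identical TSV
outputs, including all p values (the Dunnett quadrature has no Monte
Carlo component).  The simulation studies use 100 cohorts for the CV
pattern, 200 for detection rates and 1000 for the null error rate, sizes
at which the binomial standard errors (≈ 0.7–1.5 percentage points) are
small against the margins being tested; the imaging demonstrations use
one study-sized cohort (63 subjects, 32×32×8 voxels) and two-region
micro-phantoms for exactness checks.
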