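# Methods

This package re-implements, as a tested pipeline on synthetic data, a
multi-site resting-state fMRI analysis of sex-dependent and sex-independent
differences in intrinsic brain function between autistic (ASD) and
neurotypical (NT) children: five voxel-wise metrics, empirical-Bayes site
harmonization, a diagnosis x sex group GLM with Gaussian-random-field (GRF)
cluster correction, and an effect-size-based robustness/replicability
framework. Real multi-site repositories are access-restricted; every stage
is therefore exercised end to end on a synthetic cohort whose ground truth
is known, so that recovery, calibration and replicability claims are
checkable rather than asserted.

## Synthetic cohort model

**Phenotypes.** A cohort is a 2 (diagnosis) x 2 (sex) design across `S`
sites with explicit per-cell counts. Ages are uniform on 7-18 y (the
school-age range the analysis targets), FIQ is normal with group means
106 (ASD) / 112 (NT) and SD 13 IQ points, and each subject receives a
target mean framewise displacement drawn from a right-skewed gamma
distribution (mean ~0.11 mm, slightly higher in the clinical group, plus a
per-site offset) — the motion regime of a well-scrubbed pediatric sample.

**Motion.** Six rigid-body parameters follow a random walk whose increments
are rescaled so the realized mean FD (Power convention: backward
differences, 50 mm rotation lever arm) equals the subject's target; the
walk is folded back inside +-3 mm / +-0.06 rad. A zero target yields a
constant trace.

**BOLD.** Each voxel mixes unit-variance band-limited (0.01-0.1 Hz)
latent signals with a broadband AR(1) (phi = 0.3) noise floor:

- a *mirror-pair latent* shared by each left-right voxel pair with
  variance share `c` — the homotopic-coupling (VMHC) channel. Negative
  effective couplings are carried by a signed loading on one hemisphere;
- a hemisphere-specific *regional latent* per named ROI (share `r`) — the
  neighbourhood-coherence (ReHo) channel;
- one global *seed latent* (share `a`; the designated seed region loads it
  at 0.6) — the seed-iFC channel;
- one *hub latent* (share `h`) — the degree-centrality channel;
- a private band-limited remainder, so the in-band part has unit variance;
- the in-band fraction `f` (default 0.55) against broadband noise — the
  fALFF channel;
- an optional global motion-locked component (standardized FD trace,
  amplitude 0.25) that the nuisance regression should remove.

Inside a named ROI each channel's parameter is
`base + beta_dx*dx + beta_sex*sex + beta_int*dx*sex` (dx, sex in {0,1});
parameters must stay in [0, 1]. Site batch effects enter on the Fisher-z
scale of the coupling — `z = atanh(c) + gamma_site + delta_site * eta`,
with `eta ~ N(0, 0.08)` the subject's random coupling level — because
additive/multiplicative transforms of the time series itself are invisible
to correlation- and ratio-based metrics; on the extracted Fisher-z metric
maps this reproduces the additive-location/multiplicative-scale structure
that ComBat models. The seed/hub/regional compartments claim their
variance budget first; pair coupling yields where the total would exceed 1.

**Default fixture.** 4 sites x (10,10,10,10) per cell (N = 160), grid
24 x 24 x 16 at 3 mm, 150 frames at TR = 2 s, ellipsoidal mirror-symmetric
mask (~4200 voxels). The default ground truth mirrors the target result
pattern: a bilateral dorsolateral-occipital-like ROI with
`beta_dx = +0.02, beta_sex = +0.10, beta_int = -0.30` on homotopic coupling
(NT-F highest, ASD-F lowest), and a midline ROI with main effects
`beta_dx = -0.15`, `beta_sex = +0.12`. These scales put the interaction
around the detection edge of a Z > 3.1 / cluster-corrected analysis at
N = 160 rather than saturating it.

**Behaviour.** ADOS-style scores are filled for ASD rows only. The
social-affect score is a rounded, range-clipped linear transform of the
(standardized) ROI signal plus noise with sex-specific target correlations
(defaults r_F = -0.3, r_M = 0.0); rounding and clipping are accepted
inside the +-0.1 recovery tolerance. Total-severity and RRB scores are
range-clipped noise with moments typical of school-age autism cohorts
(total severity ~6.9 +- 2.0, RRB ~3.0 +- 1.7); modules 2-4 are drawn from
(0.1, 0.3, 0.6). What the generator does *not* model: hemodynamics,
anatomy/tissue classes, distance-dependent noise correlations, scanner
drift beyond polynomial trends, or missingness patterns — so passing tests
demonstrate correctness of the analysis machinery, not performance on real
data.

## Quality control

FD is the Power backward-difference variant with a configurable 50 mm
radius (the most common convention in this literature; the radius is a
parameter because the cited heritage is ambiguous). Eligibility keeps
7 <= age <= 18, 70 <= FIQ <= 148 (inclusive bounds) and mean FD at or
below Q3 + 3*IQR of the input sample (type-7 linear-interpolation
quantiles); the threshold is deliberately sample-adaptive (a fixed
override can be passed, e.g. to freeze a first pass's value for
idempotent re-application). Sites need >= 3 subjects in each
diagnosis-by-sex cell. Group matching is verified by `cohort_summary`
(ANOVA for age/FIQ, Kruskal-Wallis for the skewed mean FD, chi-square
without continuity correction for composition, within-ASD t tests for
ADOS scores) rather than enforced by an optimizer.

## Denoising

The discovery nuisance design concatenates an intercept, centred linear
and quadratic trends, the Friston-24 motion expansion (parameters, one-lag
backward differences with a zero first row, and both sets squared), and
aCompCor — the top-5 unit-variance principal component time series of the
variance-normalized voxels in a designated noise compartment (in the
synthetic pipeline, a 2-voxel peripheral shell of the mask). The GSR
robustness variant appends the global mean; CompCor is retained in that
variant by default (the combination is toggleable). Regression is
per-voxel OLS via a QR projection. Band-pass filtering is an ideal
(hard) FFT mask on [0.01, 0.1] Hz with DC removed — idempotent by
construction; a Butterworth alternative was deliberately not used so the
fALFF band bookkeeping stays exact. fALFF consumes the regressed but
*unfiltered* series. Metric maps (not the 4D series) are smoothed with a
6 mm FWHM Gaussian — smoothing derivatives rather than the series is the
usual R-fMRI toolchain convention and keeps the metric definitions exact;
a pre-metric smoothing option exists for sensitivity checks.

## Metrics

- **seed-iFC**: Pearson correlation with the seed-mean series, Fisher-z
  with |r| clipped at 1 - 1e-7 (keeps maps finite).
- **VMHC**: correlation of each voxel with its x-mirrored counterpart on
  the symmetric grid (registration to a symmetric template is upstream
  and out of scope); the map is exactly mirror-symmetric; degenerate
  series give 0 and a flag.
- **ReHo**: Kendall's W over the voxel plus its 26 (or 18/6) in-mask
  neighbours, midranks for ties with the standard tie-correction in the
  denominator; edge voxels use the available neighbourhood and voxels
  with < 4 neighbours are zeroed and flagged.
- **DC**: count (default; or sum) of positive correlations above r = 0.25
  with all other in-mask voxels, self excluded. Threshold and
  binarization are configurable; r > 0.25 binarized is the method's
  common default.
- **fALFF**: in-band Fourier amplitude over total positive-frequency
  amplitude, DC excluded. The numerator band is set to the pipeline's
  0.01-0.1 Hz filter band (classic implementations use 0.01-0.08 Hz;
  configurable).

ReHo/DC/fALFF maps are z-scored within the mask at the subject level so
the group model sees scale-free inputs; correlation metrics stay on the
Fisher-z scale. The choice is recorded in the map's standardization tag.

## Harmonization

Parametric empirical-Bayes ComBat, authored in-package: voxel-wise
standardization by a covariate-adjusted grand mean and pooled variance;
per-site location/scale estimates shrunk toward a normal / inverse-gamma
prior by iterated conditional modes to a 1e-4 relative tolerance. The
protected design is diagnosis, sex, their interaction, age and mean FD,
so the batch step cannot absorb the effects of interest. Numerics match
the Bioconductor `sva::ComBat` reference to ~1e-6 on shared fixtures (a
test runs the R implementation when available). A single-site fit returns
the identity adjustment — with one batch there is no identifiable site
effect, and the otherwise-standard ddof-1 scale estimate would rescale
deviations by sqrt(n/(n-1)). Zero-variance voxels pass through flagged.
Note that *in-sample* site F-tests after any mean-removing harmonization
are conservative (p skewed toward 1), so "no residual site effect" is
checked as absence of excess small p-values, not strict uniformity.

## Group inference

The group design codes dx (NT = 0, ASD = 1), sex (M = 0, F = 1), their
product, and centred age and mean FD (FIQ optional). Per-voxel OLS t
statistics are mapped to Z by CDF matching through log survival
functions (stable in the far tails). Residual smoothness uses the
Kiebel/Worsley derivative estimator on unit-normed residual images
(FWHM_i = sqrt(4 ln 2 / v_i) voxels); RESELs = mask volume / FWHM
product. Clusters are 26-connected components of Z > 3.1 and Z < -3.1
separately (both signed maps are always reported, which sidesteps the
one- vs two-sided ambiguity). The cluster-level corrected p is the classic GRF
chain: expected cluster count from the 3D Euler-characteristic density
times RESELs, expected cluster size from expected suprathreshold volume,
exponential tail on size^(2/3). The cluster alpha defaults to 0.01 —
0.05 Bonferroni-split across the five metrics examined in one study —
kept as a configuration constant, not a computation.
A Freedman-Lane permutation (reduced-model residual shuffling, max
cluster size) provides a distribution-free oracle; it is the reference
the GRF decisions are calibrated against in the test suite. GRF cluster
inference is known to be conservative for low-df t-fields and
low-smoothness lattices; calibration is verified at the study scale
(df ~ 150, ~2-voxel FWHM), not claimed universally.

## Effect sizes and replicability

Cluster means enter a full model (dx, sex, dx x sex, age, mFD) with
*effect coding* (+-0.5), so type-III sums of squares and the adjusted
cell means are well defined with unbalanced cells. Partial eta squared is
SS_term / (SS_term + SS_error); its CI comes from noncentral-F inversion
(90% two-sided by default — the field convention for eta-squared CIs; the
level is a parameter). Contrast directions: dx = ASD - NT, sex = F - M,
interaction = (ASD_F - NT_F) - (ASD_M - NT_M). A discovery effect is R+
in a comparison analysis iff the direction matches and eta_p^2 >= 0.01.
Leave-one-site-out stability refits the adjusted cell means with each
site excluded and reports sign consistency. Cognitive-ontology overlap
binarizes probability maps at P = 1e-5 and reports the percentage of
cluster voxels covered, per map.

## Brain-behaviour model

Within ASD subjects with available scores (listwise deletion, counts
logged): cluster mean ~ sex + score + sex x score + age + mFD, optionally
plus ADOS-module dummies (reference = most frequent module, so the error
df drops by exactly the number of added dummies). The interaction F is a
1-df model comparison; within-sex Pearson correlations are reported
descriptively. The Bonferroni alpha for the three scores is reported
exactly (0.05/3 = 0.0167), alongside the commonly quoted rounded 0.02.

## Problem sizes used in tests and the acceptance script

Simulation sizes were chosen to give stable statistics at desk scale:
metric-oracle parity on a 6x6x4x40 volume at 1e-10; the independence
limit of W over >= 500 interior voxels; ComBat recovery at 3 sites x 40
subjects x 500 voxels; voxel-null calibration pooled over 1e6 draws; GRF
family-wise error over 500 smooth null fields (estimator-derived
smoothness); permutation agreement over 8 datasets x 400 permutations;
end-to-end recovery over 10-12 seeds of the default N = 160 fixture
(VMHC, the injected interaction channel); replicability rates over
80-100 paired cohorts simulated at the cluster-mean level with the
default interaction magnitude. The end-to-end seed batch uses the VMHC
metric alone because the injected interaction lives on the homotopic
channel; the five-metric path is exercised on a reduced grid in the
integration test.

## Known limitations

- The generator's latent-signal model gives each metric an independently
  tunable ground truth but no realistic cross-metric covariance.
- Site effects are injected only on the homotopic-coupling channel; the
  other channels see sites only through motion offsets.
- GRF p-values inherit the usual lattice/df approximations; the
  permutation oracle is the fallback where those assumptions are doubtful.
- The eligibility filter's motion threshold is sample-dependent by
  design; two different samples get different thresholds.
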