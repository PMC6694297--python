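# Methods

## Overview

This package implements a longitudinal resting-state-network (RSN) analysis
for cohort 4D fMRI data: temporal preprocessing, temporal-concatenation group
spatial ICA, dual regression, per-network amplitude/shape/connectivity
metrics, default-mode-network (DMN) subnetwork decomposition, and
mixed-effects longitudinal statistics. Because no real cohort is bundled,
the package ships a synthetic 4D cohort generator with known ground truth,
and every pipeline stage is validated by recovering what was planted.

## Signal model of the synthetic cohort

One acquisition of subject *s* (group *g*, age *a* in months) is

    x(v, t) = Σ_k A_k · m_k(v) · c_k(t) + λ · Σ_j b_j(v) μ_j(t) + ε(v, t)

* `m_k` — planted spatial network maps: flat-topped super-Gaussian
  ellipsoids (`exp(-(d/r)^14)`, in-plane radius 4.7 voxels, through-plane
  4.0) placed on a jittered lattice with ≥ 8-voxel centre separation, so
  maps are pairwise near-orthogonal (|spatial r| < 0.05) and each covers
  ≥ 300 voxels.
* `c_k` — band-limited unit-SD source time-courses synthesized on the DFT
  bins inside 0.01–0.1 Hz, so they survive the pipeline's own band-pass.
* `A_k = intercept[g,k] + slope[g,k]·a + b_s,k` — the amplitude trajectory,
  with subject random offsets `b_s,k ~ N(0, 0.08²)` shared across that
  subject's timepoints. This is exactly the structure the downstream mixed
  model fits.
* motion term — the six simulated rigid-body parameters `μ_j` (slow random
  walks) couple into the volume through fixed random spatial patterns `b_j`
  with weight λ = 0.2; the *same* motion table is later regressed out, so
  nuisance regression has a real target.
* `ε ~ N(0, 3²)` iid voxel noise.

### Default study conditions

The sampling design mirrors a two-group, five-timepoint rodent aging study:
wild-type group sizes (6, 10, 9, 9, 9) and transgenic (8, 9, 9, 9, 6) — 84
acquisitions — at mean ages ≈ 5.3/8.1/11.3/14.8/17.8 and
6.3/8.5/11.3/14.9/18.1 months with the per-timepoint jitter SDs of the
reference design; subjects keep their identity across timepoints, and
missing early/late scans follow the group-size table.

Six networks are planted: two "somatosensory" effect networks with
wild-type amplitude rising (+0.015/month) and transgenic falling
(−0.015/month) — a group×age interaction of −0.03/month; one "sensorimotor"
null network and the three DMN subnetworks with flat, group-independent
amplitude. The three DMN sub-blobs share a common latent course with
loading √0.5, so each sub-course correlates with the parent course at
r ≈ 0.7 (> the 0.4 matching threshold) while remaining separable by
high-order ICA. Behavioral scores couple to the first somatosensory
network's planted amplitude only, mapped monotonically to a trial count
(≤ 90) and a correct-response ratio in [0, 1] with additive noise.

### Why the noise floor is high (noise_sd = 3, network amplitude ≈ 1)

The pipeline z-scores every voxel time-series (a fixed stage of the
protocol). Standardization divides each voxel by its total SD
√(A²m² + σ²): when the network signal dominates (σ small) amplitude
differences are divided out almost entirely, and the amplitude metric
saturates. Amplitude is therefore informative exactly when network signal
is a minority share of voxel variance — the realistic BOLD regime — and the
generator's default noise floor puts the phantom there (blob-voxel
signal fraction ≈ 10 % of variance after smoothing and band-passing).
Recovery of the planted interaction is excellent in this regime
(Wald z ≈ 10 at the default effect size) and would *degrade* if the noise
were reduced, a direct consequence of the standardization step.

### Desk-scale grid

The default grid is 26×26×16 voxels (1 mm isotropic, full-grid mask),
120 volumes at TR = 2 s; the full acquisition protocol (64×64×34, 0.4 mm
in-plane, 600 volumes) is available via `CohortDesign.full_protocol()`.
The grid size is dictated by the subnetwork-matching rule, which is an
absolute constant (> 250 shared voxels above z = 2.3): the z-scored union
parent map only exceeds z = 2.3 when it occupies ≲ 16 % of the mask, so
three ≥ 280-voxel subnetworks need a mask of ≳ 10⁴ voxels. On this grid
the planted geometry passes the rule with margin (minimum planted overlap
285 voxels across 25 seeds) while one end-to-end cohort run takes about
half a minute. For the same reason the phantom plants three DMN subnetworks
(a fourth cannot satisfy the fixed overlap rule at desk scale; the matching
logic itself is count-agnostic). Monte-Carlo sizes (25 end-to-end seeds,
100 recovery + 500 null mixed-model cohorts) are the package's chosen
problem sizes for all validation runs.

## Preprocessing

Fixed stage order: discard → smooth → detrend+nuisance → z-score →
band-pass.

* **Discard**: first 5 volumes (steady-state), motion rows dropped in
  lockstep.
* **Smoothing**: Gaussian at FWHM 1.2 mm via normalized convolution
  (smooth `data·mask` / smooth `mask`), so nothing bleeds across the mask
  boundary and a mid-mask impulse conserves mass. An edge-preserving
  variant (`method="intensity"`) additionally damps the spatial weights by
  intensity differences of the time-averaged image, so smoothing does not
  average across strong edges; the exact brightness-threshold heuristics of
  edge-preserving scanner filters are not reproduced.
* **Nuisance regression**: OLS projection of each voxel on an intercept, a
  polynomial trend (order 1 by default — the protocol says only
  "detrending"), and the six centred motion parameters; collinear columns
  are dropped with a warning. Residuals are orthogonal to the design by
  construction.
* **Z-scoring**: per-voxel mean 0, sample SD 1 (ddof = 1). Constant voxels
  are zeroed and flagged rather than propagating NaN into the ICA.
* **Band-pass**: 0.01–0.1 Hz Hamming-window FIR. Tap count is
  4/(transition width) with the transition width taken as the lower band
  edge, capped at T/3 and forced odd. The symmetric kernel is applied once
  by centred convolution with reflect padding — exactly zero phase — and
  the taps are DC-corrected (`h −= mean(h)`) so constants are rejected
  exactly. The filtered series is not re-standardized (the z-score comes
  first, matching the stated stage order).

## Group ICA

All cleaned acquisitions are concatenated along time (per-voxel, per-block
variance normalization on by default so no acquisition dominates). The
concatenated matrix is voxel-centred, reduced by randomized truncated SVD
to the model order, and the spatial principal directions are unmixed with
FastICA (logcosh, deterministic given the seed), giving *spatial* sources:
component maps shared by the cohort plus a concatenated mixing time-course
per component. Maps are z-scored over mask voxels, signs fixed to
nonnegative skewness, components ordered by mixing variance.

FastICA is a fixed-point iteration with local optima (for sparse sources a
typical failure mode splits one source across two components and drops the
weakest). The unmixing therefore runs several restarts on randomly rotated
copies of the reduced basis — ICA is rotation-equivariant, and the mixing
matrix is rotated back exactly — and keeps the converged solution with the
highest logcosh-negentropy contrast (5 restarts by default, all derived
from the seed). If no restart converges within the iteration cap the call
raises, reporting the iteration count and tolerance.

Model orders: the reference protocol fixes 30 (networks) and 150
(subnetworks); these remain the `PipelineConfig` defaults. The desk-scale
synthetic block uses order 4 — three main networks plus one component that
absorbs the temporally-correlated DMN subnetworks, which merge because
their shared latent course forms a single strong temporal direction — and
order 8 for the subnetwork decomposition (six planted sources plus
headroom; at order exactly 6 the weakest signal direction occasionally sits
at the PCA noise floor and two sources stay mixed).

Components are labeled automatically against binary templates (the planted
blob supports; the DMN template is the union of the sub-blobs) by greedy
Dice overlap of the |z| > 2.3 thresholded maps, ties broken toward the
lower component index, with configurable per-label capacity (a
somatosensory label may accept two components).

## Dual regression and metrics

Stage 1 regresses every volume on the group maps (plus intercept) — the
per-network subject time-series; stage 2 regresses every voxel's series on
those time-courses (plus intercept) — subject beta maps, standardized over
mask voxels into z-maps. Stage-2 design normalization is off by default so
the amplitude metric and stage 2 read the same series; both behaviours are
exposed. Subject z-maps default to spatial standardizations of the beta
maps — the downstream shape metric uses a pooled z > 2.3 cut — with a
per-voxel t-to-z conversion available as `z_mode="tstat"`; shape thresholds
the subject's own map by default, with an optional group-map restriction
(`within=`).

* **amplitude** = sample SD (T−1) of the stage-1 series (signal units).
* **shape** = mean of z-values strictly above 2.3 in the stage-2 z-map;
  *missing* (never zero, never imputed) when no voxel survives.
* **between-network connectivity** = Pearson r of stage-1 series pairs;
  Fisher-z transformed before entering the mixed model (back-transform for
  reporting), raw-r mode available.
* **subnetwork matching**: a high-order component belongs to a parent iff
  its concatenated group course correlates with the parent's at r > 0.4
  (signed by default; absolute-value mode available) AND the two maps share
  more than 250 voxels above z = 2.3 — both jointly. Matching is done once
  at cohort level, not per subject. **mean within-DMN connectivity** =
  average of the C(n,2) pairwise stage-1 correlations of the assigned
  subnetworks per acquisition.

## Longitudinal statistics

* **Mixed model**: y = β0 + β1·group + β2·age + β3·group·age + b_s + ε with
  subject random intercept, REML estimation, two-sided Wald z p-values
  (statsmodels MixedLM). Group coded WT = 0 / Tg = 1; age in months,
  uncentered by default (centering flag provided; it changes only the
  β0/β1 interpretation). When the interaction is significant (p < 0.05)
  each group is refitted with age as the only predictor — the follow-up is
  gated, never produced otherwise.
* **Per-timepoint group tests**: Kruskal–Wallis (tie-corrected H,
  chi-square p) on the two groups; identical-value degenerate samples get
  H = 0, p = 1 with a warning. An exact-permutation p (all label
  assignments, two samples of ≤ 8) is available as the small-sample
  oracle (`exact=True`). BH-FDR is applied across timepoints within
  one network×metric family (the family is configurable; the choice of
  family is a reporting convention, not derivable from the protocol), with
  tiers: significant p_FDR < 0.05, tendency p_FDR < 0.1.
* **Brain–behavior**: Spearman rank correlation per group × timepoint ×
  network between metrics (amplitude, shape) and behavioral measures
  (n_trials, correct_ratio), two-sided p, flagged at uncorrected p < 0.05;
  strata with n < 4 are skipped with a warning.

## Numerical conventions

0-based voxel indexing, X·Y·Z·T storage, diagonal affine (grid-based
analysis; cohorts are assumed pre-registered). Sample SD (ddof = 1)
throughout, including spatial z-scoring. All OLS fits solve least squares
in float64 (`lstsq`), validated against closed-form normal equations to
1e-8. Determinism: every stochastic step derives from an integer seed
(`SeedSequence` spawning per subject/acquisition); identical
(design, truth, seed) reproduce bit-identical datasets and result tables
within one platform. FastICA non-convergence raises (iteration count and
tolerance in the message) rather than returning silently.

## What the phantom does and does not emulate

It emulates: longitudinal two-group sampling with dropout/late entry,
band-limited network sources, group- and age-dependent amplitude with
subject random effects, motion-coupled structured nuisance, behavioral
coupling to network amplitude. It does not emulate: hemodynamic response
shapes, physiological (cardiac/respiratory) noise spectra, scanner drift
beyond a polynomial trend, anatomical network shapes, or spatial
autocorrelation of the noise floor. Passing tests therefore demonstrate
the correctness and statistical calibration of the chain on a compact,
fully-specified generative model — not performance on real acquisitions.

## Known limitations

* Amplitude passes through the voxelwise standardization nonlinearly
  (see above): the fitted β3 on measured amplitude is a compressed version
  of the planted one; sign and significance carry, magnitudes do not.
* Wald z p-values with ~19 subjects are mildly liberal; the type-I error of
  the interaction test is checked by simulation (target band 3–8 %).
* MELODIC-style probabilistic ICA (mixture-model thresholding, automatic
  order selection) is intentionally out of scope; orders are fixed.
* The per-timepoint two-group Kruskal–Wallis is equivalent to a
  Mann–Whitney test up to the statistic; within-group timepoint
  comparisons, where used, are unpaired.
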