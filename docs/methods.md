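# Methods

## The group ISC statistic

At each in-mask voxel the group statistic is the mean of the Pearson
correlations between all N(N−1)/2 unordered subject pairs' time courses,
r̄ = mean_{i<j} r_ij, averaging raw correlations (not Fisher-z values).
Under the component model ρ_ij = ρ + ε_ij with E[ε] = 0, r̄ is a consistent
estimator of the population ISC ρ, which is why it is preferred over
statistics (such as each-subject-versus-average-of-others correlations) that
lack that interpretation. Zero-variance time courses produce NaN pair values;
these propagate NaN for the voxel and are excluded from inference rather than
raising, since degenerate masked-in voxels are routine in real data. Pair
order is lexicographic in (i, j) and fixed by subject order at session
assembly; all pairwise machinery (difference maps, permutations) indexes
pairs the same way.

## Circular-shift resampling inference

The pair correlations are dependent (each subject appears in N−1 pairs) and
BOLD series are autocorrelated, so parametric correlation tests are invalid.
The null hypothesis is "no time structure shared across subjects": each
subject's series is circularly rotated by an independent lag drawn uniformly
from {0, …, T−1} (the joint all-zero draw is rejected and redrawn), which
preserves each series' marginal distribution and circular autocorrelation
exactly while destroying alignment. One realization draws a random masked
voxel and a random lag vector and evaluates r̄; all realizations pool into a
single brain-wide null. This pooling is what makes a large fixed realization
count meaningful for a whole brain, and it is reused unchanged by the
windowed analysis (which additionally randomizes the window).

Voxelwise p-values are right-tail exceedance probabilities read from the
pooled null by linear interpolation of the empirical CDF at plotting
positions F(s_(k)) = k/(n+1), clipped to [1/(n+1), 1]; the floor encodes
that n realizations cannot certify a smaller p. Multiplicity is handled by
Benjamini–Hochberg FDR over masked voxels (via statsmodels); the implied
critical r̄ (smallest rejected value) is written to a plain-text sidecar next
to each map. The test is one-sided toward high r̄ by default, matching the
directional question "is there significant shared response"; a negative-tail
flag exists.

Defaults: n_realizations = 10^6 at the library level — appropriate for
whole-brain grids; the test suite and acceptance script use 10^4–10^5 on
their small grids, where the voxel count (and hence the p-value resolution
needed) is orders of magnitude smaller.

The Fisher-z one-sample t-test (dof = N(N−1)/2 − 1, two-sided) is provided
for parity with common practice; its independence assumption is violated by
construction and it should be treated as anti-conservative.

## Sum-ZPF condition differences

For paired conditions a, b of the same subjects, the per-pair statistic is

ZPF_ij = (z_ij^a − z_ij^b) √((T−3)/2) / √(1 − cov(r_ij^a, r_ij^b) /
[(1−(r_ij^a)²)(1−(r_ij^b)²)]),

with z the Fisher transform and cov(·,·) the large-sample (T-scaled)
Pearson–Filon covariance of two nonoverlapping dependent correlations,
estimated by plugging the six pairwise sample correlations of the four
observed series into the asymptotic expression. Conventions checked by the
self-consistency limit: when condition b is a copy of a, the estimate equals
(1−r²)², the T-scaled large-sample variance of a correlation with itself.
The group map sums ZPF_ij over pairs per voxel.

Degeneracies: a non-positive radicand (possible under estimation noise) sets
the pair term to NaN and excludes it with a logged count; an exactly zero
z-difference contributes exactly 0 (the 0/0 limit of identical conditions,
where the radicand also vanishes); |r| = 1 in either condition excludes the
pair.

Inference flips one random sign per subject pair (applied identically across
voxels, preserving spatial dependence), recomputes the voxelwise sum, and
records image-wide maxima and minima per relabeling (default 25,000, sampled
with replacement). The (1−α) quantile of the maxima and the α quantile of the
minima give FWER thresholds for the two directions — one-sided at the user's
α each by default, with a strict two-sided (α/2 per tail) flag.

Two calibration facts a user should know, both verified empirically in this
package's test suite:

1. **Discreteness.** With P pairs there are only 2^P distinct labelings, so
   the smallest achievable familywise p-value is 2^−P; with N = 3 subjects
   (P = 3) an α of 0.05 is unreachable and the test can never reject. N ≥ 5
   (P ≥ 10) is needed for conventional α levels.
2. **Dependence.** Pair-level sign flipping is exchangeable only when the
   pair statistics are (asymptotically) independent, which holds under a
   global null with no shared signal (ρ = 0), where the measured any-voxel
   exceedance rate matches α. When both conditions carry a common shared
   signal (ρ > 0), the r_ij are correlated across pairs through the shared
   component and the shared subjects; independent sign flips do not preserve
   that correlation and the test becomes anti-conservative (measured
   exceedance ≈ 0.30 at nominal 0.05 with ρ = 0.3, N = 5, T = 60). This is a
   property of the method as defined, not of this implementation; results on
   strongly synchronized data should be read accordingly.

The null Monte-Carlo (`zpf_null_simulation`) reproduces the validation
design: two subjects, two independent conditions with equal true ρ, pink
noise, T = 100. The empirical pairwise-ZPF distribution is Gaussian by QQ
diagnostic, zero-mean, with variance well above 1 (≈ 2.9 under these study
conditions — autocorrelation of the pink noise and the smoothed shared
signal reduces the effective sample size below T, inflating the variance of
r and hence of ZPF beyond its temporally-white nominal value), and its sd
varies only mildly across ρ ∈ [−0.5, 0.5].

## Wavelet filter bank

Frequency-specific ISC filters every series into octave sub-bands with the
stationary (undecimated) wavelet transform and reruns the standard analysis
per band. The SWT is used because it is time-invariant: a small hemodynamic
delay between subjects passes through each band as the same small delay, so
between-subject correlations of filtered series remain consistent — the
decimated DWT does not have this property. Defaults: Daubechies filters with
K = 4 coefficients (V = K/2 = 2 vanishing moments, annihilating constant and
linear trends in the detail bands; short filters suit short fMRI series and
limit boundary artifacts), L = 2 levels, i.e. 3 bands.

Numerical choices: boundary handling is circular (periodic), which makes
shift-invariance exact (verified to ≤ 1e−10) and is consistent with the
circular-shift null; series whose length is not a multiple of 2^L are
periodically tiled to the next multiple and trimmed after reconstruction.
Bands are returned as time-domain band-limited signals, each obtained by
inverting the transform with all other bands zeroed, so the L+1 bands sum to
the input exactly (perfect reconstruction ≤ 1e−10); correlations are computed
on these reconstructed signals. PyWavelets provides the swt/iswt kernels.
Note that a linear ramp is annihilated only away from the circular wrap
(the wrap itself is a discontinuity); the vanishing-moment tests therefore
check the interior.

## Sliding-window ISC

Windows are half-open ranges of W samples stepped by S (count
⌊(T−W)/S⌋ + 1); trailing partial windows are dropped rather than padded so
every window's estimator has the same variance. The null is pooled over
voxels, windows and lags, yielding one common threshold for all windows;
with a single full-length window both the maps and the null reduce exactly
(bit-for-bit) to the basic analysis. Windows shorter than 10 samples trigger
a warning (usable but very noisy). ROI curves report mean r̄ over
atlas-region voxels per window, indexed by window-center time (center × TR)
for alignment with stimulus features.

## Inter-subject phase synchronization

Each series is demeaned and Hilbert-transformed; the instantaneous phase is
the analytic signal's argument. The pairwise dissimilarity is the printed
absolute angular distance p_ij(t) = |θ_i − θ_j| mod π, averaged over pairs
and normalized to IPS(t) = 1 − p̄(t)/π ∈ [0, 1], with 1 meaning complete
phase agreement at that voxel and time point — per-timepoint resolution, in
contrast to any W ≥ 2 window. The mod-π form maps an exact antiphase
difference of π to distance 0; an alternate mode wraps differences to
[0, π] so antiphase is maximally dissimilar. The printed form is the
default.

Broadband BOLD has no well-defined instantaneous phase, so IPS accepts a
filter-bank spec and computes phases on one band (default: the coarsest
detail band); calling it on raw series works but warns. The first and last
⌈T/20⌉ samples are flagged as Hilbert edge-affected in the output metadata
rather than removed.

## Synthetic data

Subject s in condition a is x_s^a = β t^a + n_s^a. The shared signal t^a is
white Gaussian noise smoothed with a 5-sample box filter and convolved with
a canonical double-gamma HRF (response peak ≈ 6 s, undershoot ≈ 16 s at 1/6
amplitude, sampled at the TR), then standardized; n_s^a is unit-variance
pink (1/f) noise synthesized by spectral shaping of white noise (white by
option). With both components at unit variance, β = √(ρ/(1−ρ)) gives
population inter-subject correlation ρ; the calibration is population-level,
so sample correlations fluctuate around ρ. Negative ρ is realized by
negating the second subject's β and is therefore limited to N = 2 (a common
negative pairwise correlation among N > 2 subjects is not realizable with
one shared additive component).

Voxels are spatially independent — each draws its own shared signal and
noise — so masked voxels serve as i.i.d. Monte-Carlo replicates; this is
also what the ZPF null simulation exploits to evaluate all repetitions
through the same vectorized code path as a real analysis. The generator does
not model spatial autocorrelation, cross-condition dependence, motion, or
physiological confounds, so passing calibration tests demonstrate
correctness of the statistics under exchangeable, spatially independent
noise, not robustness to those real-data features. The shared component can
be confined to one octave band and/or a time window (re-standardized after
confinement) to give the frequency and window analyses targeted positives.

## Pipeline and determinism

A YAML config drives six ordered stages: output allocation, band filtering
(skipped unless frequency analysis is enabled), ISC maps + null
distributions, thresholds (FDR; sign-flip FWER for differences), ROI/IPS
curves, and NIfTI export with plain-text sidecars and a JSON manifest. A
stage failure stops the run; the manifest checkpoint records the completed
stages and artifacts already on disk. Work inside a stage is split into
independent items (analysis units, null chunks of 25,000 realizations) run
on an ordered thread pool; every random item carries a seed derived from the
master seed by item index, never a shared generator, so (config, seed)
determines every output byte for any worker count. Intermediate artifacts
(band series, null samples) are flagged in the manifest and removable with
`isckit prune`. Maps are written float32; thresholds additionally go to text
sidecars so downstream viewers need no binary metadata.

## Problem sizes in the shipped checks

The test suite and acceptance script use deliberately small grids (10^2–10^3
voxels), N = 2–5 subjects, T = 40–244, 10^4–10^5 null realizations, 10^4 ZPF
repetitions at the headline ρ = 0.3 and 2,500 per point on the 11-point ρ
grid, and 250 replicates × 500 permutations for the FWER calibration —
sizes at which the Monte-Carlo error bands quoted in each test are tight
enough to be informative while the whole suite runs in seconds to minutes.

## Known limitations

- The sign-flip FWER test's anti-conservativeness under shared signal and
  its p-value discreteness for small N (see above).
- The parametric t-test is reported as defined despite its violated
  independence assumption.
- mat-format ingestion is supported only as a plain 4-D array container;
  NIfTI is canonical. No registration, preprocessing, or template fetching;
  template space is advisory metadata only.
- Group-vs-group (different-subjects) comparisons are out of scope; the
  difference test covers the same-subjects two-condition design only.
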