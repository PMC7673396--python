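# Methods

This note records the models, parameter choices, and numerical decisions
behind `boldlag`, and what the synthetic-data experiments do and do not
demonstrate about real fMRI data.

## Signal model

A resting voxel is modeled as a weighted sum of synchronous band-limited
sources, each expressed with the voxel's own hemodynamic delay, plus
noise:

    y_v(t) = sum_k w_kv * s_k(t − d_v) + eps_v(t).

This encodes the hypothesis the pipeline is built to probe: the lag
pattern reflects *local variance in hemodynamic response timing* rather
than a signal physically traveling between regions. All sources at a
voxel share one delay d_v; there is no per-source delay, no dispersion,
and no biophysical (balloon/Windkessel) dynamics. Task runs replace the
sources with an HRF-convolved block regressor, delayed per voxel the
same way. The arterial model is `baseline + intensity_offset +
gain * g(t − shift) + noise` with `gain < 0` (inverted coupling to the
global source) and `shift < 0` (the artery leads), plus an elevated
baseline mimicking inflow brightening.

## Synthetic sources

Sources are white Gaussian noise, band-pass filtered, passed through a
winsorized cube (clip at ±2.5 SD, then cube), re-filtered, and
standardized. Two things matter here:

* **The final operation is the band-pass**, so the band limit is a
  construction guarantee. The generation filter edges are inset 20 %
  above the low cutoff and 15 % below the high cutoff so that the
  Butterworth transition band stays inside the nominal 0.01–0.1 Hz
  analysis band.
* **The nonlinearity is not optional.** Band-limited *Gaussian* sources
  with identical spectra are unrecoverable by ICA in principle (any
  rotation of an i.i.d. Gaussian vector is equally independent). The
  winsorized cube leaves each source clearly super-Gaussian — bursty,
  like real network fluctuations — while the clip prevents the opposite
  degenerate case, a source dominated by one extreme sample, which is
  as bad for finite-sample ICA as Gaussianity. Network sources are
  exactly decorrelated over the run window by symmetric
  orthogonalization (a near-identity mix that leaves their higher-order
  structure essentially intact).

Sources carry an **extended temporal support** (~16 s margin per side);
rendering reads time-shifted copies from the extended series. Shifting
an excised finite segment instead (with reflect padding) corrupts
edge-localized bursts — in pilots this biased arterial lag estimates by
up to a second. The underlying physiological signal exists outside the
scan window; the generator honors that.

Sub-sample delays are applied by frequency-domain phase shift on the
(further reflect-padded) extended series, never by nearest-sample
rounding, so the stored ground truth is finer than the estimator's
quarter-TR grid.

Defaults: 20×20×12 voxels, 400–1200 frames at TR 0.72 s, delay range
±2 s, i.i.d. Gaussian noise of SD 1.33 per unit-variance signal (raw
voxel-to-source r = 0.6 — a realistic mid-range magnitude; after
band-passing, the in-band magnitude is ≈ 0.85–0.9). An AR(1) noise
option (configurable coefficient) exists for autocorrelation-aware
threshold calibration. The delay-field smoothness bound (neighbor steps
≤ 0.5 s) is a free parameter of the generator, not an empirical value:
the spatial covariance of real delay fields is not characterized well
enough to copy.

## Lag estimation

Both series are upsampled by trigonometric (band-limited) interpolation
— consistent with the 0.01–0.1 Hz content; a cubic-spline fallback
exists — to 1/4 TR. For every candidate shift in ±5.8 s the Pearson
correlation is computed **over the overlapping segment only**, with
means and SDs recomputed per shift; zero-padded correlation would bias
toward small shifts. Shifts leaving less than 80 % overlap are excluded.
Only positive peaks are accepted (`lag > 0` = voxel later than the
reference); ties break deterministically toward the smallest |lag|,
negative first. The implementation computes all shifts with one batched
FFT cross-correlation plus prefix-sum segment statistics; series are
standardized first, which is exact for Pearson correlation and avoids
catastrophic cancellation. The test suite pins this path against an
explicit brute-force enumeration oracle (exact shift agreement, r to
1e−10).

The adjusted-Z statistic estimates the null variance of a sample
correlation as `(1/n)[1 + 2 Σ ρ_x(k)ρ_y(k) + Σ ρ_xy(k)ρ_yx(k)]` with
each sum truncated at the first lag where the sample correlation
function sits inside its ±2/√n band for two consecutive lags. This is
an adaptive-truncation *approximation* to the published xDF family of
estimators, not a reimplementation of any specific one. For white noise
it reduces to z = r·√n; Monte-Carlo calibration shows a false-positive
rate ≈ 0.0005–0.001 at Z > 3 under white noise, and under AR(1)(0.5)
noise the adjusted rule stays near nominal where the naive rule inflates
~8-fold. Degenerate inputs (|r| → 1) are capped at |z| = 10⁴ with a
warning. The r > 0.3 primary threshold and the Z > 3 check are
independent switches; the default mirrors common practice (r > 0.3,
Z reported as a diagnostic).

An intrinsic precision limit worth stating: with band-limited content, a
600-frame run carries only ~80–150 effective samples, so at in-band
magnitude r ≈ 0.9 the per-voxel lag error SD is ≈ 0.15–0.2 s — about
one grid step. Recovery correlations of ~0.98 against a ±2 s field are
near the information-theoretic ceiling; individual voxels can still err
by 3–4 SD in a 4800-voxel map, so worst-case per-voxel error bounds
tighter than ~0.7 s are not achievable at that SNR by any unbiased
single-pass estimator.

## Temporal ICA and Icasso

Stage one is a group spatial ICA: per-voxel demeaning, explicit SVD
whitening across voxels, FastICA rotation of the whitened spatial
basis, time courses by least-squares projection. Whitening is explicit
because a library default of centering each time point across voxels
would subtract the instantaneous spatial mean — precisely the global
component this analysis must keep. Stage two runs FastICA (symmetric
updates, log-cosh contrast, defaults configurable) on the stage-one time
courses `n_repeats` times, each repeat fitted on a bootstrap resample of
the time points (ICA is order-invariant, so resampling rows is
legitimate) and evaluated on the full data. Pooled estimates are
clustered by average-linkage agglomeration on 1 − |r|; each cluster
returns its centrotype, and iq = mean intra-cluster − mean
extra-cluster similarity. Bootstrap resampling is what gives iq its
meaning: deterministic restarts converge to the same optima even for
noise components, whereas resampling makes unstable components wander
(components beyond the true model order drop to iq ≈ 0.6–0.7 while true
sources stay ≥ 0.95). Model order is an input, never estimated.
Local/global labeling by gray-matter coverage of the magnitude map is a
stand-in heuristic for visual spatial-pattern judgment and should not be
read as a validated rule.

## Task GLM

Canonical double-gamma HRF (peak delay 6 s, undershoot delay 16 s,
ratio 1/6, 32 s support, unit peak), block regressor convolved on a
16× oversampled grid, orthonormal cosine drift basis implementing the
1/128 Hz high-pass, optional nuisance columns, per-voxel OLS with
t = estimate/SE. Serial correlation is ignored (the calibration tests
use white noise; real-data efficiency is out of scope). Activation masks
take suprathreshold voxels by 26-connectivity and keep clusters larger
than 10 voxels — a deterministic threshold+extent rule chosen for
synthetic data in place of random-field familywise-error machinery,
which targets smoothed real group data. The task reference is the mean
in-mask series, by default from the group-style mask applied per run.

## Arterial analysis

Artery ROIs are intensity-thresholded within a search region (largest
connected component, lexicographic tie-break); the periphery is a
6-connectivity dilation shell (default radius 2; no empirical radius
exists to copy) minus the artery. Unlike voxelwise lag mapping, the
artery-vs-GMS cross-correlation searches **both signs** and reports both
signed extrema — the phenomenon of interest is a negative coupling, and
a positive-only rule would mask it. Group summaries average the
cross-correlation functions before locating the extremum; per-artery
peaks at realistic noise jitter by one to two grid steps around the
injected −2.7 s.

## Composite maps and comparisons

IC lag maps are aligned to the GMS map by adding, per IC, the offset
`midpoint(GMS lag range) − midpoint(IC lag range)` (the mean-based
variant is available; "mean of the lag range" is ambiguous in common
usage, and the midpoint is the default read-out). Offsets are per-IC
constants, so within-IC lag contrasts are untouched; voxels covered by
several ICs go to the highest-magnitude IC. One caveat found during
design: midpoint alignment is only well-posed when each IC's voxels
span comparable true-lag ranges — ICs tiling *along* a delay gradient
have truncated, asymmetric ranges and midpoint alignment then
misregisters them (the closure experiment therefore tiles
perpendicular to the gradient). Zero-centering of lag maps is plain
mean-removal over valid voxels; a lag map has no natural axis along
which a "linear trend" could be removed, so nothing beyond the mean is
subtracted. Map comparisons use Pearson correlation over the
intersection of valid masks; group inference is a two-tailed one-sample
t-test on Fisher-Z transformed per-run correlations.

## Problem sizes

The shipped experiments use 20×20×12 grids with 400–1200 frames, 2–3
sources, 18 simulated arteries, and 2000-pair Monte-Carlo calibrations
— sizes chosen so the full suite exercises every stage in about a
minute while keeping every recovery target statistically
well-determined.

## What passing tests do and do not show

The generator reproduces the statistical skeleton the analysis assumes:
band-limited synchronous sources, smooth delay fields, additive (white
or AR(1)) noise, inflow-bright arteries. It does not simulate motion,
physiological aliasing (cardiac/respiratory harmonics), scanner drift
beyond a linear trend, multiband reconstruction artifacts, spatial
noise correlations, or draining-vein geometry. Recovery at the tested
SNRs therefore demonstrates the *estimators* are correct and
well-calibrated, not that real-data lag maps reach any particular
accuracy; on real data the reference signals are themselves noisy and
the delay field need not be smooth.
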