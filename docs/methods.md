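# Methods

## Decay model and conventions

Measured TCSPC histograms are modelled as the instrument response function
(IRF) convolved with a biexponential decay
`f(t) = a0 + a1 exp(-t/tau1) + a2 exp(-t/tau2)`. Component order is
canonical: construction of `BiexpParams` swaps pairs so that `tau1 <= tau2`,
making "component 1 = fast" an invariant of every downstream quantity
(`a1%` is always the fast fraction — free NADH in the NADH channel, bound
FAD in the FAD channel). Lifetimes are in nanoseconds, bin widths and IRF
parameters in picoseconds, everywhere.

Two mean-lifetime conventions exist in FLIM practice. Maps and fit results
use the **amplitude-weighted** mean `tau_m = (a1 tau1 + a2 tau2)/(a1 + a2)`,
which is bounded by `[tau1, tau2]` and monotone in the slow fraction; the
intensity-weighted variant (each component weighted by its integrated
photon contribution `a_i tau_i`) is available through
`mean_lifetime(..., weighting="intensity")` and is labelled distinctly. The
amplitude weighting was chosen because the amplitude fractions themselves
are the analysis readout, and the two conventions must stay consistent.

## IRF and convolution numerics

The IRF is a shifted Gaussian parameterized by FWHM (default 300 ps) and a
peak position (default 1.22 ns into the window, leaving pre-rise baseline
bins), or an arbitrary empirical nonnegative curve normalized to unit sum.
The discrete kernel is sampled at `t_j = j * dt` (index 0 at t = 0) and
renormalized, so a vanishing FWHM reduces to an identity kernel.

Convolution is causal by default — the decay is zero before the excitation
pulse, linear convolution truncated to the window — with an optional
periodic mode that wraps the tail, modelling incomplete decay between
80 MHz pulses. With the default window (256 bins x 48.8 ps = 12.5 ns) and
slow lifetimes near 2.5 ns the wrapped tail is below ~1% of the peak, so
periodic mode is off by default. The constant offset `a0` represents
uncorrelated background and is added *after* convolution. Model curves are
evaluated on a 4x oversampled grid, convolved there, then box-averaged to
bins, which removes bin-centering bias when a lifetime is comparable to
the bin width.

## Fitting

**Free fits** use variable projection: `scipy.optimize.least_squares`
searches over `(tau1, tau2, shift)` while the linear amplitudes
`(a0, a1, a2) >= 0` are solved by weighted NNLS at each step. The default
objective is weighted least squares with Neyman weights `1/max(counts, 1)`;
a Poisson maximum-likelihood polish (`objective="poisson"`) starts from the
WLS solution and is preferable below ~1e3 counts, where the WLS and ML
estimates diverge. Initial lifetimes are 0.4 and 2.5 ns (literature anchors
for free NADH and free FAD); five multi-starts jitter them log-normally
under a fixed seed, the lowest objective wins, and ties go to the lowest
`tau1`. The IRF temporal shift is a bounded nuisance parameter (±3 bins
around the nominal IRF position) in free fits and frozen in fixed-lifetime
refits. The fit window runs from the bin where the (lightly smoothed) curve
reaches 90% of its rising edge to the last bin. Non-convergence is flagged
on the result, never silent, and `tau1 ≈ tau2` (within 5%) attaches a
collinearity warning. Standard errors come from the Gauss-Newton
approximation with a finite-difference Jacobian.

**Fixed-lifetime fits** clamp `(tau1, tau2)` and solve only the amplitudes
by weighted NNLS — a linear problem, exact and fast, which is what makes
per-pixel maps tractable. Refitting at a free fit's own lifetimes and shift
reproduces its amplitudes to numerical precision (tested).

**Model adequacy**: `compare_models` fits one- and two-component models and
flags "biexponential required" when the reduced chi-square improves by more
than 0.2 (configurable). At 1e5 photons this yields a >=95% hit rate on
well-separated two-component truths and a <=5% false-positive rate on
single-component truths (tested at 100 seeds each).

**Goodness of fit** is the Neyman reduced chi-square over the fit window.
Averaged over the window's mix of high- and low-count bins it is calibrated
(mean within [0.9, 1.1] over 200 Poisson replicates of a true model),
although individual low-count bins bias it slightly.

## Two-pass image analysis

Per image, an intensity threshold on the summed-count image selects the
region of interest (default Otsu, since per-image manual thresholds are not
reproducible; fixed and percentile policies are available and logged), and
the masked pixels' decays are summed into one pooled histogram. Pass 1 fits
each pooled decay freely; per channel, `tau1` and `tau2` are averaged over
all fields-of-view (unweighted — each image counts once; photon-weighted
averaging is an option). Pass 2 refits every pooled decay with the channel
means clamped, so amplitude fractions are comparable across images; the
same clamped fit runs per pixel for the maps. Channels are fitted fully
independently (separate detectors and filters; no cross-channel unmixing).

Pixelwise maps default to 3x3 spatial binning (`binning=1`). The per-pixel
linear solve starts from Neyman weights and iterates twice to model-based
(Pearson) weights, which removes the few-point upward bias of `a1%` that
Neyman weighting produces at single-pixel photon counts (a few hundred to a
few thousand); pixels below a minimum count after binning are flagged
unfitted, not errors.

## Synthetic data generator

The generator emulates the statistical structure of two-channel metabolic
MPM-FLIM timecourses: non-overlapping elliptical "cells" on a dark
background; per-pixel biexponential decays at channel lifetime truths of
0.53/2.53 ns (NADH channel) and 0.41/2.43 ns (FAD channel); a 300 ps FWHM
Gaussian IRF; Poisson photon noise; flat low-rate background (2 counts per
pixel vs 250 expected photons per cell pixel — chosen for stable pooled
fits at ~64x64 fields-of-view, as repetition rates and photon budgets are
acquisition-specific); and a five-day linear drift of amplitude fractions
(a1 of NADH 0.85 -> 0.70, a2 of FAD 0.70 -> 0.54) with per-cell Gaussian
jitter (sd 0.02 on the fraction, clipped) providing within-day spread. The
drift schedules are modelling choices that reproduce the qualitative
monotone decrease of both free-coenzyme fractions during differentiation;
they are configuration, not code. Everything is driven by a single seed
through spawned SeedSequence streams: identical configurations give
bit-identical stacks.

Deliberately **not** modelled: optical blur (no PSF), photobleaching,
detector afterpulsing and dead time, spectral crosstalk (e.g. keratin
autofluorescence), cell-to-cell lifetime heterogeneity, and z-structure.
Passing tests therefore demonstrate correctness of the estimation pipeline
under Poisson statistics with known ground truth — not robustness to the
optical and biochemical confounders of real tissue.

## Day discrimination

Each imaged position contributes the fixed-fit `(a1%_NADH, a2%_FAD)` pair.
k-means (k = 5, Euclidean, Lloyd's algorithm with k-means++ and 50 seeded
restarts, via scikit-learn) clusters the raw percentages — both axes are
percentages of comparable spread, so no standardization is applied by
default (a z-score option exists). Day labels play no role in fitting; they
enter only to assign each cluster its modal day (ties to the smallest day,
reported) and to score the clustering by modal-day purity and mode ± 1
adjacency. Restarts make the partition stable under row permutation; the
exact restart stream consumes the seed through scikit-learn's `random_state`.

## Problem sizes

The test suite and the acceptance script use: 50 decays per channel at
1e5–1e6 photons for parameter recovery; 20 64-bin decays against a dense
(0.01 ns step) lifetime-lattice oracle; 100 seeds per truth class for
model-adequacy rates; one default timecourse (5 days x 2 channels x 9
fields-of-view of 64x64 pixels) for trend and clustering recovery; and 200
replicates for chi-square calibration. These sizes give Monte-Carlo errors
comfortably inside the asserted tolerances while keeping a full run in the
low minutes.

## Known limitations

- No tri-exponential or stretched-exponential models, phasor transform, or
  global multi-pixel fitting.
- The empirical-IRF path assumes the curve fits inside the acquisition
  window; there is no IRF *estimation* from data beyond the shift nuisance.
- Becker & Hickl SDT ingestion is not implemented; data enter as TIFF
  time-stacks (+ JSON sidecar) or HDF5.
- Cell segmentation is out of scope; masks are intensity thresholds, and
  all per-image statistics are whole-ROI, not per cell.
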