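# flimkit

Analysis tools for **time-correlated single photon counting (TCSPC)
fluorescence lifetime imaging (FLIM)** of cellular metabolism. The package
targets the standard two-channel autofluorescence experiment — NADH
(750 nm excitation, 445/60 nm emission) and FAD (900 nm excitation,
580/150 nm emission) — in which the balance of free and protein-bound
coenzyme, read out through decay-component amplitudes, tracks the shift
between glycolysis and oxidative phosphorylation, for example during
keratinocyte differentiation.

## What it computes

Each pixel's photon arrival-time histogram is modelled as the instrument
response function (IRF) convolved with a biexponential decay

```
f(t) = a0 + a1 exp(-t / tau1) + a2 exp(-t / tau2)
```

where `tau1` is the fast lifetime (free NADH / bound FAD regime), `tau2`
the slow one (bound NADH / free FAD), `a1`, `a2` the pre-exponential
amplitudes, and `a0` a constant background. Reported per fit are the
relative amplitude fractions `a1% = 100 a1 / (a1 + a2)` (and its
complement), the amplitude-weighted mean lifetime
`tau_m = (a1 tau1 + a2 tau2) / (a1 + a2)`, and a Neyman-weighted reduced
chi-square.

The package provides:

- **`flimkit.decay`** — the model, IRF representations (Gaussian FWHM or
  empirical curve), causal/periodic convolution on an oversampled grid,
  derived quantities.
- **`flimkit.fitting`** — sklearn-style estimators for free biexponential
  fits (variable projection with nonnegative amplitudes, multi-start,
  seeded), fixed-lifetime amplitude refits, mono-vs-bi model adequacy, and
  goodness-of-fit. Weighted least squares by default, Poisson-likelihood
  polish optional.
- **`flimkit.pipeline`** — whole-image orchestration: Otsu (or fixed /
  percentile) intensity masking, pooled decay histograms, the **two-pass
  analysis** (free pooled fit per field-of-view, then a refit with `tau1`,
  `tau2` clamped to their experiment-wide channel means so only amplitudes
  vary), and pixelwise `tau_m` / `a1%` maps with optional spatial binning.
- **`flimkit.cluster`** — per-position `(a1%_NADH, a2%_FAD)` feature tables
  and unsupervised k-means (k = 5, Euclidean) day discrimination with
  per-cluster modal-day purity and mode ± 1 adjacency reports.
- **`flimkit.simulate`** — a seeded synthetic TCSPC generator (decays,
  cell-shaped two-channel image stacks, multi-day timecourses) with known
  ground truth, used by the test suite in place of a microscope.
- **`flimkit.io`** — TIFF time-stack + JSON sidecar and HDF5 dataset
  round-trips, CSV manifests.

## Worked example

```python
from flimkit import default_config, generate_decay, fit_free, fit_fixed_tau

cfg = default_config(seed=7)                   # 256 bins x 48.8 ps, 300 ps IRF
truth = cfg.channel("NADH")                    # tau1 = 0.53 ns, tau2 = 2.53 ns
hist, gt = generate_decay(truth, day=0, total_photons=5e5, config=cfg, seed=7)

free = fit_free(hist, cfg.irf, seed=7)
print(f"free fit:  tau1 = {free.params.tau1:.3f} ns, tau2 = {free.params.tau2:.3f} ns, "
      f"a1 = {free.fractions[0]:.1f}%, chi2_red = {free.chi2_red:.2f}")

fixed = fit_fixed_tau(hist, cfg.irf, truth.tau1_ns, truth.tau2_ns)
print(f"fixed fit: a1 = {fixed.fractions[0]:.1f}%  (truth 85.0%), "
      f"tau_m = {fixed.tau_m:.2f} ns")
```

prints

```
free fit:  tau1 = 0.533 ns, tau2 = 2.568 ns, a1 = 85.3%, chi2_red = 1.02
fixed fit: a1 = 85.0%  (truth 85.0%), tau_m = 0.83 ns
```

i.e. from half a million photons the free fit recovers the fast and slow
lifetimes to a few percent, and the fixed-lifetime refit pins the free-NADH
amplitude fraction at its ground-truth value; `tau_m` is the mean lifetime
that colors FLIM images. A full dataset goes through the same machinery via
the CLI:

```sh
flimkit simulate --out data/ --seed 11
flimkit analyze  --data data/ --out table.csv --seed 11
flimkit cluster  --features table.csv --k 5 --seed 0 --out report.json
```

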