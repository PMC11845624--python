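"""Biexponential fluorescence-decay model and instrument-response convolution.

The measured TCSPC histogram of a fluorophore mixture is modelled as

    f(t) = a0 + a1 * exp(-t / tau1) + a2 * exp(-t / tau2)

convolved with the instrument response function (IRF). ``tau1`` is the fast
component (free NADH / bound FAD regime, sub-nanosecond) and ``tau2`` the slow
one (bound NADH / free FAD, a few nanoseconds); ``a1``/``a2`` are the
pre-exponential amplitudes whose relative fractions carry the metabolic
information, and ``a0`` is a constant background offset that is *not*
convolved with the IRF.

Units: lifetimes are in nanoseconds, histogram bin widths and IRF widths in
picoseconds. These conventions hold package-wide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NS_PER_PS = 1e-3

__all__ = [
    "BiexpParams",
    "IRFModel",
    "DecayHistogram",
    "eval_model",
    "convolve_irf",
    "model_expectation",
    "mean_lifetime",
    "amplitude_fractions",
    "InvalidDecayModelError",
]


class InvalidDecayModelError(ValueError):
    """Raised for physically invalid model parameters or IRF configuration."""


@dataclass(frozen=True)
class BiexpParams:
    """Parameters of the biexponential decay model.

    Construction canonicalizes component order: if ``tau1 > tau2`` the
    (amplitude, lifetime) pairs are swapped so that component 1 is always the
    fast one. This keeps the a1/a2 semantics ("fraction of the short decay
    component") stable regardless of how a fit converged.
    """

    a0: float
    a1: float
    a2: float
    tau1: float
    tau2: float

    def __post_init__(self) -> None:
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise InvalidDecayModelError(
                f"lifetimes must be positive, got tau1={self.tau1}, tau2={self.tau2}"
            )
        if self.a0 < 0 or self.a1 < 0 or self.a2 < 0:
            raise InvalidDecayModelError("amplitudes must be nonnegative")
        if self.tau1 > self.tau2:
            a1, a2 = self.a2, self.a1
            t1, t2 = self.tau2, self.tau1
            object.__setattr__(self, "a1", a1)
            object.__setattr__(self, "a2", a2)
            object.__setattr__(self, "tau1", t1)
            object.__setattr__(self, "tau2", t2)

    @property
    def total_amplitude(self) -> float:
        return self.a1 + self.a2


@dataclass(frozen=True)
class IRFModel:
    """Instrument response: shifted Gaussian (by FWHM) or empirical curve.

    ``shift_ps`` positions the IRF peak on the time axis (the excitation pulse
    usually arrives a nanosecond or so into the recorded window, leaving
    pre-rise baseline bins). For ``kind="empirical"`` the curve is stored
    normalized to unit sum at histogram-bin resolution.
    """

    kind: str = "gaussian"
    fwhm_ps: float = 300.0
    shift_ps: float = 0.0
    curve: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kind == "gaussian":
            if self.fwhm_ps <= 0:
                raise InvalidDecayModelError(f"IRF FWHM must be positive, got {self.fwhm_ps}")
        elif self.kind == "empirical":
            if self.curve is None:
                raise InvalidDecayModelError("empirical IRF requires a curve")
            c = np.asarray(self.curve, dtype=float)
            if c.ndim != 1 or c.size == 0 or np.any(c < 0) or c.sum() <= 0:
                raise InvalidDecayModelError("empirical IRF curve must be 1-D, nonnegative, nonzero")
            object.__setattr__(self, "curve", c / c.sum())
        else:
            raise InvalidDecayModelError(f"unknown IRF kind {self.kind!r}")

    @property
    def sigma_ps(self) -> float:
        """Gaussian standard deviation equivalent of the FWHM."""
        return self.fwhm_ps / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    def kernel(self, bin_width_ps: float, n_samples: int, oversample: int = 1,
               shift_ps: float | None = None) -> np.ndarray:
        """Discretize the IRF on a (possibly oversampled) time grid.

        Returns a unit-sum kernel whose index 0 corresponds to t = 0; the
        peak sits at ``shift_ps`` (defaults to the model's own shift).

        Raises if an empirical curve is longer than the requested window.
        """
        if bin_width_ps <= 0:
            raise InvalidDecayModelError(f"bin width must be positive, got {bin_width_ps}")
        dt = bin_width_ps / oversample
        shift = self.shift_ps if shift_ps is None else shift_ps
        if self.kind == "empirical":
            fine = np.repeat(self.curve, oversample)
            if fine.size > n_samples:
                raise InvalidDecayModelError(
                    f"empirical IRF ({fine.size} samples) exceeds window ({n_samples} samples)"
                )
            # optional extra shift, rolled at fine resolution (zeros shifted in)
            roll = int(round(shift / dt))
            out = np.zeros(n_samples)
            out[: fine.size] = fine
            if roll:
                out = np.roll(out, roll)
                if roll > 0:
                    out[:roll] = 0.0
                else:
                    out[roll:] = 0.0
            s = out.sum()
            if s <= 0:
                raise InvalidDecayModelError("IRF shift moved the empirical curve out of the window")
            return out / s
        sigma = self.sigma_ps
        n_kernel = min(n_samples, int(np.ceil((shift + 6.0 * sigma) / dt)) + 1)
        t = np.arange(n_kernel) * dt  # impulse convention: index 0 is t = 0
        k = np.exp(-0.5 * ((t - shift) / sigma) ** 2)
        s = k.sum()
        if s <= 0:
            raise InvalidDecayModelError("IRF kernel vanished on the grid")
        return k / s


@dataclass(frozen=True)
class DecayHistogram:
    """A 1-D photon arrival-time histogram with its time calibration."""

    counts: np.ndarray
    bin_width_ps: float

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 1:
            raise ValueError(f"counts must be 1-D, got shape {c.shape}")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        if self.bin_width_ps <= 0:
            raise ValueError(f"bin width must be positive, got {self.bin_width_ps}")
        object.__setattr__(self, "counts", c)

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def time_axis_ns(self) -> np.ndarray:
        """Bin-center times in nanoseconds."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width_ps * NS_PER_PS


def eval_model(params: BiexpParams, time_axis_ns: np.ndarray) -> np.ndarray:
    """Evaluate the unconvolved biexponential model on a time axis (ns)."""
    t = np.asarray(time_axis_ns, dtype=float)
    if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
        raise ValueError("time axis must be nonnegative and strictly increasing")
    return (
        params.a0
        + params.a1 * np.exp(-t / params.tau1)
        + params.a2 * np.exp(-t / params.tau2)
    )


def convolve_irf(model_curve: np.ndarray, irf: IRFModel, bin_width_ps: float,
                 periodic: bool = False, oversample: int = 1,
                 shift_ps: float | None = None) -> np.ndarray:
    """Convolve a sampled model curve with the IRF on the same time base.

    Default mode is causal linear convolution: the signal is taken to be zero
    before t = 0 and the output is truncated to the input length (the kernel
    has unit sum, so the full-length integral is preserved exactly; the
    truncated tail is negligible for curves that have decayed by the window
    end). ``periodic=True`` instead wraps the tail around, modelling
    incomplete decay between successive excitation pulses.
    """
    y = np.asarray(model_curve, dtype=float)
    k = irf.kernel(bin_width_ps, y.size, oversample=oversample, shift_ps=shift_ps)
    if periodic:
        kk = np.zeros(y.size)
        kk[: k.size] = k
        return np.real(np.fft.irfft(np.fft.rfft(y) * np.fft.rfft(kk), n=y.size))
    return np.convolve(y, k)[: y.size]


def model_expectation(params: BiexpParams, irf: IRFModel, n_bins: int,
                      bin_width_ps: float, oversample: int = 4,
                      periodic: bool = False,
                      shift_ps: float | None = None) -> np.ndarray:
    """Expected counts per bin for the IRF-convolved biexponential model.

    The exponential part is evaluated on an ``oversample``-times finer grid,
    convolved at that resolution, and box-integrated (averaged) back to the
    histogram bins; this avoids bin-centering bias when a lifetime is
    comparable to the bin width. The constant offset ``a0`` represents
    uncorrelated background and is added after convolution.

    Amplitudes are in counts-per-bin units (a1 + a2 is the unconvolved peak
    height of the decay part).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    dt_ns = bin_width_ps * NS_PER_PS / oversample
    t = (np.arange(n_bins * oversample) + 0.5) * dt_ns
    decay = params.a1 * np.exp(-t / params.tau1) + params.a2 * np.exp(-t / params.tau2)
    conv = convolve_irf(decay, irf, bin_width_ps, periodic=periodic,
                        oversample=oversample, shift_ps=shift_ps)
    binned = conv.reshape(n_bins, oversample).mean(axis=1)
    return params.a0 + binned


def mean_lifetime(params: BiexpParams, weighting: str = "amplitude") -> float:
    """Mean fluorescence lifetime tau_m in ns.

    ``weighting="amplitude"`` (default, the convention used for tau_m maps
    here): tau_m = (a1*tau1 + a2*tau2) / (a1 + a2). ``weighting="intensity"``
    weights each component by its integrated photon contribution a_i*tau_i.
    Both lie in [tau1, tau2].
    """
    s = params.a1 + params.a2
    if s <= 0:
        raise InvalidDecayModelError("mean lifetime undefined when a1 + a2 = 0")
    if weighting == "amplitude":
        return (params.a1 * params.tau1 + params.a2 * params.tau2) / s
    if weighting == "intensity":
        num = params.a1 * params.tau1**2 + params.a2 * params.tau2**2
        den = params.a1 * params.tau1 + params.a2 * params.tau2
        return num / den
    raise ValueError(f"unknown weighting {weighting!r}")


def amplitude_fractions(params: BiexpParams) -> tuple[float, float]:
    """Relative amplitude percentages (a1%, a2%); they sum to 100 exactly."""
    s = params.a1 + params.a2
    if s <= 0:
        raise InvalidDecayModelError("amplitude fractions undefined when a1 + a2 = 0")
    f1 = 100.0 * params.a1 / s
    return f1, 100.0 - f1
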