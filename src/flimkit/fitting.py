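"""Nonlinear estimation of decay parameters from TCSPC histograms.

Two fit modes mirror the two-pass analysis used for metabolic FLIM:

* a *free* fit estimating (a0, a1, a2, tau1, tau2) and an IRF shift nuisance
  from a pooled decay, and
* a *fixed-lifetime* refit in which tau1 and tau2 are clamped (typically to
  experiment-wide means) and only the amplitudes vary, which makes amplitude
  fractions comparable across images and is cheap enough to run per pixel.

The free fit uses variable projection: the optimizer searches over lifetimes
(and shift) while the amplitudes, which enter linearly, are solved by
nonnegative least squares at every step. The default objective is weighted
least squares with Neyman weights 1/max(counts, 1); a Poisson
maximum-likelihood polish is available and preferable below ~1e3 counts.

Estimators follow the sklearn protocol (``fit`` + trailing-underscore
attributes); ``fit_free`` / ``fit_fixed_tau`` / ``compare_models`` are thin
functional wrappers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize, nnls
from sklearn.base import BaseEstimator

from .decay import (NS_PER_PS, BiexpParams, DecayHistogram, IRFModel,
                    amplitude_fractions, convolve_irf, mean_lifetime)

__all__ = [
    "FitResult",
    "ModelComparison",
    "LowSignalError",
    "DecayFitter",
    "BiexponentialFitter",
    "MonoexponentialFitter",
    "FixedTauFitter",
    "fit_free",
    "fit_fixed_tau",
    "compare_models",
    "reduced_chi2",
]

DEFAULT_TAU_BOUNDS_NS = (0.02, 10.0)
DEFAULT_INITIAL_TAUS = (0.4, 2.5)  # free-NADH / free-FAD literature anchors


class LowSignalError(ValueError):
    """Histogram carries too few photons for a stable fit."""


def _conv_exp(tau_ns: float, irf: IRFModel, n_bins: int, bin_width_ps: float,
              oversample: int, periodic: bool, shift_ps: float) -> np.ndarray:
    """Unit-amplitude exponential decay convolved with the IRF, per bin."""
    dt_ns = bin_width_ps * NS_PER_PS / oversample
    t = (np.arange(n_bins * oversample) + 0.5) * dt_ns
    conv = convolve_irf(np.exp(-t / tau_ns), irf, bin_width_ps,
                        periodic=periodic, oversample=oversample,
                        shift_ps=shift_ps)
    return conv.reshape(n_bins, oversample).mean(axis=1)


def _auto_window(counts: np.ndarray) -> tuple[int, int]:
    """Fit window from 90% of the rising edge to the last bin."""
    if counts.sum() == 0:
        return 0, counts.size
    # light smoothing so single-photon spikes do not define the rise
    kernel = np.ones(3) / 3.0
    sm = np.convolve(counts.astype(float), kernel, mode="same")
    peak = int(np.argmax(sm))
    level = 0.9 * sm[peak]
    start = peak
    while start > 0 and sm[start - 1] >= level:
        start -= 1
    return start, counts.size


def reduced_chi2(hist: DecayHistogram, model_curve: np.ndarray,
                 n_free_params: int, window: tuple[int, int] | None = None) -> float:
    """Neyman reduced chi-square of a model curve over the fit window."""
    model_curve = np.asarray(model_curve, dtype=float)
    if np.any(model_curve < 0):
        raise ValueError("model curve must be nonnegative")
    lo, hi = window if window is not None else (0, hist.n_bins)
    obs = hist.counts[lo:hi].astype(float)
    exp = model_curve[lo:hi]
    dof = obs.size - n_free_params
    if dof <= 0:
        raise ValueError(f"nonpositive degrees of freedom ({obs.size} bins, "
                         f"{n_free_params} free parameters)")
    return float(np.sum((obs - exp) ** 2 / np.maximum(obs, 1.0)) / dof)


@dataclass(frozen=True)
class FitResult:
    """Everything a decay fit reports, with provenance for serialization."""

    params: BiexpParams
    fractions: tuple[float, float]
    tau_m: float
    chi2_red: float
    n_photons_used: int
    mode: str  # "free" | "fixed_tau" | "mono"
    converged: bool
    shift_ps: float
    window: tuple[int, int]
    objective: str
    objective_value: float
    n_free_params: int
    stderr: dict[str, float] = field(default_factory=dict)
    warnings: tuple[str, ...] = ()
    seed: int | None = None

    def model_curve(self, irf: IRFModel, n_bins: int, bin_width_ps: float,
                    oversample: int = 4, periodic: bool = False) -> np.ndarray:
        c1 = _conv_exp(self.params.tau1, irf, n_bins, bin_width_ps,
                       oversample, periodic, self.shift_ps)
        c2 = _conv_exp(self.params.tau2, irf, n_bins, bin_width_ps,
                       oversample, periodic, self.shift_ps)
        return self.params.a0 + self.params.a1 * c1 + self.params.a2 * c2

    def to_dict(self) -> dict:
        p = self.params
        d = {
            "a0": p.a0, "a1": p.a1, "a2": p.a2,
            "tau1_ns": p.tau1, "tau2_ns": p.tau2,
            "a1_pct": self.fractions[0], "a2_pct": self.fractions[1],
            "tau_m_ns": self.tau_m, "chi2_red": self.chi2_red,
            "n_photons": self.n_photons_used, "mode": self.mode,
            "converged": self.converged, "shift_ps": self.shift_ps,
            "window_start": self.window[0], "window_end": self.window[1],
            "objective": self.objective, "seed": self.seed,
            "warnings": ";".join(self.warnings),
        }
        d["options_hash"] = hashlib.sha1(
            json.dumps({"objective": self.objective, "window": self.window,
                        "mode": self.mode}, sort_keys=True).encode()
        ).hexdigest()[:12]
        return d


@dataclass(frozen=True)
class ModelComparison:
    mono: FitResult
    bi: FitResult
    delta_chi2_red: float
    bi_required: bool
    threshold: float


class DecayFitter(BaseEstimator):
    """Mono- or biexponential TCSPC decay fitter with IRF convolution.

    Parameters
    ----------
    irf : IRFModel
        Instrument response used for convolution; its nominal shift anchors
        the fitted shift nuisance.
    n_components : 1 or 2
        Number of exponential components besides the constant offset.
    fixed_taus : tuple of float or None
        If given (ns, fast then slow), lifetimes are clamped and only the
        amplitudes are estimated (linear nonnegative fit); the shift is
        frozen too.
    objective : "wls" or "poisson"
        Weighted least squares (Neyman weights) or a Poisson-likelihood
        polish started from the WLS solution.
    fit_window : (start, end) bin indices or None
        None selects the window automatically: from 90% of the rising edge
        to the last bin.
    shift_ps : float or None
        Frozen shift for fixed-tau fits (defaults to the IRF's own shift).
    """

    def __init__(self, irf: IRFModel | None = None, n_components: int = 2,
                 fixed_taus: tuple[float, float] | None = None,
                 objective: str = "wls", fit_window: tuple[int, int] | None = None,
                 min_photons: int = 1000, n_restarts: int = 5,
                 fit_shift: bool = True, shift_halfwidth_bins: float = 3.0,
                 shift_ps: float | None = None,
                 tau_bounds_ns: tuple[float, float] = DEFAULT_TAU_BOUNDS_NS,
                 initial_taus: tuple[float, float] = DEFAULT_INITIAL_TAUS,
                 oversample: int = 4, periodic: bool = False, seed: int = 0):
        self.irf = irf
        self.n_components = n_components
        self.fixed_taus = fixed_taus
        self.objective = objective
        self.fit_window = fit_window
        self.min_photons = min_photons
        self.n_restarts = n_restarts
        self.fit_shift = fit_shift
        self.shift_halfwidth_bins = shift_halfwidth_bins
        self.shift_ps = shift_ps
        self.tau_bounds_ns = tau_bounds_ns
        self.initial_taus = initial_taus
        self.oversample = oversample
        self.periodic = periodic
        self.seed = seed

    # ---------------------------------------------------------------- fit --
    def fit(self, hist: DecayHistogram, y=None) -> "DecayFitter":
        self._validate(hist)
        irf = self.irf
        window = self.fit_window or _auto_window(hist.counts)
        lo, hi = window
        if not (0 <= lo < hi <= hist.n_bins):
            raise ValueError(f"fit window {window} outside histogram")
        yobs = hist.counts.astype(float)
        w = 1.0 / np.maximum(yobs, 1.0)
        sqrtw = np.sqrt(w[lo:hi])

        if self.fixed_taus is not None:
            result = self._fit_fixed(hist, irf, window, yobs, sqrtw)
        else:
            result = self._fit_free(hist, irf, window, yobs, sqrtw)
        self.result_ = result
        self.params_ = result.params
        self.fractions_ = result.fractions
        self.tau_m_ = result.tau_m
        self.chi2_red_ = result.chi2_red
        return self

    def _validate(self, hist: DecayHistogram) -> None:
        if not isinstance(hist, DecayHistogram):
            raise TypeError("fit expects a DecayHistogram")
        if self.irf is None:
            raise ValueError("an IRFModel is required")
        if self.n_components not in (1, 2):
            raise ValueError("n_components must be 1 or 2")
        if self.objective not in ("wls", "poisson"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.fixed_taus is not None:
            t1, t2 = self.fixed_taus
            if not (0 < t1 < t2):
                raise ValueError(
                    f"fixed lifetimes need 0 < tau1 < tau2, got {t1}, {t2}")
        if hist.total < self.min_photons:
            raise LowSignalError(
                f"histogram has {hist.total} photons; "
                f"minimum for fitting is {self.min_photons}")

    # -------------------------------------------------------- linear stage --
    def _amplitudes(self, taus: list[float], shift: float, hist: DecayHistogram,
                    irf: IRFModel, window: tuple[int, int], yobs: np.ndarray,
                    sqrtw: np.ndarray) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
        """Solve (a0, a1[, a2]) >= 0 by weighted NNLS at given lifetimes."""
        lo, hi = window
        comps = [_conv_exp(t, irf, hist.n_bins, hist.bin_width_ps,
                           self.oversample, self.periodic, shift) for t in taus]
        A = np.column_stack([np.ones(hi - lo)] + [c[lo:hi] for c in comps])
        coef, _ = nnls(A * sqrtw[:, None], yobs[lo:hi] * sqrtw)
        resid = (yobs[lo:hi] - A @ coef) * sqrtw
        return coef, resid, comps

    # ----------------------------------------------------------- free fits --
    def _fit_free(self, hist, irf, window, yobs, sqrtw) -> FitResult:
        lo, hi = window
        shift0 = irf.shift_ps if self.shift_ps is None else self.shift_ps
        dshift = self.shift_halfwidth_bins * hist.bin_width_ps
        tlo, thi = self.tau_bounds_ns
        k = self.n_components
        rng = np.random.default_rng(self.seed)

        def unpack(x):
            taus = list(x[:k])
            shift = x[k] if self.fit_shift else shift0
            return taus, shift

        def residuals(x):
            taus, shift = unpack(x)
            _, resid, _ = self._amplitudes(taus, shift, hist, irf, window,
                                           yobs, sqrtw)
            return resid

        if k == 2:
            base = list(self.initial_taus)
        else:
            base = [float(np.sqrt(self.initial_taus[0] * self.initial_taus[1]))]
        lb = [tlo] * k + ([shift0 - dshift] if self.fit_shift else [])
        ub = [thi] * k + ([shift0 + dshift] if self.fit_shift else [])
        x_scale = [0.1] * k + ([hist.bin_width_ps] if self.fit_shift else [])

        starts = [np.array(base + ([shift0] if self.fit_shift else []))]
        for _ in range(max(0, self.n_restarts - 1)):
            taus = np.clip(np.array(base) * np.exp(rng.normal(0, 0.3, size=k)),
                           tlo * 1.01, thi * 0.99)
            taus.sort()
            s = (shift0 + rng.uniform(-0.5, 0.5) * dshift) if self.fit_shift else None
            starts.append(np.array(list(taus) + ([s] if s is not None else [])))

        best = None
        best_obj = np.inf
        best_tau1 = np.inf
        any_converged = False
        for x0 in starts:
            try:
                sol = least_squares(residuals, x0, bounds=(lb, ub),
                                    x_scale=x_scale, max_nfev=400)
            except Exception:
                continue
            obj = 2.0 * sol.cost
            taus, _ = unpack(sol.x)
            t1 = min(taus)
            # ties broken by lowest tau1
            if obj < best_obj * (1 - 1e-12) or (
                    abs(obj - best_obj) <= 1e-12 * max(best_obj, 1.0)
                    and t1 < best_tau1):
                best, best_obj, best_tau1 = sol, obj, t1
                any_converged = any_converged or bool(sol.success)
            elif sol.success:
                any_converged = True
        if best is None:
            raise RuntimeError("free fit failed for every start")

        taus, shift = unpack(best.x)
        coef, resid, comps = self._amplitudes(taus, shift, hist, irf, window,
                                              yobs, sqrtw)
        warnings_: list[str] = []
        if not best.success:
            warnings_.append("nonconvergence: optimizer did not report success")
        obj_val = float(resid @ resid)

        if self.objective == "poisson":
            coef, taus, shift, obj_val, ok = self._poisson_polish(
                hist, irf, window, coef, taus, shift, shift0, dshift)
            if not ok:
                warnings_.append("poisson polish did not converge; WLS solution kept")
            _, _, comps = self._amplitudes(taus, shift, hist, irf, window,
                                           yobs, sqrtw)

        if k == 2:
            params = BiexpParams(a0=coef[0], a1=coef[1], a2=coef[2],
                                 tau1=taus[0], tau2=taus[1])
            if abs(params.tau2 - params.tau1) <= 0.05 * params.tau2:
                warnings_.append("collinearity: tau1 and tau2 within 5%")
            mode = "free"
            nfree = 5 + int(self.fit_shift)
        else:
            params = BiexpParams(a0=coef[0], a1=coef[1], a2=0.0,
                                 tau1=taus[0], tau2=taus[0])
            mode = "mono"
            nfree = 3 + int(self.fit_shift)

        return self._finalize(hist, irf, params, mode, nfree, shift, window,
                              obj_val, warnings_,
                              converged=bool(best.success) or any_converged,
                              stderr=self._stderr_free(hist, irf, params, shift,
                                                       window, sqrtw, k))

    def _poisson_polish(self, hist, irf, window, coef, taus, shift,
                        shift0, dshift):
        """Maximize the Poisson likelihood starting from the WLS solution."""
        lo, hi = window
        yobs = hist.counts[lo:hi].astype(float)
        k = len(taus)
        tlo, thi = self.tau_bounds_ns

        def nll(x):
            a = x[:k + 1]
            ts = x[k + 1:2 * k + 1]
            s = x[-1] if self.fit_shift else shift
            comps = [_conv_exp(t, irf, hist.n_bins, hist.bin_width_ps,
                               self.oversample, self.periodic, s) for t in ts]
            lam = a[0] + sum(ai * c[lo:hi] for ai, c in zip(a[1:], comps))
            lam = np.maximum(lam, 1e-12)
            return float(np.sum(lam - yobs * np.log(lam)))

        x0 = np.concatenate([coef, taus, [shift] if self.fit_shift else []])
        bounds = ([(0, None)] * (k + 1) + [(tlo, thi)] * k
                  + ([(shift0 - dshift, shift0 + dshift)] if self.fit_shift else []))
        sol = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 300})
        x = sol.x
        new_shift = x[-1] if self.fit_shift else shift
        return (x[:k + 1], list(x[k + 1:2 * k + 1]), new_shift,
                float(sol.fun), bool(sol.success))

    # ---------------------------------------------------------- fixed taus --
    def _fit_fixed(self, hist, irf, window, yobs, sqrtw) -> FitResult:
        t1, t2 = self.fixed_taus
        shift = self.irf.shift_ps if self.shift_ps is None else self.shift_ps
        coef, resid, comps = self._amplitudes([t1, t2], shift, hist, irf,
                                              window, yobs, sqrtw)
        params = BiexpParams(a0=coef[0], a1=coef[1], a2=coef[2],
                             tau1=t1, tau2=t2)
        stderr = self._stderr_linear(hist, window, sqrtw, comps)
        return self._finalize(hist, irf, params, "fixed_tau", 3, shift, window,
                              float(resid @ resid), [], converged=True,
                              stderr=stderr)

    # ------------------------------------------------------------- helpers --
    def _finalize(self, hist, irf, params, mode, nfree, shift, window,
                  obj_val, warnings_, converged, stderr) -> FitResult:
        curve = (params.a0
                 + params.a1 * _conv_exp(params.tau1, irf, hist.n_bins,
                                         hist.bin_width_ps, self.oversample,
                                         self.periodic, shift)
                 + params.a2 * _conv_exp(params.tau2, irf, hist.n_bins,
                                         hist.bin_width_ps, self.oversample,
                                         self.periodic, shift))
        chi2 = reduced_chi2(hist, curve, nfree, window)
        if params.total_amplitude > 0:
            fr = amplitude_fractions(params)
            tm = mean_lifetime(params)
        else:
            fr, tm = (float("nan"), float("nan")), float("nan")
            warnings_ = list(warnings_) + ["degenerate: zero total amplitude"]
        return FitResult(params=params, fractions=fr, tau_m=tm, chi2_red=chi2,
                         n_photons_used=hist.total, mode=mode,
                         converged=converged, shift_ps=float(shift),
                         window=tuple(window), objective=self.objective,
                         objective_value=obj_val, n_free_params=nfree,
                         stderr=stderr, warnings=tuple(warnings_),
                         seed=self.seed)

    def _stderr_linear(self, hist, window, sqrtw, comps) -> dict[str, float]:
        lo, hi = window
        A = np.column_stack([np.ones(hi - lo)] + [c[lo:hi] for c in comps])
        Aw = A * sqrtw[:, None]
        try:
            cov = np.linalg.inv(Aw.T @ Aw)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se = np.full(A.shape[1], np.nan)
        names = ["a0", "a1", "a2"][: len(se)]
        return dict(zip(names, se.tolist()))

    def _stderr_free(self, hist, irf, params, shift, window, sqrtw, k
                     ) -> dict[str, float]:
        """Gauss-Newton standard errors via a finite-difference Jacobian."""
        lo, hi = window
        names = (["a0", "a1", "a2", "tau1_ns", "tau2_ns"] if k == 2
                 else ["a0", "a1", "tau1_ns"])
        x0 = (np.array([params.a0, params.a1, params.a2, params.tau1,
                        params.tau2]) if k == 2
              else np.array([params.a0, params.a1, params.tau1]))

        def model(x):
            if k == 2:
                c1 = _conv_exp(x[3], irf, hist.n_bins, hist.bin_width_ps,
                               self.oversample, self.periodic, shift)
                c2 = _conv_exp(x[4], irf, hist.n_bins, hist.bin_width_ps,
                               self.oversample, self.periodic, shift)
                return x[0] + x[1] * c1[lo:hi] + x[2] * c2[lo:hi]
            c1 = _conv_exp(x[2], irf, hist.n_bins, hist.bin_width_ps,
                           self.oversample, self.periodic, shift)
            return x[0] + x[1] * c1[lo:hi]

        try:
            J = np.empty((hi - lo, x0.size))
            f0 = model(x0)
            for j in range(x0.size):
                h = 1e-6 * max(abs(x0[j]), 1e-3)
                xp = x0.copy()
                xp[j] += h
                J[:, j] = (model(xp) - f0) / h
            Jw = J * sqrtw[:, None]
            cov = np.linalg.pinv(Jw.T @ Jw)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
            return dict(zip(names, se.tolist()))
        except Exception:
            return dict.fromkeys(names, float("nan"))


class BiexponentialFitter(DecayFitter):
    """Free biexponential fit (both lifetimes and amplitudes estimated)."""

    def __init__(self, irf=None, objective="wls", fit_window=None,
                 min_photons=1000, n_restarts=5, fit_shift=True,
                 shift_halfwidth_bins=3.0, shift_ps=None,
                 tau_bounds_ns=DEFAULT_TAU_BOUNDS_NS,
                 initial_taus=DEFAULT_INITIAL_TAUS, oversample=4,
                 periodic=False, seed=0):
        super().__init__(irf=irf, n_components=2, fixed_taus=None,
                         objective=objective, fit_window=fit_window,
                         min_photons=min_photons, n_restarts=n_restarts,
                         fit_shift=fit_shift,
                         shift_halfwidth_bins=shift_halfwidth_bins,
                         shift_ps=shift_ps, tau_bounds_ns=tau_bounds_ns,
                         initial_taus=initial_taus, oversample=oversample,
                         periodic=periodic, seed=seed)

    def _get_param_names(self=None):
        return [p for p in DecayFitter._get_param_names()
                if p not in ("n_components", "fixed_taus")]


class MonoexponentialFitter(DecayFitter):
    """Single-exponential fit, used for model-adequacy comparison."""

    def __init__(self, irf=None, objective="wls", fit_window=None,
                 min_photons=1000, n_restarts=5, fit_shift=True,
                 shift_halfwidth_bins=3.0, shift_ps=None,
                 tau_bounds_ns=DEFAULT_TAU_BOUNDS_NS,
                 initial_taus=DEFAULT_INITIAL_TAUS, oversample=4,
                 periodic=False, seed=0):
        super().__init__(irf=irf, n_components=1, fixed_taus=None,
                         objective=objective, fit_window=fit_window,
                         min_photons=min_photons, n_restarts=n_restarts,
                         fit_shift=fit_shift,
                         shift_halfwidth_bins=shift_halfwidth_bins,
                         shift_ps=shift_ps, tau_bounds_ns=tau_bounds_ns,
                         initial_taus=initial_taus, oversample=oversample,
                         periodic=periodic, seed=seed)

    _get_param_names = BiexponentialFitter._get_param_names


class FixedTauFitter(DecayFitter):
    """Amplitude-only fit with both lifetimes clamped to given values."""

    def __init__(self, irf=None, tau1_ns: float = 0.4, tau2_ns: float = 2.5,
                 objective="wls", fit_window=None, min_photons=1000,
                 shift_ps=None, oversample=4, periodic=False, seed=0):
        self.tau1_ns = tau1_ns
        self.tau2_ns = tau2_ns
        super().__init__(irf=irf, n_components=2,
                         fixed_taus=(tau1_ns, tau2_ns), objective=objective,
                         fit_window=fit_window, min_photons=min_photons,
                         shift_ps=shift_ps, oversample=oversample,
                         periodic=periodic, seed=seed)

    def _get_param_names(self=None):
        return ["irf", "tau1_ns", "tau2_ns", "objective", "fit_window",
                "min_photons", "shift_ps", "oversample", "periodic", "seed"]

    def set_params(self, **params):
        super().set_params(**params)
        if "tau1_ns" in params or "tau2_ns" in params:
            self.fixed_taus = (self.tau1_ns, self.tau2_ns)
        return self


# ------------------------------------------------------ functional wrappers --

def fit_free(hist: DecayHistogram, irf: IRFModel, **options) -> FitResult:
    """Free biexponential fit of a pooled decay histogram."""
    return BiexponentialFitter(irf=irf, **options).fit(hist).result_


def fit_fixed_tau(hist: DecayHistogram, irf: IRFModel, tau1_ns: float,
                  tau2_ns: float, **options) -> FitResult:
    """Amplitude-only refit at clamped lifetimes (two-pass second stage)."""
    return FixedTauFitter(irf=irf, tau1_ns=tau1_ns, tau2_ns=tau2_ns,
                          **options).fit(hist).result_


def compare_models(hist: DecayHistogram, irf: IRFModel, threshold: float = 0.2,
                   **options) -> ModelComparison:
    """Mono vs biexponential adequacy check on one histogram.

    Flags "biexponential required" when the reduced chi-square improves by
    more than ``threshold`` going from one to two components.
    """
    mono = MonoexponentialFitter(irf=irf, **options).fit(hist).result_
    bi = BiexponentialFitter(irf=irf, **options).fit(hist).result_
    delta = mono.chi2_red - bi.chi2_red
    return ModelComparison(mono=mono, bi=bi, delta_chi2_red=float(delta),
                           bi_required=bool(delta > threshold),
                           threshold=threshold)
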