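"""Image-level FLIM analysis: masking, decay pooling, two-pass fits, maps.

The procedure mirrors the whole-image analysis used for metabolic FLIM of
differentiating keratinocytes:

1. an intensity threshold excludes dark background pixels from each image;
2. photon decays of all retained pixels are summed into one pooled histogram
   per image and fit freely with the biexponential model (pass 1);
3. per channel, tau1 and tau2 are averaged over all fields-of-view of the
   experiment and the pooled fits are repeated with the lifetimes clamped to
   those means, so only the amplitudes vary (pass 2);
4. the same fixed-lifetime fit runs per pixel (after optional square spatial
   binning) to produce mean-lifetime and amplitude-fraction maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from scipy.optimize import nnls
from skimage.filters import threshold_otsu

from .decay import DecayHistogram, IRFModel
from .fitting import DecayFitter, FitResult, _conv_exp, fit_fixed_tau, fit_free
from .io import TCSPCImage

__all__ = [
    "RoiMask",
    "LifetimeMap",
    "TwoPassResult",
    "NoSignalError",
    "ExperimentError",
    "threshold_mask",
    "pool_decays",
    "run_two_pass",
    "pixelwise_map",
]

logger = logging.getLogger(__name__)


class NoSignalError(ValueError):
    """The threshold left no pixels in the region of interest."""


class ExperimentError(RuntimeError):
    """No image of an experiment produced a usable fit."""


@dataclass(frozen=True)
class RoiMask:
    mask: np.ndarray
    threshold: float
    retained_fraction: float


@dataclass
class LifetimeMap:
    """Per-pixel fixed-lifetime fit outputs; NaN marks unfitted pixels."""

    tau_m: np.ndarray
    a1_pct: np.ndarray
    a2_pct: np.ndarray
    chi2_red: np.ndarray
    fitted: np.ndarray      # bool: pixel was fit
    background: np.ndarray  # bool: excluded by the intensity mask
    tau1_ns: float
    tau2_ns: float
    binning: int


@dataclass
class TwoPassResult:
    """Outputs of the experiment-wide two-pass analysis."""

    table: pd.DataFrame                      # one row per image: both passes
    fixed_taus: dict[str, tuple[float, float]]  # per channel (tau1, tau2) ns
    free_fits: list[FitResult | None]
    fixed_fits: list[FitResult | None]
    excluded: list[tuple[int, str]] = field(default_factory=list)


def threshold_mask(image: TCSPCImage, policy="otsu") -> RoiMask:
    """Intensity mask over the summed-count image.

    ``policy`` is ``"otsu"`` (default), a fixed numeric threshold, or
    ``("percentile", q)``. Pixels with summed counts >= threshold are kept.
    """
    intensity = image.summed_intensity()
    if intensity.size == 0:
        raise ValueError("empty image")
    if policy == "otsu":
        if intensity.min() == intensity.max():
            thr = float(intensity.max()) + 1.0  # uniform image: nothing stands out
        else:
            thr = float(threshold_otsu(intensity))
    elif isinstance(policy, tuple) and policy[0] == "percentile":
        thr = float(np.percentile(intensity, policy[1]))
    elif np.isscalar(policy):
        thr = float(policy)
    else:
        raise ValueError(f"unknown threshold policy {policy!r}")
    mask = intensity >= thr
    if not mask.any():
        raise NoSignalError(f"threshold {thr:g} removed every pixel")
    return RoiMask(mask=mask, threshold=thr,
                   retained_fraction=float(mask.mean()))


def pool_decays(image: TCSPCImage, mask: RoiMask | np.ndarray) -> DecayHistogram:
    """Bin-wise sum of the decays of all masked pixels."""
    m = mask.mask if isinstance(mask, RoiMask) else np.asarray(mask)
    if m.shape != image.counts.shape[:2]:
        raise ValueError(f"mask shape {m.shape} does not match image "
                         f"{image.counts.shape[:2]}")
    if not m.any():
        raise NoSignalError("mask is empty")
    pooled = image.counts[m].sum(axis=0)
    return DecayHistogram(counts=pooled, bin_width_ps=image.bin_width_ps)


def run_two_pass(images: list[TCSPCImage], irf: IRFModel,
                 threshold_policy="otsu", tau_mean: str = "unweighted",
                 **fit_options) -> TwoPassResult:
    """Experiment-wide two-pass pooled analysis.

    Pass 1 fits each image's pooled decay freely; per channel the lifetimes
    are averaged over all fields-of-view (unweighted by default, each image
    counting once; ``tau_mean="photon"`` weights by pooled photon count).
    Pass 2 refits every pooled decay with the channel's mean lifetimes
    clamped, keeping the per-image pass-1 shift. Images whose free fit fails
    are excluded with a logged reason.
    """
    if not images:
        raise ExperimentError("no images supplied")
    free_fits: list[FitResult | None] = []
    pooled_hists: list[DecayHistogram | None] = []
    excluded: list[tuple[int, str]] = []
    for i, im in enumerate(images):
        try:
            m = threshold_mask(im, threshold_policy)
            h = pool_decays(im, m)
            free_fits.append(fit_free(h, irf, **fit_options))
            pooled_hists.append(h)
        except Exception as exc:
            logger.warning("image %d (%s day %s) excluded from pass 1: %s",
                           i, im.channel, im.day, exc)
            free_fits.append(None)
            pooled_hists.append(None)
            excluded.append((i, str(exc)))

    channels = sorted({im.channel for im in images})
    fixed_taus: dict[str, tuple[float, float]] = {}
    for ch in channels:
        idx = [i for i, im in enumerate(images)
               if im.channel == ch and free_fits[i] is not None]
        if not idx:
            raise ExperimentError(f"every {ch} image failed pass 1")
        t1s = np.array([free_fits[i].params.tau1 for i in idx])
        t2s = np.array([free_fits[i].params.tau2 for i in idx])
        if tau_mean == "photon":
            wts = np.array([free_fits[i].n_photons_used for i in idx], dtype=float)
            fixed_taus[ch] = (float(np.average(t1s, weights=wts)),
                              float(np.average(t2s, weights=wts)))
        else:
            fixed_taus[ch] = (float(t1s.mean()), float(t2s.mean()))

    fixed_fits: list[FitResult | None] = []
    rows = []
    for i, im in enumerate(images):
        if free_fits[i] is None:
            fixed_fits.append(None)
            continue
        t1, t2 = fixed_taus[im.channel]
        fx = fit_fixed_tau(pooled_hists[i], irf, t1, t2,
                           shift_ps=free_fits[i].shift_ps,
                           **{k: v for k, v in fit_options.items()
                              if k not in ("n_restarts", "fit_shift")})
        fixed_fits.append(fx)
        row = {"image_index": i, "channel": im.channel, "day": im.day,
               "treatment": im.treatment, "fov": im.fov,
               "fixed_tau1_ns": t1, "fixed_tau2_ns": t2}
        row.update({f"free_{k}": v for k, v in free_fits[i].to_dict().items()})
        row.update({f"fixed_{k}": v for k, v in fx.to_dict().items()})
        rows.append(row)
    if not rows:
        raise ExperimentError("every image was excluded in pass 1")
    return TwoPassResult(table=pd.DataFrame(rows), fixed_taus=fixed_taus,
                         free_fits=free_fits, fixed_fits=fixed_fits,
                         excluded=excluded)


def pixelwise_map(image: TCSPCImage, mask: RoiMask | np.ndarray, irf: IRFModel,
                  tau1_ns: float, tau2_ns: float, binning: int = 1,
                  min_photons_pixel: int = 100, shift_ps: float | None = None,
                  oversample: int = 4, periodic: bool = False) -> LifetimeMap:
    """Fixed-lifetime amplitude fit per pixel, producing parameter maps.

    ``binning=b`` sums counts over a (2b+1) x (2b+1) square around each pixel
    before fitting, trading spatial resolution for photon statistics. Pixels
    below ``min_photons_pixel`` after binning are flagged unfitted (NaN),
    never an error. Amplitudes are solved by weighted nonnegative least
    squares against the IRF-convolved component curves; the whole-image
    solve is vectorized, with a per-pixel NNLS fallback where the
    unconstrained solution goes negative.
    """
    if not (0 < tau1_ns < tau2_ns):
        raise ValueError("need 0 < tau1 < tau2")
    m = mask.mask if isinstance(mask, RoiMask) else np.asarray(mask)
    rows, cols, nb = image.counts.shape
    if m.shape != (rows, cols):
        raise ValueError("mask shape mismatch")

    stack = image.counts.astype(float)
    if binning > 0:
        size = 2 * binning + 1
        stack = uniform_filter(stack, size=(size, size, 1), mode="constant") \
            * (size * size)
    shift = irf.shift_ps if shift_ps is None else shift_ps
    c1 = _conv_exp(tau1_ns, irf, nb, image.bin_width_ps, oversample, periodic, shift)
    c2 = _conv_exp(tau2_ns, irf, nb, image.bin_width_ps, oversample, periodic, shift)
    A = np.column_stack([np.ones(nb), c1, c2])

    nan = np.full((rows, cols), np.nan)
    out = LifetimeMap(tau_m=nan.copy(), a1_pct=nan.copy(), a2_pct=nan.copy(),
                      chi2_red=nan.copy(), fitted=np.zeros((rows, cols), bool),
                      background=~m, tau1_ns=tau1_ns, tau2_ns=tau2_ns,
                      binning=binning)
    totals = stack.sum(axis=2)
    sel = m & (totals >= min_photons_pixel)
    if not sel.any():
        return out
    Y = stack[sel]                       # (npix, nb)

    def _solve(W):
        # per-pixel weighted normal equations, vectorized
        G = np.einsum("pb,bi,bj->pij", W, A, A)
        rhs = np.einsum("pb,bi,pb->pi", W, A, Y)
        try:
            c = np.linalg.solve(G, rhs[..., None])[..., 0]
        except np.linalg.LinAlgError:
            c = np.stack([np.linalg.lstsq(Gi, ri, rcond=None)[0]
                          for Gi, ri in zip(G, rhs)])
        bad = (c < -1e-12).any(axis=1)
        for p in np.flatnonzero(bad):
            s = np.sqrt(W[p])
            c[p] = nnls(A * s[:, None], Y[p] * s)[0]
        return np.maximum(c, 0.0)

    # Neyman start, then iterate to model-based (Pearson) weights, which are
    # far less biased at the low counts typical of single pixels
    W = 1.0 / np.maximum(Y, 1.0)
    coef = _solve(W)
    for _ in range(2):
        model = np.maximum(coef @ A.T, 0.5)
        coef = _solve(1.0 / model)

    a1, a2 = coef[:, 1], coef[:, 2]
    s = a1 + a2
    ok = s > 0
    f1 = np.where(ok, 100.0 * a1 / np.where(ok, s, 1.0), np.nan)
    tm = np.where(ok, (a1 * tau1_ns + a2 * tau2_ns) / np.where(ok, s, 1.0), np.nan)
    model = coef @ A.T
    resid2 = (Y - model) ** 2 * W
    dof = nb - 3
    chi2 = resid2.sum(axis=1) / dof

    out.a1_pct[sel] = f1
    out.a2_pct[sel] = 100.0 - f1
    out.tau_m[sel] = tm
    out.chi2_red[sel] = chi2
    out.fitted[sel] = ok
    return out
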