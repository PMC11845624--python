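"""Seeded synthetic TCSPC data: decays, two-channel image stacks, timecourses.

The generator emulates the statistical structure of live-cell metabolic
MPM-FLIM acquisitions: per-pixel biexponential decays (fast/slow lifetime
pairs typical of the NADH and FAD autofluorescence channels) convolved with
a ~300 ps FWHM Gaussian instrument response, Poisson photon noise, dark
background below an intensity threshold, elliptical cell-shaped foreground
regions, and a day-by-day drift of the fast-component amplitude fraction
that mimics a metabolic shift from glycolysis toward oxidative
phosphorylation during differentiation.

Everything is deterministic under a seed: the same configuration yields
bit-identical stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .decay import BiexpParams, DecayHistogram, IRFModel, model_expectation
from .io import TCSPCImage, write_image

__all__ = [
    "ChannelTruth",
    "SimulationConfig",
    "GroundTruthMap",
    "TimecourseDataset",
    "SimulationConfigError",
    "PlacementError",
    "generate_decay",
    "generate_image",
    "generate_timecourse",
    "default_config",
]


class SimulationConfigError(ValueError):
    """Invalid simulation configuration."""


class PlacementError(RuntimeError):
    """Cells could not be placed without overlap within the retry budget."""


@dataclass(frozen=True)
class ChannelTruth:
    """Ground-truth decay parameters for one spectral channel.

    ``a1_fraction_by_day[d]`` is the amplitude fraction a1/(a1+a2) of the
    fast component on day ``d``. For the NADH channel the fast component is
    free NADH, so its fraction falls as cells shift toward oxidative
    phosphorylation; for the FAD channel the *slow* component is free FAD,
    so there a1 rises (equivalently a2 = 1 - a1 falls).
    """

    name: str
    tau1_ns: float
    tau2_ns: float
    a1_fraction_by_day: tuple[float, ...]
    offset_fraction: float = 0.005

    def __post_init__(self) -> None:
        if not (0 < self.tau1_ns < self.tau2_ns):
            raise SimulationConfigError(
                f"need 0 < tau1 < tau2, got {self.tau1_ns}, {self.tau2_ns}"
            )
        fr = tuple(float(f) for f in self.a1_fraction_by_day)
        if not fr or any(not (0.0 < f < 1.0) for f in fr):
            raise SimulationConfigError("every a1 fraction must lie in (0, 1)")
        if not (0.0 <= self.offset_fraction < 1.0):
            raise SimulationConfigError("offset fraction must lie in [0, 1)")
        object.__setattr__(self, "a1_fraction_by_day", fr)


# Channel lifetime truths used throughout: fast/slow pairs of 0.53/2.53 ns
# (NADH channel) and 0.41/2.43 ns (FAD channel), the experiment-wide means
# reported for keratinocyte autofluorescence. Drift schedules are linear and
# are a modelling choice, not measured values.
DEFAULT_NADH = ChannelTruth(
    name="NADH", tau1_ns=0.53, tau2_ns=2.53,
    a1_fraction_by_day=(0.85, 0.8125, 0.775, 0.7375, 0.70),
)
DEFAULT_FAD = ChannelTruth(
    name="FAD", tau1_ns=0.41, tau2_ns=2.43,
    a1_fraction_by_day=(0.30, 0.34, 0.38, 0.42, 0.46),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a synthetic acquisition.

    Defaults: 256 time bins of 48.8 ps (a 12.5 ns window, matching an 80 MHz
    Ti:Sapphire repetition rate), 300 ps FWHM Gaussian IRF peaking 1.22 ns
    into the window, 64 x 64 pixel fields-of-view with 5 elliptical cells.
    """

    n_time_bins: int = 256
    bin_width_ps: float = 48.8
    image_size: tuple[int, int] = (64, 64)
    irf_fwhm_ps: float = 300.0
    irf_shift_ps: float = 1220.0
    n_cells: int = 5
    cell_radius_range: tuple[float, float] = (5.0, 10.0)
    photons_per_cell_pixel: float = 250.0
    background_rate: float = 2.0
    channels: tuple[ChannelTruth, ...] = (DEFAULT_NADH, DEFAULT_FAD)
    days: tuple[int, ...] = (0, 1, 2, 3, 4)
    n_fov: int = 9
    fraction_jitter_sd: float = 0.02
    oversample: int = 4
    periodic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_time_bins < 8:
            raise SimulationConfigError("need at least 8 time bins")
        if self.bin_width_ps <= 0 or self.irf_fwhm_ps <= 0:
            raise SimulationConfigError("bin width and IRF FWHM must be positive")
        if not (self.photons_per_cell_pixel > self.background_rate >= 0):
            raise SimulationConfigError(
                "need photons_per_cell_pixel > background_rate >= 0"
            )
        if self.cell_radius_range[0] <= 0 or self.cell_radius_range[0] > self.cell_radius_range[1]:
            raise SimulationConfigError("invalid cell radius range")
        if self.n_cells < 0 or self.n_fov < 1:
            raise SimulationConfigError("n_cells must be >= 0 and n_fov >= 1")
        for ch in self.channels:
            if len(ch.a1_fraction_by_day) < len(self.days):
                raise SimulationConfigError(
                    f"channel {ch.name} drift schedule covers "
                    f"{len(ch.a1_fraction_by_day)} days, config has {len(self.days)}"
                )

    @property
    def irf(self) -> IRFModel:
        return IRFModel(kind="gaussian", fwhm_ps=self.irf_fwhm_ps,
                        shift_ps=self.irf_shift_ps)

    def channel(self, name: str) -> ChannelTruth:
        for ch in self.channels:
            if ch.name == name:
                return ch
        raise KeyError(f"no channel named {name!r}")


def default_config(**overrides) -> SimulationConfig:
    """The package's reference study conditions, with keyword overrides."""
    return replace(SimulationConfig(), **overrides) if overrides else SimulationConfig()


@dataclass
class GroundTruthMap:
    """Per-pixel ground truth accompanying a generated image."""

    a0: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    tau1: np.ndarray
    tau2: np.ndarray
    cell_id: np.ndarray  # 0 = background
    day: int
    channel: str
    cell_a1_fractions: dict[int, float] = field(default_factory=dict)

    @property
    def foreground(self) -> np.ndarray:
        return self.cell_id > 0

    def mean_a1_fraction(self) -> float:
        """Amplitude-fraction a1/(a1+a2) averaged over foreground pixels."""
        m = self.foreground
        s = self.a1[m] + self.a2[m]
        return float(np.mean(self.a1[m] / s)) if m.any() else float("nan")


def _scaled_params(truth: ChannelTruth, a1_fraction: float, total_photons: float,
                   config: SimulationConfig) -> tuple[BiexpParams, np.ndarray]:
    """Ground-truth counts-per-bin parameters and the expected-count curve.

    Amplitudes are scaled so the expected total over the window equals
    ``total_photons``, with ``offset_fraction`` of it in the constant a0.
    """
    f1 = float(a1_fraction)
    unit = BiexpParams(a0=0.0, a1=f1, a2=1.0 - f1,
                       tau1=truth.tau1_ns, tau2=truth.tau2_ns)
    shape = model_expectation(unit, config.irf, config.n_time_bins,
                              config.bin_width_ps, oversample=config.oversample,
                              periodic=config.periodic)
    decay_sum = shape.sum()
    off = truth.offset_fraction
    if total_photons <= 0:
        scale, a0 = 0.0, 0.0
    else:
        scale = (1.0 - off) * total_photons / decay_sum
        a0 = off * total_photons / config.n_time_bins
    params = BiexpParams(a0=a0, a1=scale * f1, a2=scale * (1.0 - f1),
                         tau1=truth.tau1_ns, tau2=truth.tau2_ns)
    return params, a0 + scale * shape


def generate_decay(truth: ChannelTruth, day: int, total_photons: float,
                   config: SimulationConfig, seed: int | None = None,
                   rng: np.random.Generator | None = None,
                   expectation: bool = False) -> tuple[DecayHistogram, BiexpParams]:
    """One pooled synthetic decay histogram plus its ground-truth parameters.

    Counts are Poisson draws around the IRF-convolved model expectation;
    ``expectation=True`` returns the noise-free expected curve instead
    (useful as a fitting oracle).
    """
    if total_photons < 0:
        raise ValueError("total_photons must be >= 0")
    if not (0 <= day < len(truth.a1_fraction_by_day)):
        raise SimulationConfigError(f"day {day} outside drift schedule of {truth.name}")
    params, lam = _scaled_params(truth, truth.a1_fraction_by_day[day],
                                 total_photons, config)
    if expectation:
        counts = lam
    else:
        if rng is None:
            rng = np.random.default_rng(config.seed if seed is None else seed)
        counts = rng.poisson(lam)
    return DecayHistogram(counts=counts, bin_width_ps=config.bin_width_ps), params


def _place_cells(config: SimulationConfig, rng: np.random.Generator,
                 max_retries: int = 200) -> list[tuple[float, float, float, float, float]]:
    """Non-overlapping ellipses as (row, col, semi_r, semi_c, angle)."""
    rows, cols = config.image_size
    lo, hi = config.cell_radius_range
    placed: list[tuple[float, float, float, float, float]] = []
    for _ in range(config.n_cells):
        for attempt in range(max_retries):
            a = rng.uniform(lo, hi)
            b = rng.uniform(lo, hi)
            r = rng.uniform(max(a, b), rows - max(a, b)) if rows > 2 * max(a, b) else rows / 2
            c = rng.uniform(max(a, b), cols - max(a, b)) if cols > 2 * max(a, b) else cols / 2
            theta = rng.uniform(0, np.pi)
            # conservative overlap test on bounding circles
            if all(np.hypot(r - r2, c - c2) > max(a, b) + m2 + 1.0
                   for (r2, c2, a2, b2, _t), m2 in
                   ((p, max(p[2], p[3])) for p in placed)):
                placed.append((r, c, a, b, theta))
                break
        else:
            raise PlacementError(
                f"could not place cell {len(placed) + 1}/{config.n_cells} "
                f"after {max_retries} retries"
            )
    return placed


def _ellipse_mask(shape: tuple[int, int],
                  ellipse: tuple[float, float, float, float, float]) -> np.ndarray:
    r0, c0, a, b, theta = ellipse
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    dr, dc = rr - r0, cc - c0
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_image(config: SimulationConfig, day: int, channel: str,
                   seed: int | None = None,
                   rng: np.random.Generator | None = None
                   ) -> tuple[TCSPCImage, GroundTruthMap]:
    """One synthetic field-of-view: cells on dark background, Poisson noise.

    Cell interiors share a per-cell amplitude fraction (the day's scheduled
    value plus small Gaussian jitter, sd ``fraction_jitter_sd``, clipped to
    (0.01, 0.99)); background pixels carry flat low-rate dark counts.
    """
    truth = config.channel(channel)
    if not (0 <= day < len(truth.a1_fraction_by_day)):
        raise SimulationConfigError(f"day {day} outside drift schedule of {channel}")
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    rows, cols = config.image_size
    nb = config.n_time_bins
    cells = _place_cells(config, rng)

    gt = GroundTruthMap(
        a0=np.zeros((rows, cols)), a1=np.zeros((rows, cols)),
        a2=np.zeros((rows, cols)), tau1=np.full((rows, cols), truth.tau1_ns),
        tau2=np.full((rows, cols), truth.tau2_ns),
        cell_id=np.zeros((rows, cols), dtype=np.int32),
        day=day, channel=channel,
    )
    counts = np.empty((rows, cols, nb), dtype=np.int64)
    # background: flat dark counts, expected total background_rate per pixel
    bg_lam = config.background_rate / nb
    counts[:] = rng.poisson(bg_lam, size=(rows, cols, nb))

    f_day = truth.a1_fraction_by_day[day]
    for cid, ell in enumerate(cells, start=1):
        mask = _ellipse_mask((rows, cols), ell) & (gt.cell_id == 0)
        npx = int(mask.sum())
        if npx == 0:
            continue
        f_cell = float(np.clip(f_day + rng.normal(0.0, config.fraction_jitter_sd),
                               0.01, 0.99))
        params, lam = _scaled_params(truth, f_cell,
                                     config.photons_per_cell_pixel, config)
        counts[mask] = rng.poisson(np.broadcast_to(lam, (npx, nb)))
        gt.cell_id[mask] = cid
        gt.a0[mask] = params.a0
        gt.a1[mask] = params.a1
        gt.a2[mask] = params.a2
        gt.cell_a1_fractions[cid] = f_cell

    image = TCSPCImage(counts=counts, bin_width_ps=config.bin_width_ps,
                       channel=channel, day=day)
    return image, gt


@dataclass
class TimecourseDataset:
    """A multi-day, two-channel synthetic experiment with its ground truth."""

    config: SimulationConfig
    images: list[TCSPCImage]
    truths: list[GroundTruthMap]
    manifest: pd.DataFrame

    def truth_table(self) -> pd.DataFrame:
        """Per-image ground-truth foreground-mean fractions."""
        rows = []
        for i, gt in enumerate(self.truths):
            f1 = gt.mean_a1_fraction()
            rows.append({"image_index": i, "day": gt.day, "channel": gt.channel,
                         "true_a1_pct": 100.0 * f1, "true_a2_pct": 100.0 * (1 - f1)})
        return pd.DataFrame(rows)


def generate_timecourse(config: SimulationConfig, out_dir: str | Path | None = None
                        ) -> TimecourseDataset:
    """Images for every (day, channel, field-of-view) combination.

    Per-image random streams are spawned from ``config.seed`` via a
    SeedSequence, so the dataset is reproducible and individual images are
    statistically independent. With ``out_dir`` set, writes TIFF+JSON per
    image and a ``manifest.csv``.
    """
    ss = np.random.SeedSequence(config.seed)
    n_images = len(config.days) * len(config.channels) * config.n_fov
    children = ss.spawn(n_images)
    images: list[TCSPCImage] = []
    truths: list[GroundTruthMap] = []
    records = []
    idx = 0
    for day in config.days:
        for ch in config.channels:
            for fov in range(config.n_fov):
                rng = np.random.default_rng(children[idx])
                image, gt = generate_image(config, day, ch.name, rng=rng)
                image.fov = fov
                fname = f"day{day}_{ch.name}_fov{fov}.tif"
                records.append({"filename": fname, "day": day,
                                "channel": ch.name, "fov": fov,
                                "image_index": idx})
                images.append(image)
                truths.append(gt)
                idx += 1
    manifest = pd.DataFrame(records)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec, image in zip(records, images):
            write_image(image, out_dir / rec["filename"])
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return TimecourseDataset(config=config, images=images, truths=truths,
                             manifest=manifest)
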