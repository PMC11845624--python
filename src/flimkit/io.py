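"""TCSPC image containers and dataset I/O.

A TCSPC image is a (rows, cols, time-bins) photon-count stack plus metadata
(channel, day, treatment, field-of-view id, z-level). On disk it is a
multi-page 16-bit TIFF (one page per time bin) with a JSON sidecar holding
the bin width and metadata; a whole dataset can also round-trip through one
HDF5 file. Manifests (CSV, one row per image) link files to day/channel/FOV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

__all__ = ["TCSPCImage", "FormatError", "write_image", "read_image",
           "write_dataset_hdf5", "read_dataset_hdf5", "load_manifest"]

KNOWN_CHANNELS = ("NADH", "FAD")


class FormatError(ValueError):
    """Raised when an on-disk image or dataset is malformed."""


@dataclass
class TCSPCImage:
    """A photon-count stack (rows x cols x time bins) with acquisition metadata."""

    counts: np.ndarray
    bin_width_ps: float
    channel: str
    day: int | None = None
    treatment: str | None = None
    fov: int | None = None
    z_level: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 3:
            raise ValueError(f"counts must be rows x cols x bins, got shape {c.shape}")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        if self.bin_width_ps <= 0:
            raise ValueError("bin width must be positive")
        self.counts = c

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    def summed_intensity(self) -> np.ndarray:
        """Total photons per pixel (rows x cols)."""
        return self.counts.sum(axis=2)

    def metadata_dict(self) -> dict:
        return {
            "bin_width_ps": float(self.bin_width_ps),
            "channel": self.channel,
            "day": self.day,
            "treatment": self.treatment,
            "fov": self.fov,
            "z_level": self.z_level,
            **self.extra,
        }


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".json")


def write_image(image: TCSPCImage, path: str | Path) -> Path:
    """Write a stack as a multi-page uint16 TIFF (page = time bin) + JSON sidecar."""
    path = Path(path)
    if image.counts.max(initial=0) > np.iinfo(np.uint16).max:
        raise FormatError(f"counts exceed uint16 range in {path.name}")
    pages = np.ascontiguousarray(np.moveaxis(image.counts.astype(np.uint16), 2, 0))
    tifffile.imwrite(path, pages)
    meta = image.metadata_dict()
    meta["n_bins"] = image.n_bins
    meta["shape"] = list(image.counts.shape)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_image(path: str | Path) -> TCSPCImage:
    """Read a TIFF time stack written by :func:`write_image`."""
    path = Path(path)
    side = _sidecar_path(path)
    if not side.exists():
        raise FormatError(f"missing JSON sidecar for {path.name}")
    meta = json.loads(side.read_text())
    try:
        pages = tifffile.imread(path)
    except Exception as exc:  # corrupt/truncated file
        raise FormatError(f"cannot read TIFF stack {path.name}: {exc}") from exc
    if pages.ndim == 2:
        pages = pages[None]
    counts = np.moveaxis(pages, 0, 2).astype(np.int64)
    if list(counts.shape) != meta.get("shape", list(counts.shape)):
        raise FormatError(f"stack dimensions of {path.name} disagree with sidecar")
    extra = {k: v for k, v in meta.items()
             if k not in {"bin_width_ps", "channel", "day", "treatment", "fov",
                          "z_level", "n_bins", "shape"}}
    return TCSPCImage(
        counts=counts,
        bin_width_ps=meta["bin_width_ps"],
        channel=meta["channel"],
        day=meta.get("day"),
        treatment=meta.get("treatment"),
        fov=meta.get("fov"),
        z_level=meta.get("z_level"),
        extra=extra,
    )


def write_dataset_hdf5(images: list[TCSPCImage], path: str | Path) -> Path:
    """Store a list of stacks in one HDF5 file (group ``images/<i>``)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for i, im in enumerate(images):
            g = f.create_group(f"images/{i:04d}")
            g.create_dataset("counts", data=im.counts.astype(np.uint16),
                             compression="gzip", compression_opts=4)
            g.attrs["metadata"] = json.dumps(im.metadata_dict())
    return path


def read_dataset_hdf5(path: str | Path) -> list[TCSPCImage]:
    path = Path(path)
    out: list[TCSPCImage] = []
    with h5py.File(path, "r") as f:
        if "images" not in f:
            raise FormatError(f"{path.name} has no 'images' group")
        for key in sorted(f["images"]):
            g = f["images"][key]
            meta = json.loads(g.attrs["metadata"])
            extra = {k: v for k, v in meta.items()
                     if k not in {"bin_width_ps", "channel", "day", "treatment",
                                  "fov", "z_level"}}
            out.append(TCSPCImage(
                counts=g["counts"][()].astype(np.int64),
                bin_width_ps=meta["bin_width_ps"],
                channel=meta["channel"],
                day=meta.get("day"),
                treatment=meta.get("treatment"),
                fov=meta.get("fov"),
                z_level=meta.get("z_level"),
                extra=extra,
            ))
    return out


def load_manifest(directory: str | Path) -> tuple[pd.DataFrame, list[TCSPCImage]]:
    """Load every image listed in ``<directory>/manifest.csv``."""
    directory = Path(directory)
    manifest_path = directory / "manifest.csv"
    if not manifest_path.exists():
        raise FormatError(f"no manifest.csv in {directory}")
    manifest = pd.read_csv(manifest_path)
    images = [read_image(directory / fn) for fn in manifest["filename"]]
    return manifest, images
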