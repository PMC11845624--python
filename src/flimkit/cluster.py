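"""Discrimination of differentiation day from amplitude-fraction features.

Each imaged position contributes one point in the (a1% of the NADH channel,
a2% of the FAD channel) plane — the fractions of free NADH and free FAD,
both of which fall as cells shift from glycolysis toward oxidative
phosphorylation. Unsupervised k-means (k = 5, Euclidean distance) groups the
points; day labels enter only afterwards, when each cluster is summarized by
its modal day and the clustering is scored by how many points fall on their
cluster's modal day (purity) or within one day of it (adjacency).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler

__all__ = ["EmptyFeaturesError", "extract_features", "DayKMeans",
           "kmeans_fit", "assign_modes", "plot_clusters"]

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = ["a1_nadh_pct", "a2_fad_pct"]


class EmptyFeaturesError(ValueError):
    """No image had both channels fitted."""


def extract_features(experiment_table: pd.DataFrame,
                     use_pass: str = "fixed") -> pd.DataFrame:
    """Join per-image NADH a1% and FAD a2% into one feature row per position.

    ``experiment_table`` is the two-pass pipeline output (one row per image
    and channel). Positions are matched on (day, fov); an image with only
    one channel fitted is dropped with a log entry. ``use_pass`` selects the
    fixed-lifetime ("fixed", default — the comparable fractions) or free
    ("free") fractions.
    """
    prefix = {"fixed": "fixed_", "free": "free_"}[use_pass]
    col = f"{prefix}a1_pct"
    df = experiment_table
    rows = []
    keys = df[["day", "fov"]].drop_duplicates().itertuples(index=False)
    for day, fov in keys:
        sub = df[(df["day"] == day) & (df["fov"] == fov)]
        nadh = sub[sub["channel"] == "NADH"]
        fad = sub[sub["channel"] == "FAD"]
        if len(nadh) != 1 or len(fad) != 1:
            logger.info("position day=%s fov=%s dropped: needs exactly one "
                        "fit per channel (got %d NADH, %d FAD)",
                        day, fov, len(nadh), len(fad))
            continue
        rows.append({
            "image_id": f"day{day}_fov{fov}",
            "day": day,
            "a1_nadh_pct": float(nadh[col].iloc[0]),
            "a2_fad_pct": float(fad[f"{prefix}a2_pct"].iloc[0]),
        })
    if not rows:
        raise EmptyFeaturesError("no position has both channels fitted")
    return pd.DataFrame(rows)


class DayKMeans(BaseEstimator):
    """k-means over (a1%_NADH, a2%_FAD) with per-cluster day modes.

    Features are clustered on their raw percentage scales (both axes are
    percentages of comparable spread); set ``standardize=True`` to z-score
    them first. Lloyd's algorithm with k-means++ initialization and
    ``n_restarts`` independent starts, keeping the lowest inertia;
    deterministic under ``seed``.
    """

    def __init__(self, k: int = 5, n_restarts: int = 50, seed: int = 0,
                 standardize: bool = False):
        self.k = k
        self.n_restarts = n_restarts
        self.seed = seed
        self.standardize = standardize

    def _matrix(self, features: pd.DataFrame) -> np.ndarray:
        X = features[FEATURE_COLUMNS].to_numpy(dtype=float)
        if self.standardize:
            X = self.scaler_.transform(X)
        return X

    def fit(self, features: pd.DataFrame, y=None) -> "DayKMeans":
        if len(features) < self.k:
            raise ValueError(f"{len(features)} rows < k={self.k}")
        X = features[FEATURE_COLUMNS].to_numpy(dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("features contain non-finite values")
        if self.standardize:
            self.scaler_ = StandardScaler().fit(X)
            X = self.scaler_.transform(X)
        km = KMeans(n_clusters=self.k, init="k-means++",
                    n_init=self.n_restarts, algorithm="lloyd",
                    random_state=self.seed)
        self.labels_ = km.fit_predict(X)
        self.centers_ = km.cluster_centers_
        self.inertia_ = float(km.inertia_)
        self.kmeans_ = km
        return self

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return self.kmeans_.predict(self._matrix(features))

    def assign_modes(self, features: pd.DataFrame) -> dict:
        """Per-cluster modal day plus purity and mode±1 adjacency report.

        Ties on the mode go to the smallest day and are reported. Rows with
        missing day labels are excluded from the report but counted.
        """
        labels = self.labels_ if len(features) == len(self.labels_) \
            else self.predict(features)
        days = features["day"].to_numpy()
        labelled = pd.notna(days)
        n_unlabelled = int((~labelled).sum())
        modes: dict[int, int] = {}
        ties: list[int] = []
        on_mode = 0
        adjacent = 0
        n = 0
        for c in range(self.k):
            sel = (labels == c) & labelled
            if not sel.any():
                continue
            vals, counts = np.unique(days[sel].astype(int), return_counts=True)
            top = vals[counts == counts.max()]
            if top.size > 1:
                ties.append(c)
            modes[c] = int(top.min())
        for lab, day in zip(labels[labelled], days[labelled].astype(int)):
            if lab not in modes:
                continue
            n += 1
            if day == modes[lab]:
                on_mode += 1
            if abs(day - modes[lab]) <= 1:
                adjacent += 1
        self.cluster_modes_ = modes
        return {
            "cluster_modes": modes,
            "mode_purity": on_mode / n if n else float("nan"),
            "adjacency_fraction": adjacent / n if n else float("nan"),
            "n_points": n,
            "n_unlabelled": n_unlabelled,
            "tied_clusters": ties,
        }


def kmeans_fit(features: pd.DataFrame, k: int = 5, seed: int = 0,
               n_restarts: int = 50, standardize: bool = False) -> DayKMeans:
    """Fit the day clusterer; thin wrapper over :class:`DayKMeans`."""
    return DayKMeans(k=k, n_restarts=n_restarts, seed=seed,
                     standardize=standardize).fit(features)


def assign_modes(model: DayKMeans, features: pd.DataFrame) -> dict:
    return model.assign_modes(features)


def plot_clusters(model: DayKMeans, features: pd.DataFrame,
                  path: str | Path) -> Path:
    """Scatter of the feature plane colored by cluster, centers as crosses."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    X = features[FEATURE_COLUMNS].to_numpy(dtype=float)
    sc = ax.scatter(X[:, 0], X[:, 1], c=model.labels_, cmap="viridis", s=30)
    centers = model.centers_
    if model.standardize:
        centers = model.scaler_.inverse_transform(centers)
    ax.scatter(centers[:, 0], centers[:, 1], marker="x", c="k", s=80,
               linewidths=2, label="centers")
    ax.set_xlabel("a1 (NADH channel) [%]")
    ax.set_ylabel("a2 (FAD channel) [%]")
    ax.legend(loc="best")
    fig.colorbar(sc, ax=ax, label="cluster")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def save_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=1, default=str))
    return path
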