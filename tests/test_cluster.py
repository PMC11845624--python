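"""Tests for feature extraction and k-means day discrimination."""

import numpy as np
import pandas as pd
import pytest

from flimkit.cluster import (DayKMeans, EmptyFeaturesError, extract_features,
                             kmeans_fit)

from oracles import exhaustive_kmeans_inertia


def _table(rows):
    return pd.DataFrame(rows)


def _two_channel_table(n_positions=9, day=0):
    rows = []
    for fov in range(n_positions):
        for ch, a1 in (("NADH", 80.0 + fov), ("FAD", 30.0 + fov)):
            rows.append({"day": day, "fov": fov, "channel": ch,
                         "fixed_a1_pct": a1, "fixed_a2_pct": 100.0 - a1,
                         "free_a1_pct": a1 - 1, "free_a2_pct": 101.0 - a1})
    return _table(rows)


class TestExtractFeatures:
    def test_counts_one_row_per_complete_position(self):
        feats = extract_features(_two_channel_table(9))
        assert len(feats) == 9
        assert set(feats.columns) >= {"day", "a1_nadh_pct", "a2_fad_pct"}

    def test_single_channel_position_dropped(self):
        df = _two_channel_table(3)
        df = df[~((df["fov"] == 1) & (df["channel"] == "FAD"))]
        feats = extract_features(df)
        assert len(feats) == 2
        assert "day0_fov1" not in set(feats["image_id"])

    def test_values_join_bit_exactly(self):
        df = _two_channel_table(4)
        feats = extract_features(df)
        row = feats[feats["image_id"] == "day0_fov2"].iloc[0]
        nadh = df[(df["fov"] == 2) & (df["channel"] == "NADH")].iloc[0]
        fad = df[(df["fov"] == 2) & (df["channel"] == "FAD")].iloc[0]
        assert row["a1_nadh_pct"] == nadh["fixed_a1_pct"]
        assert row["a2_fad_pct"] == fad["fixed_a2_pct"]

    def test_free_pass_selection(self):
        feats = extract_features(_two_channel_table(3), use_pass="free")
        assert feats["a1_nadh_pct"].iloc[0] == 79.0

    def test_no_complete_rows_is_an_error(self):
        df = _two_channel_table(2)
        with pytest.raises(EmptyFeaturesError):
            extract_features(df[df["channel"] == "NADH"])


class TestKMeans:
    def test_k1_center_is_mean_and_inertia_total_ss(self, rng):
        X = rng.normal(size=(12, 2)) * 5 + 50
        feats = pd.DataFrame({"day": 0, "a1_nadh_pct": X[:, 0],
                              "a2_fad_pct": X[:, 1]})
        m = kmeans_fit(feats, k=1, seed=0, n_restarts=5)
        np.testing.assert_allclose(m.centers_[0], X.mean(axis=0), rtol=1e-9)
        assert m.inertia_ == pytest.approx(((X - X.mean(0)) ** 2).sum())

    def test_matches_exhaustive_assignment_oracle(self, rng):
        # tiny instance: 9 points, k = 3, every assignment enumerable
        centers = np.array([[70, 30], [80, 50], [60, 60]], dtype=float)
        X = np.vstack([c + rng.normal(scale=0.8, size=(3, 2)) for c in centers])
        feats = pd.DataFrame({"day": 0, "a1_nadh_pct": X[:, 0],
                              "a2_fad_pct": X[:, 1]})
        m = kmeans_fit(feats, k=3, seed=0, n_restarts=20)
        assert m.inertia_ == pytest.approx(exhaustive_kmeans_inertia(X, 3),
                                           rel=1e-9)

    def test_separated_blobs_recovered(self, rng):
        # 5 well-separated blobs of 3 points: partition equals blob labels
        centers = np.array([[85, 70], [80, 65], [76, 62], [73, 58], [69, 54]],
                           dtype=float)
        X = np.vstack([c + rng.normal(scale=0.15, size=(3, 2))
                       for c in centers])
        blob = np.repeat(np.arange(5), 3)
        feats = pd.DataFrame({"day": blob, "a1_nadh_pct": X[:, 0],
                              "a2_fad_pct": X[:, 1]})
        m = kmeans_fit(feats, k=5, seed=0, n_restarts=50)
        # same partition up to relabeling: each cluster is one blob
        for c in range(5):
            assert len(set(blob[m.labels_ == c])) == 1

    def test_identical_points_no_crash(self):
        feats = pd.DataFrame({"day": 0, "a1_nadh_pct": np.full(6, 77.0),
                              "a2_fad_pct": np.full(6, 33.0)})
        m = kmeans_fit(feats, k=2, seed=0, n_restarts=3)
        assert m.inertia_ == pytest.approx(0.0, abs=1e-12)

    def test_fewer_rows_than_k_rejected(self):
        feats = pd.DataFrame({"day": [0, 1], "a1_nadh_pct": [80.0, 70.0],
                              "a2_fad_pct": [60.0, 50.0]})
        with pytest.raises(ValueError):
            kmeans_fit(feats, k=5)

    def test_row_order_invariance_of_partition(self, rng):
        centers = np.array([[85, 70], [75, 60], [65, 50]], dtype=float)
        X = np.vstack([c + rng.normal(scale=0.5, size=(6, 2))
                       for c in centers])
        blob = np.repeat(np.arange(3), 6)
        feats = pd.DataFrame({"day": blob, "a1_nadh_pct": X[:, 0],
                              "a2_fad_pct": X[:, 1]})
        perm = rng.permutation(len(feats))
        m1 = kmeans_fit(feats, k=3, seed=0)
        m2 = kmeans_fit(feats.iloc[perm].reset_index(drop=True), k=3, seed=0)
        assert m1.inertia_ == pytest.approx(m2.inertia_, rel=1e-9)
        # permuted labels induce the same partition
        relabelled = np.empty_like(m2.labels_)
        relabelled[perm] = m2.labels_
        for c in set(relabelled):
            assert len({m1.labels_[i] for i in np.flatnonzero(relabelled == c)}) == 1

    def test_standardize_option_equals_raw_for_shared_rescale(self, rng):
        # scaling both features by one shared factor leaves the partition alone
        X = rng.normal(size=(20, 2)) * 4 + np.array([75, 60])
        feats = pd.DataFrame({"day": 0, "a1_nadh_pct": X[:, 0],
                              "a2_fad_pct": X[:, 1]})
        scaled = feats.copy()
        scaled[["a1_nadh_pct", "a2_fad_pct"]] *= 0.1
        m1 = kmeans_fit(feats, k=3, seed=0)
        m2 = kmeans_fit(scaled, k=3, seed=0)
        assert (m1.labels_ == m2.labels_).all()


class TestAssignModes:
    def _fit(self, pts, days, k):
        feats = pd.DataFrame({"day": days, "a1_nadh_pct": pts[:, 0],
                              "a2_fad_pct": pts[:, 1]})
        return kmeans_fit(feats, k=k, seed=0, n_restarts=10), feats

    def test_perfect_separation_purity_one(self, rng):
        centers = np.array([[90, 80], [70, 60], [50, 40]], dtype=float)
        pts = np.vstack([c + rng.normal(scale=0.3, size=(4, 2))
                         for c in centers])
        days = np.repeat([0, 1, 2], 4)
        model, feats = self._fit(pts, days, 3)
        report = model.assign_modes(feats)
        assert report["mode_purity"] == 1.0
        assert report["adjacency_fraction"] == 1.0
        assert sorted(report["cluster_modes"].values()) == [0, 1, 2]

    def test_mixed_cluster_counting(self):
        # one tight cluster holds days {2, 2, 3}; the other {0, 0, 0}
        pts = np.array([[80.0, 60.0], [80.1, 60.1], [79.9, 59.9],
                        [20.0, 10.0], [20.1, 10.1], [19.9, 9.9]])
        days = [2, 2, 3, 0, 0, 0]
        model, feats = self._fit(pts, days, 2)
        report = model.assign_modes(feats)
        mixed = model.labels_[0]
        assert report["cluster_modes"][int(mixed)] == 2
        assert report["mode_purity"] == pytest.approx(5 / 6)
        assert report["adjacency_fraction"] == 1.0

    def test_tie_goes_to_smallest_day_and_is_reported(self):
        pts = np.array([[80.0, 60.0], [80.1, 60.1], [20.0, 10.0], [20.1, 10.1]])
        days = [3, 1, 0, 0]
        model, feats = self._fit(pts, days, 2)
        report = model.assign_modes(feats)
        tied = model.labels_[0]
        assert report["cluster_modes"][int(tied)] == 1
        assert int(tied) in report["tied_clusters"]

    def test_unlabelled_rows_counted_not_scored(self):
        pts = np.array([[80.0, 60.0], [80.1, 60.1], [20.0, 10.0], [20.1, 10.1]])
        days = [1.0, 1.0, 0.0, np.nan]
        model, feats = self._fit(pts, days, 2)
        report = model.assign_modes(feats)
        assert report["n_unlabelled"] == 1
        assert report["n_points"] == 3
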