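"""tSNR, parcel time series, connectivity, and the group-level QC-FD
statistics (edge-wise correlations, tSNR-FD, DVARS-FD, group tests)."""

import numpy as np
import pandas as pd
import pytest

from scrubkit import qc
from scrubkit.core import Run
from scrubkit.qc import (binomial_null_band, compute_tsnr, connectivity_matrix,
                         dvars_fd_regression, group_fd_stats, parcel_timeseries,
                         qcfd_edges, tsnr_fd_correlation)


class TestTSNR:
    def test_exact_arithmetic(self):
        # alternating 98/102 -> mean 100, population sd 2 -> tSNR 50
        tc = np.tile([98.0, 102.0], 10)
        data = np.broadcast_to(tc, (5, 5, 4, 20)).copy()
        mask = np.ones((5, 5, 4), dtype=bool)
        tsnr, tmap = compute_tsnr(Run(data, tr=1.0), mask)
        assert tsnr == pytest.approx(50.0, abs=1e-9)
        assert tmap[mask].min() == pytest.approx(50.0, abs=1e-9)

    def test_scale_invariance(self, rng):
        data = rng.normal(200, 10, (6, 6, 4, 50))
        mask = np.ones((6, 6, 4), dtype=bool)
        a, _ = compute_tsnr(Run(data, tr=1.0), mask)
        b, _ = compute_tsnr(Run(2.0 * data, tr=1.0), mask)
        assert a == pytest.approx(b, rel=1e-12)

    def test_white_noise_sampling(self, rng):
        data = rng.normal(200, 10, (8, 8, 6, 500))
        mask = np.ones((8, 8, 6), dtype=bool)
        tsnr, _ = compute_tsnr(Run(data, tr=1.0), mask)
        assert 19.0 <= tsnr <= 21.0

    def test_global_mode(self, rng):
        data = rng.normal(200, 10, (6, 6, 4, 100))
        mask = np.ones((6, 6, 4), dtype=bool)
        g, _ = compute_tsnr(Run(data, tr=1.0), mask, mode="global")
        v, _ = compute_tsnr(Run(data, tr=1.0), mask, mode="voxelwise")
        assert g > v  # spatial averaging suppresses independent noise

    def test_constant_data_raises(self):
        data = np.full((4, 4, 4, 10), 7.0)
        with pytest.raises(ValueError):
            compute_tsnr(Run(data, tr=1.0), np.ones((4, 4, 4), dtype=bool))


class TestParcelTimeseries:
    def test_identical_voxels_give_that_timecourse(self, rng):
        labels = np.zeros((6, 6, 4), dtype=int)
        labels[0:2, 0:2, 0:2] = 1
        tc = rng.random(30)
        data = np.zeros((6, 6, 4, 30))
        data[labels == 1] = tc
        series, kept = parcel_timeseries(Run(data, tr=1.0), labels, min_voxels=5)
        np.testing.assert_allclose(series[0], tc, atol=1e-12)
        assert list(kept) == [1]

    def test_small_node_dropped(self, rng):
        labels = np.zeros((6, 6, 4), dtype=int)
        labels[0, 0, :4] = 1        # 4 voxels: below the 5-voxel rule
        labels[3:5, 3:5, 0:2] = 2   # 8 voxels
        data = rng.random((6, 6, 4, 10))
        series, kept = parcel_timeseries(Run(data, tr=1.0), labels, min_voxels=5)
        assert list(kept) == [2]

    def test_matches_bruteforce_average(self, rng):
        labels = rng.integers(0, 4, (8, 8, 6))
        data = rng.random((8, 8, 6, 12))
        series, kept = parcel_timeseries(Run(data, tr=1.0), labels, min_voxels=5)
        for row, lab in zip(series, kept):
            acc = np.zeros(12)
            n = 0
            for i in range(8):
                for j in range(8):
                    for k in range(6):
                        if labels[i, j, k] == lab:
                            acc += data[i, j, k]
                            n += 1
            np.testing.assert_allclose(row, acc / n, atol=1e-9)


class TestConnectivity:
    def test_perfect_and_anti_correlation(self, rng):
        a = rng.random(50)
        series = np.vstack([a, a, -a])
        cm = connectivity_matrix(series, np.zeros((3, 3)))
        assert cm.matrix[0, 1] == pytest.approx(1.0)
        assert cm.matrix[0, 2] == pytest.approx(-1.0)

    def test_edge_count_67_nodes(self, rng):
        series = rng.random((67, 40))
        cm = connectivity_matrix(series, rng.random((67, 3)) * 100)
        edges, dists = cm.edges()
        assert edges.size == 2211  # 67 * 66 / 2
        assert dists.size == 2211

    def test_symmetry_and_bruteforce_oracle(self, rng):
        series = rng.random((5, 30))
        cents = rng.random((5, 3)) * 50
        cm = connectivity_matrix(series, cents)
        np.testing.assert_array_equal(cm.matrix, cm.matrix.T)
        np.testing.assert_allclose(np.diag(cm.matrix), 1.0)
        for i in range(5):
            for j in range(i + 1, 5):
                x, y = series[i], series[j]
                r = (np.sum((x - x.mean()) * (y - y.mean()))
                     / np.sqrt(np.sum((x - x.mean()) ** 2)
                               * np.sum((y - y.mean()) ** 2)))
                assert cm.matrix[i, j] == pytest.approx(r, abs=1e-12)
                d = np.sqrt(np.sum((cents[i] - cents[j]) ** 2))
                assert cm.node_distances[i, j] == pytest.approx(d, abs=1e-12)


class TestQcFdEdges:
    def test_null_proportion_in_band(self):
        rng = np.random.default_rng(42)
        edges = rng.normal(size=(30, 200))
        fd = rng.uniform(0.1, 0.6, 30)
        res = qcfd_edges(edges, fd, rng.uniform(10, 100, 200))
        lo, hi = binomial_null_band(200)
        assert lo <= res.proportion_significant <= hi

    def test_perfectly_linear_edge(self, rng):
        fd = rng.uniform(0.1, 0.6, 20)
        edges = rng.normal(size=(20, 10))
        edges[:, 3] = 0.2 + 0.5 * fd
        res = qcfd_edges(edges, fd, rng.uniform(10, 100, 10))
        assert res.r[3] == pytest.approx(1.0, abs=1e-9)
        assert res.p[3] < 1e-12

    def test_zero_fd_variance_raises(self, rng):
        with pytest.raises(ValueError):
            qcfd_edges(rng.normal(size=(10, 5)), np.full(10, 0.3),
                       rng.random(5))

    def test_lowess_profile_flat_under_null(self, rng):
        edges = rng.normal(size=(40, 300))
        fd = rng.uniform(0.1, 0.6, 40)
        res = qcfd_edges(edges, fd, rng.uniform(10, 150, 300))
        assert res.profile_range < 0.25


class TestTsnrFd:
    def test_exact_negative_linear(self):
        fd = np.linspace(0.1, 0.6, 10)
        qc_table = pd.DataFrame(
            {"mean_fd": fd, "tsnr_pre": 100 - 50 * fd, "tsnr_post": 100 + fd})
        r, p = tsnr_fd_correlation(qc_table, "pre")
        assert r == pytest.approx(-1.0, abs=1e-9)

    def test_null_rarely_large(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            qc_table = pd.DataFrame({
                "mean_fd": rng.uniform(0.1, 0.6, 100),
                "tsnr_pre": rng.normal(60, 5, 100),
                "tsnr_post": rng.normal(90, 5, 100)})
            r, _ = tsnr_fd_correlation(qc_table, "pre")
            hits += abs(r) < 0.3
        assert hits >= 19  # >= 95 % of seeds at n = 100


class TestDvarsFd:
    def test_exact_linear(self):
        fd = np.concatenate([[0.0], np.linspace(0.1, 1.0, 40)])
        dv = np.concatenate([[0.0], 2.0 * fd[1:] + 1.0])
        res = dvars_fd_regression({"s1": (fd, dv)})
        row = res.per_subject.iloc[0]
        assert row.slope == pytest.approx(2.0, abs=1e-9)
        assert row.intercept == pytest.approx(1.0, abs=1e-9)
        assert row.r2 == pytest.approx(1.0, abs=1e-12)
        assert res.pooled_r2 == pytest.approx(1.0, abs=1e-12)

    def test_null_r2_small(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            fd = np.abs(rng.normal(0.3, 0.2, 500))
            dv = rng.normal(30, 3, 500)
            res = dvars_fd_regression({"s": (fd, dv)})
            hits += res.pooled_r2 < 0.02
        assert hits >= 19

    def test_constant_fd_subject_skipped(self, rng):
        good = (np.abs(rng.normal(0.3, 0.1, 50)), rng.normal(30, 3, 50))
        bad = (np.full(50, 0.2), rng.normal(30, 3, 50))
        with pytest.warns(UserWarning, match="constant FD"):
            res = dvars_fd_regression({"good": good, "bad": bad})
        assert list(res.per_subject.subject) == ["good"]


class TestGroupStats:
    def test_offset_recovery(self):
        # mean recovered offset over 10 replicate cohorts: se ~ 0.006
        offsets = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = rng.normal(0.40, 0.1, 50)
            b = rng.normal(0.48, 0.1, 50)
            qc_table = pd.DataFrame({
                "mean_fd": np.concatenate([a, b]),
                "group": ["F"] * 50 + ["M"] * 50,
                "age": rng.uniform(6, 8, 100)})
            out = group_fd_stats(qc_table)
            offsets.append(out["offset"])
        assert 0.05 <= np.mean(offsets) <= 0.11

    def test_null_covariate_correlation(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            qc_table = pd.DataFrame({
                "mean_fd": rng.uniform(0.2, 0.6, 100),
                "group": ["A", "B"] * 50,
                "age": rng.uniform(6, 8, 100)})
            out = group_fd_stats(qc_table)
            hits += abs(out["covariate_r"]) < 0.3
        assert hits >= 19

    def test_small_group_raises(self):
        qc_table = pd.DataFrame({"mean_fd": [0.1, 0.2, 0.3],
                                 "group": ["A", "A", "B"]})
        with pytest.raises(ValueError):
            group_fd_stats(qc_table, covariate_field=None)
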