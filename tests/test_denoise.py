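"""Intensity normalization, spatial ICA, component features, rule-based
classification and aggressive cleanup."""

import numpy as np
import pytest

from scrubkit import denoise
from scrubkit.core import Run
from scrubkit.denoise import (ClassifierThresholds, ComponentFeatures,
                              ComponentLabels, ComponentSet,
                              aggressive_cleanup, classify_components,
                              decompose_ica, extract_component_features,
                              normalize_intensity, read_fix_labels, rim_mask,
                              write_fix_labels)


@pytest.fixture()
def ball_mask():
    ii, jj, kk = np.meshgrid(*[np.arange(12)] * 3, indexing="ij")
    return (ii - 5.5) ** 2 + (jj - 5.5) ** 2 + (kk - 5.5) ** 2 <= 25


class TestNormalize:
    def test_scale_factor(self, ball_mask, rng):
        data = np.full(ball_mask.shape + (3,), 500.0)
        run = Run(data, tr=1.0)
        out = normalize_intensity(run, ball_mask, target=10_000.0)
        np.testing.assert_allclose(out.data, 10_000.0)

    def test_idempotent(self, ball_mask, rng):
        run = Run(rng.uniform(100, 200, ball_mask.shape + (4,)), tr=1.0)
        once = normalize_intensity(run, ball_mask)
        twice = normalize_intensity(once, ball_mask)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-9)

    def test_global_scale_invariance(self, ball_mask, rng):
        data = rng.uniform(100, 200, ball_mask.shape + (4,))
        a = normalize_intensity(Run(data, tr=1.0), ball_mask)
        b = normalize_intensity(Run(3.0 * data, tr=1.0), ball_mask)
        np.testing.assert_allclose(a.data, b.data, atol=1e-8)

    def test_nonpositive_mean_raises(self, ball_mask):
        data = np.zeros(ball_mask.shape + (2,))
        with pytest.raises(ValueError, match="non-positive"):
            normalize_intensity(Run(data, tr=1.0), ball_mask)


class TestICA:
    @staticmethod
    def planted_data(rng, n_frames=120, shape=(12, 12, 10)):
        """Two disjoint spatial blobs with independent super-Gaussian
        (Laplacian) time courses plus weak noise."""
        mask = np.ones(shape, dtype=bool)
        m1 = np.zeros(shape)
        m2 = np.zeros(shape)
        m1[2:6, 2:6, 2:6] = 1.0
        m2[7:11, 7:11, 4:8] = 1.0
        t1 = rng.laplace(size=n_frames)
        t2 = rng.laplace(size=n_frames)
        data = (100.0 + 5.0 * m1[..., None] * t1[None, None, None]
                + 5.0 * m2[..., None] * t2[None, None, None]
                + 0.3 * rng.normal(size=shape + (n_frames,)))
        return Run(data, tr=1.0), mask, (t1, t2)

    def test_planted_sources_recovered(self, rng):
        run, mask, (t1, t2) = self.planted_data(rng)
        comps = decompose_ica(run, mask, n_components=4, seed=0)
        for truth in (t1, t2):
            cors = [abs(np.corrcoef(truth, comps.timecourses[:, i])[0, 1])
                    for i in range(comps.n_components)]
            assert max(cors) >= 0.95

    def test_unit_variance_timecourses(self, rng):
        run, mask, _ = self.planted_data(rng)
        comps = decompose_ica(run, mask, 4, seed=0)
        np.testing.assert_allclose(comps.timecourses.std(axis=0), 1.0, atol=1e-8)

    def test_too_many_components_raises(self, rng):
        run, mask, _ = self.planted_data(rng, n_frames=20)
        with pytest.raises(ValueError):
            decompose_ica(run, mask, n_components=20, seed=0)

    def test_deterministic_for_fixed_seed(self, rng):
        run, mask, _ = self.planted_data(rng)
        a = decompose_ica(run, mask, 4, seed=11)
        b = decompose_ica(run, mask, 4, seed=11)
        np.testing.assert_array_equal(a.timecourses, b.timecourses)
        np.testing.assert_array_equal(a.spatial_maps, b.spatial_maps)

    def test_reconstruction_matches_input(self, rng):
        run, mask, _ = self.planted_data(rng, n_frames=60)
        comps = decompose_ica(run, mask, 30, seed=0)
        rec = denoise.reconstruct(comps)
        x = run.data[mask]
        # residual after 30 of 60 possible dimensions is small but nonzero;
        # adding it back reproduces the data exactly by construction
        resid = x - rec
        assert np.sqrt(np.mean(resid ** 2)) < np.sqrt(np.mean((x - x.mean()) ** 2))


def make_component_set(maps, tcs, mask):
    maps = np.asarray(maps, dtype=float)
    tcs = np.asarray(tcs, dtype=float)
    k = tcs.shape[1]
    return ComponentSet(
        spatial_maps=maps, timecourses=tcs, mask=mask,
        explained_variance=np.ones(k) / k,
        voxel_means=np.zeros(int(mask.sum())),
        frame_means=np.zeros(tcs.shape[0]))


class TestFeatures:
    def test_planted_rim_component(self, ball_mask):
        rim = rim_mask(ball_mask)
        gm = ball_mask & ~rim
        n_frames = 100
        maps = rim.astype(float)[..., None]
        tcs = np.sin(np.arange(n_frames))[:, None]
        tcs = (tcs - tcs.mean()) / tcs.std()
        comps = make_component_set(maps, tcs, ball_mask)
        f = extract_component_features(comps, ball_mask, gm, tr=0.78)
        assert f.edge_fraction[0] > 0.9
        assert f.gm_overlap[0] < 0.1

    def test_slice_periodic_component(self):
        shape = (16, 16, 16)
        brain = np.ones(shape, dtype=bool)
        gm = np.zeros(shape, dtype=bool)
        maps = np.zeros(shape)
        maps[:, :, ::4] = 1.0  # strongest every fourth slice
        rng = np.random.default_rng(0)
        tcs = rng.normal(size=(80, 1))
        comps = make_component_set(maps[..., None], tcs, brain)
        f = extract_component_features(comps, brain, gm, tr=0.78, slice_period=4)
        # the period-4 frequency is the dominant off-DC peak
        prof = np.array([np.abs(maps[:, :, z]).mean() for z in range(16)])
        spec = np.abs(np.fft.rfft(prof - prof.mean())) ** 2
        assert np.argmax(spec[1:]) + 1 == 4  # 16/4 cycles
        assert f.slice_periodicity[0] > 0.9

    def test_low_frequency_sinusoid_has_no_highfreq(self, ball_mask):
        t = np.arange(200) * 0.78
        tc = np.sin(2 * np.pi * 0.03 * t)
        tc = (tc - tc.mean()) / tc.std()
        comps = make_component_set(
            ball_mask.astype(float)[..., None], tc[:, None], ball_mask)
        f = extract_component_features(comps, ball_mask, ball_mask, tr=0.78,
                                       f_cut=0.1)
        assert f.highfreq_fraction[0] < 0.05

    def test_jump_score_flags_spikes(self, ball_mask):
        rng = np.random.default_rng(1)
        tc = 0.1 * rng.normal(size=150)
        tc[70] += 5.0  # one sudden jump
        tc = (tc - tc.mean()) / tc.std()
        comps = make_component_set(
            ball_mask.astype(float)[..., None], tc[:, None], ball_mask)
        f = extract_component_features(comps, ball_mask, ball_mask, tr=0.78)
        assert f.jump_score[0] > 6.0


class TestClassify:
    def test_all_zero_features_default_to_signal(self):
        z = np.zeros(3)
        labels = classify_components(ComponentFeatures(z, z, z, z, z))
        assert (labels.labels == "signal").all()

    def test_gm_override_protects(self):
        f = ComponentFeatures(
            edge_fraction=np.array([0.9]), gm_overlap=np.array([0.8]),
            highfreq_fraction=np.array([0.0]), slice_periodicity=np.array([0.0]),
            jump_score=np.array([0.0]))
        labels = classify_components(f)
        assert labels.labels[0] == "signal"
        assert labels.rule_trace[0] == ["gm_override"]

    def test_each_rule_fires(self):
        th = ClassifierThresholds()
        z = np.zeros(4)
        f = ComponentFeatures(
            edge_fraction=np.array([th.edge + 0.1, 0, 0, 0]),
            gm_overlap=np.zeros(4),
            highfreq_fraction=np.array([0, th.highfreq + 0.1, 0, 0]),
            slice_periodicity=np.array([0, 0, th.slice_periodicity + 0.1, 0]),
            jump_score=np.array([0, 0, 0, th.jump + 1]))
        labels = classify_components(f)
        assert (labels.labels == "noise").all()
        assert [t[0] for t in labels.rule_trace] == \
            ["edge", "highfreq", "slice", "jump"]


class TestCleanup:
    def test_pure_noise_voxel_flattened(self, ball_mask, rng):
        n = 80
        tc = rng.laplace(size=n)
        tc = (tc - tc.mean()) / tc.std()
        blob = np.zeros(ball_mask.shape)
        blob[4:8, 4:8, 4:8] = 1.0
        data = 100.0 + blob[..., None] * tc[None, None, None]
        run = Run(data, tr=1.0)
        comps = make_component_set(blob[..., None], tc[:, None], ball_mask)
        labels = ComponentLabels(np.array(["noise"], dtype=object))
        cleaned = aggressive_cleanup(run, comps, labels)
        assert cleaned.data.std(axis=-1).max() < 1e-8

    def test_no_noise_components_is_identity(self, ball_mask, rng):
        run = Run(rng.random(ball_mask.shape + (20,)), tr=1.0)
        comps = make_component_set(
            ball_mask.astype(float)[..., None],
            rng.normal(size=(20, 1)), ball_mask)
        labels = ComponentLabels(np.array(["signal"], dtype=object))
        cleaned = aggressive_cleanup(run, comps, labels)
        np.testing.assert_array_equal(cleaned.data, run.data)

    def test_residual_orthogonal_to_regressors(self, ball_mask, rng):
        n = 100
        tcs = rng.normal(size=(n, 3))
        tcs = (tcs - tcs.mean(0)) / tcs.std(0)
        run = Run(rng.normal(100, 5, ball_mask.shape + (n,)), tr=1.0)
        maps = rng.normal(size=ball_mask.shape + (3,))
        comps = make_component_set(maps, tcs, ball_mask)
        labels = ComponentLabels(np.array(["noise"] * 3, dtype=object))
        cleaned = aggressive_cleanup(run, comps, labels)
        sample = cleaned.data[ball_mask][::50]
        for k in range(3):
            cors = np.abs(np.corrcoef(
                np.vstack([sample, tcs[:, k]]))[-1, :-1])
            assert cors.max() <= 1e-8

    def test_never_increases_voxel_variance(self, ball_mask, rng):
        n = 60
        tcs = (lambda x: (x - x.mean(0)) / x.std(0))(rng.normal(size=(n, 2)))
        run = Run(rng.normal(0, 1, ball_mask.shape + (n,)), tr=1.0)
        comps = make_component_set(
            rng.normal(size=ball_mask.shape + (2,)), tcs, ball_mask)
        labels = ComponentLabels(np.array(["noise", "noise"], dtype=object))
        cleaned = aggressive_cleanup(run, comps, labels)
        assert np.all(cleaned.data.var(axis=-1) <= run.data.var(axis=-1) + 1e-12)

    def test_collinear_timecourses_warn_and_drop(self, ball_mask, rng):
        n = 50
        t1 = rng.normal(size=n)
        tcs = np.column_stack([t1, t1])  # duplicated regressor
        run = Run(rng.normal(size=ball_mask.shape + (n,)), tr=1.0)
        comps = make_component_set(
            rng.normal(size=ball_mask.shape + (2,)), tcs, ball_mask)
        labels = ComponentLabels(np.array(["noise", "noise"], dtype=object))
        with pytest.warns(UserWarning, match="collinear"):
            aggressive_cleanup(run, comps, labels)


def test_fix_label_file_roundtrip(tmp_path):
    labels = ComponentLabels(
        np.array(["signal", "noise", "signal", "noise"], dtype=object))
    path = tmp_path / "labels.txt"
    write_fix_labels(labels, path)
    last = path.read_text().strip().splitlines()[-1]
    assert last == "[2, 4]"  # 1-based bracketed list on the last line
    back = read_fix_labels(path, 4)
    np.testing.assert_array_equal(back.labels, labels.labels)
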