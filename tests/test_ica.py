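"""PCA reduction, FastICA unmixing, component metrics and ranking."""

import numpy as np
import pytest

from fpetbold.ica import (
    ICADecomposition,
    component_metrics,
    group_ica,
    metrics_table,
    rank_components,
    reduce_and_whiten,
    run_fastica,
)
from fpetbold.phantom import PhantomSpec, make_atlas, simulate_fpet
from fpetbold.preprocess import wholebrain_normalize
from fpetbold.protocol import FrameTiming
from fpetbold.series import FrameSeries


def _series(courses: np.ndarray) -> FrameSeries:
    """All-mask series: courses is (voxels, frames)."""
    n_vox, n_frames = courses.shape
    data = courses.reshape(n_vox, 1, 1, n_frames)
    return FrameSeries(data, FrameTiming.uniform(n_frames, 60.0),
                       (1.0, 1.0, 1.0), np.ones((n_vox, 1, 1), bool))


def _decomposition(maps, mixing, mask=None):
    mask = mask if mask is not None else np.ones((maps.shape[1], 1, 1), bool)
    return ICADecomposition(maps, mixing, maps.shape[0], 1.0, mask, 60.0)


class TestReduceAndWhiten:
    def test_low_rank_noiseless(self, rng):
        sources = rng.normal(size=(3, 500))
        mixing = rng.normal(size=(40, 3))
        y = mixing @ sources  # frames x voxels, rank 3
        reduced, retained = reduce_and_whiten([_series(y.T)])
        assert retained[0] >= 0.99
        assert reduced.shape[0] <= 3
        # reconstruction: reduced rows span the (centered) signal subspace
        yc = y - y.mean(axis=0, keepdims=True)
        yc = yc - yc.mean(axis=1, keepdims=True)
        proj = reduced.T @ np.linalg.pinv(reduced.T)
        err = np.linalg.norm(yc - yc @ proj) / np.linalg.norm(yc)
        assert err < 0.01

    def test_whitened_rows_uncorrelated(self, rng):
        y = rng.normal(size=(200, 60)) @ rng.normal(size=(60, 500))
        reduced, _ = reduce_and_whiten([_series(y.T)])
        cov = reduced @ reduced.T / reduced.shape[1]  # population covariance
        np.testing.assert_allclose(cov, np.eye(cov.shape[0]), atol=1e-6)

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            reduce_and_whiten([_series(np.ones((50, 20)))])


class TestFastICA:
    def _mixed_sparse_sources(self, rng, n_vox=2000):
        s1 = np.zeros(n_vox)
        s1[rng.choice(n_vox, 60, replace=False)] = rng.normal(5, 1, 60)
        s2 = np.zeros(n_vox)
        s2[rng.choice(n_vox, 60, replace=False)] = rng.normal(-4, 1, 60)
        sources = np.stack([s1, s2]) + 0.1 * rng.normal(size=(2, n_vox))
        mixing = np.array([[1.0, 0.4], [0.3, 1.0], [0.7, 0.7]])
        return sources, mixing @ sources

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_sparse_sources(self, seed):
        rng = np.random.default_rng(seed)
        sources, mixed = self._mixed_sparse_sources(rng)
        est, _, _ = run_fastica(mixed, n_components=2, seed=seed)
        corr = np.abs(np.corrcoef(np.vstack([sources, est]))[:2, 2:])
        # each true source matched by some estimate up to sign/permutation
        assert corr.max(axis=1).min() >= 0.95

    def test_deterministic_under_seed(self, rng):
        _, mixed = self._mixed_sparse_sources(rng)
        a, _, _ = run_fastica(mixed, n_components=2, seed=123)
        b, _, _ = run_fastica(mixed, n_components=2, seed=123)
        np.testing.assert_array_equal(a, b)

    def test_rank_guard(self, rng):
        _, mixed = self._mixed_sparse_sources(rng)
        with pytest.raises(ValueError, match="rank"):
            run_fastica(mixed, n_components=5, seed=0)


class TestComponentMetrics:
    def test_gaussian_map_near_zero_moments(self, rng):
        z = rng.normal(size=100_000)
        z = (z - z.mean()) / z.std()
        deco = _decomposition(z[None, :], np.ones((10, 1)))
        m = component_metrics(deco, 0)
        assert abs(m.kurtosis) < 0.1
        assert abs(m.skewness) < 0.1

    def test_sparse_map_high_kurtosis(self, rng):
        z = rng.normal(size=10_000)
        z[:100] = 10.0
        z = (z - z.mean()) / z.std()
        m = component_metrics(_decomposition(z[None, :], np.ones((10, 1))), 0)
        assert m.kurtosis > 5
        assert m.skewness > 0

    def test_sinusoid_frequency_centre(self):
        n = 256
        f0 = 0.125  # cycles per frame
        course = np.sin(2 * np.pi * f0 * np.arange(n))
        maps = np.random.default_rng(0).normal(size=(1, 500))
        m = component_metrics(_decomposition(maps, course[:, None]), 0)
        assert abs(m.frequency - f0) <= 1.0 / n  # within one spectral bin

    def test_variability_focal_vs_widespread(self, rng):
        mask = np.ones((20, 20, 10), bool)
        n_vox = mask.sum()
        focal = rng.normal(0, 0.1, n_vox)
        vol = np.zeros(mask.shape)
        vol[8:12, 8:12, 4:6] = 5.0
        focal = focal + vol[mask]
        focal = (focal - focal.mean()) / focal.std()
        m = component_metrics(
            _decomposition(focal[None, :], np.ones((10, 1)), mask), 0
        )
        assert m.variability_defined and m.variability < 0.5

    def test_no_suprathreshold_flagged(self):
        z = np.zeros(1000)
        z[:500] = 0.5
        z[500:] = -0.5
        m = component_metrics(_decomposition(z[None, :] / z.std(), np.ones((10, 1))), 0)
        assert not m.variability_defined
        assert np.isnan(m.variability)


class TestRanking:
    def _three_component_deco(self, rng):
        gauss1 = rng.normal(size=5000)
        gauss2 = rng.normal(size=5000)
        sparse = rng.normal(size=5000)
        sparse[:50] += 12.0
        maps = np.stack([gauss1, gauss2, sparse])
        maps = (maps - maps.mean(axis=1, keepdims=True)) / maps.std(axis=1, keepdims=True)
        return _decomposition(maps, rng.normal(size=(30, 3)))

    def test_sparse_component_ranks_first(self, rng):
        deco = self._three_component_deco(rng)
        assert rank_components(deco, by="kurtosis")[0] == 2

    def test_sign_flip_invariance(self, rng):
        deco = self._three_component_deco(rng)
        order = rank_components(deco)
        deco.spatial_maps = deco.spatial_maps * np.array([[-1], [1], [-1]])
        # kurtosis is an even moment: flipping signs cannot change the order
        np.testing.assert_array_equal(rank_components(deco), order)

    def test_tie_break_by_index(self):
        maps = np.tile(np.random.default_rng(0).normal(size=5000), (3, 1))
        maps = (maps - maps.mean(axis=1, keepdims=True)) / maps.std(axis=1, keepdims=True)
        deco = _decomposition(maps, np.ones((10, 3)))
        np.testing.assert_array_equal(rank_components(deco), [0, 1, 2])

    def test_unknown_key(self, rng):
        with pytest.raises(ValueError):
            rank_components(self._three_component_deco(rng), by="entropy")


class TestGroupICA:
    def test_phantom_task_component_identified(self):
        """Kurtosis rank 1 is the injected task component on the phantom."""
        spec = PhantomSpec(grid_shape=(16, 16, 8), n_chr2=4, n_gfp=1, seed=21)
        atlas = make_atlas(spec)
        from fpetbold.phantom import subject_seeds
        seeds = subject_seeds(spec)[: spec.n_chr2]
        rel = [wholebrain_normalize(simulate_fpet(spec, atlas, s)) for s in seeds]
        deco = group_ica(rel, n_components=12, seed=0)
        top = int(rank_components(deco)[0])
        task = np.zeros(atlas.label_volume.shape, bool)
        for name in spec.fdg_task_slope_increment:
            task |= atlas.mask(name)
        zvol = np.abs(deco.map_volume(top))
        in_brain = rel[0].brain_mask
        assert zvol[task].mean() > 3 * zvol[in_brain & ~task].mean()
        table = metrics_table(deco)
        assert table.loc[top, "kurtosis"] == table["kurtosis"].max()
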