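"""Voxelwise OLS, group t tests and permutation cluster inference."""

import numpy as np
import pytest
from scipy import ndimage, stats

from fpetbold.glm import (
    DesignMatrix,
    cluster_inference,
    fit_glm,
    fpet_baseline_regressor,
    fpet_design,
    group_ttest,
    region_summary,
)
from fpetbold.phantom import PhantomSpec, make_atlas, simulate_fpet
from fpetbold.protocol import ramp_regressor


class TestFitGlm:
    def test_exact_recovery_noiseless(self):
        rng = np.random.default_rng(0)
        n = 50
        ramp = np.cumsum(rng.integers(0, 2, n)).astype(float)
        baseline = np.arange(n, dtype=float)
        X = DesignMatrix(np.column_stack([ramp, baseline]), ("ramp", "baseline"))
        y = (2.0 * ramp + 5.0 * baseline)[None, :]
        res = fit_glm(y, X)
        np.testing.assert_allclose(res.betas[0], [2.0, 5.0], atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        """OLS betas equal the brute-force normal-equations solution."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            n, p = rng.integers(20, 60), rng.integers(2, 5)
            X = rng.normal(size=(n, p))
            y = rng.normal(size=(7, n))
            design = DesignMatrix(X, tuple(f"x{i}" for i in range(p)))
            res = fit_glm(y, design)
            oracle = np.linalg.solve(X.T @ X, X.T @ y.T).T
            np.testing.assert_allclose(res.betas, oracle, atol=1e-8)

    def test_t_statistic_null_calibration(self):
        """Pure-noise t for the task regressor follows t(dof)."""
        rng = np.random.default_rng(7)
        n = 40
        X = DesignMatrix(
            np.column_stack([rng.normal(size=n), np.ones(n)]), ("task", "const")
        )
        y = rng.normal(size=(4000, n))
        res = fit_glm(y, X)
        t = res.t_values("task")
        crit = stats.t.ppf(0.975, res.dof)
        rate = np.mean(np.abs(t) > crit)
        assert rate == pytest.approx(0.05, abs=0.012)  # ~3 MC sd

    def test_dof_and_rank_deficiency(self):
        with pytest.raises(ValueError, match="rank deficient"):
            DesignMatrix(np.ones((10, 2)), ("a", "a_copy"))
        X = DesignMatrix(np.column_stack([np.arange(10.0), np.ones(10)]), ("x", "c"))
        assert fit_glm(np.random.default_rng(0).normal(size=(3, 10)), X).dof == 8

    def test_summary_table(self):
        rng = np.random.default_rng(1)
        X = DesignMatrix(np.column_stack([np.arange(20.0), np.ones(20)]), ("x", "c"))
        res = fit_glm(rng.normal(size=(5, 20)), X)
        table = res.summary()
        assert list(table["regressor"]) == ["x", "c"]
        assert (table["dof"] == 18).all()


class TestBaselineRegressor:
    def test_exclusion_removes_task_contamination(self):
        spec = PhantomSpec(grid_shape=(16, 16, 8), noise_sd_pet=0.0,
                           n_chr2=1, n_gfp=1)
        atlas = make_atlas(spec)
        s = simulate_fpet(spec, atlas, 0)
        gm = atlas.gray_matter_mask()
        task = np.zeros(gm.shape, dtype=bool)
        for name in spec.fdg_task_slope_increment:
            task |= atlas.mask(name)
        contaminated = fpet_baseline_regressor(s, gm, None)
        clean = fpet_baseline_regressor(s, gm, task)
        # noiseless: excluding activated voxels leaves the pure linear uptake
        slopes = np.diff(clean)
        np.testing.assert_allclose(slopes, spec.fdg_baseline_slope, atol=1e-9)
        assert np.diff(contaminated).max() > spec.fdg_baseline_slope

    def test_empty_remaining_mask(self, small_cohort):
        s = small_cohort.subjects[0].fpet
        gm = small_cohort.atlas.gray_matter_mask()
        with pytest.raises(ValueError):
            fpet_baseline_regressor(s, gm, np.ones_like(gm))


class TestGroupTTest:
    def test_one_sample_hand_example(self):
        maps = np.array([[1.0], [2.0], [3.0]])
        t = group_ttest(maps, "one_sample")
        assert t[0] == pytest.approx(2 * np.sqrt(3))

    def test_identical_groups_zero(self):
        maps = np.tile(np.arange(5.0), (6, 1))
        groups = np.array(["a"] * 3 + ["b"] * 3)
        t = group_ttest(maps, "two_sample", groups)
        np.testing.assert_array_equal(t, 0.0)

    def test_label_swap_flips_sign(self):
        rng = np.random.default_rng(3)
        maps = rng.normal(size=(8, 20))
        groups = np.array(["a"] * 4 + ["b"] * 4)
        t1 = group_ttest(maps, "two_sample", groups)
        swapped = np.where(groups == "a", "b", "a")
        # labels sort identically, so swapping membership flips the sign
        t2 = group_ttest(maps, "two_sample", swapped)
        np.testing.assert_allclose(t1, -t2, atol=1e-12)

    def test_insufficient_subjects(self):
        with pytest.raises(ValueError):
            group_ttest(np.ones((1, 4)), "one_sample")


class TestClusterInference:
    def test_all_zero_maps_empty_table(self):
        maps = np.zeros((6, 8, 8, 4))
        table = cluster_inference(maps, np.ones((8, 8, 4), bool), n_perm=100)
        assert len(table.clusters) == 0
        assert table.n_significant == 0

    def test_rejects_tiny_n_perm(self):
        with pytest.raises(ValueError):
            cluster_inference(np.zeros((6, 4, 4, 4)), np.ones((4, 4, 4), bool),
                              n_perm=50)

    def test_injected_blob_detected(self, rng):
        """A strong blob yields exactly one significant cluster covering it."""
        shape = (12, 12, 8)
        maps = rng.normal(size=(8,) + shape)
        blob = np.zeros(shape, dtype=bool)
        blob[4:8, 4:8, 2:6] = True
        maps[:, blob] += 5.0
        table = cluster_inference(maps, np.ones(shape, bool), n_perm=200, seed=0)
        assert table.n_significant == 1
        sig = table.significant_mask()
        centroid = tuple(int(round(c)) for c in ndimage.center_of_mass(blob))
        assert sig[centroid]

    def test_corrected_p_invariant_to_rescaling(self, rng):
        maps = rng.normal(size=(8, 10, 10, 6))
        maps[:, 3:7, 3:7, 2:5] += 2.0
        mask = np.ones((10, 10, 6), bool)
        t1 = cluster_inference(maps, mask, n_perm=150, seed=4, voxel_p=0.01)
        t2 = cluster_inference(maps * 37.5, mask, n_perm=150, seed=4, voxel_p=0.01)
        np.testing.assert_array_equal(
            t1.clusters["p_corrected"], t2.clusters["p_corrected"]
        )
        np.testing.assert_array_equal(
            t1.clusters["size_voxels"], t2.clusters["size_voxels"]
        )

    def test_two_sample_blob(self, rng):
        shape = (10, 10, 6)
        maps = rng.normal(size=(12,) + shape)
        groups = np.array(["chr2"] * 6 + ["gfp"] * 6)
        maps[:6, 3:7, 3:7, 2:5] += 4.0
        table = cluster_inference(maps, np.ones(shape, bool), kind="two_sample",
                                  groups=groups, n_perm=200, seed=0)
        assert table.n_significant == 1


class TestRegionSummary:
    def test_empty_map(self, small_atlas):
        shape = small_atlas.label_volume.shape
        table = region_summary(np.zeros(shape), np.zeros(shape, bool), small_atlas)
        assert (table["pct_significant"] == 0).all()
        assert (table["mean_t"] == 0).all()

    def test_full_region_constant_t(self, small_atlas):
        shape = small_atlas.label_volume.shape
        t_map = np.full(shape, 4.0)
        sig = small_atlas.mask("right_striatum")
        table = region_summary(t_map, sig, small_atlas).set_index("region")
        assert table.loc["right_striatum", "pct_significant"] == 100.0
        assert table.loc["right_striatum", "mean_t"] == 4.0
        assert table.loc["left_striatum", "pct_significant"] == 0.0

    def test_partial_region_hand_mean(self, small_atlas):
        """Half of a region significant with known t values."""
        shape = small_atlas.label_volume.shape
        region = small_atlas.mask("right_sn")
        idx = np.argwhere(region)
        half = idx[: len(idx) // 2]
        sig = np.zeros(shape, bool)
        sig[tuple(half.T)] = True
        t_map = np.zeros(shape)
        vals = np.resize([3.0, 3.0, 4.0, 4.0, 6.0], len(half))
        t_map[tuple(half.T)] = vals
        table = region_summary(t_map, sig, small_atlas).set_index("region")
        assert table.loc["right_sn", "pct_significant"] == pytest.approx(
            100.0 * len(half) / len(idx)
        )
        assert table.loc["right_sn", "mean_t"] == pytest.approx(vals.mean())


def test_fpet_design_contrast(protocol, pet_timing):
    baseline = np.arange(1, 96, dtype=float)
    design = fpet_design(protocol, pet_timing, baseline)
    np.testing.assert_array_equal(design.contrast("ramp"), [1, 0, 0])
    np.testing.assert_array_equal(design.matrix[:, 0],
                                  ramp_regressor(protocol, pet_timing))
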