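"""Atlas construction and the synthetic fPET/BOLD generators."""

import numpy as np
import pytest
from scipy import stats

from fpetbold.glm import DesignMatrix, fit_glm
from fpetbold.phantom import (
    PhantomSpec,
    make_atlas,
    simulate_bold,
    simulate_cohort,
    simulate_fpet,
    subject_seeds,
)
from fpetbold.protocol import ramp_regressor

REQUIRED_REGIONS = [
    "right_striatum", "left_striatum", "right_sn", "right_thalamus",
    "left_thalamus", "right_cortex", "left_cortex", "cerebellum",
]


class TestAtlas:
    def test_required_regions_present_and_sized(self):
        atlas = make_atlas(PhantomSpec())
        for name in REQUIRED_REGIONS:
            assert atlas.mask(name).sum() >= 27
        assert atlas.gray_matter_mask().sum() > 0

    def test_deterministic(self):
        a = make_atlas(PhantomSpec(seed=1))
        b = make_atlas(PhantomSpec(seed=99))  # seed does not affect layout
        np.testing.assert_array_equal(a.label_volume, b.label_volume)

    def test_regions_within_brain_mask(self):
        atlas = make_atlas(PhantomSpec())
        assert ((atlas.label_volume > 0) & ~atlas.brain_mask()).sum() == 0

    def test_grid_too_small(self):
        with pytest.raises(ValueError, match="too small"):
            make_atlas(PhantomSpec(grid_shape=(6, 6, 4)))


class TestFpet:
    def test_noiseless_control_is_linear(self, noiseless_spec):
        atlas = make_atlas(noiseless_spec)
        s = simulate_fpet(noiseless_spec, atlas, 0, responsive=False)
        tac = s.data[atlas.mask("right_striatum")][0]
        slopes = np.diff(tac)
        np.testing.assert_allclose(slopes, noiseless_spec.fdg_baseline_slope)

    def test_noiseless_identifiability(self, noiseless_spec):
        """OLS on [ramp, baseline, 1] returns the injected slope exactly."""
        atlas = make_atlas(noiseless_spec)
        s = simulate_fpet(noiseless_spec, atlas, 0, responsive=True)
        timing = s.timing
        ramp = ramp_regressor(noiseless_spec.protocol, timing)
        frames = np.arange(1, timing.n_frames + 1, dtype=float)
        design = DesignMatrix(
            np.column_stack([ramp, frames, np.ones_like(frames)]),
            ("ramp", "baseline", "intercept"),
        )
        res = fit_glm(s.data[atlas.mask("right_striatum")], design)
        truth = noiseless_spec.fdg_task_slope_increment["right_striatum"]
        np.testing.assert_allclose(res.betas[:, 0], truth, atol=1e-9)
        # cerebellum carries no task effect
        res_cb = fit_glm(s.data[atlas.mask("cerebellum")], design)
        np.testing.assert_allclose(res_cb.betas[:, 0], 0.0, atol=1e-9)

    def test_recovery_unbiased_over_seeds(self):
        """Monte-Carlo mean of the ramp beta matches truth at default noise."""
        spec = PhantomSpec(grid_shape=(16, 16, 8), n_chr2=1, n_gfp=1)
        atlas = make_atlas(spec)
        timing = spec.pet_timing()
        ramp = ramp_regressor(spec.protocol, timing)
        frames = np.arange(1, timing.n_frames + 1, dtype=float)
        design = DesignMatrix(
            np.column_stack([ramp, frames, np.ones_like(frames)]),
            ("ramp", "baseline", "intercept"),
        )
        roi = atlas.mask("right_striatum")
        truth = spec.fdg_task_slope_increment["right_striatum"]
        means = []
        for seed in range(40):
            s = simulate_fpet(spec, atlas, seed)
            means.append(fit_glm(s.data[roi], design).betas[:, 0].mean())
        bias = np.mean(means) - truth
        assert abs(bias) < 0.05 * truth

    def test_effect_free_voxels_stationary_after_detrend(self, small_cohort):
        """Control voxel courses have no residual slope after linear detrend."""
        s = small_cohort.group("gfp")[0].fpet
        y = s.in_mask()
        n = y.shape[1]
        x = np.arange(n, dtype=float)
        X = np.column_stack([x, np.ones(n)])
        beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)
        resid = y - (X @ beta).T
        # slope t test on residuals: should be ~0 everywhere
        slope = resid @ (x - x.mean()) / np.sum((x - x.mean()) ** 2)
        se = resid.std(axis=1, ddof=2) / np.sqrt(np.sum((x - x.mean()) ** 2))
        tvals = slope / se
        frac_sig = np.mean(np.abs(tvals) > stats.t.ppf(0.995, n - 2))
        assert frac_sig < 0.05


class TestBold:
    def test_zero_amplitude_is_drift_only(self, small_atlas):
        spec = PhantomSpec(grid_shape=(16, 16, 8), noise_sd_bold=0.0,
                           bold_on_amplitude={}, bold_overshoot_amplitude={},
                           bold_frame_duration=15.0)
        s = simulate_bold(spec, small_atlas, 0)
        course = s.data[small_atlas.mask("right_striatum")][0]
        t = s.timing.frame_centers
        drift = spec.drift_amplitude * spec.bold_baseline * np.cos(
            np.pi * t / spec.protocol.acquisition_duration
        )
        np.testing.assert_allclose(course, spec.bold_baseline + drift, atol=1e-9)

    def test_positive_region_on_exceeds_rest(self, noiseless_spec, small_atlas):
        s = simulate_bold(noiseless_spec, small_atlas, 0)
        t = s.timing.frame_centers
        p = noiseless_spec.protocol
        course = s.data[small_atlas.mask("right_striatum")].mean(axis=0)
        on = np.zeros(t.size, dtype=bool)
        for b in range(1, p.n_blocks + 1):
            b0 = p.block_start(b)
            on |= (t >= b0) & (t < b0 + p.block_duration)
        rest = ~on & (t > p.stim_onset)
        assert course[on].mean() > course[rest].mean()

    def test_negative_region_suppressed(self, noiseless_spec, small_atlas):
        s = simulate_bold(noiseless_spec, small_atlas, 0)
        t = s.timing.frame_centers
        p = noiseless_spec.protocol
        course = s.data[small_atlas.mask("left_striatum")].mean(axis=0)
        b0 = p.block_start(2)
        in_block = (t >= b0 + 30) & (t < b0 + p.block_duration)
        assert course[in_block].mean() < noiseless_spec.bold_baseline

    def test_post_block_overshoot_exceeds_plateau(self, small_atlas):
        spec = PhantomSpec(grid_shape=(16, 16, 8), noise_sd_bold=0.0,
                           drift_amplitude=0.0, bold_frame_duration=2.0)
        s = simulate_bold(spec, small_atlas, 0)
        t = s.timing.frame_centers
        p = spec.protocol
        course = s.data[small_atlas.mask("right_striatum")].mean(axis=0)
        b_end = p.block_start(1) + p.block_duration
        plateau = course[(t > p.block_start(1) + 60) & (t < b_end - 15)].mean()
        post_peak = course[(t >= b_end) & (t < b_end + 15)].max()
        assert post_peak > plateau


class TestCohort:
    def test_deterministic_rerun(self, small_spec):
        a = simulate_cohort(small_spec, include_bold=False)
        b = simulate_cohort(small_spec, include_bold=False)
        for sa, sb in zip(a.subjects, b.subjects):
            np.testing.assert_array_equal(sa.fpet.data, sb.fpet.data)

    def test_subject_counts_and_truth(self, small_cohort, small_spec):
        assert len(small_cohort.subjects) == small_spec.n_chr2 + small_spec.n_gfp
        gfp_rows = small_cohort.truth[small_cohort.truth.group == "gfp"]
        effect_cols = ["fdg_slope_increment", "bold_on_amplitude",
                       "bold_overshoot_amplitude", "pet_coupling"]
        assert (gfp_rows[effect_cols] == 0).all().all()

    def test_subject_seeds_distinct_and_bounded(self, small_spec):
        seeds = subject_seeds(small_spec)
        assert len(set(seeds)) == len(seeds)
        assert all(0 <= s < 2**31 for s in seeds)

    def test_save_roundtrip(self, tmp_path, noiseless_spec):
        cohort = simulate_cohort(noiseless_spec, include_bold=False)
        cohort.save(tmp_path / "cohort")
        assert (tmp_path / "cohort" / "atlas.nii.gz").exists()
        assert (tmp_path / "cohort" / "truth.csv").exists()
        from fpetbold.series import FrameSeries
        sub = cohort.subjects[0]
        loaded = FrameSeries.from_nifti(
            tmp_path / "cohort" / sub.subject_id / "fpet.nii.gz",
            tmp_path / "cohort" / sub.subject_id / "brain_mask.nii.gz",
            frame_duration=60.0,
        )
        np.testing.assert_allclose(loaded.data, sub.fpet.data, rtol=1e-5)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            PhantomSpec(n_chr2=0)
        with pytest.raises(ValueError):
            PhantomSpec(noise_sd_pet=np.nan)
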