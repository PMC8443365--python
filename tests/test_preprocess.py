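"""Unit tests for the preprocessing chain: volume dropping, smoothing,
detrend/band-pass, motion expansion, nuisance regression, FD and scrubbing."""

import numpy as np
import pytest

from fcdegree.errors import ConfigurationError, DataError
from fcdegree.imaging_io import BoldRun
from fcdegree.preprocess import (
    PreprocessConfig,
    build_nuisance_design,
    compute_fd,
    detrend_and_bandpass,
    drop_initial,
    friston24,
    motion_exclusion_check,
    preprocess_run,
    regress_nuisance,
    scrub,
    scrub_indices,
    smooth_gaussian,
)

from conftest import make_run


class TestDropInitial:
    def test_240_to_230(self, rng):
        run = make_run(rng.standard_normal((3, 3, 3, 240)))
        assert drop_initial(run, 10).n_volumes == 230

    def test_zero_is_identity_and_order_preserved(self, rng):
        run = make_run(rng.standard_normal((2, 2, 2, 12)))
        out = drop_initial(run, 3)
        np.testing.assert_array_equal(out.data, run.data[..., 3:])
        assert drop_initial(run, 0) is run

    def test_dropping_everything_rejected(self, rng):
        run = make_run(rng.standard_normal((2, 2, 2, 5)))
        with pytest.raises(DataError):
            drop_initial(run, 5)


class TestSmoothing:
    def test_fwhm_zero_identity(self, random_run):
        assert smooth_gaussian(random_run, 0.0) is random_run

    def test_constant_image_unchanged(self):
        run = make_run(np.full((7, 7, 7, 3), 5.0), affine=np.eye(4) * 3)
        out = smooth_gaussian(run, 4.0)
        np.testing.assert_allclose(out.data, run.data, atol=1e-10)

    def test_delta_matches_closed_form_gaussian(self):
        """A unit impulse smoothed with a 4 mm kernel on 3 mm voxels equals the
        (discretely normalized) separable Gaussian evaluated at each offset."""
        shape = (9, 9, 9)
        data = np.zeros((*shape, 2))
        data[4, 4, 4, 0] = 1.0
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        out = smooth_gaussian(make_run(data, affine=affine), 4.0).data[..., 0]

        sigma = 4.0 / (2.0 * np.sqrt(2.0 * np.log(2.0))) / 3.0  # voxels
        radius = int(6.0 * sigma + 0.5)
        offsets = np.arange(-radius, radius + 1)
        w = np.exp(-(offsets**2) / (2 * sigma**2))
        w /= w.sum()
        kernel3 = w[:, None, None] * w[None, :, None] * w[None, None, :]
        expected = np.zeros(shape)
        sl = slice(4 - radius, 4 + radius + 1)
        expected[sl, sl, sl] = kernel3
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_sum_conserved(self, random_run):
        out = smooth_gaussian(random_run, 5.0)
        np.testing.assert_allclose(
            out.data.sum(axis=(0, 1, 2)), random_run.data.sum(axis=(0, 1, 2)),
            rtol=1e-10,
        )


class TestDetrendBandpass:
    TR = 2.0

    def test_linear_ramp_removed(self):
        t = np.arange(230)
        series = 3.0 + 0.5 * t
        out = detrend_and_bandpass(series, self.TR)
        assert np.abs(out).max() < 1e-8

    @pytest.mark.parametrize(
        "freq,expectation",
        [(0.04, "preserved"), (0.2, "suppressed"), (0.005, "suppressed")],
    )
    def test_sinusoid_response(self, freq, expectation):
        """FFT oracle: in-band sinusoids keep >=95% amplitude, out-of-band
        sinusoids lose >=95%."""
        n_t = 230
        t = np.arange(n_t) * self.TR
        series = np.sin(2 * np.pi * freq * t)
        out = detrend_and_bandpass(series, self.TR)
        spec_in = np.abs(np.fft.rfft(series))
        spec_out = np.abs(np.fft.rfft(out))
        k = np.argmax(spec_in)
        ratio = spec_out[k] / spec_in[k]
        if expectation == "preserved":
            assert ratio > 0.95
        else:
            assert ratio < 0.05

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            detrend_and_bandpass(np.zeros(64), self.TR, band=(0.01, 0.3))

    def test_too_short_rejected(self):
        with pytest.raises(DataError):
            detrend_and_bandpass(np.zeros(5), self.TR)


class TestFriston24:
    def test_six_in_24_out(self, rng):
        out = friston24(rng.standard_normal((20, 6)))
        assert out.shape == (20, 24)

    def test_all_zero_motion(self):
        assert not friston24(np.zeros((10, 6))).any()

    def test_hand_expansion_of_single_parameter(self):
        """p = [0, 1, 2] expands to square [0, 1, 4], lag [0, 0, 1], lag
        square [0, 0, 1]."""
        motion = np.zeros((3, 6))
        motion[:, 0] = [0.0, 1.0, 2.0]
        out = friston24(motion)
        np.testing.assert_array_equal(out[:, 0], [0, 1, 2])
        np.testing.assert_array_equal(out[:, 6], [0, 1, 4])  # squares block
        np.testing.assert_array_equal(out[:, 12], [0, 0, 1])  # lag block
        np.testing.assert_array_equal(out[:, 18], [0, 0, 1])  # lag^2 block

    def test_wrong_column_count(self, rng):
        with pytest.raises(DataError):
            friston24(rng.standard_normal((10, 5)))


class TestNuisanceRegression:
    def _design(self, rng, n_t, gsr=False):
        motion = np.cumsum(rng.normal(0, 0.01, (n_t, 6)), axis=0)
        wm = rng.standard_normal(n_t)
        csf = rng.standard_normal(n_t)
        gs = rng.standard_normal(n_t) if gsr else None
        return build_nuisance_design(motion, wm, csf, gs)

    def test_column_count(self, rng):
        assert self._design(rng, 30).columns.shape[1] == 26
        assert self._design(rng, 30, gsr=True).columns.shape[1] == 27

    def test_residuals_orthogonal_to_design(self, rng):
        design = self._design(rng, 40)
        run = make_run(rng.standard_normal((4, 4, 4, 40)))
        out = regress_nuisance(run, design)
        y = out.data.reshape(-1, 40)
        dots = y @ design.columns
        norm = np.linalg.norm(design.columns, axis=0) * np.abs(y).max()
        assert np.abs(dots / norm).max() < 1e-8
        # intercept always included -> residual means vanish
        np.testing.assert_allclose(y.mean(axis=1), 0.0, atol=1e-10)

    def test_voxel_equal_to_regressor_goes_to_zero(self, rng):
        design = self._design(rng, 30)
        data = np.tile(design.columns[:, 24], (2, 2, 2, 1))
        out = regress_nuisance(make_run(data), design)
        assert np.abs(out.data).max() < 1e-8

    def test_collinear_design_named(self, rng):
        motion = np.cumsum(rng.normal(0, 0.01, (30, 6)), axis=0)
        wm = rng.standard_normal(30)
        design = build_nuisance_design(motion, wm, wm)  # csf duplicates wm
        run = make_run(rng.standard_normal((2, 2, 2, 30)))
        with pytest.raises(DataError, match="csf"):
            regress_nuisance(run, design)


class TestFramewiseDisplacement:
    def test_zero_motion(self):
        np.testing.assert_array_equal(compute_fd(np.zeros((10, 6))), np.zeros(10))

    def test_translation_arithmetic(self):
        """0.1 mm change on each translation axis -> FD = 0.3."""
        motion = np.zeros((2, 6))
        motion[1, :3] = 0.1
        np.testing.assert_allclose(compute_fd(motion), [0.0, 0.3])

    def test_rotation_scaled_by_sphere_radius(self):
        """One rotation changing by 0.004 rad -> FD = 50 * 0.004 = 0.2."""
        motion = np.zeros((2, 6))
        motion[1, 3] = 0.004
        np.testing.assert_allclose(compute_fd(motion), [0.0, 0.2])

    def test_first_volume_is_zero(self, rng):
        fd = compute_fd(rng.standard_normal((20, 6)))
        assert fd[0] == 0.0 and fd.shape == (20,)


class TestScrubbing:
    def test_worked_example(self, rng):
        """FD = [0, .1, .3, .1, .1, .1, .1] at threshold .2 with window (1, 2)
        removes volumes {1, 2, 3, 4} and keeps {0, 5, 6}."""
        fd = np.array([0, 0.1, 0.3, 0.1, 0.1, 0.1, 0.1])
        removed, retained = scrub_indices(fd, 0.2, before=1, after=2)
        np.testing.assert_array_equal(removed, [1, 2, 3, 4])
        np.testing.assert_array_equal(retained, [0, 5, 6])
        run = make_run(rng.standard_normal((2, 2, 2, 7)))
        out, kept, n_scrubbed = scrub(run, fd, 0.2, 1, 2)
        assert n_scrubbed == 4
        np.testing.assert_array_equal(out.data, run.data[..., [0, 5, 6]])

    def test_nothing_flagged_is_identity(self, rng):
        run = make_run(rng.standard_normal((2, 2, 2, 7)))
        out, kept, n_scrubbed = scrub(run, np.full(7, 0.05), 0.2)
        assert n_scrubbed == 0 and out is run

    def test_adjacent_spikes_remove_each_volume_once(self, rng):
        """Overlapping windows behave as a set union (oracle below)."""
        fd = rng.random(40) * 0.4
        removed, retained = scrub_indices(fd, 0.2, before=1, after=2)
        oracle = set()
        for t in np.flatnonzero(fd > 0.2):
            oracle |= set(range(max(0, t - 1), min(40, t + 3)))
        assert set(removed.tolist()) == oracle
        assert len(removed) == len(set(removed.tolist()))
        assert sorted(set(range(40)) - oracle) == retained.tolist()

    def test_fully_flagged_subject_unusable(self, rng):
        run = make_run(rng.standard_normal((2, 2, 2, 5)))
        with pytest.raises(DataError):
            scrub(run, np.full(5, 1.0), 0.2)


class TestMotionExclusion:
    def test_translation_over_limit_fails(self):
        motion = np.zeros((5, 6))
        motion[3, 1] = 2.1
        passed, offending = motion_exclusion_check(motion)
        assert not passed and offending.tolist() == [3]

    def test_all_zero_passes(self):
        passed, offending = motion_exclusion_check(np.zeros((5, 6)))
        assert passed and offending.size == 0

    def test_rotation_unit_conversion(self):
        """0.04 rad is about 2.29 degrees and must fail the 2-degree limit."""
        motion = np.zeros((4, 6))
        motion[2, 4] = 0.04
        passed, offending = motion_exclusion_check(motion)
        assert not passed and offending.tolist() == [2]

    def test_and_rule_requires_both(self):
        motion = np.zeros((4, 6))
        motion[2, 0] = 2.5  # translation only
        passed, _ = motion_exclusion_check(motion, rule="and")
        assert passed


class TestChain:
    def test_gsr_toggle_changes_only_the_design(self, rng, small_sim_config):
        """With GSR toggled, FD/scrubbing QC is identical and only the
        regression output differs."""
        from fcdegree.synthcohort import gray_matter_mask, simulate_subject

        run, motion, nuis = simulate_subject(small_sim_config, "control", 3)
        mask = gray_matter_mask(small_sim_config)
        base = PreprocessConfig(n_drop=4)
        gsr = PreprocessConfig(n_drop=4, use_gsr=True)
        out0, qc0 = preprocess_run(run, motion, nuis["wm"], nuis["csf"], base, mask)
        out1, qc1 = preprocess_run(run, motion, nuis["wm"], nuis["csf"], gsr, mask)
        assert qc0 == qc1
        assert not np.allclose(out0.data, out1.data)

    def test_motion_rows_must_match_volumes(self, rng):
        run = make_run(rng.standard_normal((3, 3, 3, 20)))
        with pytest.raises(DataError):
            preprocess_run(run, np.zeros((19, 6)), np.zeros(20), np.zeros(20),
                           PreprocessConfig(n_drop=0))
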