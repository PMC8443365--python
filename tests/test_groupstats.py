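"""Group-statistics tests: GLM against the pooled-t oracle, smoothness
recovery with known truth, resel counting, cluster labeling against a
flood-fill oracle, and GRF report behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from fcdegree.degree import DegreeConfig, DegreeMap
from fcdegree.errors import DataError
from fcdegree.imaging_io import MaskVolume
from fcdegree.groupstats import (
    StatsConfig,
    estimate_smoothness,
    fit_voxelwise_glm,
    grf_cluster_correct,
    label_clusters,
    resel_counts,
)


def make_maps(values, mask, ids=None):
    maps = []
    for i, v in enumerate(values):
        full = np.full(mask.data.shape, np.nan)
        full[mask.data] = v
        maps.append(DegreeMap(full, DegreeConfig(), ids[i] if ids else f"s{i}",
                              mask.n_voxels))
    return maps


@pytest.fixture
def mask10():
    return MaskVolume(np.pad(np.ones((4, 4, 4), bool), 1), np.eye(4))


class TestVoxelwiseGlm:
    def test_reduces_to_pooled_t_without_covariates(self, rng, mask10):
        """With an empty covariate list the GLM group t equals the classical
        pooled two-sample t at every voxel (textbook oracle)."""
        n1, n2 = 9, 7
        v = mask10.n_voxels
        y = rng.standard_normal((n1 + n2, v))
        pheno = pd.DataFrame({"group": ["patient"] * n1 + ["control"] * n2})
        glm = fit_voxelwise_glm(
            make_maps(y, mask10), pheno, StatsConfig(covariates=()), mask10
        )
        got = glm.t_map[mask10.data]
        want = stats.ttest_ind(y[:n1], y[n1:], axis=0).statistic
        np.testing.assert_allclose(got, want, atol=1e-8)
        assert glm.df == n1 + n2 - 2

    def test_null_calibration_of_voxel_t(self, rng, mask10):
        """Permuted labels: about 5% of voxels exceed the two-sided alpha=.05
        critical value."""
        n = 24
        y = rng.standard_normal((n, mask10.n_voxels))
        crit = stats.t.isf(0.025, n - 2)
        rates = []
        for _ in range(40):
            labels = rng.permutation(["patient"] * 12 + ["control"] * 12)
            pheno = pd.DataFrame({"group": labels})
            glm = fit_voxelwise_glm(
                make_maps(y, mask10), pheno, StatsConfig(covariates=()), mask10
            )
            rates.append(np.mean(np.abs(glm.t_map[mask10.data]) > crit))
        assert np.mean(rates) == pytest.approx(0.05, abs=0.02)

    def test_covariate_equal_to_group_is_collinear(self, rng, mask10):
        y = rng.standard_normal((10, mask10.n_voxels))
        pheno = pd.DataFrame(
            {"group": ["patient"] * 5 + ["control"] * 5,
             "dup": [1.0] * 5 + [0.0] * 5}
        )
        with pytest.raises(DataError, match="collinear"):
            fit_voxelwise_glm(
                make_maps(y, mask10), pheno, StatsConfig(covariates=("dup",)),
                mask10,
            )

    def test_missing_covariate_value_rejected(self, rng, mask10):
        y = rng.standard_normal((8, mask10.n_voxels))
        pheno = pd.DataFrame(
            {"group": ["patient"] * 4 + ["control"] * 4,
             "age": [30.0, np.nan, 31, 29, 33, 28, 30, 27]}
        )
        with pytest.raises(DataError, match="age"):
            fit_voxelwise_glm(
                make_maps(y, mask10), pheno, StatsConfig(covariates=("age",)),
                mask10,
            )


class TestSmoothness:
    def test_known_kernel_recovered(self, rng):
        """White-noise maps smoothed with a 6 mm kernel on 3 mm voxels (2.0
        voxels FWHM) are recovered within 15% over 50 replicates."""
        shape = (16, 16, 16)
        mask = MaskVolume(np.ones(shape, bool), np.diag([3.0, 3, 3, 1]))
        sigma = 6.0 / 2.3548 / 3.0
        estimates = []
        for _ in range(50):
            res = ndimage.gaussian_filter(
                rng.standard_normal((8, *shape)), (0, sigma, sigma, sigma),
                mode="wrap",
            )
            estimates.append(estimate_smoothness(res, mask))
        fwhm_vox = np.mean(estimates, axis=0)
        np.testing.assert_allclose(fwhm_vox, 2.0, rtol=0.15)

    def test_white_noise_floor_is_about_one_voxel(self, rng):
        shape = (14, 14, 14)
        mask = MaskVolume(np.ones(shape, bool), np.eye(4))
        fwhm = estimate_smoothness(rng.standard_normal((10, *shape)), mask)
        np.testing.assert_allclose(fwhm, 1.0, atol=0.25)

    def test_too_few_maps_rejected(self, rng, mask10):
        with pytest.raises(DataError):
            estimate_smoothness(rng.standard_normal((2, 6, 6, 6)), mask10)


class TestResels:
    def test_full_box_counts(self):
        """For an a x b x c box with FWHM f, R_3 = (a-1)(b-1)(c-1) / f^3."""
        mask = MaskVolume(np.ones((5, 6, 7), bool), np.eye(4))
        r = resel_counts(mask, np.array([2.0, 2.0, 2.0]))
        assert r[0] == pytest.approx(1.0)
        assert r[3] == pytest.approx(4 * 5 * 6 / 8.0)

    def test_volume_doubling_doubles_r3(self):
        m1 = MaskVolume(np.ones((4, 4, 7), bool), np.eye(4))
        m2 = MaskVolume(np.ones((4, 4, 13), bool), np.eye(4))
        f = np.array([1.5, 1.5, 1.5])
        r1, r2 = resel_counts(m1, f), resel_counts(m2, f)
        assert r2[3] == pytest.approx(2 * r1[3])


class TestClusterLabeling:
    def _flood_fill(self, binary, connectivity):
        """Exhaustive BFS oracle for connected components."""
        offsets = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    if (dx, dy, dz) == (0, 0, 0):
                        continue
                    order = abs(dx) + abs(dy) + abs(dz)
                    if connectivity == 6 and order > 1:
                        continue
                    if connectivity == 18 and order > 2:
                        continue
                    offsets.append((dx, dy, dz))
        seen = np.zeros_like(binary, bool)
        comps = []
        for idx in np.argwhere(binary):
            idx = tuple(idx)
            if seen[idx]:
                continue
            stack, comp = [idx], set()
            seen[idx] = True
            while stack:
                cur = stack.pop()
                comp.add(cur)
                for off in offsets:
                    nb = tuple(np.add(cur, off))
                    if any(c < 0 or c >= s for c, s in zip(nb, binary.shape)):
                        continue
                    if binary[nb] and not seen[nb]:
                        seen[nb] = True
                        stack.append(nb)
            comps.append(frozenset(comp))
        return set(comps)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_labels_match_flood_fill(self, rng, connectivity):
        for _ in range(5):
            binary = rng.random((10, 10, 10)) < 0.25
            labels, n = label_clusters(binary, connectivity)
            got = {
                frozenset(map(tuple, np.argwhere(labels == k)))
                for k in range(1, n + 1)
            }
            assert got == self._flood_fill(binary, connectivity)


class TestGrfReport:
    def test_subthreshold_map_gives_empty_table(self, mask10):
        t_map = np.where(mask10.data, 0.5, np.nan)
        table, label_map, thr = grf_cluster_correct(
            t_map, df=30, fwhm_vox=np.array([2.0, 2, 2]), mask=mask10,
            config=StatsConfig(),
        )
        assert len(table) == 0
        assert not label_map.any() and not thr.any()

    def test_massive_cluster_survives_with_direction_and_peak(self, mask10):
        t_map = np.zeros(mask10.data.shape)
        t_map[2:5, 2:5, 2:5] = 9.0
        t_map[3, 3, 3] = 11.0
        affine = np.diag([3.0, 3, 3, 1])
        table, label_map, thr = grf_cluster_correct(
            t_map, df=30, fwhm_vox=np.array([2.0, 2, 2]), mask=mask10,
            config=StatsConfig(), affine=affine,
        )
        assert len(table) == 1
        row = table.iloc[0]
        assert row["direction"] == "increase"
        assert row["n_voxels"] == 27
        assert row["peak_t"] == pytest.approx(11.0)
        assert (row["peak_x"], row["peak_y"], row["peak_z"]) == (9.0, 9.0, 9.0)
        assert row["corrected_p"] < 0.05

    def test_decrease_direction_reported(self, mask10):
        t_map = np.zeros(mask10.data.shape)
        t_map[2:5, 2:5, 2:5] = -9.0
        table, *_ = grf_cluster_correct(
            t_map, df=30, fwhm_vox=np.array([2.0, 2, 2]), mask=mask10,
            config=StatsConfig(),
        )
        assert list(table["direction"]) == ["decrease"]
        assert table.iloc[0]["peak_t"] < 0

    def test_low_df_rejected(self, mask10):
        with pytest.raises(DataError):
            grf_cluster_correct(
                np.zeros(mask10.data.shape), df=2,
                fwhm_vox=np.array([2.0, 2, 2]), mask=mask10, config=StatsConfig(),
            )
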