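"""GLM contrasts, TFCE (vs a scipy.ndimage oracle), and permutation FWE."""

import numpy as np
import pytest
from scipy import ndimage, stats

from decm.errors import DegenerateDesignError, ValidationError
from decm.inference import (
    GroupDesign,
    TfceParams,
    bonferroni_threshold,
    cluster_report,
    glm_contrast_tmap,
    make_group_design,
    median_split,
    permutation_fwe,
    tfce,
)
from decm.volumes import Mask3D, mask_coordinates


def tfce_oracle(stat, mask, e_exp, h_exp, dh):
    """Brute-force TFCE: scipy.ndimage labelling at every threshold step."""
    coords = mask_coordinates(mask)
    out = np.zeros_like(stat)
    structure = np.ones((3, 3, 3), bool)
    for sign in (1.0, -1.0):
        part = sign * stat
        vmax = part.max(initial=0.0)
        if vmax <= 0:
            continue
        h = dh
        while h <= vmax * (1 + 1e-12):
            grid = np.zeros(mask.shape)
            grid[coords[:, 0], coords[:, 1], coords[:, 2]] = part
            active = grid >= h
            labels, _ = ndimage.label(active, structure=structure)
            sizes = np.bincount(labels.ravel())
            lab_vox = labels[coords[:, 0], coords[:, 1], coords[:, 2]]
            sel = part >= h
            out[sel] += sign * sizes[lab_vox[sel]] ** e_exp * h**h_exp * dh
            h += dh
    return out


class TestMedianSplit:
    def test_even_split(self):
        np.testing.assert_array_equal(
            median_split([20, 22, 24, 26]), ["young", "young", "old", "old"]
        )

    def test_odd_count_median_goes_old(self):
        labels = median_split([20, 24, 30])
        assert list(labels) == ["young", "old", "old"]

    def test_ties_at_median_go_old(self):
        labels = median_split([20, 24, 24, 24, 30])
        assert list(labels) == ["young", "old", "old", "old", "old"]

    def test_identical_ages_rejected(self):
        with pytest.raises(ValidationError):
            median_split([24, 24, 24])


class TestGlmContrast:
    def test_identical_groups_zero_t(self):
        maps = np.tile(np.arange(5.0), (6, 1))
        d = make_group_design(["A", "B", "A", "B", "A", "B"])
        with pytest.warns(RuntimeWarning):
            t = glm_contrast_tmap(maps, d)
        np.testing.assert_array_equal(t, 0.0)

    def test_matches_two_sample_t(self, rng):
        """Two-group design without covariate equals the pooled-variance t-test."""
        a, b = rng.standard_normal(3) + 1.0, rng.standard_normal(3)
        maps = np.concatenate([a, b])[:, None]
        d = make_group_design(["A"] * 3 + ["B"] * 3)
        t = glm_contrast_tmap(maps, d)
        expected = stats.ttest_ind(a, b, equal_var=True).statistic
        # indicator is +/-1 coded: contrast effect = 2 * group-mean difference,
        # but the t statistic is scale invariant
        assert t[0] == pytest.approx(expected, rel=1e-10)

    def test_covariate_equal_to_indicator_rejected(self):
        groups = ["A", "B"] * 4
        ind = np.where(np.array(groups) == "A", 1.0, -1.0)
        with pytest.raises(DegenerateDesignError):
            make_group_design(groups, covariates=ind[:, None])


class TestTfce:
    def _single_voxel_mask(self):
        data = np.zeros((5, 5, 5))
        data[2, 2, 2] = 1
        return Mask3D(data=data)

    def test_all_zero_map(self, ball_mask):
        out = tfce(np.zeros(ball_mask.count), ball_mask)
        np.testing.assert_array_equal(out, 0.0)

    def test_single_voxel_closed_form(self):
        # isolated peak of height 2, E=0.5, H=2: integral of h^2 dh = 8/3
        mask = self._single_voxel_mask()
        params = TfceParams(e_exponent=0.5, h_exponent=2.0, dh=0.01)
        out = tfce(np.array([2.0]), mask, params)
        assert out[0] == pytest.approx(8.0 / 3.0, rel=0.01)

    def test_uniform_cube_scales_with_sqrt_extent(self):
        # 2x2x2 cube at height h: e(h)=8 throughout, so value = sqrt(8) x single-voxel
        data = np.zeros((6, 6, 6))
        data[2:4, 2:4, 2:4] = 1
        mask = Mask3D(data=data)
        params = TfceParams(e_exponent=0.5, h_exponent=2.0, dh=0.005)
        cube = tfce(np.full(8, 1.7), mask, params)
        single = tfce(np.array([1.7]), self._single_voxel_mask(), params)
        np.testing.assert_allclose(cube, np.sqrt(8.0) * single[0], rtol=1e-10)

    def test_matches_ndimage_oracle_on_random_maps(self, rng, ball_mask):
        params = TfceParams(dh=0.05)
        for _ in range(5):
            stat = rng.standard_normal(ball_mask.count) * 2.0
            fast = tfce(stat, ball_mask, params)
            slow = tfce_oracle(stat, ball_mask, 0.5, 2.0, 0.05)
            np.testing.assert_allclose(fast, slow, atol=1e-9)

    def test_monotone_in_input(self, rng, ball_mask):
        params = TfceParams(dh=0.05)
        for _ in range(10):
            lo = np.abs(rng.standard_normal(ball_mask.count))
            hi = lo + np.abs(rng.standard_normal(ball_mask.count))
            assert np.all(tfce(hi, ball_mask, params) >= tfce(lo, ball_mask, params) - 1e-12)

    def test_negative_values_enhanced_symmetrically(self, ball_mask, rng):
        stat = rng.standard_normal(ball_mask.count)
        params = TfceParams(dh=0.05)
        np.testing.assert_allclose(
            tfce(-stat, ball_mask, params), -tfce(stat, ball_mask, params), atol=1e-12
        )


class TestPermutationFwe:
    def _cohort_maps(self, rng, mask, effect=0.0, n_per_group=6):
        groups = ["A", "B"] * n_per_group
        maps = rng.standard_normal((2 * n_per_group, mask.count))
        maps[np.array(groups) == "B"] += effect
        return maps, make_group_design(groups, direction=-1)

    def test_identical_maps_p_one(self, ball_mask, rng):
        maps = np.tile(rng.standard_normal(ball_mask.count), (8, 1))
        d = make_group_design(["A", "B"] * 4)
        res = permutation_fwe(maps, d, ball_mask, n_perm=100, seed=0)
        np.testing.assert_array_equal(res.pcorr, 1.0)

    def test_pcorr_monotone_in_tfce(self, ball_mask, rng):
        maps, d = self._cohort_maps(rng, ball_mask, effect=0.8)
        res = permutation_fwe(maps, d, ball_mask, n_perm=200, seed=1)
        order = np.argsort(res.tfce_map)
        assert np.all(np.diff(res.pcorr[order]) <= 1e-12)
        assert res.null_max.shape == (200,)
        assert res.pcorr.min() >= 1.0 / 201.0

    def test_strong_effect_detected(self, ball_mask, rng):
        maps, d = self._cohort_maps(rng, ball_mask, effect=3.0, n_per_group=8)
        res = permutation_fwe(maps, d, ball_mask, n_perm=300, seed=2)
        assert res.pcorr.min() < 0.05

    def test_deterministic_given_seed(self, ball_mask, rng):
        maps, d = self._cohort_maps(rng, ball_mask, effect=1.0)
        r1 = permutation_fwe(maps, d, ball_mask, n_perm=150, seed=42)
        r2 = permutation_fwe(maps, d, ball_mask, n_perm=150, seed=42)
        np.testing.assert_array_equal(r1.pcorr, r2.pcorr)
        np.testing.assert_array_equal(r1.null_max, r2.null_max)

    def test_exhaustive_enumeration_for_tiny_cohorts(self, rng):
        data = np.zeros((3, 3, 3))
        data[1, 1, :] = 1
        mask = Mask3D(data=data)
        maps = rng.standard_normal((5, mask.count))
        d = GroupDesign(
            design=np.column_stack([[1, -1, 1, -1, 1], np.ones(5)]),
            contrast=[1.0, 0.0],
        )
        with pytest.warns(RuntimeWarning, match="exhaustively"):
            res = permutation_fwe(maps, d, mask, n_perm=1000, seed=0)
        assert res.n_perm == 120  # 5!

    def test_freedman_lane_and_labels_agree_without_nuisance(self, ball_mask, rng):
        # with only an intercept as nuisance the two schemes use the same
        # permutation space; results should be statistically indistinguishable
        maps, d = self._cohort_maps(rng, ball_mask, effect=1.5)
        r_fl = permutation_fwe(maps, d, ball_mask, n_perm=300, seed=3)
        r_lb = permutation_fwe(maps, d, ball_mask, n_perm=300, seed=3, scheme="labels")
        np.testing.assert_array_equal(r_fl.tmap, r_lb.tmap)
        assert abs(r_fl.pcorr.min() - r_lb.pcorr.min()) < 0.05


def test_bonferroni_threshold():
    assert bonferroni_threshold(0.05, 10) == pytest.approx(0.005)
    assert bonferroni_threshold(0.05, 1) == pytest.approx(0.05)
    ks = [1, 2, 5, 10, 20]
    thresholds = [bonferroni_threshold(0.05, k) for k in ks]
    assert thresholds == sorted(thresholds, reverse=True)


class TestClusterReport:
    def test_empty_when_nothing_significant(self, ball_mask):
        table = cluster_report(np.ones(ball_mask.count), np.zeros(ball_mask.count), ball_mask)
        assert len(table) == 0

    def test_size_filter_keeps_only_large_clusters(self):
        data = np.ones((30, 4, 4))
        mask = Mask3D(data=data)
        pcorr = np.ones(mask.count)
        coords = mask_coordinates(mask)
        # one 12-voxel block and one 8-voxel block, well separated in x
        big = (coords[:, 0] < 3) & (coords[:, 1] < 2) & (coords[:, 2] < 2)
        small = (coords[:, 0] >= 20) & (coords[:, 0] < 22) & (coords[:, 1] < 2) & (coords[:, 2] < 2)
        assert big.sum() == 12 and small.sum() == 8
        pcorr[big | small] = 0.01
        stat = np.where(pcorr < 0.05, 5.0, 0.0)
        table = cluster_report(pcorr, stat, mask, alpha=0.05, min_size=10)
        assert len(table) == 1
        assert table.iloc[0]["size"] == 12

    def test_component_sizes_match_flood_fill(self, rng, ball_mask):
        pcorr = rng.uniform(0, 1, ball_mask.count)
        stat = rng.standard_normal(ball_mask.count)
        table = cluster_report(pcorr, stat, ball_mask, alpha=0.3, min_size=1)
        # brute force: label the significant set with scipy and count
        coords = mask_coordinates(ball_mask)
        grid = np.zeros(ball_mask.shape, bool)
        sel = pcorr < 0.3
        grid[coords[sel, 0], coords[sel, 1], coords[sel, 2]] = True
        labels, n = ndimage.label(grid, structure=np.ones((3, 3, 3), bool))
        sizes = sorted(np.bincount(labels.ravel())[1:], reverse=True)
        expected = [s for s in sizes if s > 1]
        assert sorted(table["size"], reverse=True) == expected
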