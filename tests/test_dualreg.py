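"""Dual regression: exact recovery, oracle equivalence, network masks."""

import numpy as np
import pytest

from decm.dualregression import (
    TemplateSet,
    dual_regression,
    make_network_mask,
    normalize_timecourses,
    stage1_spatial_regression,
    stage2_temporal_regression,
)
from decm.errors import DegenerateDesignError, ValidationError
from decm.sliding import CentralitySeries
from decm.volumes import Mask3D


def _cs(values):
    return CentralitySeries(
        values=np.asarray(values, float),
        window_length=10,
        window_starts=np.arange(np.asarray(values).shape[1]),
    )


def _orthogonal_templates(rng, n=200, k=3):
    """Demeaned, mutually orthogonal spatial patterns."""
    q, _ = np.linalg.qr(rng.standard_normal((n, k + 1)))
    maps = q[:, 1:]  # orthogonal to the constant direction? enforce demeaning:
    maps = maps - maps.mean(axis=0)
    q2, _ = np.linalg.qr(maps)
    return q2


def test_exact_recovery_of_known_timecourses(rng):
    c = _orthogonal_templates(rng)
    s_true = rng.standard_normal((3, 12))
    cs = _cs(c @ s_true)
    t = TemplateSet(maps=c)
    s = stage1_spatial_regression(cs, t)
    np.testing.assert_allclose(s.values, s_true, atol=1e-8)


def test_noisy_recovery_matches_normal_equations_oracle(rng):
    c = _orthogonal_templates(rng) + 0.1 * rng.standard_normal((200, 3))
    s_true = rng.standard_normal((3, 15))
    signal = c @ s_true
    cs = _cs(signal + 0.1 * signal.std() * rng.standard_normal(signal.shape))
    t = TemplateSet(maps=c)
    s = stage1_spatial_regression(cs, t)
    # independent oracle: solve the normal equations directly
    cd = c - c.mean(axis=0)
    y = cs.values - cs.values.mean(axis=0)
    oracle = np.linalg.solve(cd.T @ cd, cd.T @ y)
    np.testing.assert_allclose(s.values, oracle, atol=1e-8)
    for row, true_row in zip(s.values, s_true):
        assert np.corrcoef(row, true_row)[0, 1] > 0.99


def test_stage2_constant_voxel_gets_zero_coefficients(rng):
    c = _orthogonal_templates(rng, n=50, k=2)
    s_true = rng.standard_normal((2, 10))
    values = c @ s_true
    values[7] = 4500.0  # constant centrality across windows
    d = stage2_temporal_regression(
        _cs(values), normalize_timecourses(stage1_spatial_regression(_cs(values), TemplateSet(maps=c)))
    )
    np.testing.assert_allclose(d.values[7], 0.0, atol=1e-8)


def test_stage2_matches_normal_equations_oracle(rng):
    c = _orthogonal_templates(rng)
    s_true = rng.standard_normal((3, 20))
    cs = _cs(c @ s_true + 0.05 * rng.standard_normal((200, 20)))
    s = normalize_timecourses(stage1_spatial_regression(cs, TemplateSet(maps=c)))
    d = stage2_temporal_regression(cs, s)
    x = np.column_stack([np.ones(20), s.values.T])
    oracle = np.linalg.solve(x.T @ x, x.T @ cs.values.T)[1:].T
    np.testing.assert_allclose(d.values, oracle, atol=1e-8)


def test_full_roundtrip_recovers_both_factors(rng):
    c = _orthogonal_templates(rng)
    s_true = rng.standard_normal((3, 25))
    cs = _cs(c @ s_true)
    s, d = dual_regression(cs, TemplateSet(maps=c))
    for k in range(3):
        assert abs(np.corrcoef(s.values[k], s_true[k])[0, 1]) > 0.999
        assert abs(np.corrcoef(d.values[:, k], c[:, k])[0, 1]) > 0.999


def test_template_order_invariance(rng):
    c = _orthogonal_templates(rng)
    cs = _cs(c @ rng.standard_normal((3, 12)) + 0.01 * rng.standard_normal((200, 12)))
    s1, d1 = dual_regression(cs, TemplateSet(maps=c, names=["a", "b", "c"]))
    perm = [2, 0, 1]
    s2, d2 = dual_regression(cs, TemplateSet(maps=c[:, perm], names=["c", "a", "b"]))
    np.testing.assert_allclose(s2.values, s1.values[perm], atol=1e-8)
    np.testing.assert_allclose(d2.values, d1.values[:, perm], atol=1e-8)


def test_normalize_timecourses_unit_sd(rng):
    from decm.dualregression import SubjectTimecourses

    s = SubjectTimecourses(values=rng.standard_normal((4, 30)) * [[1], [10], [0.1], [3]])
    out = normalize_timecourses(s)
    np.testing.assert_allclose(out.values.std(axis=1, ddof=1), 1.0, atol=1e-12)
    assert out.variance_normalized


def test_collinear_templates_named(rng):
    base = rng.standard_normal(100)
    maps = np.column_stack([base, 2 * base + 1e-9, rng.standard_normal(100)])
    t = TemplateSet(maps=maps, names=["dmn", "dmn_copy", "visual"])
    with pytest.raises(DegenerateDesignError, match="dmn"):
        stage1_spatial_regression(_cs(rng.standard_normal((100, 8))), t)


class TestNetworkMask:
    def _setup(self, rng, ball_mask):
        n = ball_mask.count
        maps = rng.standard_normal((n, 2))
        return TemplateSet(maps=maps, names=["a", "b"], zthreshold=0.0), ball_mask

    def test_zero_threshold_gives_positive_support(self, rng, ball_mask):
        t, mask = self._setup(rng, ball_mask)
        m = make_network_mask(t, 0, mask)
        assert m.count == int((t.maps[:, 0] > 0).sum())

    def test_threshold_above_max_empty_with_warning(self, rng, ball_mask):
        t, mask = self._setup(rng, ball_mask)
        t.zthreshold = float(t.maps.max()) + 1
        with pytest.warns(RuntimeWarning):
            assert make_network_mask(t, 1, mask).count == 0

    def test_known_suprathreshold_count(self, ball_mask):
        n = ball_mask.count
        maps = np.zeros((n, 1))
        maps[:17, 0] = 5.0
        maps[17:, 0] = -1.0
        t = TemplateSet(maps=maps, zthreshold=3.0)
        assert make_network_mask(t, 0, ball_mask).count == 17
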