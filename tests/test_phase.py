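import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isckit.frequency import FilterBankSpec
from isckit.phase import analytic_phase, ips, ips_roi_curves, pairwise_phase_distance
from isckit.datamodel import AtlasDefinition
from isckit.synthetic import SyntheticSpec, synth_session

from conftest import make_session


def wrap_to_pi(x):
    return np.mod(x + np.pi, 2 * np.pi) - np.pi


class TestAnalyticPhase:
    def test_cosine_phase_advances_linearly(self):
        omega = 2 * np.pi * 0.1
        t = np.arange(200)
        theta = analytic_phase(np.cos(omega * t))
        interior = slice(20, 180)
        np.testing.assert_allclose(
            wrap_to_pi(theta[interior] - omega * t[interior]), 0.0, atol=0.05
        )

    def test_sine_lags_cosine_by_half_pi(self):
        omega = 2 * np.pi * 0.1
        t = np.arange(200)
        th_cos = analytic_phase(np.cos(omega * t))
        th_sin = analytic_phase(np.sin(omega * t))
        interior = slice(20, 180)
        np.testing.assert_allclose(
            wrap_to_pi(th_cos[interior] - th_sin[interior]), np.pi / 2, atol=0.05
        )

    def test_identical_inputs_identical_phases(self, rng):
        x = rng.standard_normal(64)
        np.testing.assert_array_equal(analytic_phase(x), analytic_phase(x.copy()))

    def test_constant_series_yields_nan_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            theta = analytic_phase(np.ones(16))
        assert np.all(np.isnan(theta))


class TestPhaseDistance:
    def test_equal_phases_give_zero(self, rng):
        th = rng.uniform(-np.pi, np.pi, 50)
        np.testing.assert_array_equal(pairwise_phase_distance(th, th), 0.0)

    def test_constant_offset_half_pi(self):
        th = np.linspace(-np.pi / 2, np.pi / 2, 30)
        d = pairwise_phase_distance(th, th + np.pi / 2)
        np.testing.assert_allclose(d, np.pi / 2, atol=1e-12)

    def test_matches_scalar_loop(self, rng):
        ti = rng.uniform(-np.pi, np.pi, 40)
        tj = rng.uniform(-np.pi, np.pi, 40)
        d = pairwise_phase_distance(ti, tj)
        for k in range(40):
            assert d[k] == pytest.approx(abs(ti[k] - tj[k]) % np.pi, abs=1e-14)

    def test_antiphase_in_both_modes(self):
        # the printed mod-pi distance scores exact antiphase as 0;
        # the wrap mode scores it as maximal
        th = np.zeros(5)
        assert pairwise_phase_distance(th, th + np.pi)[0] == pytest.approx(0.0)
        assert pairwise_phase_distance(th, th + np.pi, mode="wrap")[0] == pytest.approx(np.pi)


class TestIPS:
    def test_identical_subjects_give_ips_one_everywhere(self, rng):
        data = rng.standard_normal((2, 2, 2, 40))
        sess = make_session([data.copy() for _ in range(4)])
        with pytest.warns(UserWarning, match="broadband"):
            result = ips(sess)
        np.testing.assert_array_equal(result.ips, 1.0)
        np.testing.assert_array_equal(result.p_bar, 0.0)

    def test_quarter_cycle_offset_gives_half(self):
        omega = 2 * np.pi * 0.1
        t = np.arange(200)
        a = np.cos(omega * t).reshape(1, 1, 1, -1)
        b = np.sin(omega * t).reshape(1, 1, 1, -1)
        sess = make_session([a, b])
        with pytest.warns(UserWarning, match="broadband"):
            result = ips(sess)
        interior = result.ips[0, 0, 0, 20:180]
        np.testing.assert_allclose(interior, 0.5, atol=0.02)

    def test_three_subject_hand_average(self):
        # pairwise distances (0, pi/2, pi/2) -> p_bar = pi/3, ips = 2/3
        d = np.array([0.0, np.pi / 2, np.pi / 2])
        p_bar = d.mean()
        assert 1 - p_bar / np.pi == pytest.approx(2 / 3)
        omega = 2 * np.pi * 0.1
        t = np.arange(200)
        x = np.cos(omega * t).reshape(1, 1, 1, -1)
        y = np.sin(omega * t).reshape(1, 1, 1, -1)
        sess = make_session([x, x.copy(), y])
        with pytest.warns(UserWarning, match="broadband"):
            result = ips(sess)
        np.testing.assert_allclose(result.ips[0, 0, 0, 20:180], 2 / 3, atol=0.02)

    def test_values_bounded_and_full_temporal_resolution(self, tiny_session):
        result = ips(tiny_session, bank=FilterBankSpec(n_levels=2))
        vals = result.ips[tiny_session.mask.mask]
        assert vals.shape[-1] == tiny_session.n_timepoints
        assert np.all(vals >= 0) and np.all(vals <= 1)

    def test_subject_permutation_invariance(self, rng):
        arrays = [rng.standard_normal((2, 2, 1, 64)) for _ in range(4)]
        with pytest.warns(UserWarning, match="broadband"):
            a = ips(make_session(arrays))
            b = ips(make_session([arrays[i] for i in (3, 1, 0, 2)]))
        np.testing.assert_allclose(a.ips, b.ips, atol=1e-12)

    def test_edge_samples_flagged(self, tiny_session):
        result = ips(tiny_session, bank=FilterBankSpec(n_levels=2))
        assert result.edge_samples == int(np.ceil(tiny_session.n_timepoints / 20))


class TestIPSCurves:
    def test_whole_mask_curve_is_global_mean(self, tiny_session):
        result = ips(tiny_session, bank=FilterBankSpec(n_levels=2))
        atlas = AtlasDefinition(regions=[("all", np.ones(tiny_session.spatial_shape))])
        (curve,) = ips_roi_curves(result, atlas, tiny_session)
        np.testing.assert_allclose(
            curve.values, np.nanmean(result.ips[tiny_session.mask.mask], axis=0)
        )
        assert len(curve.values) == tiny_session.n_timepoints

    def test_constant_map_gives_constant_curve(self, rng):
        data = rng.standard_normal((2, 2, 1, 40))
        sess = make_session([data.copy() for _ in range(3)])
        with pytest.warns(UserWarning, match="broadband"):
            result = ips(sess)
        atlas = AtlasDefinition(regions=[("all", np.ones((2, 2, 1)))])
        (curve,) = ips_roi_curves(result, atlas, sess)
        np.testing.assert_allclose(curve.values, 1.0)

    def test_time_localized_locking_peaks_at_locked_interval(self):
        rng = np.random.default_rng(17)
        T = 160
        omega = 2 * np.pi * 0.08
        t = np.arange(T)
        locked = np.cos(omega * t)
        arrays = []
        for _ in range(4):
            x = rng.standard_normal(T)
            x[60:100] = locked[60:100] + 0.05 * rng.standard_normal(40)
            arrays.append(x.reshape(1, 1, 1, -1))
        sess = make_session(arrays)
        with pytest.warns(UserWarning, match="broadband"):
            result = ips(sess)
        atlas = AtlasDefinition(regions=[("all", np.ones((1, 1, 1)))])
        (curve,) = ips_roi_curves(result, atlas, sess)
        inside = curve.values[65:95].mean()
        outside = np.concatenate([curve.values[10:50], curve.values[110:150]]).mean()
        assert inside > outside + 0.2
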