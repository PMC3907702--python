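import numpy as np
import pytest

from isckit.core import isc_map
from isckit.datamodel import AtlasDefinition
from isckit.resampling import sample_null_distribution
from isckit.synthetic import SyntheticSpec, synth_session
from isckit.timewindow import (
    WindowSpec,
    curves_to_frame,
    make_windows,
    pooled_window_null,
    roi_curves,
    windowed_isc,
)

from conftest import make_session


class TestMakeWindows:
    def test_session_length_244_with_30_30(self):
        windows = make_windows(244, WindowSpec(30, 30))
        assert len(windows) == 8
        assert windows[0] == (0, 30) and windows[-1] == (210, 240)

    def test_full_length_window(self):
        assert make_windows(10, WindowSpec(10, 1)) == [(0, 10)]

    def test_unit_step_starts(self):
        with pytest.warns(UserWarning):  # short-window warning
            spec = WindowSpec(2, 1)
        assert [s for s, _ in make_windows(4, spec)] == [0, 1, 2]

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            make_windows(5, WindowSpec(10, 1))

    @pytest.mark.parametrize("T,W,S", [(100, 17, 3), (50, 50, 7), (33, 12, 12)])
    def test_count_formula_and_bounds(self, T, W, S):
        windows = make_windows(T, WindowSpec(W, S))
        assert len(windows) == (T - W) // S + 1
        assert all(0 <= a and b <= T and b - a == W for a, b in windows)


class TestWindowedISC:
    def test_whole_series_window_reduces_to_basic_map(self, tiny_session):
        T = tiny_session.n_timepoints
        wmaps = windowed_isc(tiny_session, WindowSpec(T, T))
        assert wmaps.n_windows == 1
        np.testing.assert_array_equal(
            wmaps.maps[0].rbar, isc_map(tiny_session).rbar
        )

    def test_window_localized_signal_peaks_in_its_window(self):
        sess = synth_session(
            SyntheticSpec(
                n_subjects=4,
                T=120,
                rho=0.6,
                dims=(3, 3, 1),
                seed=2,
                shared_window=(60, 90),
                noise_kind="white",
            )
        )
        wmaps = windowed_isc(sess, WindowSpec(30, 30))
        means = [float(np.nanmean(m.rbar)) for m in wmaps.maps]
        assert int(np.argmax(means)) == 2  # window [60, 90)

    def test_window_centers_on_time_axis(self, tiny_session):
        wmaps = windowed_isc(tiny_session, WindowSpec(20, 20))
        np.testing.assert_allclose(
            wmaps.window_centers_seconds,
            (wmaps.window_starts + 9.5) * tiny_session.tr_seconds,
        )


class TestPooledWindowNull:
    def test_reproducible_given_seed(self, null_session):
        spec = WindowSpec(20, 20)
        a = pooled_window_null(null_session, spec, 400, seed=3)
        b = pooled_window_null(null_session, spec, 400, seed=3)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_single_window_reduces_to_basic_null(self, null_session):
        T = null_session.n_timepoints
        pooled = pooled_window_null(null_session, WindowSpec(T, T), 500, seed=9)
        basic = sample_null_distribution(null_session, 500, seed=9)
        np.testing.assert_array_equal(pooled.samples, basic.samples)

    def test_common_threshold_calibrated_across_windows(self):
        # null data: the common uncorrected threshold should be exceeded at
        # comparable rates in every window
        sess = synth_session(
            SyntheticSpec(n_subjects=4, T=120, rho=0.0, dims=(5, 5, 2), seed=31)
        )
        spec = WindowSpec(30, 30)
        null = pooled_window_null(sess, spec, 20_000, seed=5)
        crit = np.quantile(null.samples, 0.95)
        wmaps = windowed_isc(sess, spec)
        rates = [float(np.mean(m.rbar[sess.mask.mask] > crit)) for m in wmaps.maps]
        n_vox = sess.mask.n_voxels
        ci = 3 * np.sqrt(0.05 * 0.95 / n_vox)
        for rate in rates:
            assert abs(rate - 0.05) < ci


class TestROICurves:
    def _atlas(self, shape, split):
        a = np.zeros(shape)
        b = np.zeros(shape)
        a[:split] = 1.0
        b[split:] = 1.0
        return AtlasDefinition(regions=[("front", a), ("back", b)])

    def test_whole_mask_roi_equals_global_mean(self, tiny_session):
        atlas = AtlasDefinition(
            regions=[("all", np.ones(tiny_session.spatial_shape))]
        )
        wmaps = windowed_isc(tiny_session, WindowSpec(20, 20))
        (curve,) = roi_curves(wmaps, atlas, tiny_session)
        expected = [float(np.nanmean(m.rbar)) for m in wmaps.maps]
        np.testing.assert_allclose(curve.values, expected)

    def test_disjoint_rois_separate_by_construction(self):
        strong = synth_session(
            SyntheticSpec(n_subjects=4, T=80, rho=0.7, dims=(2, 2, 2), seed=6, noise_kind="white")
        )
        null = synth_session(
            SyntheticSpec(n_subjects=4, T=80, rho=0.0, dims=(2, 2, 2), seed=7, noise_kind="white")
        )
        arrays = [
            np.concatenate([a.data, b.data], axis=0)
            for a, b in zip(strong.subjects, null.subjects)
        ]
        sess = make_session(arrays)
        atlas = self._atlas((4, 2, 2), split=2)
        wmaps = windowed_isc(sess, WindowSpec(40, 40))
        front, back = roi_curves(wmaps, atlas, sess)
        assert np.all(front.values > back.values)

    def test_empty_roi_yields_nan_curve_with_warning(self, tiny_session):
        atlas = AtlasDefinition(
            regions=[("nothing", np.zeros(tiny_session.spatial_shape))]
        )
        wmaps = windowed_isc(tiny_session, WindowSpec(20, 20))
        with pytest.warns(UserWarning, match="empty"):
            (curve,) = roi_curves(wmaps, atlas, tiny_session)
        assert np.all(np.isnan(curve.values))

    def test_curves_frame_layout(self, tiny_session):
        atlas = AtlasDefinition(
            regions=[("all", np.ones(tiny_session.spatial_shape))]
        )
        wmaps = windowed_isc(tiny_session, WindowSpec(20, 20))
        frame = curves_to_frame(roi_curves(wmaps, atlas, tiny_session))
        assert list(frame.columns) == ["all"]
        assert frame.index.name == "time_s"
        assert len(frame) == wmaps.n_windows
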