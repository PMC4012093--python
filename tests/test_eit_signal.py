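import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from eitflow.breath_phase import BreathCycle, BreathSegmentation, segment_breaths
from eitflow.eit_signal import (
    PixelFrameSeries,
    ROILayout,
    RegionalImpedanceSeries,
    SUB_ROIS,
    calibrate_volume,
    compute_tidal_amplitude,
    differentiate,
    extract_roi_series,
)


def frames_of(arr, fs=13.0):
    return PixelFrameSeries(frames=np.asarray(arr, dtype=float), fs=fs)


class TestPixelFrameSeries:
    def test_requires_two_frames(self):
        with pytest.raises(ValueError, match="2 frames"):
            frames_of(np.zeros((1, 32, 32)))

    def test_requires_positive_fs(self):
        with pytest.raises(ValueError, match="fs"):
            frames_of(np.zeros((3, 32, 32)), fs=0.0)

    def test_rejects_non_finite(self):
        bad = np.zeros((3, 32, 32))
        bad[1, 4, 4] = np.nan
        with pytest.raises(ValueError, match="finite"):
            frames_of(bad)

    def test_times(self):
        f = frames_of(np.zeros((3, 32, 32)), fs=10.0)
        np.testing.assert_allclose(f.times, [0.0, 0.1, 0.2])


class TestROILayout:
    def test_default_partition(self):
        layout = ROILayout()
        assert layout.rows("ventral") == slice(0, 8)
        assert layout.rows("middle") == slice(8, 16)
        assert layout.rows("dorsal") == slice(16, 24)
        assert layout.mask("global").sum() == 24 * 32
        assert not layout.mask("global")[24:].any()

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ROILayout(ventral=(0, 9), middle=(8, 16))

    def test_gap_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            ROILayout(ventral=(0, 7))

    def test_small_matrix(self):
        layout = ROILayout(
            ventral=(0, 2), middle=(2, 4), dorsal=(4, 6), excluded=(6, 8),
            n_rows=8, n_cols=8,
        )
        assert layout.mask("middle").sum() == 16


class TestExtractRoiSeries:
    def test_zero_frames_give_zero_series(self):
        z = extract_roi_series(frames_of(np.zeros((5, 32, 32))))
        for roi in ("global", *SUB_ROIS):
            assert np.all(z[roi] == 0.0)

    def test_uniform_fill_forced_sums(self):
        # ventral=1, middle=2, dorsal=3, excluded=99 -> 256/512/768/1536
        arr = np.zeros((4, 32, 32))
        arr[:, 0:8, :] = 1.0
        arr[:, 8:16, :] = 2.0
        arr[:, 16:24, :] = 3.0
        arr[:, 24:32, :] = 99.0
        z = extract_roi_series(frames_of(arr))
        assert np.all(z["ventral"] == 256.0)
        assert np.all(z["middle"] == 512.0)
        assert np.all(z["dorsal"] == 768.0)
        assert np.all(z["global"] == 1536.0)

    def test_matches_pixel_loop_oracle(self):
        rng = np.random.default_rng(42)
        arr = rng.normal(size=(5, 32, 32))
        layout = ROILayout()
        z = extract_roi_series(frames_of(arr))
        for roi in SUB_ROIS:
            mask = layout.mask(roi)
            expected = np.array(
                [
                    sum(
                        arr[t, r, c]
                        for r in range(32)
                        for c in range(32)
                        if mask[r, c]
                    )
                    for t in range(5)
                ]
            )
            np.testing.assert_allclose(z[roi], expected, rtol=1e-12)

    def test_dimension_error(self):
        with pytest.raises(ValueError, match="16x16"):
            extract_roi_series(frames_of(np.zeros((3, 16, 16))))

    @settings(max_examples=25, deadline=None)
    @given(
        hnp.arrays(
            dtype=float,
            shape=st.tuples(st.integers(2, 6), st.just(32), st.just(32)),
            elements=st.floats(-1e6, 1e6, allow_nan=False),
        )
    )
    def test_additivity_property(self, arr):
        z = extract_roi_series(frames_of(arr))
        np.testing.assert_allclose(
            z["global"], z["ventral"] + z["middle"] + z["dorsal"], atol=1e-9
        )


def manual_seg(n_cycles, samples_per_cycle, fs, expected=None):
    cycles = [
        BreathCycle(i * samples_per_cycle, (i + 1) * samples_per_cycle, True)
        for i in range(n_cycles)
    ]
    return BreathSegmentation(
        cycles=cycles,
        expected_duration=expected or samples_per_cycle / fs,
        fs=fs,
    )


class TestComputeTidalAmplitude:
    def test_triangle_wave_amplitude(self):
        fs, period, amp = 10.0, 40, 5.0
        half = period // 2
        one = np.concatenate([np.linspace(0, amp, half, endpoint=False),
                              np.linspace(amp, 0, half, endpoint=False)])
        z = RegionalImpedanceSeries(
            data={"global": np.tile(one, 3), "ventral": np.tile(one, 3),
                  "middle": np.zeros(3 * period), "dorsal": np.zeros(3 * period)},
            fs=fs,
        )
        seg = manual_seg(3, period, fs)
        # descending ramp starts at the apex, so each cycle spans [0, amp]
        assert compute_tidal_amplitude(z, seg) == pytest.approx(amp)

    def test_flat_signal_errors(self):
        z = RegionalImpedanceSeries(
            data={roi: np.ones(40) for roi in ("global", *SUB_ROIS)}, fs=10.0
        )
        seg = manual_seg(1, 40, 10.0)
        with pytest.raises(ValueError, match="zero tidal amplitude"):
            compute_tidal_amplitude(z, seg)

    def test_no_complete_breath_errors(self):
        z = RegionalImpedanceSeries(
            data={roi: np.sin(np.arange(40)) for roi in ("global", *SUB_ROIS)},
            fs=10.0,
        )
        seg = BreathSegmentation(
            cycles=[BreathCycle(0, 40, False)], expected_duration=4.0, fs=10.0
        )
        with pytest.raises(ValueError, match="complete breath"):
            compute_tidal_amplitude(z, seg)

    def test_matches_simulator_tidal_impedance(self, clean_record, clean_analysis):
        _, _, truth = clean_record
        assert clean_analysis.z_t == pytest.approx(truth.z_t, abs=1e-9)


class TestCalibrateVolume:
    def z_series(self, values):
        values = np.asarray(values, dtype=float)
        return RegionalImpedanceSeries(
            data={
                "global": values,
                "ventral": values / 2,
                "middle": values / 4,
                "dorsal": values / 4,
            },
            fs=13.0,
        )

    def test_identity_scaling(self):
        z = self.z_series(np.full(10, 2.5))
        v = calibrate_volume(z, v_t=300.0, z_t=2.5)
        assert np.all(v["global"] == 300.0)

    def test_homogeneity_in_v_t(self):
        z = self.z_series(np.arange(1.0, 6.0))
        v1 = calibrate_volume(z, v_t=300.0, z_t=2.0)
        v2 = calibrate_volume(z, v_t=600.0, z_t=2.0)
        for roi in v1.data:
            np.testing.assert_allclose(v2[roi], 2.0 * v1[roi])

    def test_hand_arithmetic(self):
        # Z = {0, 1, 2}, v_t = 300, z_t = 2 -> V = {0, 150, 300}
        z = self.z_series([0.0, 1.0, 2.0])
        v = calibrate_volume(z, v_t=300.0, z_t=2.0)
        np.testing.assert_allclose(v["global"], [0.0, 150.0, 300.0])

    def test_additivity_preserved(self):
        z = self.z_series(np.linspace(0, 7, 12))
        v = calibrate_volume(z, v_t=250.0, z_t=1.7)
        np.testing.assert_allclose(
            v["global"], v["ventral"] + v["middle"] + v["dorsal"], atol=1e-9
        )

    @pytest.mark.parametrize("v_t,z_t", [(0.0, 1.0), (-5.0, 1.0), (300.0, 0.0), (300.0, -1.0)])
    def test_invalid_calibration(self, v_t, z_t):
        z = self.z_series([0.0, 1.0])
        with pytest.raises(ValueError):
            calibrate_volume(z, v_t=v_t, z_t=z_t)


class TestDifferentiate:
    def volume_of(self, values, fs=13.0):
        values = np.asarray(values, dtype=float)
        z = RegionalImpedanceSeries(
            data={"global": values, "ventral": values,
                  "middle": np.zeros_like(values), "dorsal": np.zeros_like(values)},
            fs=fs,
        )
        return calibrate_volume(z, v_t=1.0, z_t=1.0)

    def test_constant_volume_zero_flow(self):
        f = differentiate(self.volume_of(np.full(20, 7.0)))
        assert np.all(f["global"] == 0.0)

    def test_linear_ramp(self):
        fs = 13.0
        t = np.arange(30) / fs
        f = differentiate(self.volume_of(5.0 * t, fs=fs))
        np.testing.assert_allclose(f["global"], 5.0, rtol=1e-12)

    def test_exponential_closed_form(self):
        # V = V_T (1 - exp(-t/tau)) at 13 Hz vs the closed-form difference
        fs, tau, v_t = 13.0, 0.6, 300.0
        t = np.arange(40) / fs
        f = differentiate(self.volume_of(v_t * (1 - np.exp(-t / tau)), fs=fs))
        expected = v_t * (np.exp(-t[:-1] / tau) - np.exp(-t[1:] / tau)) * fs
        np.testing.assert_allclose(f["global"], expected, atol=1e-12 * v_t * fs)

    def test_flow_length_and_timebase(self):
        v = self.volume_of(np.arange(10.0))
        f = differentiate(v)
        assert f.n_samples == v.n_samples - 1
        np.testing.assert_allclose(f.times, v.times[1:])

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="2 volume samples"):
            differentiate(self.volume_of([1.0, 2.0]).__class__(
                data={"global": np.array([1.0]), "ventral": np.array([1.0]),
                      "middle": np.array([1.0]), "dorsal": np.array([1.0])},
                fs=13.0,
            ))

    @settings(max_examples=25, deadline=None)
    @given(
        hnp.arrays(dtype=float, shape=st.integers(2, 50),
                   elements=st.floats(-1e3, 1e3, allow_nan=False))
    )
    def test_telescoping_reconstruction(self, values):
        v = self.volume_of(values)
        f = differentiate(v)
        reconstructed = values[0] + np.cumsum(f["global"]) / v.fs
        np.testing.assert_allclose(reconstructed, values[1:], atol=1e-9)


class TestCalibrationClosure:
    def test_global_tidal_amplitude_equals_v_t(self, clean_record):
        frames, _, _ = clean_record
        z = extract_roi_series(frames)
        seg = segment_breaths(z["global"], z.fs, rr_hint=8.0)
        z_t = compute_tidal_amplitude(z, seg)
        v = calibrate_volume(z, v_t=300.0, z_t=z_t)
        amps = [np.ptp(v["global"][c.start:c.stop]) for c in seg.complete_cycles]
        assert np.mean(amps) == pytest.approx(300.0, rel=1e-6)
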