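import numpy as np
import pandas as pd
import pytest

from oisflow import (
    EvokedResponse,
    GroundTruthHemodynamics,
    epoch_and_average,
    locate_roi,
    lowpass,
    quantify_peak,
)
from oisflow.evoked import InsufficientDataError, stim_response_map
from oisflow.protocol import ConfigurationError
from oisflow.speckle import EmptyROIError

FS = 7.5


def _onsets(n_blocks=3, period=50.0, start=20.0, stim=10.0):
    on = start + np.arange(n_blocks) * period
    return pd.DataFrame({"block": np.arange(n_blocks), "onset_s": on,
                         "offset_s": on + stim})


class TestLowpass:
    def test_constant_signal_unchanged(self):
        x = np.full(500, 3.7)
        np.testing.assert_allclose(lowpass(x, 0.3, FS), x, rtol=1e-9)

    def test_stopband_sinusoid_attenuated_20db(self):
        t = np.arange(3000) / FS
        x = np.sin(2 * np.pi * 2.0 * t)
        y = lowpass(x, 0.3, FS)
        mid = slice(500, 2500)
        assert y[mid].std() / x[mid].std() < 0.1  # >= 20 dB down

    def test_passband_sinusoid_preserved_with_zero_phase(self):
        t = np.arange(6000) / FS
        x = np.sin(2 * np.pi * 0.05 * t)
        y = lowpass(x, 0.3, FS)
        mid = slice(1000, 5000)
        amp = y[mid].std() / x[mid].std()
        assert abs(amp - 1.0) < 0.05
        # zero phase: residual against the input stays tiny in the passband
        assert np.abs(y[mid] - x[mid]).max() < 0.05

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            lowpass(np.zeros(100), cutoff=4.0, fs=FS)


class TestEpochAndAverage:
    def test_identical_blocks_average_to_single_block(self):
        onsets = _onsets()
        truth = GroundTruthHemodynamics()
        t = np.arange(int(180 * FS)) / FS
        signal = 2.5 * truth.block_response(t, onsets)
        resp = epoch_and_average(t, signal, onsets)
        single = epoch_and_average(t, signal, onsets.iloc[:1], min_blocks=1)
        np.testing.assert_allclose(resp.trace, single.trace, atol=1e-6)
        assert resp.n_blocks == 3

    def test_prestimulus_mean_rebaselined_to_zero(self):
        rng = np.random.default_rng(0)
        onsets = _onsets()
        t = np.arange(int(180 * FS)) / FS
        resp = epoch_and_average(t, rng.standard_normal(t.size) + 5.0, onsets)
        base = (resp.epoch_times >= -4.0) & (resp.epoch_times <= -0.5)
        assert abs(resp.trace[base].mean()) < 1e-12

    def test_epoch_grid_covers_fig_window(self):
        onsets = _onsets()
        t = np.arange(int(180 * FS)) / FS
        resp = epoch_and_average(t, np.zeros(t.size), onsets, pre=4.0, post=2.0)
        assert resp.epoch_times[0] == pytest.approx(-4.0, abs=1 / FS)
        assert resp.epoch_times[-1] == pytest.approx(12.0, abs=1 / FS)

    def test_out_of_bounds_blocks_dropped_then_error(self):
        onsets = _onsets(n_blocks=3, start=150.0)  # blocks at 150, 200, 250 s
        t = np.arange(int(215 * FS)) / FS          # recording ends at 215 s
        resp = epoch_and_average(t, np.zeros(t.size), onsets)
        assert resp.n_blocks == 2
        with pytest.raises(InsufficientDataError):
            epoch_and_average(t[: int(160 * FS)], np.zeros(int(160 * FS)), onsets)

    def test_known_injected_peak_recovered(self):
        onsets = _onsets()
        truth = GroundTruthHemodynamics()
        t = np.arange(int(180 * FS)) / FS
        signal = 4.16 * truth.block_response(t, onsets)
        resp = epoch_and_average(t, signal, onsets, component="HbO")
        assert resp.peak() == pytest.approx(4.16, rel=1e-3)


class TestQuantifyPeak:
    def _resp(self, trace, component):
        n = trace.size
        times = np.linspace(-4, 12, n)
        return EvokedResponse(component=component, epoch_times=times, trace=trace,
                              n_blocks=3, stim_duration=10.0,
                              block_traces=np.tile(trace, (3, 1)), baseline_sd=0.0)

    def test_maximum_during_stimulation(self):
        t = np.linspace(-4, 12, 121)
        trace = np.where((t > 0) & (t < 10), np.sin(np.pi * t / 10), 0.0) * 3.3
        assert quantify_peak(self._resp(trace, "HbO")) == pytest.approx(3.3, rel=1e-3)

    def test_hbr_polarity_returns_negative_dip(self):
        t = np.linspace(-4, 12, 121)
        trace = np.where((t > 0) & (t < 10), -np.sin(np.pi * t / 10), 0.0) * 0.8
        assert quantify_peak(self._resp(trace, "HbR")) == pytest.approx(-0.8, rel=1e-3)

    def test_hbt_peak_equals_peak_of_summed_epochs(self):
        rng = np.random.default_rng(3)
        onsets = _onsets()
        t = np.arange(int(180 * FS)) / FS
        hbo = rng.standard_normal(t.size)
        hbr = rng.standard_normal(t.size)
        r_o = epoch_and_average(t, hbo, onsets, component="HbO")
        r_r = epoch_and_average(t, hbr, onsets, component="HbR")
        r_t = epoch_and_average(t, hbo + hbr, onsets, component="HbT")
        # epoching is linear, so the HbT trace is exactly the sum of traces
        np.testing.assert_allclose(r_t.trace, r_o.trace + r_r.trace, atol=1e-12)


class TestLocateROI:
    def test_centroid_recovers_activation_center(self):
        truth = GroundTruthHemodynamics(activation_center=(30.0, 70.0),
                                        activation_radius=10, edge_sigma=3)
        g = truth.spatial_profile((96, 96))
        rng = np.random.default_rng(0)
        roi = locate_roi(g + 0.02 * rng.standard_normal(g.shape), smooth_sigma=3)
        cy, cx = roi.centroid()
        assert abs(cy - 30.0) < 2 and abs(cx - 70.0) < 2

    def test_zero_response_raises(self):
        with pytest.raises(EmptyROIError):
            locate_roi(np.zeros((32, 32)))

    def test_vessel_pixels_excluded(self):
        truth = GroundTruthHemodynamics(activation_radius=10, edge_sigma=3)
        g = truth.spatial_profile((64, 64))
        baseline = np.full((64, 64), 1000.0)
        baseline[32, :] = 10.0  # dark vessel stripe through the patch
        roi = locate_roi(g, smooth_sigma=2, baseline_image=baseline,
                         vessel_percentile=5.0)
        assert not roi.mask[32, :].any()
        assert roi.mask.any()

    def test_manual_mask_passthrough_matches_auto_quantification(self,
                                                                 tiny_protocol,
                                                                 tiny_config,
                                                                 optics,
                                                                 tiny_truth):
        from oisflow import analyze_reflectance, simulate_reflectance
        from oisflow.evoked import ROIMask

        stack = simulate_reflectance(tiny_truth, optics, tiny_protocol,
                                     tiny_config, seed=4)
        auto = analyze_reflectance(stack, optics)
        h, w = tiny_config.image_shape
        yy, xx = np.ogrid[:h, :w]
        disk = np.hypot(yy - (h - 1) / 2, xx - (w - 1) / 2) <= 8
        manual = analyze_reflectance(stack, optics,
                                     roi=ROIMask(disk, provenance="manual"))
        assert manual["peaks"]["HbO"] == pytest.approx(auto["peaks"]["HbO"],
                                                       rel=0.05)


def test_stim_response_map_highlights_patch():
    onsets = _onsets(n_blocks=2)
    truth = GroundTruthHemodynamics(activation_radius=6, edge_sigma=2)
    t = np.arange(int(130 * FS)) / FS
    g = truth.spatial_profile((32, 32))
    maps = truth.block_response(t, onsets)[:, None, None] * g
    rmap = stim_response_map(maps, t, onsets)
    assert rmap[15, 15] > 0.5
    assert abs(rmap[0, 0]) < 1e-6
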