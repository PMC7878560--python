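import numpy as np
import pandas as pd
import pytest

from oisflow import (
    AcquisitionConfig,
    MultichannelStack,
    OpticalModel,
    StimulusProtocol,
    simulate_reflectance,
    to_absorbance,
    unmix,
)
from oisflow.optics import DegenerateModelError
from oisflow.protocol import ConfigurationError
from oisflow.spectroscopy import AbsorbanceStack
from oisflow.synthetic import NOISELESS


def _manual_stack(values_by_channel, config=None, n=40, first_onset=30.0):
    """Stack whose frames are constant per channel (scaled after frame 20)."""
    config = config or AcquisitionConfig(image_shape=(4, 4))
    onsets = pd.DataFrame({"block": [0], "onset_s": [first_onset],
                           "offset_s": [first_onset + 10.0]})
    frames, stamps = {}, {}
    for wl, (r0, r_late) in values_by_channel.items():
        arr = np.full((n, 4, 4), r0, dtype=np.float64)
        arr[20:] = r_late
        frames[wl] = arr
        stamps[wl] = config.timestamps(wl, n)
    return MultichannelStack(frames, stamps, onsets, config, StimulusProtocol())


class TestToAbsorbance:
    def test_constant_reflectance_gives_zero(self):
        stack = _manual_stack({525: (1000.0, 1000.0)})
        ab = to_absorbance(stack, baseline_window=(0.0, 2.0))
        np.testing.assert_allclose(ab.dA[525], 0.0, atol=1e-12)

    def test_e_fold_darkening_gives_unit_absorbance(self):
        stack = _manual_stack({590: (1000.0, 1000.0 * np.exp(-1.0))})
        ab = to_absorbance(stack, baseline_window=(0.0, 2.0))
        np.testing.assert_allclose(ab.dA[590][20:], 1.0, rtol=1e-12)
        # the printed-convention switch flips the sign
        ab_log = to_absorbance(stack, baseline_window=(0.0, 2.0), sign="log")
        np.testing.assert_allclose(ab_log.dA[590][20:], -1.0, rtol=1e-12)

    def test_nonpositive_baseline_masks_pixel(self):
        stack = _manual_stack({525: (1000.0, 1000.0)})
        stack.frames[525][:, 1, 2] = 0.0
        ab = to_absorbance(stack, baseline_window=(0.0, 2.0))
        assert not ab.mask[1, 2] and ab.mask[0, 0]
        assert np.all(np.isnan(ab.dA[525][:, 1, 2]))

    def test_baseline_overlapping_stimulation_rejected(self):
        stack = _manual_stack({525: (1000.0, 1000.0)}, first_onset=1.0)
        with pytest.raises(ConfigurationError):
            to_absorbance(stack, baseline_window=(0.0, 2.0))

    def test_forward_model_exponent_recovered_pointwise(self, tiny_protocol,
                                                        aligned_tiny_config,
                                                        optics, tiny_truth):
        stack = simulate_reflectance(tiny_truth, optics, tiny_protocol,
                                     aligned_tiny_config, seed=0,
                                     noise=NOISELESS, dtype=np.float64)
        ab = to_absorbance(stack)
        g = tiny_truth.spatial_profile(aligned_tiny_config.image_shape)
        for i, wl in enumerate(aligned_tiny_config.led_wavelengths):
            eps = optics.epsilon[optics.wavelengths.index(wl)]
            d = optics.pathlength[optics.wavelengths.index(wl)]
            r_t = tiny_truth.block_response(stack.timestamps[wl], stack.onsets)
            expected = (
                (eps[0] * tiny_truth.peak_dhbo + eps[1] * tiny_truth.peak_dhbr)
                * d * r_t[:, None, None] * g
            )
            np.testing.assert_allclose(ab.dA[wl], expected, atol=1e-10)


class TestUnmix:
    def _absorbance_from(self, optics, dc, n=8, shape=(3, 3)):
        """Construct dA = (eps*D) @ dC exactly for a known dC field."""
        design = optics.design_matrix()
        rng = np.random.default_rng(0)
        dhbo = np.full((n,) + shape, dc[0]) * rng.uniform(0.5, 1.5, (n, 1, 1))
        dhbr = np.full((n,) + shape, dc[1]) * rng.uniform(0.5, 1.5, (n, 1, 1))
        dA = {
            wl: design[i, 0] * dhbo + design[i, 1] * dhbr
            for i, wl in enumerate(optics.wavelengths)
        }
        stamps = {wl: np.arange(n) / 7.5 for wl in optics.wavelengths}
        ab = AbsorbanceStack(dA, stamps, (0.0, 1.0), np.ones(shape, dtype=bool))
        return ab, dhbo, dhbr

    def test_exact_system_recovered(self, optics):
        ab, dhbo, dhbr = self._absorbance_from(optics, (2.5, -0.8))
        maps = unmix(ab, optics)
        np.testing.assert_allclose(maps.dhbo, dhbo, rtol=1e-8)
        np.testing.assert_allclose(maps.dhbr, dhbr, rtol=1e-8)

    def test_zero_absorbance_gives_zero_concentrations(self, optics):
        ab, *_ = self._absorbance_from(optics, (0.0, 0.0))
        maps = unmix(ab, optics)
        np.testing.assert_array_equal(maps.dhbo, 0.0)
        np.testing.assert_array_equal(maps.dhbr, 0.0)

    def test_pseudo_inverse_matches_normal_equations_oracle(self):
        """OLS solved two ways on random small systems: pinv vs (A'A)^-1 A'."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            eps = rng.uniform(0.5, 40.0, (3, 2))
            if np.linalg.matrix_rank(eps) < 2:
                continue
            path = rng.uniform(0.001, 0.1, 3)
            model = OpticalModel(wavelengths=(1, 2, 3), epsilon=eps, pathlength=path)
            a = model.design_matrix()
            y = rng.standard_normal((3, 6))
            via_pinv = np.linalg.pinv(a) @ y
            via_normal = np.linalg.solve(a.T @ a, a.T @ y)
            np.testing.assert_allclose(via_pinv, via_normal, atol=1e-10)

    def test_linearity(self, optics):
        ab_x, *_ = self._absorbance_from(optics, (1.0, -0.3))
        ab_y, *_ = self._absorbance_from(optics, (-0.4, 0.9))
        a, b = 1.7, -0.6
        combo = AbsorbanceStack(
            {wl: a * ab_x.dA[wl] + b * ab_y.dA[wl] for wl in optics.wavelengths},
            ab_x.timestamps, ab_x.baseline_window, ab_x.mask,
        )
        mc = unmix(combo, optics)
        mx, my = unmix(ab_x, optics), unmix(ab_y, optics)
        np.testing.assert_allclose(mc.dhbo, a * mx.dhbo + b * my.dhbo, atol=1e-10)
        np.testing.assert_allclose(mc.dhbr, a * mx.dhbr + b * my.dhbr, atol=1e-10)

    def test_single_channel_perturbation_propagates_by_pinv_column(self, optics):
        ab, *_ = self._absorbance_from(optics, (1.0, -0.5))
        delta = 0.01
        wl0 = optics.wavelengths[0]
        perturbed = AbsorbanceStack(
            {wl: ab.dA[wl] + (delta if wl == wl0 else 0.0)
             for wl in optics.wavelengths},
            ab.timestamps, ab.baseline_window, ab.mask,
        )
        pinv = np.linalg.pinv(optics.design_matrix())
        m0, m1 = unmix(ab, optics), unmix(perturbed, optics)
        np.testing.assert_allclose(m1.dhbo - m0.dhbo, pinv[0, 0] * delta, atol=1e-10)
        np.testing.assert_allclose(m1.dhbr - m0.dhbr, pinv[1, 0] * delta, atol=1e-10)

    def test_rank_deficient_model_rejected(self):
        eps = np.array([[10.0, 10.0], [5.0, 5.0], [1.0, 1.0]])  # HbO == HbR column
        with pytest.raises(DegenerateModelError):
            OpticalModel(wavelengths=(525, 590, 625), epsilon=eps,
                         pathlength=np.ones(3))


def test_noiseless_round_trip_identity(tiny_protocol, aligned_tiny_config, optics,
                                       tiny_truth):
    """Generator -> absorbance -> unmix returns the injected chromophore
    fields to 1e-8 relative accuracy when noise is off."""
    stack = simulate_reflectance(tiny_truth, optics, tiny_protocol,
                                 aligned_tiny_config, seed=5, noise=NOISELESS,
                                 dtype=np.float64)
    maps = unmix(to_absorbance(stack), optics)
    g = tiny_truth.spatial_profile(aligned_tiny_config.image_shape)
    r_t = tiny_truth.block_response(maps.timestamps, stack.onsets)
    scale = abs(tiny_truth.peak_dhbo)
    np.testing.assert_allclose(maps.dhbo, tiny_truth.peak_dhbo * r_t[:, None, None] * g,
                               atol=1e-8 * scale)
    np.testing.assert_allclose(maps.dhbr, tiny_truth.peak_dhbr * r_t[:, None, None] * g,
                               atol=1e-8 * scale)
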