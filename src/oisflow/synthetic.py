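"""Forward acquisition simulator.

Generates raw multispectral reflectance and laser-speckle frame stacks
from a known ground-truth hemodynamic response, so the whole analysis
chain (absorbance conversion, spectral unmixing, speckle flowmetry,
epoching, peak quantification) can be validated by parameter recovery.

The hemodynamic response to a sustained stimulus is modelled as a
gamma-variate rise that saturates toward a plateau during stimulation and
decays exponentially after stimulus offset; its peak is normalized to the
requested amplitude.  Activation is confined to a "barrel cortex" patch:
a flat-top disk with a Gaussian shoulder, so the patch interior carries
the nominal peak amplitude (group-mean peak values reported from
ROI-averaged traces are plateau-level quantities, and a region drawn
around the maximum response samples mostly plateau).

Reflectance channels follow the forward modified Beer-Lambert model; the
laser channel draws per-pixel integrated-speckle intensities whose local
spatial contrast K encodes the flow field through K = K0 * sqrt(F0/F),
the exact inverse of the default contrast-to-flow map in
:mod:`oisflow.speckle`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammainc

from .optics import OpticalModel
from .protocol import AcquisitionConfig, StimulusProtocol, generate_protocol

__all__ = [
    "GroundTruthHemodynamics",
    "NoiseModel",
    "MultichannelStack",
    "simulate_reflectance",
    "simulate_speckle",
    "simulate_acquisition",
]

# Control-offspring group means used as neutral defaults; see the class
# methods for the two study groups.
_CONTROL_HBO = 2.50    # concentration units of the extinction table ("mM")
_CONTROL_HBR = -0.80
_CONTROL_CBF = 6.93    # % change from baseline
_PREECLAMPTIC_HBO = 4.16
_PREECLAMPTIC_HBR = -0.80
_PREECLAMPTIC_CBF = 11.22


class InvalidTruthError(ValueError):
    """Ground-truth parameters outside their physical domain."""


@dataclass(frozen=True)
class GroundTruthHemodynamics:
    """Injected evoked response: amplitudes, time course and spatial extent.

    Parameters
    ----------
    peak_dhbo, peak_dhbr : float
        Peak concentration changes of oxy-/deoxyhemoglobin (HbR typically
        negative: venous washout), in the unit system of the extinction
        table used by the forward model.
    peak_dcbf : float
        Peak cerebral-blood-flow change, % of baseline.
    rise_shape, rise_time : float
        Shape and scale (s) of the gamma-variate rise toward the plateau.
    decay_time : float
        Exponential decay constant (s) after stimulus offset.
    activation_center : (row, col) or None
        Patch center in pixels; image center if None.
    activation_radius : float
        Radius of the flat-top activation core, pixels.
    edge_sigma : float
        Gaussian shoulder width of the patch edge, pixels.
    """

    peak_dhbo: float = _CONTROL_HBO
    peak_dhbr: float = _CONTROL_HBR
    peak_dcbf: float = _CONTROL_CBF
    rise_shape: float = 2.0
    rise_time: float = 1.5
    decay_time: float = 2.0
    activation_center: tuple[float, float] | None = None
    activation_radius: float = 16.0
    edge_sigma: float = 4.0

    def __post_init__(self) -> None:
        if self.rise_shape <= 0 or self.rise_time <= 0 or self.decay_time <= 0:
            raise InvalidTruthError("HRF time constants must be > 0")
        if self.activation_radius <= 0 or self.edge_sigma <= 0:
            raise InvalidTruthError("activation geometry must be > 0")

    @property
    def peak_dhbt(self) -> float:
        """Total-hemoglobin peak; HbT = HbO + HbR by conservation."""
        return self.peak_dhbo + self.peak_dhbr

    @classmethod
    def control_offspring(cls, **kw) -> "GroundTruthHemodynamics":
        """Group-mean evoked response of offspring of normotensive mothers."""
        defaults = dict(peak_dhbo=_CONTROL_HBO, peak_dhbr=_CONTROL_HBR,
                        peak_dcbf=_CONTROL_CBF)
        return cls(**{**defaults, **kw})

    @classmethod
    def preeclamptic_offspring(cls, **kw) -> "GroundTruthHemodynamics":
        """Group-mean evoked response of offspring of preeclamptic mothers."""
        defaults = dict(peak_dhbo=_PREECLAMPTIC_HBO, peak_dhbr=_PREECLAMPTIC_HBR,
                        peak_dcbf=_PREECLAMPTIC_CBF)
        return cls(**{**defaults, **kw})

    # -- building blocks ------------------------------------------------

    def temporal_profile(self, t: np.ndarray, stim_duration: float) -> np.ndarray:
        """Unit-peak response to one block, t in seconds from block onset.

        Regularized-incomplete-gamma rise during stimulation (saturating
        plateau), exponential decay after offset, zero before onset.
        Normalized so the supremum over the stimulation window is exactly 1.
        """
        t = np.asarray(t, dtype=float)
        rise = gammainc(self.rise_shape, np.maximum(t, 0.0) / self.rise_time)
        end_level = gammainc(self.rise_shape, stim_duration / self.rise_time)
        out = np.where(
            t <= stim_duration,
            rise,
            end_level * np.exp(-(t - stim_duration) / self.decay_time),
        )
        out[t < 0] = 0.0
        return out / end_level

    def block_response(self, times: np.ndarray, onsets: pd.DataFrame) -> np.ndarray:
        """Superposed unit-peak response at absolute times for all blocks."""
        r = np.zeros_like(np.asarray(times, dtype=float))
        for onset, offset in zip(onsets["onset_s"], onsets["offset_s"]):
            r += self.temporal_profile(times - onset, offset - onset)
        return r

    def spatial_profile(self, shape: tuple[int, int]) -> np.ndarray:
        """Flat-top activation patch with Gaussian shoulder, values in [0, 1]."""
        h, w = shape
        cy, cx = self.activation_center or ((h - 1) / 2.0, (w - 1) / 2.0)
        yy, xx = np.ogrid[:h, :w]
        r = np.hypot(yy - cy, xx - cx)
        excess = np.maximum(r - self.activation_radius, 0.0)
        return np.exp(-(excess ** 2) / (2.0 * self.edge_sigma ** 2))


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: shot-like multiplicative + additive read noise.

    ``multiplicative_sigma`` is the relative SD of a per-pixel Gaussian
    gain fluctuation; ``additive_sigma`` is in counts.  Defaults give a
    per-frame SNR at which 7-block averaging yields clean evoked traces.
    """

    multiplicative_sigma: float = 0.02
    additive_sigma: float = 5.0

    def apply(self, frames: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        dt = np.float32 if frames.dtype == np.float32 else np.float64
        if self.multiplicative_sigma > 0:
            frames = frames * (
                1.0
                + self.multiplicative_sigma
                * rng.standard_normal(frames.shape, dtype=dt)
            )
        if self.additive_sigma > 0:
            frames = frames + self.additive_sigma * rng.standard_normal(
                frames.shape, dtype=dt
            )
        if self.multiplicative_sigma > 0 or self.additive_sigma > 0:
            frames = np.maximum(frames, 0.0, out=frames)
        return frames


NOISELESS = NoiseModel(multiplicative_sigma=0.0, additive_sigma=0.0)


@dataclass
class MultichannelStack:
    """Time-ordered frames per acquisition channel.

    ``frames`` maps wavelength (nm) to a (time, height, width) float32
    array of non-negative intensities; ``timestamps`` gives each
    channel's frame times in seconds from acquisition start (channels are
    interleaved, so timestamps differ by sub-frame phase offsets).
    ``onsets`` is the realized block table in acquisition time.
    """

    frames: dict[int, np.ndarray]
    timestamps: dict[int, np.ndarray]
    onsets: pd.DataFrame
    config: AcquisitionConfig
    protocol: StimulusProtocol

    def __post_init__(self) -> None:
        for wl, arr in self.frames.items():
            if arr.ndim != 3:
                raise ValueError(f"channel {wl}: frames must be 3-D (t, y, x)")
            if arr.shape[0] != len(self.timestamps[wl]):
                raise ValueError(f"channel {wl}: timestamps/frames mismatch")

    @property
    def channels(self) -> tuple[int, ...]:
        return tuple(self.frames)

    def channel(self, wavelength: int) -> np.ndarray:
        return self.frames[wavelength]


def _realized_onsets(
    protocol: StimulusProtocol,
    config: AcquisitionConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Jittered block table shifted into acquisition time."""
    tab = generate_protocol(protocol, rng)
    tab = tab.copy()
    tab["onset_s"] += config.baseline_duration
    tab["offset_s"] += config.baseline_duration
    return tab


def simulate_reflectance(
    truth: GroundTruthHemodynamics,
    optics: OpticalModel,
    protocol: StimulusProtocol | None = None,
    config: AcquisitionConfig | None = None,
    *,
    seed: int | np.random.Generator | None = 0,
    noise: NoiseModel | None = None,
    baseline_reflectance: float = 1000.0,
    onsets: pd.DataFrame | None = None,
    dtype: type = np.float32,
) -> MultichannelStack:
    """Generate the three LED reflectance stacks by forward Beer-Lambert.

    Per wavelength, ``R = R0 * exp(-(eps_HbO*dHbO + eps_HbR*dHbR) * D)``
    with the chromophore fields separable into the block-design temporal
    response times the spatial activation patch; then camera noise.

    Raises :class:`oisflow.optics.MissingCoefficientError` if a
    configured LED wavelength is absent from the optics table.
    """
    protocol = protocol or StimulusProtocol()
    config = config or AcquisitionConfig()
    noise = NoiseModel() if noise is None else noise
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if onsets is None:
        onsets = _realized_onsets(protocol, config, rng)

    n = config.n_frames(protocol)
    dtype = np.dtype(dtype).type
    g = truth.spatial_profile(config.image_shape).astype(dtype)
    frames: dict[int, np.ndarray] = {}
    timestamps: dict[int, np.ndarray] = {}
    for wl in config.led_wavelengths:
        eps_hbo, eps_hbr = optics.coefficients(wl)
        d = optics.pathlength[optics.wavelengths.index(wl)]
        t = config.timestamps(wl, n)
        r_t = truth.block_response(t, onsets).astype(dtype)
        # separable exponent: scalar * time profile (x) spatial patch
        coef = dtype((eps_hbo * truth.peak_dhbo + eps_hbr * truth.peak_dhbr) * d)
        exponent = coef * r_t[:, None, None] * g[None, :, :]
        ch = dtype(baseline_reflectance) * np.exp(-exponent)
        frames[wl] = noise.apply(ch, rng)
        timestamps[wl] = t
    return MultichannelStack(frames, timestamps, onsets, config, protocol)


def simulate_speckle(
    truth: GroundTruthHemodynamics,
    protocol: StimulusProtocol | None = None,
    config: AcquisitionConfig | None = None,
    *,
    seed: int | np.random.Generator | None = 0,
    mean_intensity: float = 1000.0,
    k_baseline: float = 0.3,
    baseline_flow: float = 1.0,
    onsets: pd.DataFrame | None = None,
) -> MultichannelStack:
    """Generate the laser channel as flow-modulated integrated speckle.

    The flow field is ``F = baseline_flow * (1 + dCBF/100)``; the local
    speckle contrast is enforced as ``K = k_baseline * sqrt(F0/F)``
    (capped at the fully developed ceiling K = 1, the static-scatterer
    limit), and each pixel intensity is drawn from a Gamma distribution
    with shape ``1/K^2`` and mean ``mean_intensity`` — the classical
    statistics of speckle integrated over ``1/K^2`` independent
    correlation cells.  Fully developed speckle (K = 1) reduces to
    exponentially distributed intensities.
    """
    protocol = protocol or StimulusProtocol()
    config = config or AcquisitionConfig()
    if baseline_flow <= 0:
        raise InvalidTruthError("baseline_flow must be > 0")
    if not 0 < k_baseline <= 1:
        raise InvalidTruthError("k_baseline must lie in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if onsets is None:
        onsets = _realized_onsets(protocol, config, rng)

    wl = config.laser_wavelength
    n = config.n_frames(protocol)
    t = config.timestamps(wl, n)
    g = truth.spatial_profile(config.image_shape).astype(np.float32)
    r_t = truth.block_response(t, onsets).astype(np.float32)
    dcbf = truth.peak_dcbf * r_t[:, None, None] * g[None, :, :]  # %
    if np.any(dcbf <= -100.0):
        raise InvalidTruthError("dCBF <= -100% implies non-positive flow")
    rel_flow = 1.0 + dcbf / 100.0
    k = np.minimum(k_baseline / np.sqrt(rel_flow), 1.0).astype(np.float32)
    shape = 1.0 / (k * k)
    frames = rng.standard_gamma(shape, dtype=np.float32)
    frames *= np.float32(mean_intensity) / shape
    return MultichannelStack({wl: frames}, {wl: t}, onsets, config, protocol)


def simulate_acquisition(
    truth: GroundTruthHemodynamics,
    optics: OpticalModel,
    protocol: StimulusProtocol | None = None,
    config: AcquisitionConfig | None = None,
    *,
    seed: int | np.random.Generator | None = 0,
    noise: NoiseModel | None = None,
    mean_intensity: float = 1000.0,
    k_baseline: float = 0.3,
) -> MultichannelStack:
    """Full interleaved acquisition: LED channels + laser channel sharing
    one realized stimulation schedule."""
    protocol = protocol or StimulusProtocol()
    config = config or AcquisitionConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    onsets = _realized_onsets(protocol, config, rng)
    led = simulate_reflectance(
        truth, optics, protocol, config, seed=rng, noise=noise, onsets=onsets
    )
    laser = simulate_speckle(
        truth, protocol, config, seed=rng,
        mean_intensity=mean_intensity, k_baseline=k_baseline, onsets=onsets,
    )
    frames = {**led.frames, **laser.frames}
    timestamps = {**led.timestamps, **laser.timestamps}
    return MultichannelStack(frames, timestamps, onsets, config, protocol)
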