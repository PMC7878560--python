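"""Stimulation protocol and camera acquisition geometry.

The experiment is a block design: repeated whisker-stimulation blocks
(stimulus on for ``stim_duration`` seconds, then rest) with a uniform
random jitter added to each nominal onset so the animal cannot anticipate
stimulus timing.  Four illumination channels (three LEDs and one laser)
share a single camera in round-robin, so each channel is sampled at
``total_frame_rate / n_channels``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProtocolError",
    "ConfigurationError",
    "StimulusProtocol",
    "AcquisitionConfig",
    "generate_protocol",
]


class ProtocolError(ValueError):
    """Invalid stimulation protocol (non-positive durations, no blocks...)."""


class ConfigurationError(ValueError):
    """Inconsistent acquisition configuration."""


@dataclass(frozen=True)
class StimulusProtocol:
    """Block-design whisker stimulation schedule.

    Parameters
    ----------
    n_blocks : int
        Number of stimulation blocks (default 7).
    stim_duration : float
        Stimulus-on duration per block, seconds (default 10).
    rest_duration : float
        Rest between blocks, seconds (default 40).
    jitter_max : float
        Upper bound of the uniform onset jitter, seconds (default 3).
        Each realized onset is ``nominal + U(0, jitter_max)``.
    stim_frequency : float
        Whisker deflection rate in Hz.  Metadata only; it never enters
        the analysis.
    """

    n_blocks: int = 7
    stim_duration: float = 10.0
    rest_duration: float = 40.0
    jitter_max: float = 3.0
    stim_frequency: float = 8.0

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ProtocolError(f"n_blocks must be >= 1, got {self.n_blocks}")
        if self.stim_duration <= 0 or self.rest_duration <= 0:
            raise ProtocolError("stim_duration and rest_duration must be > 0")
        if self.jitter_max < 0:
            raise ProtocolError("jitter_max must be >= 0")

    @property
    def block_period(self) -> float:
        return self.stim_duration + self.rest_duration

    @property
    def nominal_duration(self) -> float:
        """Duration of the nominal (unjittered) schedule, seconds."""
        return self.n_blocks * self.block_period


@dataclass(frozen=True)
class AcquisitionConfig:
    """Camera/illumination timing and geometry.

    Channels are strobed round-robin, so consecutive frames of the same
    channel are ``1/per_channel_rate`` apart and channel *i* is phase
    shifted by ``i/total_frame_rate``.
    """

    total_frame_rate: float = 30.0
    per_channel_rate: float = 7.5
    exposure_time: float = 0.014
    led_wavelengths: tuple[int, ...] = (525, 590, 625)
    laser_wavelength: int = 780
    image_shape: tuple[int, int] = (128, 128)
    baseline_duration: float = 20.0  # pre-protocol rest, seconds
    post_duration: float = 10.0      # tail after the last block, seconds
    #: round-robin strobing (False, the default) staggers channels by
    #: 1/total_frame_rate; True models simultaneous (beam-split) sampling
    simultaneous_channels: bool = False
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        n_ch = len(self.channels)
        if not np.isclose(self.per_channel_rate * n_ch, self.total_frame_rate):
            raise ConfigurationError(
                f"per_channel_rate ({self.per_channel_rate} Hz) x {n_ch} channels "
                f"!= total_frame_rate ({self.total_frame_rate} Hz)"
            )
        if self.exposure_time >= 1.0 / self.total_frame_rate:
            raise ConfigurationError(
                "exposure_time must be shorter than the inter-frame interval"
            )
        if len(self.image_shape) != 2 or min(self.image_shape) < 1:
            raise ConfigurationError(f"bad image_shape {self.image_shape}")
        if len(set(self.channels)) != len(self.channels):
            raise ConfigurationError("channel wavelengths must be unique")

    @property
    def channels(self) -> tuple[int, ...]:
        """All channel wavelengths in strobe order (LEDs then laser)."""
        return tuple(self.led_wavelengths) + (self.laser_wavelength,)

    def channel_offset(self, wavelength: int) -> float:
        """Phase offset of one channel within the round-robin cycle, seconds."""
        try:
            i = self.channels.index(wavelength)
        except ValueError:
            raise ConfigurationError(
                f"{wavelength} nm is not an acquisition channel {self.channels}"
            ) from None
        return 0.0 if self.simultaneous_channels else i / self.total_frame_rate

    def timestamps(self, wavelength: int, n_frames: int) -> np.ndarray:
        """Frame times for one channel, seconds from acquisition start."""
        return self.channel_offset(wavelength) + np.arange(n_frames) / self.per_channel_rate

    def n_frames(self, protocol: StimulusProtocol) -> int:
        """Frames per channel covering baseline + jittered protocol + tail."""
        duration = (
            self.baseline_duration
            + protocol.nominal_duration
            + protocol.jitter_max
            + self.post_duration
        )
        return int(np.ceil(duration * self.per_channel_rate))


def generate_protocol(
    protocol: StimulusProtocol,
    rng_seed: int | np.random.Generator | None = 0,
) -> pd.DataFrame:
    """Realize the jittered block schedule.

    Onset ``k`` is ``k * (stim + rest) + U_k`` with ``U_k ~ Uniform(0,
    jitter_max)`` drawn from the seeded generator; offsets follow after
    ``stim_duration``.  Times are relative to protocol start (the
    acquisition prepends ``AcquisitionConfig.baseline_duration``).

    Returns
    -------
    pandas.DataFrame
        Columns ``block``, ``onset_s``, ``offset_s``; one row per block,
        onsets strictly increasing.  Deterministic for a fixed seed.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    nominal = np.arange(protocol.n_blocks) * protocol.block_period
    jitter = rng.uniform(0.0, protocol.jitter_max, size=protocol.n_blocks) \
        if protocol.jitter_max > 0 else np.zeros(protocol.n_blocks)
    onsets = nominal + jitter
    return pd.DataFrame(
        {
            "block": np.arange(protocol.n_blocks, dtype=int),
            "onset_s": onsets,
            "offset_s": onsets + protocol.stim_duration,
        }
    )
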