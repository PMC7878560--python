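"""Evoked-response extraction: filtering, ROI location, epoching, peaks.

Time series are lowpass filtered at 0.3 Hz (zero-phase 4th-order
Butterworth) to suppress respiration noise, epoched around the realized
block onsets on a grid from 4 s before onset to 2 s after stimulus
offset, re-baselined per block to the pre-stimulus mean, and averaged
across blocks.  The peak is the signed extremum during the stimulation
window: maximum for HbO/HbT/CBF, minimum for the HbR washout dip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, label
from scipy.signal import butter, sosfiltfilt

from .protocol import ConfigurationError
from .speckle import EmptyROIError

__all__ = [
    "InsufficientDataError",
    "ROIMask",
    "EvokedResponse",
    "lowpass",
    "epoch_and_average",
    "locate_roi",
    "quantify_peak",
    "stim_response_map",
    "roi_trace",
]

logger = logging.getLogger(__name__)

#: Signed-extremum convention per hemodynamic component.
PEAK_POLARITY = {"HbO": "max", "HbT": "max", "CBF": "max", "HbR": "min"}


class InsufficientDataError(ValueError):
    """Too few valid blocks/samples to produce an estimate."""


@dataclass
class ROIMask:
    """Boolean response region; True = included pixel."""

    mask: np.ndarray
    provenance: str = "auto"  # auto | manual
    note: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise EmptyROIError("ROI mask is empty")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def centroid(self) -> tuple[float, float]:
        yy, xx = np.nonzero(self.mask)
        return float(yy.mean()), float(xx.mean())


@dataclass
class EvokedResponse:
    """Trial-averaged evoked trace on the epoch grid.

    ``epoch_times`` run from -pre to stim_duration + post seconds
    relative to onset; the trace is re-baselined so its mean over the
    pre-stimulus window is ~0.  ``block_traces`` keeps the individual
    re-baselined epochs (n_blocks, n_samples) for dispersion estimates.
    """

    component: str
    epoch_times: np.ndarray
    trace: np.ndarray
    n_blocks: int
    stim_duration: float
    block_traces: np.ndarray
    baseline_sd: float

    @property
    def block_sd(self) -> np.ndarray:
        """Across-block SD at each epoch sample."""
        return self.block_traces.std(axis=0, ddof=1)

    def peak(self, polarity: str | None = None) -> float:
        return quantify_peak(self, polarity)


def lowpass(
    x: np.ndarray,
    cutoff: float = 0.3,
    fs: float = 7.5,
    order: int = 4,
    axis: int = 0,
) -> np.ndarray:
    """Zero-phase Butterworth lowpass with unit DC gain.

    Applied forward-backward (``sosfiltfilt``), so the effective
    attenuation is the squared magnitude response and the phase is zero.
    """
    if not 0 < cutoff < fs / 2:
        raise ConfigurationError(
            f"cutoff must lie in (0, Nyquist={fs / 2} Hz), got {cutoff}"
        )
    sos = butter(order, cutoff, btype="low", fs=fs, output="sos")
    return sosfiltfilt(sos, np.asarray(x, dtype=np.float64), axis=axis)


def epoch_and_average(
    times: np.ndarray,
    signal: np.ndarray,
    onsets: pd.DataFrame,
    *,
    component: str = "",
    pre: float = 4.0,
    post: float = 2.0,
    baseline: tuple[float, float] = (-4.0, -0.5),
    min_blocks: int = 2,
) -> EvokedResponse:
    """Epoch a 1-D series around realized block onsets and average.

    Each epoch is aligned to the sample nearest its (jittered) onset,
    re-baselined to its own pre-stimulus mean over ``baseline`` (seconds
    relative to onset), then averaged across blocks on the common grid.
    Blocks that do not fit inside the recording are dropped with a
    warning; fewer than ``min_blocks`` survivors raise
    :class:`InsufficientDataError`.
    """
    times = np.asarray(times, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if times.ndim != 1 or signal.shape[0] != times.shape[0]:
        raise ValueError("times and signal must share the leading axis")
    fs = 1.0 / np.median(np.diff(times))
    stim_duration = float(np.median(onsets["offset_s"] - onsets["onset_s"]))

    n_pre = int(round(pre * fs))
    n_total = n_pre + int(round((stim_duration + post) * fs)) + 1
    epoch_times = (np.arange(n_total) - n_pre) / fs
    base_sel = (epoch_times >= baseline[0]) & (epoch_times <= baseline[1])
    if base_sel.sum() < 2:
        raise ConfigurationError(f"baseline window {baseline} holds <2 samples")

    epochs = []
    for _, row in onsets.iterrows():
        i0 = int(np.argmin(np.abs(times - row["onset_s"])))
        start, stop = i0 - n_pre, i0 - n_pre + n_total
        if start < 0 or stop > signal.shape[0]:
            logger.warning(
                "epoch_and_average: dropping block %s (epoch outside recording)",
                row.get("block", "?"),
            )
            continue
        ep = signal[start:stop].copy()
        ep -= ep[base_sel].mean()
        epochs.append(ep)
    if len(epochs) < min_blocks:
        raise InsufficientDataError(
            f"only {len(epochs)} usable blocks (need >= {min_blocks})"
        )
    block_traces = np.stack(epochs)
    trace = block_traces.mean(axis=0)
    return EvokedResponse(
        component=component,
        epoch_times=epoch_times,
        trace=trace,
        n_blocks=block_traces.shape[0],
        stim_duration=stim_duration,
        block_traces=block_traces,
        baseline_sd=float(trace[base_sel].std(ddof=1)),
    )


def stim_response_map(
    maps: np.ndarray,
    times: np.ndarray,
    onsets: pd.DataFrame,
    baseline: tuple[float, float] = (-4.0, -0.5),
) -> np.ndarray:
    """Mean stimulation-window image minus mean pre-stimulus image.

    The localizer image used to find the responding patch: for each
    block, frames within [onset, offset] count as stimulation and frames
    within ``baseline`` (relative to onset) as rest.
    """
    times = np.asarray(times, dtype=float)
    stim_sel = np.zeros(times.shape, dtype=bool)
    base_sel = np.zeros(times.shape, dtype=bool)
    for _, row in onsets.iterrows():
        stim_sel |= (times >= row["onset_s"]) & (times <= row["offset_s"])
        base_sel |= (times >= row["onset_s"] + baseline[0]) & (
            times <= row["onset_s"] + baseline[1]
        )
    if stim_sel.sum() == 0 or base_sel.sum() == 0:
        raise InsufficientDataError("no frames fall in stimulation/baseline windows")
    return np.nanmean(maps[stim_sel], axis=0) - np.nanmean(maps[base_sel], axis=0)


def locate_roi(
    response_map: np.ndarray,
    method: str = "auto",
    *,
    threshold: float = 0.6,
    smooth_sigma: float = 6.0,
    ref_percentile: float = 99.0,
    baseline_image: np.ndarray | None = None,
    vessel_percentile: float | None = None,
    manual_mask: np.ndarray | None = None,
) -> ROIMask:
    """Delineate the region of interest around the maximum response.

    Auto mode smooths the response map, thresholds at ``threshold`` times
    a robust maximum (the ``ref_percentile`` percentile of the smoothed
    map — a single-pixel max would ride on residual noise, particularly
    in speckle-derived flow maps), and keeps the connected component
    containing the peak — a reproducible stand-in for manual delineation
    around the maximum response.  Pixels darker than
    ``vessel_percentile`` of ``baseline_image`` are excluded (large
    vessels are dark under green illumination).  Manual mode accepts a
    user-drawn boolean mask.
    """
    if method == "manual":
        if manual_mask is None:
            raise ValueError("manual method requires manual_mask")
        return ROIMask(mask=manual_mask, provenance="manual")
    if method != "auto":
        raise ValueError(f"unknown ROI method {method!r}")

    rmap = np.asarray(response_map, dtype=float)
    rmap = np.where(np.isfinite(rmap), rmap, 0.0)
    smoothed = gaussian_filter(rmap, smooth_sigma) if smooth_sigma > 0 else rmap
    peak_val = float(np.percentile(smoothed, ref_percentile))
    if peak_val <= 0 or smoothed.max() <= 0:
        raise EmptyROIError("response map has no positive response to localize")
    binary = smoothed >= threshold * peak_val
    labels, _ = label(binary)
    peak_idx = np.unravel_index(np.argmax(smoothed), smoothed.shape)
    mask = labels == labels[peak_idx]

    note = ""
    if baseline_image is not None and vessel_percentile is not None:
        cut = np.percentile(baseline_image, vessel_percentile)
        n_before = int(mask.sum())
        mask &= baseline_image >= cut
        note = f"excluded {n_before - int(mask.sum())} vessel-like dark pixels"
    if not mask.any():
        raise EmptyROIError("ROI empty after thresholding/vessel exclusion")
    return ROIMask(mask=mask, provenance="auto", note=note)


def roi_trace(maps: np.ndarray, roi: ROIMask | np.ndarray) -> np.ndarray:
    """Average a (time, y, x) stack over the ROI pixels, NaN-aware."""
    mask = roi.mask if isinstance(roi, ROIMask) else np.asarray(roi, dtype=bool)
    if not mask.any():
        raise EmptyROIError("ROI mask is empty")
    return np.nanmean(maps[:, mask], axis=1)


def quantify_peak(resp: EvokedResponse, polarity: str | None = None) -> float:
    """Signed extremum of the averaged trace within the stimulation window."""
    if polarity is None:
        polarity = PEAK_POLARITY.get(resp.component, "max")
    if polarity not in ("max", "min"):
        raise ValueError("polarity must be 'max' or 'min'")
    sel = (resp.epoch_times >= 0) & (resp.epoch_times <= resp.stim_duration)
    window = resp.trace[sel]
    if window.size == 0 or np.all(np.isnan(window)):
        raise InsufficientDataError("no valid samples in the stimulation window")
    return float(np.nanmax(window) if polarity == "max" else np.nanmin(window))
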