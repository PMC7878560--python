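"""Laser speckle contrast flowmetry.

Spatial speckle contrast is K = sigma/mu over a small sliding window of
each laser frame.  Moving scatterers blur the speckle pattern within the
camera exposure, lowering K, so a decreasing function of K indexes flow;
the default map is flow_index = 1/K^2 (number of decorrelation events
integrated within the exposure), with an exposure-normalized variant
1/(2*T*K^2) that differs only by a constant factor and therefore yields
identical percent-change CBF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .protocol import ConfigurationError
from .synthetic import MultichannelStack

__all__ = ["ContrastMap", "FlowSeries", "spatial_contrast", "contrast_to_flow",
           "flow_index_maps"]


class EmptyROIError(ValueError):
    """ROI contains no valid pixels."""


@dataclass
class ContrastMap:
    """Spatial speckle contrast per frame.

    ``K`` is (time, height, width); NaN marks windows with zero mean.
    """

    K: np.ndarray
    timestamps: np.ndarray
    window_size: int
    exposure_time: float


@dataclass
class FlowSeries:
    """ROI-averaged flow index and relative CBF time series.

    ``dcbf_percent`` is 100 * (flow_index / baseline mean - 1): zero on
    average over the baseline window by construction.
    """

    timestamps: np.ndarray
    k_roi: np.ndarray
    flow_index: np.ndarray
    dcbf_percent: np.ndarray
    baseline_window: tuple[float, float]
    model: str


def spatial_contrast(
    stack_or_frames: MultichannelStack | np.ndarray,
    window_size: int = 5,
    timestamps: np.ndarray | None = None,
    exposure_time: float = 0.014,
) -> ContrastMap:
    """Local sigma/mu of each laser frame over a sliding square window.

    Borders are handled by reflection padding; the sample variance uses
    the n-1 correction.  Windows with zero mean are NaN-masked; exactly
    constant regions give K = 0.
    """
    if isinstance(stack_or_frames, MultichannelStack):
        stack = stack_or_frames
        wl = stack.config.laser_wavelength
        if wl not in stack.frames:
            raise ConfigurationError(f"stack has no laser channel ({wl} nm)")
        frames = stack.frames[wl]
        timestamps = stack.timestamps[wl]
        exposure_time = stack.config.exposure_time
    else:
        frames = np.asarray(stack_or_frames)
        if frames.ndim == 2:
            frames = frames[None]
        if timestamps is None:
            timestamps = np.arange(frames.shape[0], dtype=float)
    if window_size < 3 or window_size % 2 == 0:
        raise ConfigurationError("window_size must be odd and >= 3")
    if window_size >= min(frames.shape[1:]):
        raise ConfigurationError(
            f"window_size {window_size} must be smaller than the image "
            f"{frames.shape[1:]}"
        )
    if np.any(frames < 0):
        raise ValueError("speckle intensities must be non-negative")

    # keep float64 inputs exact for oracle comparisons; image stacks from
    # the camera/simulator stay float32 for speed
    dtype = np.float64 if frames.dtype == np.float64 else np.float32
    x = frames.astype(dtype, copy=False)
    size = (1, window_size, window_size)
    m = uniform_filter(x, size=size, mode="reflect")
    m2 = uniform_filter(x * x, size=size, mode="reflect")
    n = window_size * window_size
    var = (m2 - m * m) * dtype(n / (n - 1.0))
    # kill negative/rounding residue so constant regions give exactly 0
    eps_rel = dtype(1e-12) if dtype is np.float64 else dtype(1e-6)
    var[var <= m2 * eps_rel] = 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.sqrt(var) / m
    k[m <= 0] = np.nan
    return ContrastMap(
        K=k.astype(np.float32),
        timestamps=np.asarray(timestamps),
        window_size=window_size,
        exposure_time=exposure_time,
    )


def flow_index_maps(contrast: ContrastMap, model: str = "inverse_square") -> np.ndarray:
    """Pixelwise K -> flow transform.

    ``inverse_square``: 1/K^2.  ``exposure_normalized``: 1/(2*T*K^2) with
    T the exposure time; the constant factor cancels in percent change.
    """
    if model not in ("inverse_square", "exposure_normalized"):
        raise ValueError(f"unknown flow model {model!r}")
    k = contrast.K.astype(np.float64, copy=False)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = 1.0 / (k * k)
    f[~np.isfinite(f)] = np.nan
    if model == "exposure_normalized":
        f /= 2.0 * contrast.exposure_time
    return f


def contrast_to_flow(
    contrast: ContrastMap,
    baseline_window: tuple[float, float],
    roi: np.ndarray | None = None,
    model: str = "inverse_square",
) -> FlowSeries:
    """ROI-averaged flow index and %CBF change from baseline.

    The K -> flow transform is applied pixelwise first and the ROI
    average taken afterwards; dCBF(t) = 100 * (F(t)/<F>_baseline - 1).
    """
    f = flow_index_maps(contrast, model)
    k = contrast.K
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != f.shape[1:]:
            raise ValueError(f"ROI shape {roi.shape} != image shape {f.shape[1:]}")
        if not roi.any():
            raise EmptyROIError("ROI mask is empty")
        f = f[:, roi]
        k = k[:, roi]
    else:
        f = f.reshape(f.shape[0], -1)
        k = k.reshape(k.shape[0], -1)
    if np.all(np.isnan(f)):
        raise EmptyROIError("all ROI pixels are masked")
    flow = np.nanmean(f, axis=1)
    k_roi = np.nanmean(k, axis=1)

    t = contrast.timestamps
    lo, hi = baseline_window
    in_win = (t >= lo) & (t <= hi)
    if in_win.sum() < 2:
        raise ConfigurationError(
            f"baseline window {baseline_window} holds <2 laser frames"
        )
    f0 = flow[in_win].mean()
    dcbf = 100.0 * (flow / f0 - 1.0)
    return FlowSeries(
        timestamps=t,
        k_roi=k_roi,
        flow_index=flow,
        dcbf_percent=dcbf,
        baseline_window=baseline_window,
        model=model,
    )
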