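"""Reflectance -> absorbance -> chromophore concentration changes.

Reflectance at each LED wavelength is converted to an absorbance change
against a pre-stimulus baseline, dA = -log(R/R0) (sign convention: more
absorption, i.e. darkening, is positive; a ``sign`` switch restores the
bare log form).  The three-wavelength absorbance vector is then unmixed
per pixel and frame into dHbO/dHbR by the Moore-Penrose pseudo-inverse
of the extinction*pathlength design matrix — ordinary least squares for
the overdetermined 3x2 system.  dHbT = dHbO + dHbR by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .optics import DegenerateModelError, OpticalModel
from .protocol import ConfigurationError
from .synthetic import MultichannelStack

__all__ = ["AbsorbanceStack", "ChromophoreMaps", "to_absorbance", "unmix"]

logger = logging.getLogger(__name__)


@dataclass
class AbsorbanceStack:
    """Per-wavelength absorbance-change stacks on the LED time grids.

    ``mask`` flags pixels whose baseline reflectance was non-positive in
    any channel; they are excluded downstream rather than crashing the
    conversion.
    """

    dA: dict[int, np.ndarray]
    timestamps: dict[int, np.ndarray]
    baseline_window: tuple[float, float]
    mask: np.ndarray  # True = valid pixel

    @property
    def wavelengths(self) -> tuple[int, ...]:
        return tuple(self.dA)


@dataclass
class ChromophoreMaps:
    """Per-pixel concentration-change time series for HbO/HbR (+HbT)."""

    dhbo: np.ndarray
    dhbr: np.ndarray
    timestamps: np.ndarray
    mask: np.ndarray

    @property
    def dhbt(self) -> np.ndarray:
        """Total hemoglobin; the HbO + HbR identity holds by construction."""
        return self.dhbo + self.dhbr

    def component(self, name: str) -> np.ndarray:
        try:
            return {"HbO": self.dhbo, "HbR": self.dhbr, "HbT": self.dhbt}[name]
        except KeyError:
            raise KeyError(f"unknown component {name!r}; expected HbO/HbR/HbT") from None


def default_baseline_window(stack: MultichannelStack, guard: float = 0.5) -> tuple[float, float]:
    """Whole-run baseline: acquisition start to ``guard`` s before block 1."""
    first_onset = float(stack.onsets["onset_s"].min())
    return (0.0, first_onset - guard)


def to_absorbance(
    stack: MultichannelStack,
    baseline_window: tuple[float, float] | None = None,
    sign: str = "neg",
) -> AbsorbanceStack:
    """Convert LED reflectance stacks to absorbance changes.

    R0 is the per-pixel temporal mean over ``baseline_window`` (default:
    everything up to 0.5 s before the first stimulation onset).  With
    ``sign="neg"`` (default) dA = -log(R/R0); ``sign="log"`` keeps the
    bare log(R/R0).  The sign cancels in forward/inverse round trips.
    """
    if sign not in ("neg", "log"):
        raise ValueError("sign must be 'neg' or 'log'")
    if baseline_window is None:
        baseline_window = default_baseline_window(stack)
    lo, hi = baseline_window
    first_onset = float(stack.onsets["onset_s"].min())
    if hi > first_onset:
        raise ConfigurationError(
            f"baseline window {baseline_window} overlaps stimulation "
            f"(first onset at {first_onset:.2f} s)"
        )
    led = [wl for wl in stack.channels if wl != stack.config.laser_wavelength]
    if not led:
        raise ConfigurationError("stack contains no LED channels")

    dA: dict[int, np.ndarray] = {}
    timestamps: dict[int, np.ndarray] = {}
    mask = None
    for wl in led:
        t = stack.timestamps[wl]
        in_win = (t >= lo) & (t <= hi)
        if in_win.sum() < 2:
            raise ConfigurationError(
                f"baseline window {baseline_window} holds <2 frames of channel {wl}"
            )
        frames = stack.frames[wl]
        dt = np.float64 if frames.dtype == np.float64 else np.float32
        r0 = frames[in_win].mean(axis=0, dtype=np.float64).astype(dt)
        valid = r0 > 0
        mask = valid if mask is None else (mask & valid)
        safe_r0 = np.where(valid, r0, 1.0).astype(dt)
        ratio = np.maximum(frames.astype(dt, copy=False), dt(1e-30)) / safe_r0
        da = np.log(ratio)
        if sign == "neg":
            np.negative(da, out=da)
        da[:, ~valid] = np.nan
        dA[wl] = da
        timestamps[wl] = t
    n_bad = int((~mask).sum())
    if n_bad:
        logger.warning("to_absorbance: masked %d pixels with non-positive baseline", n_bad)
    return AbsorbanceStack(dA, timestamps, baseline_window, mask)


def unmix(absorbance: AbsorbanceStack, optics: OpticalModel) -> ChromophoreMaps:
    """Solve the modified Beer-Lambert system per pixel and frame.

    Uses the pseudo-inverse of the (eps * D) design matrix; with more
    wavelengths than chromophores this is the least-squares solution.
    Channels are aligned by sample index (nearest-sample alignment: the
    interleaving phase offsets are well below the analysis bandwidth).
    """
    wavelengths = absorbance.wavelengths
    if len(wavelengths) < 2:
        raise DegenerateModelError("need at least 2 wavelengths to unmix 2 chromophores")
    model = optics.subset(wavelengths)
    design = model.design_matrix()            # (n_wl, 2)
    pinv = np.linalg.pinv(design)             # (2, n_wl)

    n_t = min(absorbance.dA[wl].shape[0] for wl in wavelengths)
    shape = absorbance.dA[wavelengths[0]].shape[1:]
    dt = np.result_type(*(absorbance.dA[wl].dtype for wl in wavelengths), np.float32)
    dhbo = np.zeros((n_t,) + shape, dtype=dt)
    dhbr = np.zeros_like(dhbo)
    for j, wl in enumerate(wavelengths):
        da = absorbance.dA[wl][:n_t]
        dhbo += dt.type(pinv[0, j]) * da
        dhbr += dt.type(pinv[1, j]) * da
    # representative time axis: mean of the per-channel interleaved stamps
    times = np.mean([absorbance.timestamps[wl][:n_t] for wl in wavelengths], axis=0)
    return ChromophoreMaps(dhbo=dhbo, dhbr=dhbr, timestamps=times, mask=absorbance.mask)
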