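"""On-disk layout for acquisitions: per-channel multi-page TIFFs plus a
YAML sidecar config, a block-onset CSV, and an optional ground-truth YAML
for recovery tests.  Real acquisitions in the same layout are read
identically."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .protocol import AcquisitionConfig, StimulusProtocol
from .synthetic import GroundTruthHemodynamics, MultichannelStack

__all__ = ["write_stack", "read_stack", "write_truth", "read_truth"]

ONSETS_CSV = "onsets.csv"
CONFIG_YAML = "acquisition.yaml"
TRUTH_YAML = "ground_truth.yaml"


def _channel_path(outdir: Path, wavelength: int) -> Path:
    return outdir / f"channel_{wavelength}nm.tif"


def write_stack(stack: MultichannelStack, outdir: str | Path) -> Path:
    """Write one acquisition: TIFF per channel + onsets CSV + config YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for wl, frames in stack.frames.items():
        tifffile.imwrite(_channel_path(outdir, wl), frames)
    stack.onsets.to_csv(outdir / ONSETS_CSV, index=False)
    meta = {
        "acquisition": dataclasses.asdict(stack.config),
        "protocol": dataclasses.asdict(stack.protocol),
        "channels": list(stack.frames),
    }
    (outdir / CONFIG_YAML).write_text(yaml.safe_dump(meta, sort_keys=False))
    return outdir


def _tuplify(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def read_stack(indir: str | Path) -> MultichannelStack:
    """Read an acquisition written by :func:`write_stack`."""
    indir = Path(indir)
    meta = yaml.safe_load((indir / CONFIG_YAML).read_text())
    config = AcquisitionConfig(**_tuplify(meta["acquisition"]))
    protocol = StimulusProtocol(**meta["protocol"])
    onsets = pd.read_csv(indir / ONSETS_CSV)
    frames: dict[int, np.ndarray] = {}
    timestamps: dict[int, np.ndarray] = {}
    for wl in meta["channels"]:
        arr = tifffile.imread(_channel_path(indir, wl))
        frames[wl] = np.asarray(arr)
        timestamps[wl] = config.timestamps(wl, arr.shape[0])
    return MultichannelStack(frames, timestamps, onsets, config, protocol)


def write_truth(truth: GroundTruthHemodynamics, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(dataclasses.asdict(truth), sort_keys=False))
    return path


def read_truth(path: str | Path) -> GroundTruthHemodynamics:
    d = yaml.safe_load(Path(path).read_text())
    if d.get("activation_center") is not None:
        d["activation_center"] = tuple(d["activation_center"])
    return GroundTruthHemodynamics(**d)
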