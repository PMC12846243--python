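"""Plain-text and image IO: CSV traces, PNG frame directories, YAML manifests."""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import yaml

from .synth import RawTrace

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_frames_png",
    "read_frames_png",
    "read_mask_png",
    "write_manifest",
    "read_manifest",
]


def write_trace_csv(path: str | os.PathLike, trace: RawTrace | np.ndarray,
                    fs: float | None = None) -> None:
    """Two-column CSV: time_s, amplitude."""
    samples = np.asarray(trace.samples if hasattr(trace, "samples") else trace, dtype=float)
    fs = float(trace.fs) if hasattr(trace, "fs") else fs
    if fs is None:
        raise ValueError("fs required when writing a bare array")
    t = np.arange(samples.size) / fs
    np.savetxt(path, np.column_stack([t, samples]), delimiter=",",
               header="time_s,amplitude", comments="", fmt="%.9g")


def read_trace_csv(path: str | os.PathLike) -> RawTrace:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time_s, amplitude)")
    t, x = data[:, 0], data[:, 1]
    dt = np.diff(t)
    if len(dt) == 0 or np.any(dt <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    return RawTrace(samples=x, fs=1.0 / float(np.median(dt)))


def write_frames_png(directory: str | os.PathLike, frames: np.ndarray) -> None:
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(np.clip(frames, 0, 255).astype(np.uint8)):
        iio.imwrite(directory / f"frame_{i:06d}.png", frame)


def read_frames_png(directory: str | os.PathLike) -> np.ndarray:
    import imageio.v3 as iio

    paths = sorted(Path(directory).glob("frame_*.png"))
    if not paths:
        raise FileNotFoundError(f"no frame_*.png files in {directory}")
    return np.stack([iio.imread(p) for p in paths]).astype(float)


def read_mask_png(path: str | os.PathLike) -> np.ndarray:
    import imageio.v3 as iio

    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return img > 0


def write_manifest(path: str | os.PathLike, manifest: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_manifest(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
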