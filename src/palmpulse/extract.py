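"""Coarse rPPG extraction: ROI green-channel mean over a frame stack."""

from __future__ import annotations

import numpy as np

from .synth import RawTrace

__all__ = ["ROIMask", "RawTrace", "green_channel_mean", "threshold_mask"]

GREEN = 1  # channel index in (..., H, W, 3) RGB frames


class ROIMask:
    """Boolean pixel mask; at least one pixel must be selected."""

    def __init__(self, mask: np.ndarray):
        mask = np.asarray(mask)
        if mask.ndim != 2:
            raise ValueError("mask must be 2-D (height x width)")
        self.mask = mask.astype(bool)
        if not self.mask.any():
            raise ValueError("mask selects no pixels")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape  # type: ignore[return-value]


def green_channel_mean(frames: np.ndarray, mask: ROIMask, fs: float = 100.0) -> RawTrace:
    """Mean green-channel intensity over the (static) ROI, per frame.

    ``samples[t] = (1/N) * sum_i I_i(t)`` over the N masked pixels of frame t.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 4 or frames.shape[-1] < 2:
        raise ValueError("frames must have shape (n, height, width, channels>=2)")
    if frames.shape[1:3] != mask.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match frame shape {frames.shape[1:3]}"
        )
    green = frames[..., GREEN]
    trace = green[:, mask.mask].mean(axis=1)
    return RawTrace(samples=trace, fs=fs)


def threshold_mask(frame: np.ndarray, percentile: float) -> ROIMask:
    """ROI = pixels whose green intensity strictly exceeds the given quantile.

    Stands in for a learned palm-segmentation network; on bright-object /
    dark-background frames it recovers the object.
    """
    if not 0.0 < percentile < 1.0:
        raise ValueError(f"percentile must be in (0, 1), got {percentile}")
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("frame is empty")
    green = frame[..., GREEN] if frame.ndim == 3 else frame
    cut = np.quantile(green, percentile)
    return ROIMask(green > cut)
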