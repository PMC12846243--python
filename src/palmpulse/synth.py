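"""Synthetic paired-data generation.

Produces clean annotated pulse waves, corrupted coarse traces, palm-like
video frame stacks, and paired (rough, reference) training windows with a
9:1 record-level train/validation split, so the full reconstruction
pipeline can be exercised without access to real recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PulseModelParams",
    "NoiseParams",
    "VideoRenderParams",
    "AnnotatedPulse",
    "PairedWindow",
    "PairedDataset",
    "generate_clean_ppg",
    "corrupt_signal",
    "render_palm_video",
    "make_paired_dataset",
]


@dataclass(frozen=True)
class PulseModelParams:
    """Shape parameters of the per-beat pulse template.

    The main (systolic) peak amplitude is the unit of the amplitude scale;
    ``notch_depth`` and ``second_peak_amp`` are relative to it.
    """

    heart_rate_bpm: float = 72.0
    hrv_cv: float = 0.02
    systolic_amp: float = 1.0
    notch_depth: float = 0.12
    second_peak_amp: float = 0.45
    systolic_width_s: float = 0.12
    diastolic_width_s: float = 0.16
    notch_delay_s: float = 0.22

    def __post_init__(self) -> None:
        if not 40.0 <= self.heart_rate_bpm <= 180.0:
            raise ValueError(f"heart_rate_bpm must be in [40, 180], got {self.heart_rate_bpm}")
        if self.hrv_cv < 0:
            raise ValueError("hrv_cv must be >= 0")
        if not 0 <= self.second_peak_amp < self.systolic_amp:
            raise ValueError("require 0 <= second_peak_amp < systolic_amp")
        if min(self.systolic_width_s, self.diastolic_width_s, self.notch_delay_s) <= 0:
            raise ValueError("widths and delays must be > 0")


@dataclass(frozen=True)
class NoiseParams:
    """Corruption model: multiplicative AM, additive drift/flicker/white noise."""

    white_sigma: float = 0.0
    drift_amp: float = 0.0
    drift_freq_hz: float = 0.1
    drift_walk_sigma: float = 0.0
    flicker_amp: float = 0.0
    flicker_freq_hz: float = 5.0
    am_depth: float = 0.0
    am_freq_hz: float = 0.08

    def __post_init__(self) -> None:
        for name in ("white_sigma", "drift_amp", "drift_walk_sigma", "flicker_amp", "am_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.drift_freq_hz >= 0.5:
            raise ValueError("drift_freq_hz must be < 0.5 Hz")
        if self.flicker_amp > 0 and 0.7 <= self.flicker_freq_hz <= 3.0:
            raise ValueError("flicker_freq_hz must lie outside the cardiac band [0.7, 3.0] Hz")


@dataclass(frozen=True)
class VideoRenderParams:
    height: int = 32
    width: int = 32
    fps: float = 100.0
    base_green: float = 120.0
    modulation_depth: float = 0.02
    pixel_noise_sigma: float = 0.0
    jitter_px: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.modulation_depth <= 0.2:
            raise ValueError("modulation_depth must be in [0, 0.2]")
        if self.height <= 0 or self.width <= 0:
            raise ValueError("frame dimensions must be positive")


@dataclass
class CycleFiducials:
    """Per-cycle sample indices, recorded exactly as the beat was built."""

    valley: int
    systolic_peak: int
    dicrotic_notch: int | None = None
    second_peak: int | None = None


@dataclass
class AnnotatedPulse:
    samples: np.ndarray
    fs: float
    fiducials: list[CycleFiducials] = field(default_factory=list)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    def fiducial_indices(self, kind: str) -> np.ndarray:
        vals = [getattr(f, kind) for f in self.fiducials]
        return np.array([v for v in vals if v is not None], dtype=int)


def _beat_template(params: PulseModelParams, n: int, fs: float) -> tuple[np.ndarray, dict]:
    """One beat of ``n`` samples plus the construction landmarks.

    The beat is a systolic Gaussian lobe plus a delayed dicrotic lobe, with
    an explicit narrow notch carved between them so notch depth is directly
    controllable.
    """
    t = np.arange(n) / fs
    period = n / fs
    t_sys = 0.3 * period
    sys_lobe = params.systolic_amp * np.exp(-((t - t_sys) ** 2) / (2 * params.systolic_width_s**2))
    beat = sys_lobe
    landmarks: dict = {"systolic": int(round(t_sys * fs))}
    if params.second_peak_amp > 0 or params.notch_depth > 0:
        # cap the fixed-seconds timing so short beats keep the notch and
        # second peak inside the cycle
        delay = min(params.notch_delay_s, 0.30 * period)
        width = min(params.diastolic_width_s, 0.18 * period)
        t_notch = t_sys + delay
        t_dic = t_notch + width
        dic_lobe = params.second_peak_amp * np.exp(-((t - t_dic) ** 2) / (2 * width**2))
        notch_sigma = min(max(delay / 4.0, 0.02), 0.06 * period)
        carve = params.notch_depth * np.exp(-((t - t_notch) ** 2) / (2 * notch_sigma**2))
        beat = beat + dic_lobe - carve
        landmarks["notch_lo"] = int(round(t_notch * fs)) - 1
        landmarks["dic_center"] = min(int(round(t_dic * fs)), n - 1)
        landmarks["dic_hi"] = min(int(round((t_dic + params.diastolic_width_s) * fs)), n - 1)
    return beat, landmarks


def generate_clean_ppg(
    params: PulseModelParams, duration_s: float, fs: float, seed: int
) -> AnnotatedPulse:
    """Generate a quasi-periodic annotated pulse wave.

    Beat-to-beat intervals are i.i.d. lognormal with mean ``60/heart_rate_bpm``
    seconds and coefficient of variation ``hrv_cv``.  Fiducials are recorded
    from the construction of each beat, not re-detected from the waveform.
    """
    mean_interval = 60.0 / params.heart_rate_bpm
    if duration_s < 2 * mean_interval:
        raise ValueError(
            f"duration_s={duration_s} too short: need at least two cycles "
            f"({2 * mean_interval:.2f} s at {params.heart_rate_bpm} bpm)"
        )
    if fs < 25:
        raise ValueError("fs must be >= 25 Hz")

    rng = np.random.default_rng(seed)
    n_total = int(round(duration_s * fs))
    samples = np.zeros(n_total)
    fiducials: list[CycleFiducials] = []

    # lognormal with the requested mean and CV
    if params.hrv_cv > 0:
        sigma2 = np.log(1.0 + params.hrv_cv**2)
        mu = np.log(mean_interval) - sigma2 / 2.0
    start = 0
    while start < n_total:
        if params.hrv_cv > 0:
            interval = float(rng.lognormal(mu, np.sqrt(sigma2)))
            interval = float(np.clip(interval, 0.4 * mean_interval, 2.5 * mean_interval))
        else:
            interval = mean_interval
        n_beat = max(int(round(interval * fs)), 8)
        beat, marks = _beat_template(params, n_beat, fs)
        stop = min(start + n_beat, n_total)
        samples[start:stop] += beat[: stop - start]

        sys_rel = marks["systolic"]
        if start + sys_rel >= n_total:
            break
        fid = CycleFiducials(valley=start, systolic_peak=start + sys_rel)
        if "notch_lo" in marks:
            seg = beat
            lo = max(marks["notch_lo"] - 2, sys_rel + 1)
            mid, hi = marks["dic_center"], marks["dic_hi"]
            if mid > lo + 1 and hi > mid:
                notch_rel = lo + int(np.argmin(seg[lo : mid + 1]))
                post = seg[notch_rel : hi + 1]
                second_rel = notch_rel + int(np.argmax(post)) if len(post) > 1 else None
                if start + notch_rel < n_total:
                    fid.dicrotic_notch = start + notch_rel
                if (
                    second_rel is not None
                    and second_rel > notch_rel
                    and start + second_rel < n_total
                ):
                    fid.second_peak = start + second_rel
        fiducials.append(fid)
        start += n_beat

    _refine_fiducials(samples, fiducials)
    return AnnotatedPulse(samples=samples, fs=fs, fiducials=fiducials)


def _refine_fiducials(x: np.ndarray, fiducials: list[CycleFiducials], halo: int = 3) -> None:
    """Snap each fiducial to the assembled signal's extremum within ±halo.

    Overlapping tails of adjacent beat templates can shift an extremum by a
    sample relative to the isolated template; this keeps the annotation
    attached to the constructed waveform (it is not a re-detection).
    """

    def snap(idx: int, sign: float) -> int:
        lo, hi = max(idx - halo, 0), min(idx + halo + 1, len(x))
        return lo + int(np.argmax(sign * x[lo:hi]))

    for f in fiducials:
        f.systolic_peak = snap(f.systolic_peak, +1.0)
        f.valley = snap(f.valley, -1.0)
        if f.dicrotic_notch is not None:
            f.dicrotic_notch = snap(f.dicrotic_notch, -1.0)
        if f.second_peak is not None:
            f.second_peak = snap(f.second_peak, +1.0)
        # ordering can only be violated by degenerate snaps; drop the
        # secondary fiducials in that case
        if f.dicrotic_notch is not None and f.dicrotic_notch <= f.systolic_peak:
            f.dicrotic_notch = None
            f.second_peak = None
        if (
            f.second_peak is not None
            and f.dicrotic_notch is not None
            and f.second_peak <= f.dicrotic_notch
        ):
            f.second_peak = None


@dataclass
class RawTrace:
    """Coarse 1-D trace (also produced by :func:`palmpulse.extract.green_channel_mean`)."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("RawTrace samples must be finite")


def corrupt_signal(clean: AnnotatedPulse, noise: NoiseParams, seed: int) -> RawTrace:
    """Apply AM, baseline drift, flicker and white noise to a clean pulse.

    ``out = clean * (1 + AM) + drift + flicker + white``; length and fs preserved.
    """
    x = np.asarray(clean.samples, dtype=float)
    if x.size == 0:
        raise ValueError("clean signal is empty")
    rng = np.random.default_rng(seed)
    t = np.arange(x.size) / clean.fs

    out = x.copy()
    if noise.am_depth > 0:
        phase = rng.uniform(0, 2 * np.pi)
        out = out * (1.0 + noise.am_depth * np.sin(2 * np.pi * noise.am_freq_hz * t + phase))
    if noise.drift_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        out = out + noise.drift_amp * np.sin(2 * np.pi * noise.drift_freq_hz * t + phase)
    if noise.drift_walk_sigma > 0:
        out = out + np.cumsum(rng.normal(0.0, noise.drift_walk_sigma, x.size))
    if noise.flicker_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        out = out + noise.flicker_amp * np.sin(2 * np.pi * noise.flicker_freq_hz * t + phase)
    if noise.white_sigma > 0:
        out = out + rng.normal(0.0, noise.white_sigma, x.size)
    return RawTrace(samples=out, fs=clean.fs)


def render_palm_video(
    clean: AnnotatedPulse, vparams: VideoRenderParams, seed: int
) -> np.ndarray:
    """Render an RGB frame stack whose green-channel mean tracks the pulse.

    Returns float frames of shape ``(n_frames, height, width, 3)``.  The green
    channel of the palm region is ``base_green * (1 + modulation_depth * p(t))``
    where ``p`` is the pulse normalized to [-1, 1]; red/blue are unmodulated.
    """
    if abs(vparams.fps - clean.fs) > 1e-9:
        raise ValueError(f"fps ({vparams.fps}) must equal the pulse fs ({clean.fs})")
    rng = np.random.default_rng(seed)
    x = np.asarray(clean.samples, dtype=float)
    span = x.max() - x.min()
    p = np.zeros_like(x) if span == 0 else 2.0 * (x - x.min()) / span - 1.0

    h, w = vparams.height, vparams.width
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius = 0.42 * min(h, w)

    frames = np.empty((x.size, h, w, 3), dtype=float)
    for i in range(x.size):
        dy = dx = 0
        if vparams.jitter_px > 0:
            dy = int(rng.integers(-vparams.jitter_px, vparams.jitter_px + 1))
            dx = int(rng.integers(-vparams.jitter_px, vparams.jitter_px + 1))
        palm = ((yy - cy - dy) ** 2 + (xx - cx - dx) ** 2) <= radius**2
        green = np.where(palm, vparams.base_green * (1.0 + vparams.modulation_depth * p[i]),
                         0.3 * vparams.base_green)
        frame = np.stack(
            [np.full((h, w), 0.5 * vparams.base_green), green,
             np.full((h, w), 0.4 * vparams.base_green)], axis=-1)
        if vparams.pixel_noise_sigma > 0:
            frame = frame + rng.normal(0.0, vparams.pixel_noise_sigma, frame.shape)
        frames[i] = frame
    return frames


@dataclass
class PairedWindow:
    """A normalized (rough, reference) training pair with peak annotations."""

    rough: np.ndarray  # in [-1, 1]
    reference: np.ndarray  # in [-1, 1]
    peak_mask: np.ndarray  # bool, True at annotated reference peak samples
    record_id: int
    start: int
    fs: float


@dataclass
class PairedDataset:
    windows: list[PairedWindow]
    train_records: np.ndarray
    val_records: np.ndarray
    window_len: int
    fs: float

    @property
    def train_windows(self) -> list[PairedWindow]:
        ids = set(self.train_records.tolist())
        return [w for w in self.windows if w.record_id in ids]

    @property
    def val_windows(self) -> list[PairedWindow]:
        ids = set(self.val_records.tolist())
        return [w for w in self.windows if w.record_id in ids]


def minmax_normalize(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Map to [-1, 1] by min-max; returns (normalized, lo, hi)."""
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo == 0:
        return np.zeros_like(x), lo, hi
    return 2.0 * (x - lo) / (hi - lo) - 1.0, lo, hi


def window_starts(n: int, window: int) -> list[int]:
    """50%-overlap window start positions covering the whole record."""
    if n < window:
        raise ValueError(f"record of {n} samples shorter than window {window}")
    starts = list(range(0, n - window + 1, window // 2))
    if starts[-1] != n - window:
        starts.append(n - window)
    return starts


def _peak_mask_from_fiducials(pulse: AnnotatedPulse, start: int, window: int) -> np.ndarray:
    mask = np.zeros(window, dtype=bool)
    for kind in ("systolic_peak", "dicrotic_notch", "second_peak"):
        idx = pulse.fiducial_indices(kind)
        sel = idx[(idx >= start) & (idx < start + window)] - start
        mask[sel] = True
    return mask


def make_paired_dataset(
    params: PulseModelParams,
    noise: NoiseParams,
    n_records: int,
    duration_s: float,
    fs: float,
    seed: int,
    *,
    window: int = 1024,
    hr_jitter_bpm: float = 8.0,
    baseline_cfg=None,
    split_by: str = "record",
) -> PairedDataset:
    """Generate ``n_records`` paired 20 s-style records and split 9:1.

    Each record draws its heart rate uniformly within ``hr_jitter_bpm`` of
    ``params.heart_rate_bpm``, is corrupted with ``noise``, optionally
    baseline-corrected (``baseline_cfg``: an ``EEMDConfig``), then cut into
    50%-overlap windows normalized to [-1, 1].
    """
    if n_records < 10:
        raise ValueError("n_records must be >= 10 to honor a 9:1 record-level split")
    if split_by not in ("record",):
        raise ValueError(f"unknown split mode {split_by!r}")
    rng = np.random.default_rng(seed)

    windows: list[PairedWindow] = []
    for rec in range(n_records):
        hr = params.heart_rate_bpm
        if hr_jitter_bpm > 0:
            hr = float(
                np.clip(hr + rng.uniform(-hr_jitter_bpm, hr_jitter_bpm), 40.0, 180.0)
            )
        rec_params = replace(params, heart_rate_bpm=hr)
        rec_seed = int(rng.integers(0, 2**31 - 1))
        clean = generate_clean_ppg(rec_params, duration_s, fs, seed=rec_seed)
        raw = corrupt_signal(clean, noise, seed=rec_seed + 1)
        rough = raw.samples
        if baseline_cfg is not None:
            from .baseline import remove_baseline

            rough = remove_baseline(raw, baseline_cfg).samples
        for start in window_starts(len(rough), window):
            r, _, _ = minmax_normalize(rough[start : start + window])
            c, _, _ = minmax_normalize(clean.samples[start : start + window])
            windows.append(
                PairedWindow(
                    rough=r,
                    reference=c,
                    peak_mask=_peak_mask_from_fiducials(clean, start, window),
                    record_id=rec,
                    start=start,
                    fs=fs,
                )
            )

    n_val = max(1, int(round(n_records / 10.0)))
    perm = rng.permutation(n_records)
    val = np.sort(perm[:n_val])
    train = np.sort(perm[n_val:])
    return PairedDataset(
        windows=windows, train_records=train, val_records=val, window_len=window, fs=fs
    )
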