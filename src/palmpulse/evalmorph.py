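"""Waveform evaluation: pointwise metrics and cycle-morphology analysis.

Metrics follow the textbook definitions (MAPE is computed on min-max
normalized signals with a floored denominator, since percentage error is
meaningless near zero crossings).  The morphology pipeline detects valleys,
segments cycles, quality-screens them automatically, averages the
normalized cycles, and measures rise/fall times and the three key
amplitudes (main peak, dicrotic notch, second peak).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "MetricReport",
    "CycleSet",
    "MorphologyIndices",
    "SiteComparison",
    "compute_metrics",
    "detect_valleys",
    "build_cycle_set",
    "average_waveform",
    "morphology_indices",
    "compare_sites",
]

RESAMPLE_LEN = 100
MAPE_EPS = 1e-3


@dataclass
class MetricReport:
    mape: float
    rmse: float
    pearson_rho: float
    cosine_similarity: float


@dataclass
class CycleSet:
    valleys: np.ndarray
    cycles: list[np.ndarray]  # normalized to [0, 1], resampled to a common length
    quality: list[bool]  # True = kept; aligned with the raw segmentation
    fs_effective: float  # samples per second of the resampled cycles

    def __len__(self) -> int:
        return len(self.cycles)


@dataclass
class MorphologyIndices:
    t1: float  # rise time, s
    t2: float  # fall time, s
    h1: float  # main peak amplitude
    h2: float | None  # dicrotic notch amplitude (None when absent)
    h3: float | None  # second peak amplitude
    physiologic: bool = True


@dataclass
class SiteComparison:
    delta_t1_ms: float
    delta_t2_ms: float
    delta_h1: float
    delta_h2: float | None
    delta_h3: float | None
    rho: float


def _minmax01(x: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def compute_metrics(reconstructed: np.ndarray, reference: np.ndarray) -> MetricReport:
    """MAPE (on normalized signals), RMSE, Pearson rho, cosine similarity."""
    rec = np.asarray(reconstructed, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if rec.shape != ref.shape or rec.size < 2:
        raise ValueError("signals must share a length of at least 2")
    if np.ptp(ref) == 0:
        raise ValueError("reference is constant: Pearson correlation is undefined")

    rec01, ref01 = _minmax01(rec), _minmax01(ref)
    mape = float(np.mean(np.abs(ref01 - rec01) / np.maximum(np.abs(ref01), MAPE_EPS)))
    rmse = float(np.sqrt(np.mean((ref - rec) ** 2)))
    rho = float(np.corrcoef(rec, ref)[0, 1])
    denom = float(np.linalg.norm(rec) * np.linalg.norm(ref))
    cosine = float(np.dot(rec, ref) / denom) if denom > 0 else 0.0
    return MetricReport(mape=mape, rmse=rmse, pearson_rho=rho, cosine_similarity=cosine)


def detect_valleys(signal: np.ndarray, fs: float,
                   refractory_s: float = 0.4, prominence_frac: float = 0.3) -> np.ndarray:
    """Cycle-start valleys: prominent local minima at least ``refractory_s`` apart."""
    x = np.asarray(signal, dtype=float)
    if len(x) < 2 * fs:
        raise ValueError("signal must be at least 2 s long")
    span = float(np.ptp(x))
    if span == 0:
        return np.array([], dtype=int)
    valleys, _ = find_peaks(
        -x, distance=max(int(refractory_s * fs), 1), prominence=prominence_frac * span
    )
    # find_peaks cannot flag the first/last sample; admit a boundary sample
    # when the record starts/ends inside a valley AND a full upstroke follows
    # (precedes) it within two refractory windows
    lo = float(np.min(x))
    gap = max(int(refractory_s * fs), 1)
    n = len(x)
    rise_ok = np.max(x[: 2 * gap]) - x[0] >= prominence_frac * span
    if (
        x[0] <= x[1]
        and x[0] <= lo + 0.15 * span
        and rise_ok
        and (len(valleys) == 0 or valleys[0] >= gap)
    ):
        valleys = np.concatenate([[0], valleys])
    fall_ok = np.max(x[-2 * gap :]) - x[-1] >= prominence_frac * span
    if (
        x[-1] <= x[-2]
        and x[-1] <= lo + 0.15 * span
        and fall_ok
        and (len(valleys) == 0 or n - 1 - valleys[-1] >= gap)
    ):
        valleys = np.concatenate([valleys, [n - 1]])
    return valleys.astype(int)


def build_cycle_set(
    signal: np.ndarray,
    valleys: np.ndarray,
    fs: float,
    *,
    resample_len: int = RESAMPLE_LEN,
    max_duration_dev: float = 0.3,
    min_prominence_frac: float = 0.3,
) -> CycleSet:
    """Segment, quality-screen, normalize to [0, 1] and resample each cycle.

    The automated screen (standing in for manual review) rejects cycles whose
    duration deviates more than ``max_duration_dev`` from the record median or
    whose peak prominence falls below ``min_prominence_frac`` of the median.
    """
    x = np.asarray(signal, dtype=float)
    valleys = np.asarray(valleys, dtype=int)
    if len(valleys) < 2:
        raise ValueError("need at least 2 valleys to segment one cycle")

    durations = np.diff(valleys)
    med_dur = float(np.median(durations))
    proms = np.array([
        float(np.max(x[a:b]) - max(x[a], x[b - 1])) for a, b in zip(valleys[:-1], valleys[1:])
    ])
    med_prom = float(np.median(proms))

    cycles: list[np.ndarray] = []
    quality: list[bool] = []
    reasons: list[str] = []
    for k, (a, b) in enumerate(zip(valleys[:-1], valleys[1:])):
        ok = True
        if med_dur > 0 and abs(durations[k] - med_dur) > max_duration_dev * med_dur:
            ok = False
            reasons.append(f"cycle {k}: duration {durations[k]} vs median {med_dur:.1f}")
        if med_prom > 0 and not (
            min_prominence_frac * med_prom <= proms[k] <= med_prom / min_prominence_frac
        ):
            ok = False
            reasons.append(f"cycle {k}: prominence {proms[k]:.3g} outside threshold band")
        quality.append(ok)
        if not ok:
            continue
        seg = _minmax01(x[a:b])
        grid = np.linspace(0.0, len(seg) - 1, resample_len)
        # renormalize after resampling: interpolation can clip the extremes
        cycles.append(_minmax01(np.interp(grid, np.arange(len(seg)), seg)))
    if not cycles:
        raise ValueError("all cycles rejected by the quality screen: " + "; ".join(reasons))
    fs_effective = resample_len / (med_dur / fs)
    return CycleSet(valleys=valleys, cycles=cycles, quality=quality, fs_effective=fs_effective)


def average_waveform(cycles: CycleSet) -> np.ndarray:
    """Pointwise mean of the normalized, resampled cycles."""
    if len(cycles) == 0:
        raise ValueError("empty cycle set")
    return np.mean(cycles.cycles, axis=0)


def morphology_indices(avg_cycle: np.ndarray, fs_effective: float) -> MorphologyIndices:
    """Rise/fall time and main-peak / notch / second-peak amplitudes.

    The input must be normalized (values in [0, 1]).  t1 runs from cycle
    start to the main peak, t2 from the main peak to cycle end.
    """
    y = np.asarray(avg_cycle, dtype=float)
    if y.min() < -1e-9 or y.max() > 1 + 1e-9:
        raise ValueError("avg_cycle must be normalized to [0, 1]")
    n = len(y)
    peak = int(np.argmax(y))
    t1 = peak / fs_effective
    t2 = (n - 1 - peak) / fs_effective
    h1 = float(y[peak])

    h2: float | None = None
    h3: float | None = None
    lo = peak + max(int(0.05 * n), 1)
    sub = y[lo:]
    minima, props = find_peaks(-sub, prominence=1e-3)
    if len(minima):
        notch = lo + int(minima[np.argmax(props["prominences"])])
        maxima, _ = find_peaks(y[notch:])
        if len(maxima):
            h2 = float(y[notch])
            h3 = float(y[notch + int(maxima[0])])

    physiologic = True
    if h2 is not None and h3 is not None:
        physiologic = 0 <= h2 <= h3 <= h1
    return MorphologyIndices(t1=t1, t2=t2, h1=h1, h2=h2, h3=h3, physiologic=physiologic)


def compare_sites(avg_a: np.ndarray, avg_b: np.ndarray, fs_effective: float) -> SiteComparison:
    """Absolute morphology-index differences (times in ms) plus waveform rho."""
    a = np.asarray(avg_a, dtype=float)
    b = np.asarray(avg_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("averaged cycles must share the resample length")
    ma = morphology_indices(a, fs_effective)
    mb = morphology_indices(b, fs_effective)

    def diff(x: float | None, y: float | None) -> float | None:
        if x is None or y is None:
            return None
        return abs(x - y)

    return SiteComparison(
        delta_t1_ms=abs(ma.t1 - mb.t1) * 1000.0,
        delta_t2_ms=abs(ma.t2 - mb.t2) * 1000.0,
        delta_h1=abs(ma.h1 - mb.h1),
        delta_h2=diff(ma.h2, mb.h2),
        delta_h3=diff(ma.h3, mb.h3),
        rho=float(np.corrcoef(a, b)[0, 1]),
    )
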