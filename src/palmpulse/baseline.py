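"""EEMD-based baseline-drift removal.

The coarse trace is decomposed into intrinsic mode functions (ensemble
average over noise-perturbed sifting trials); components too slow to carry
cardiac cycles — fewer local extrema than ``ratio * duration_s`` — are
discarded together with the monotone residual, and the mean of the input is
restored exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .synth import RawTrace

__all__ = [
    "EEMDConfig",
    "IMFSet",
    "CorrectedTrace",
    "emd",
    "eemd_decompose",
    "classify_baseline_imfs",
    "remove_baseline",
    "count_local_extrema",
]


@dataclass(frozen=True)
class EEMDConfig:
    n_trials: int = 50
    noise_width: float = 0.01  # fraction of the input standard deviation
    max_imfs: int = 8
    extrema_ratio: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0.0 < self.noise_width < 1.0:
            raise ValueError("noise_width must be in (0, 1)")
        if not 1 <= self.max_imfs <= 16:
            raise ValueError("max_imfs must be in [1, 16]")
        if not 0.0 < self.extrema_ratio < 1.0:
            raise ValueError("extrema_ratio must be in (0, 1)")


@dataclass
class IMFSet:
    components: list[np.ndarray]  # IMF 1 = highest frequency
    residual: np.ndarray

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for c in self.components:
            out += c
        return out


@dataclass
class CorrectedTrace:
    samples: np.ndarray
    fs: float
    removed_indices: list[int] = field(default_factory=list)


def _extrema_indices(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima.

    Extrema are strict sign changes of the first difference; plateaus are
    credited to their first sample.
    """
    d = np.diff(x)
    # collapse zero steps onto the sign of the next nonzero step so a plateau
    # contributes a single extremum at its first sample
    s = np.sign(d)
    for i in range(len(s) - 2, -1, -1):
        if s[i] == 0:
            s[i] = s[i + 1]
    changes = np.nonzero(s[1:] * s[:-1] < 0)[0] + 1
    maxima = changes[s[changes - 1] > 0]
    minima = changes[s[changes - 1] < 0]
    return maxima, minima


def count_local_extrema(x: np.ndarray) -> int:
    mx, mn = _extrema_indices(np.asarray(x, dtype=float))
    return len(mx) + len(mn)


def _envelope(x: np.ndarray, idx: np.ndarray, kind: str) -> np.ndarray:
    """Cubic-spline envelope through extrema, with mirrored boundary knots."""
    n = len(x)
    t = np.arange(n)
    if len(idx) < 2:
        return np.full(n, x[idx[0]] if len(idx) else (x.max() if kind == "max" else x.min()))
    # mirror up to two extrema past each end to tame spline overshoot
    k = min(2, len(idx))
    left_t = -idx[1:k + 1][::-1] if len(idx) > 1 else np.array([-idx[0] - 1])
    right_t = 2 * (n - 1) - idx[-k - 1 : -1][::-1] if len(idx) > 1 else np.array([2 * n - idx[0]])
    tt = np.concatenate([left_t, idx, right_t])
    vv = np.concatenate([x[idx[1:k + 1][::-1]] if len(idx) > 1 else x[idx[:1]],
                         x[idx],
                         x[idx[-k - 1 : -1][::-1]] if len(idx) > 1 else x[idx[:1]]])
    tt, keep = np.unique(tt, return_index=True)
    return CubicSpline(tt, vv[keep])(t)


def _sift_imf(x: np.ndarray, max_sift: int = 50, sd_stop: float = 0.2) -> np.ndarray | None:
    """Extract one IMF by standard sifting; None when x has too few extrema."""
    h = x
    for _ in range(max_sift):
        mx, mn = _extrema_indices(h)
        if len(mx) + len(mn) < 3:
            return None if h is x else h
        upper = _envelope(h, mx, "max")
        lower = _envelope(h, mn, "min")
        mean = 0.5 * (upper + lower)
        new = h - mean
        denom = np.sum(h**2) + 1e-300
        if np.sum(mean**2) / denom < sd_stop**2:
            return new
        h = new
    return h


def emd(x: np.ndarray, max_imfs: int = 8) -> IMFSet:
    """Plain empirical mode decomposition; exactly complete by construction."""
    x = np.asarray(x, dtype=float)
    residual = x.copy()
    comps: list[np.ndarray] = []
    for _ in range(max_imfs):
        if count_local_extrema(residual) < 3:
            break
        imf = _sift_imf(residual)
        if imf is None:
            break
        comps.append(imf)
        residual = residual - imf
    return IMFSet(components=comps, residual=residual)


def eemd_decompose(trace: RawTrace, cfg: EEMDConfig) -> IMFSet:
    """Ensemble EMD: average the per-trial IMFs over noise realizations.

    With ``n_trials == 1`` no noise is added (plain-EMD limit), so the
    decomposition is exactly complete; the ensemble average for larger trial
    counts is complete only up to the residual ensemble noise.
    """
    x = np.asarray(trace.samples, dtype=float)
    if x.size < 4:
        raise ValueError("trace must have at least 4 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite samples")
    if count_local_extrema(x) == 0:
        return IMFSet(components=[], residual=x.copy())

    rng = np.random.default_rng(cfg.seed)
    sigma = cfg.noise_width * float(np.std(x))
    acc: list[np.ndarray] = []
    counts: list[int] = []
    res_acc = np.zeros_like(x)
    for trial in range(cfg.n_trials):
        noisy = x if (cfg.n_trials == 1 or sigma == 0) else x + rng.normal(0.0, sigma, x.size)
        dec = emd(noisy, max_imfs=cfg.max_imfs)
        for i, c in enumerate(dec.components):
            if i >= len(acc):
                acc.append(np.zeros_like(x))
                counts.append(0)
            acc[i] += c
            counts[i] += 1
        res_acc += dec.residual
    comps = [a / cfg.n_trials for a in acc]
    return IMFSet(components=comps, residual=res_acc / cfg.n_trials)


def classify_baseline_imfs(imfs: IMFSet, fs: float, ratio: float) -> list[int]:
    """Indices of components to remove as baseline.

    Component i is baseline iff its local-extrema count is below
    ``ratio * (len / fs)`` — i.e. below a fraction of the expected cardiac
    cycle count.  (The residual is always baseline and is handled by the
    caller, not listed here.)
    """
    if not imfs.components and imfs.residual is None:
        raise ValueError("empty IMF set")
    n = len(imfs.residual)
    threshold = ratio * (n / fs)
    return [
        i for i, c in enumerate(imfs.components) if count_local_extrema(c) < threshold
    ]


def remove_baseline(trace: RawTrace, cfg: EEMDConfig) -> CorrectedTrace:
    """Reconstruct from the cardiac-bearing IMFs and restore the input mean."""
    x = np.asarray(trace.samples, dtype=float)
    imfs = eemd_decompose(trace, cfg)
    removed = classify_baseline_imfs(imfs, trace.fs, cfg.extrema_ratio)
    kept = [c for i, c in enumerate(imfs.components) if i not in removed]
    if not kept:
        warnings.warn("all IMFs classified as baseline; output is the constant mean trace")
        out = np.full_like(x, float(np.mean(x)))
    else:
        out = np.sum(kept, axis=0)
        out = out + (float(np.mean(x)) - float(np.mean(out)))
    return CorrectedTrace(samples=out, fs=trace.fs, removed_indices=removed)
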