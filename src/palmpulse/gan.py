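"""Conditional 1-D U-Net generator, convolutional discriminator, peak
annotation, and the composite least-squares-adversarial / time / spectral /
peak-aware losses.

The generator halves the temporal length at every encoder stage (kernel 4,
stride 2, padded convolutions, PReLU + instance norm) and restores it with
transposed convolutions, ending in a Tanh.  Skip connections can be gated:
the encoder features are multiplied by a sigmoid gate computed from both
paths before fusion.  The discriminator scores (candidate, rough) channel
pairs with kernel-5 / stride-3 convolutions and a final stride-1 linear
layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .nn import (
    Conv1d,
    ConvTranspose1d,
    InstanceNorm1d,
    LeakyReLU,
    Module,
    PReLU,
    Tanh,
    Tensor,
    concat,
    fft_magnitude,
)

__all__ = [
    "GeneratorConfig",
    "DiscriminatorConfig",
    "LossWeights",
    "PeakAnnotation",
    "Generator",
    "Discriminator",
    "GatedSkip",
    "annotate_peaks",
    "spectral_magnitude",
    "generator_loss",
    "discriminator_loss",
]

FFT_POINTS = 1024


@dataclass(frozen=True)
class GeneratorConfig:
    depth: int = 4
    base_channels: int = 8
    kernel: int = 4
    stride: int = 2
    gated_skips: bool = True

    def __post_init__(self) -> None:
        if self.kernel != 4 or self.stride != 2:
            raise ValueError("generator uses kernel 4 / stride 2 convolutions")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


@dataclass(frozen=True)
class DiscriminatorConfig:
    n_layers: int = 4
    kernel: int = 5
    stride: int = 3
    channels: tuple[int, ...] = (16, 32, 64)

    def __post_init__(self) -> None:
        if self.kernel != 5 or self.stride != 3:
            raise ValueError("discriminator uses kernel 5 / stride 3 (final layer stride 1)")
        if len(self.channels) != self.n_layers - 1:
            raise ValueError("need one channel count per non-final layer")


@dataclass(frozen=True)
class LossWeights:
    alpha: float = 1.0  # time-domain L1
    beta: float = 0.3  # spectral L1
    gamma: float = 0.5  # peak-aware term

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("loss weights must be >= 0")


@dataclass
class PeakAnnotation:
    """Annotated key-point indices of one window."""

    systolic: list[int] = field(default_factory=list)
    notch: list[int] = field(default_factory=list)
    second: list[int] = field(default_factory=list)

    @property
    def indices(self) -> np.ndarray:
        return np.array(sorted(self.systolic + self.notch + self.second), dtype=int)

    def mask(self, length: int) -> np.ndarray:
        m = np.zeros(length, dtype=bool)
        idx = self.indices
        m[idx[idx < length]] = True
        return m

    def __len__(self) -> int:
        return len(self.systolic) + len(self.notch) + len(self.second)


class GatedSkip(Module):
    """Sigmoid feature gate on the encoder path of a skip connection.

    ``fused = sigmoid(W_e * enc + W_u * dec + b) * enc`` with 1x1 convolutions.
    """

    def __init__(self, n_ch: int, rng: np.random.Generator, init_std: float = 0.02):
        self.proj_enc = Conv1d(n_ch, n_ch, 1, 1, 0, rng, init_std)
        self.proj_dec = Conv1d(n_ch, n_ch, 1, 1, 0, rng, init_std)

    def gate(self, enc: Tensor, dec: Tensor) -> Tensor:
        if enc.shape[2] != dec.shape[2]:
            raise ValueError("encoder/decoder temporal lengths differ")
        return (self.proj_enc(enc) + self.proj_dec(dec)).sigmoid()

    def forward(self, enc: Tensor, dec: Tensor) -> Tensor:
        return self.gate(enc, dec) * enc


class Generator(Module):
    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator, init_std: float = 0.02):
        self.cfg = cfg
        k, s, p = cfg.kernel, cfg.stride, (cfg.kernel - cfg.stride) // 2
        chans = [cfg.base_channels * 2**i for i in range(cfg.depth)]

        self.enc_convs: list[Conv1d] = []
        self.enc_acts: list[PReLU] = []
        prev = 1
        for c in chans:
            self.enc_convs.append(Conv1d(prev, c, k, s, p, rng, init_std))
            self.enc_acts.append(PReLU(c))
            prev = c

        self.dec_convs: list[ConvTranspose1d] = []
        self.dec_acts: list[PReLU] = []
        self.skips: list[GatedSkip] = []
        in_ch = chans[-1]
        for c in reversed(chans[:-1]):
            self.dec_convs.append(ConvTranspose1d(in_ch, c, k, s, p, rng, init_std))
            self.dec_acts.append(PReLU(c))
            if cfg.gated_skips:
                self.skips.append(GatedSkip(c, rng, init_std))
            in_ch = 2 * c
        self.final = ConvTranspose1d(in_ch, 1, k, s, p, rng, init_std)
        self.norm = InstanceNorm1d()
        self.tanh = Tanh()

    def forward(self, x: Tensor) -> Tensor:
        """x: (B, 1, L) with L divisible by stride**depth; returns (B, 1, L)."""
        length = x.shape[2]
        if length % self.cfg.stride**self.cfg.depth != 0:
            raise ValueError(
                f"input length {length} must be a multiple of "
                f"{self.cfg.stride**self.cfg.depth}; pad the window first"
            )
        feats = []
        h = x
        for conv, act in zip(self.enc_convs, self.enc_acts):
            h = act(self.norm(conv(h)))
            feats.append(h)
        for i, (up, act) in enumerate(zip(self.dec_convs, self.dec_acts)):
            h = act(self.norm(up(h)))
            skip = feats[len(feats) - 2 - i]
            if self.cfg.gated_skips:
                skip = self.skips[i](skip, h)
            h = concat([h, skip], axis=1)
        return self.tanh(self.final(h))


class Discriminator(Module):
    """Scores (candidate, condition) two-channel windows; linear final layer."""

    def __init__(self, cfg: DiscriminatorConfig, rng: np.random.Generator, init_std: float = 0.02):
        self.cfg = cfg
        k, s = cfg.kernel, cfg.stride
        self.convs: list[Conv1d] = []
        self.acts: list[LeakyReLU] = []
        prev = 2
        for c in cfg.channels:
            self.convs.append(Conv1d(prev, c, k, s, 1, rng, init_std))
            self.acts.append(LeakyReLU(0.2))
            prev = c
        self.final = Conv1d(prev, 1, k, 1, (k - 1) // 2, rng, init_std)
        self.norm = InstanceNorm1d()

    def forward(self, candidate: Tensor, condition: Tensor) -> Tensor:
        """Returns one patch-averaged realness score per batch item, shape (B,)."""
        if candidate.shape != condition.shape:
            raise ValueError("candidate and condition must have identical shapes")
        h = concat([candidate, condition], axis=1)
        for i, (conv, act) in enumerate(zip(self.convs, self.acts)):
            h = conv(h)
            if i > 0:
                h = self.norm(h)
            h = act(h)
        h = self.final(h)  # (B, 1, L'), linear activation
        return h.mean(axis=(1, 2))


# ---------------------------------------------------------------------------
# Peak annotation
# ---------------------------------------------------------------------------


def _cardiac_band_fraction(x: np.ndarray, fs: float, lo: float = 0.7, hi: float = 5.0) -> float:
    spec = np.abs(np.fft.rfft(x - np.mean(x))) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    total = spec[1:].sum()
    if total <= 0:
        return 0.0
    return float(spec[(freqs >= lo) & (freqs <= hi)].sum() / total)


def annotate_peaks(window: np.ndarray, fs: float) -> PeakAnnotation:
    """Annotate systolic peaks, dicrotic notches and second peaks.

    Per cardiac cycle (delimited by prominent valleys at least 0.4 s apart):
    the systolic peak is the maximum between consecutive valleys; the
    dicrotic notch is the most prominent local minimum in a physiologic
    window after the peak; the second peak is the first local maximum after
    the notch.  Windows without pulse structure (flat, or with little
    cardiac-band power) yield an empty annotation.
    """
    x = np.asarray(window, dtype=float)
    ann = PeakAnnotation()
    span = float(x.max() - x.min()) if x.size else 0.0
    if x.size < int(2 * fs) or span == 0:
        return ann
    if _cardiac_band_fraction(x, fs) < 0.3:
        return ann
    from .evalmorph import detect_valleys

    valleys = detect_valleys(x, fs)
    if len(valleys) < 2:
        return ann
    for a, b in zip(valleys[:-1], valleys[1:]):
        seg = x[a:b]
        peak = a + int(np.argmax(seg))
        ann.systolic.append(peak)
        lo = peak + max(int(0.08 * fs), 1)
        hi = min(peak + int(0.5 * fs), b - 1)
        if hi - lo < 3:
            continue
        sub = x[lo:hi]
        minima, props = find_peaks(-sub, prominence=0.0)
        if len(minima) == 0:
            continue
        notch = lo + int(minima[np.argmax(props["prominences"])])
        after = x[notch:hi]
        maxima, _ = find_peaks(after)
        if len(maxima) == 0:
            continue
        ann.notch.append(notch)
        ann.second.append(notch + int(maxima[0]))
    return ann


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------


def spectral_magnitude(window: np.ndarray, n: int = FFT_POINTS) -> np.ndarray:
    """Magnitude of the n-point FFT of the window (zero-padded/truncated)."""
    return np.abs(np.fft.fft(np.asarray(window, dtype=float), n=n, axis=-1))


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def _peak_mask(peaks, length: int) -> np.ndarray | None:
    if peaks is None:
        return None
    if isinstance(peaks, PeakAnnotation):
        return peaks.mask(length) if len(peaks) else None
    m = np.asarray(peaks)
    if m.dtype == bool:
        if m.size and m.any():
            return m
        return None
    if m.size == 0:
        return None
    mask = np.zeros(length, dtype=bool)
    mask[m.astype(int)] = True
    return mask


def generator_loss(d_score, generated, reference, peaks, w: LossWeights,
                   n_fft: int = FFT_POINTS) -> Tensor:
    """Composite generator objective.

    ``L_G = 0.5 * mean((D - 1)^2) + alpha * L1(ref, gen)
    + beta * L1(|FFT ref|, |FFT gen|) + gamma * L1 at annotated peak samples``

    All L1 terms are means; the peak term averages over the annotated
    samples only and is zero for an empty annotation.  Accepts plain arrays
    (returns a constant Tensor) or autograd Tensors (differentiable).
    """
    d_score = _as_tensor(d_score)
    gen = _as_tensor(generated)
    ref = _as_tensor(reference)
    if gen.shape != ref.shape:
        raise ValueError("generated and reference must have identical shapes")

    loss = 0.5 * ((d_score - 1.0) ** 2).mean()
    loss = loss + w.alpha * (ref - gen).abs().mean()
    spec_ref = fft_magnitude(ref, n=n_fft)
    spec_gen = fft_magnitude(gen, n=n_fft)
    loss = loss + w.beta * (spec_ref - spec_gen).abs().mean()

    if isinstance(peaks, np.ndarray) and peaks.dtype == bool and peaks.shape == ref.shape:
        mask = peaks  # per-item masks for batched windows
    else:
        mask = _peak_mask(peaks, ref.shape[-1])
    if mask is not None and np.any(mask):
        m = Tensor(np.broadcast_to(mask, ref.shape).astype(float))
        peak_term = ((ref - gen).abs() * m).sum() / float(np.broadcast_to(mask, ref.shape).sum())
        loss = loss + w.gamma * peak_term
    return loss


def discriminator_loss(d_fake_score, d_real_score) -> Tensor:
    """Least-squares discriminator objective:
    ``L_D = 0.5 * mean(D_fake^2) + 0.5 * mean((D_real - 1)^2)``."""
    fake = _as_tensor(d_fake_score)
    real = _as_tensor(d_real_score)
    return 0.5 * (fake**2).mean() + 0.5 * ((real - 1.0) ** 2).mean()
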