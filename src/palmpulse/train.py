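"""Adversarial training loop and full-record reconstruction.

Alternates three discriminator updates with one generator update per batch,
initializes every weight from N(0, init_std^2), and exposes ablation
switches for the peak-aware loss term, the gated skip connections, and
adversarial training itself.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace

import numpy as np

from .baseline import CorrectedTrace
from .gan import (
    Discriminator,
    DiscriminatorConfig,
    Generator,
    GeneratorConfig,
    LossWeights,
    discriminator_loss,
    generator_loss,
)
from .nn import Adam, Tensor
from .nn.autograd import precision
from .synth import PairedDataset, PairedWindow, minmax_normalize, window_starts

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "Checkpoint",
    "train_gan",
    "reconstruct",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    batch_size: int = 32
    d_steps_per_g: int = 3
    learning_rate: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    init_std: float = 0.02
    seed: int = 0
    use_peak_loss: bool = True
    use_gated_skips: bool = True
    use_adversarial: bool = True

    def __post_init__(self) -> None:
        if self.d_steps_per_g < 1:
            raise ValueError("d_steps_per_g must be >= 1")
        if self.init_std <= 0:
            raise ValueError("init_std must be > 0")


@dataclass
class TrainHistory:
    g_loss: list[float] = field(default_factory=list)
    d_loss: list[float] = field(default_factory=list)
    val_mape: list[float] = field(default_factory=list)
    val_rmse: list[float] = field(default_factory=list)
    val_rho: list[float] = field(default_factory=list)
    val_cosine: list[float] = field(default_factory=list)
    g_updates: int = 0
    d_updates: int = 0


@dataclass
class Checkpoint:
    gcfg: GeneratorConfig
    gen_state: dict[str, np.ndarray]
    window_len: int
    fs: float
    seed: int


def _stack(windows: list[PairedWindow]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rough = np.stack([w.rough for w in windows])
    ref = np.stack([w.reference for w in windows])
    mask = np.stack([w.peak_mask for w in windows])
    return rough, ref, mask


def _val_metrics(gen: Generator, rough: np.ndarray, ref: np.ndarray) -> dict[str, float]:
    from .evalmorph import compute_metrics

    out = gen(Tensor(rough[:, None, :])).data[:, 0, :]
    reports = [compute_metrics(out[i], ref[i]) for i in range(len(ref))]
    return {
        "mape": float(np.mean([r.mape for r in reports])),
        "rmse": float(np.mean([r.rmse for r in reports])),
        "rho": float(np.mean([r.pearson_rho for r in reports])),
        "cosine": float(np.mean([r.cosine_similarity for r in reports])),
    }


def train_gan(
    dataset: PairedDataset,
    gcfg: GeneratorConfig,
    dcfg: DiscriminatorConfig,
    w: LossWeights,
    tcfg: TrainConfig,
    *,
    validate_every: int = 1,
) -> tuple[Checkpoint, TrainHistory]:
    """Train the conditional GAN on the dataset's train split.

    Per batch: ``d_steps_per_g`` discriminator updates (on the same batch,
    against a frozen fake), then one generator update.  With
    ``use_adversarial=False`` the discriminator is never updated and the
    generator trains on the time/spectral/peak terms only.

    Training runs in float32 for speed; results are deterministic for a
    given seed and configuration.
    """
    with precision("float32"):
        return _train_gan_impl(dataset, gcfg, dcfg, w, tcfg, validate_every)


def _train_gan_impl(dataset, gcfg, dcfg, w, tcfg, validate_every):
    train_windows = dataset.train_windows
    val_windows = dataset.val_windows
    if not train_windows or not val_windows:
        raise ValueError("dataset must have non-empty train and validation splits")

    gcfg = replace(gcfg, gated_skips=tcfg.use_gated_skips)
    weights = w if tcfg.use_peak_loss else replace(w, gamma=0.0)

    rng = np.random.default_rng(tcfg.seed)
    gen = Generator(gcfg, rng, init_std=tcfg.init_std)
    disc = Discriminator(dcfg, rng, init_std=tcfg.init_std)
    opt_g = Adam(gen.parameters(), lr=tcfg.learning_rate, beta1=tcfg.beta1, beta2=tcfg.beta2)
    opt_d = Adam(disc.parameters(), lr=tcfg.learning_rate, beta1=tcfg.beta1, beta2=tcfg.beta2)

    rough_all, ref_all, mask_all = _stack(train_windows)
    val_rough, val_ref, _ = _stack(val_windows)

    history = TrainHistory()
    n = len(train_windows)
    m: dict[str, float] | None = None
    for epoch in range(tcfg.epochs):
        order = rng.permutation(n)
        g_losses, d_losses = [], []
        for lo in range(0, n, tcfg.batch_size):
            idx = order[lo : lo + tcfg.batch_size]
            rough = Tensor(rough_all[idx][:, None, :])
            ref = Tensor(ref_all[idx][:, None, :])
            masks = mask_all[idx]

            if tcfg.use_adversarial:
                fake = Tensor(gen(rough).data)  # frozen generator output
                for _ in range(tcfg.d_steps_per_g):
                    d_fake = disc(fake, rough)
                    d_real = disc(ref, rough)
                    loss_d = discriminator_loss(d_fake, d_real)
                    opt_d.zero_grad()
                    loss_d.backward()
                    opt_d.step()
                    history.d_updates += 1
                d_losses.append(loss_d.item())

            out = gen(rough)
            d_score = disc(out, rough) if tcfg.use_adversarial else Tensor(np.ones(len(idx)))
            loss_g = generator_loss(
                d_score, out.reshape(len(idx), -1), ref.reshape(len(idx), -1),
                masks, weights,
            )
            opt_g.zero_grad()
            if tcfg.use_adversarial:
                opt_d.zero_grad()  # discard D grads from the generator pass
            loss_g.backward()
            opt_g.step()
            history.g_updates += 1
            g_losses.append(loss_g.item())

        gl = float(np.mean(g_losses))
        dl = float(np.mean(d_losses)) if d_losses else 0.0
        if not np.isfinite(gl) or not np.isfinite(dl):
            raise RuntimeError(f"non-finite loss at epoch {epoch}: L_G={gl}, L_D={dl}")
        history.g_loss.append(gl)
        history.d_loss.append(dl)
        if m is None or (epoch + 1) % validate_every == 0 or epoch == tcfg.epochs - 1:
            m = _val_metrics(gen, val_rough, val_ref)
        history.val_mape.append(m["mape"])
        history.val_rmse.append(m["rmse"])
        history.val_rho.append(m["rho"])
        history.val_cosine.append(m["cosine"])

    ckpt = Checkpoint(
        gcfg=gcfg,
        gen_state=gen.state_dict(),
        window_len=dataset.window_len,
        fs=dataset.fs,
        seed=tcfg.seed,
    )
    return ckpt, history


def _load_generator(ckpt: Checkpoint) -> Generator:
    gen = Generator(ckpt.gcfg, np.random.default_rng(0))
    gen.load_state_dict(ckpt.gen_state)
    return gen


def reconstruct(ckpt: Checkpoint, rough: CorrectedTrace | np.ndarray) -> np.ndarray:
    """Denoise a full record by windowed inference with 50% overlap.

    Each window is min-max normalized to [-1, 1], passed through the
    generator, de-normalized back to the window's amplitude range, and the
    overlapping outputs are averaged.  Output length equals input length.
    """
    x = np.asarray(rough.samples if hasattr(rough, "samples") else rough, dtype=float)
    window = ckpt.window_len
    if len(x) < window:
        raise ValueError(
            f"record of {len(x)} samples is shorter than one window ({window}); "
            "pad the record or use a shorter window"
        )
    gen = _load_generator(ckpt)
    starts = window_starts(len(x), window)
    norm, spans = [], []
    for s in starts:
        seg, lo, hi = minmax_normalize(x[s : s + window])
        norm.append(seg)
        spans.append((lo, hi))
    out = gen(Tensor(np.stack(norm)[:, None, :])).data[:, 0, :]
    acc = np.zeros_like(x)
    cnt = np.zeros_like(x)
    for seg, s, (lo, hi) in zip(out, starts, spans):
        denorm = (seg + 1.0) / 2.0 * (hi - lo) + lo if hi > lo else np.full(window, lo)
        acc[s : s + window] += denorm
        cnt[s : s + window] += 1.0
    return acc / cnt


def save_checkpoint(ckpt: Checkpoint, path: str) -> None:
    meta = {
        "gcfg": vars(ckpt.gcfg) | {},
        "window_len": ckpt.window_len,
        "fs": ckpt.fs,
        "seed": ckpt.seed,
    }
    buf = io.BytesIO()
    np.savez(buf, **ckpt.gen_state)
    with open(path, "wb") as fh:
        header = json.dumps(meta).encode()
        fh.write(len(header).to_bytes(8, "little"))
        fh.write(header)
        fh.write(buf.getvalue())


def load_checkpoint(path: str) -> Checkpoint:
    with open(path, "rb") as fh:
        n = int.from_bytes(fh.read(8), "little")
        meta = json.loads(fh.read(n).decode())
        data = np.load(io.BytesIO(fh.read()))
        state = {k: data[k] for k in data.files}
    gcfg_kwargs = dict(meta["gcfg"])
    return Checkpoint(
        gcfg=GeneratorConfig(**gcfg_kwargs),
        gen_state=state,
        window_len=int(meta["window_len"]),
        fs=float(meta["fs"]),
        seed=int(meta["seed"]),
    )
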