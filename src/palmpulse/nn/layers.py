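"""Neural-network layers and the Adam optimizer on top of the autograd core."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv1d, conv_transpose1d, instance_norm, leaky_relu, prelu

__all__ = [
    "Module",
    "Conv1d",
    "ConvTranspose1d",
    "InstanceNorm1d",
    "PReLU",
    "LeakyReLU",
    "Tanh",
    "Adam",
]


class Module:
    """Base class; parameters are discovered by attribute walk."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                out.append((key, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{key}.{i}."))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.named_parameters():
            v.data = np.array(state[k], dtype=np.float64)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _init_weight(shape: tuple[int, ...], rng: np.random.Generator, std: float) -> Tensor:
    return Tensor(rng.normal(0.0, std, shape), requires_grad=True)


class Conv1d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 padding: int, rng: np.random.Generator, init_std: float = 0.02):
        self.stride = stride
        self.padding = padding
        self.weight = _init_weight((out_ch, in_ch, kernel), rng, init_std)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose1d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 padding: int, rng: np.random.Generator, init_std: float = 0.02):
        self.stride = stride
        self.padding = padding
        self.weight = _init_weight((in_ch, out_ch, kernel), rng, init_std)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose1d(x, self.weight, self.bias, self.stride, self.padding)


class InstanceNorm1d(Module):
    """Per-sample, per-channel normalization over the temporal axis (no affine)."""

    def __init__(self, eps: float = 1e-5):
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return instance_norm(x, self.eps)


class PReLU(Module):
    """Parametric ReLU with one learnable slope per channel."""

    def __init__(self, n_ch: int, init: float = 0.25):
        self.slope = Tensor(np.full((1, n_ch, 1), init), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return prelu(x, self.slope)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return leaky_relu(x, self.slope)


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 2e-4,
                 beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
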