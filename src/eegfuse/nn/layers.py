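"""Modules, layers and the Adam optimizer for the numpy autodiff engine."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, maxpool1d, unfold1d

__all__ = ["Module", "Parameter", "Linear", "Conv1d", "Adam"]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Base class with recursive parameter discovery by attribute name."""

    training: bool = False

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out.append((full, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(f"{full}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{full}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{full}.{i}", item))
        return out

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, value in vars(self).items():
            if isinstance(value, Module):
                value.train(mode)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for k, p in own.items():
            p.data = np.asarray(state[k], dtype=p.data.dtype).reshape(p.data.shape)


def _kaiming(rng: np.random.Generator, fan_in: int, shape: tuple[int, ...],
             dtype=np.float32) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        self.weight = Parameter(_kaiming(rng, in_dim, (in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim, dtype=np.float32)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y if self.bias is None else y + self.bias


class Conv1d(Module):
    """1-D convolution with 'same' zero padding, via unfold + matmul."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel width must be odd for 'same' padding")
        self.kernel = kernel
        self.in_channels = in_channels
        self.weight = Parameter(
            _kaiming(rng, in_channels * kernel, (out_channels, in_channels * kernel))
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        b, _, length = x.shape
        col = unfold1d(x, self.kernel, self.kernel // 2)   # (B, C*k, L)
        ck = col.shape[1]
        # single 2-D GEMM: (out, C*k) @ (C*k, B*L) keeps the weight gradient
        # a plain matrix product instead of a huge batched outer-product sum
        col2 = col.swapaxes(0, 1).reshape(ck, b * length)
        y = (self.weight @ col2).reshape(-1, b, length).swapaxes(0, 1).contiguous()
        return y + self.bias.reshape(1, -1, 1)


def clip_grad_norm(params: list[Parameter], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float(np.sum(np.asarray(p.grad, dtype=np.float64) ** 2))
    norm = np.sqrt(total)
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
    return norm


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                p.data.dtype
            )

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


# re-export the functional pieces next to the layers for convenience
__all__ += ["maxpool1d", "unfold1d"]
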