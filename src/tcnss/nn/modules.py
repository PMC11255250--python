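"""Module/parameter plumbing and generic layers on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class: parameter collection, train/eval mode propagation."""

    def __init__(self) -> None:
        self.training = True

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                out.append((full, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(f"{full}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{full}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append((f"{full}.{i}", item))
        return out

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def _submodules(self):
        for value in vars(self).values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def train(self) -> "Module":
        self.training = True
        for m in self._submodules():
            m.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for m in self._submodules():
            m.eval()
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update(self.buffers())
        return state

    def buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Module):
                out.update(value.buffers(f"{full}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.buffers(f"{full}.{i}."))
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                out[full] = value.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, arr in state.items():
            if name in params:
                params[name].data = np.asarray(arr, dtype=np.float64)
            else:
                self._set_buffer(name, np.asarray(arr, dtype=np.float64))

    def _set_buffer(self, dotted: str, arr: np.ndarray) -> None:
        obj = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
        setattr(obj, parts[-1], arr)


def init_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                 fan_in: int) -> Tensor:
    """Fan-in-scaled uniform initialization, U(-1/sqrt(fan_in), +1/sqrt(fan_in))."""
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-bound, bound, shape), requires_grad=True)


class Linear(Module):
    """Affine map applied to the last axis; also serves as a 1x1 convolution."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = init_uniform(rng, (d_in, d_out), d_in)
        self.bias = init_uniform(rng, (d_out,), d_in)

    def __call__(self, x) -> Tensor:
        return ad.add(ad.matmul(x, self.weight), self.bias)


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def __call__(self, x) -> Tensor:
        return ad.dropout(x, self.rate, self.rng, self.training)


class BatchNorm(Module):
    """Feature-wise batch normalization over the valid positions of a batch.

    Statistics are taken across batch and sequence axes, restricted to
    non-padding positions via the mask; running statistics are used in
    evaluation mode so evaluation is deterministic.
    """

    def __init__(self, width: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(width), requires_grad=True)
        self.beta = Tensor(np.zeros(width), requires_grad=True)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(width)
        self.running_var = np.ones(width)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        # mask: (B, L, 1) of 0/1
        if self.training:
            n = float(mask.sum())
            m = Tensor(mask)
            mean = ad.mul(ad.tsum(ad.mul(x, m), axis=(0, 1)), 1.0 / n)
            centered = ad.add(x, ad.mul(mean, -1.0))
            var = ad.mul(ad.tsum(ad.mul(ad.mul(centered, centered), m),
                                 axis=(0, 1)), 1.0 / n)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean.data)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data)
        else:
            mean = Tensor(self.running_mean)
            var = Tensor(self.running_var)
            centered = ad.add(x, ad.mul(mean, -1.0))
        inv_std = ad.pow_const(ad.add(var, self.eps), -0.5)
        out = ad.mul(ad.mul(centered, inv_std), self.gamma)
        return ad.add(out, self.beta)


class Adam:
    """Adaptive-moment gradient descent."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
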