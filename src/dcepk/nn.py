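"""Layers and optimizer on top of :mod:`dcepk.autodiff`."""
from __future__ import annotations

import numpy as np

from dcepk.autodiff import DTYPE, Tensor, conv1d, conv2d

__all__ = ["Module", "Conv1d", "Conv2d", "Linear", "Adam"]


class Module:
    """Minimal container: parameters are discovered on attributes recursively."""

    def parameters(self) -> list[Tensor]:
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = []
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                out.append((key, v))
            elif isinstance(v, Module):
                out.extend(v.named_parameters(prefix=key + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{key}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append((f"{key}.{i}", item))
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        if set(own) != set(state):
            raise ValueError("state dict keys do not match the model")
        for k, v in state.items():
            if own[k].data.shape != v.shape:
                raise ValueError(f"shape mismatch for {k}")
            own[k].data = np.asarray(v, dtype=DTYPE).copy()


def _he(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


class Conv1d(Module):
    def __init__(self, cin, cout, kernel=3, dilation=1, rng=None):
        rng = rng or np.random.default_rng(0)
        self.dilation = dilation
        self.w = Tensor(_he(rng, (cout, cin, kernel), cin * kernel), requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b, dilation=self.dilation)


class Conv2d(Module):
    def __init__(self, cin, cout, kernel=3, rng=None):
        rng = rng or np.random.default_rng(0)
        self.w = Tensor(_he(rng, (cout, cin, kernel, kernel), cin * kernel * kernel), requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b)


class Linear(Module):
    def __init__(self, fin, fout, rng=None):
        rng = rng or np.random.default_rng(0)
        self.w = Tensor(_he(rng, (fin, fout), fin), requires_grad=True)
        self.b = Tensor(np.zeros(fout, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Adam:
    """Adaptive-moment optimizer (beta1 0.9, beta2 0.999) with optional
    global-norm gradient clipping."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, beta1=0.9, beta2=0.999,
                 eps=1e-8, clip_norm: float = 0.0):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        if self.clip_norm > 0:
            total = np.sqrt(sum(
                float(np.sum(p.grad.astype(np.float64) ** 2))
                for p in self.params if p.grad is not None
            ))
            if total > self.clip_norm:
                f = self.clip_norm / (total + 1e-12)
                for p in self.params:
                    if p.grad is not None:
                        p.grad *= f
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mh / (np.sqrt(vh) + self.eps)
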