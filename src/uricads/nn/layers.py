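"""Parameterized layers and a momentum-SGD optimizer for the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d


class Module:
    """Container with recursive parameter discovery."""

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
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p.data = np.asarray(a, dtype=np.float64)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU stacks
        self.weight = Tensor(rng.standard_normal((c_out, c_in, k, k)) * scale,
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride
        self.pad = k // 2 if pad is None else pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(1.0 / n_in)
        self.weight = Tensor(rng.standard_normal((n_in, n_out)) * scale,
                             requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class Adam:
    """Adam optimizer; per-parameter adaptive steps suit the mixed
    multi-task objective better than raw SGD at batch size one."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Tensor], lr: float = 0.05,
                 momentum: float = 0.9, clip: float | None = 5.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.clip = clip
        self.velocity = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        if self.clip is not None:
            total = np.sqrt(sum(float(np.sum(p.grad ** 2))
                                for p in self.params if p.grad is not None))
            scale = self.clip / total if total > self.clip else 1.0
        else:
            scale = 1.0
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v -= self.lr * scale * p.grad
            p.data += v
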