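"""Parameter containers, initialisation, Adam, and finite-difference checks."""

from __future__ import annotations

from typing import Callable, Iterable, Mapping

import numpy as np

from .autodiff import Tensor


def glorot(rng: np.random.Generator, shape: tuple[int, ...], gain: float = 1.0) -> Tensor:
    """Glorot-uniform initialised trainable tensor."""
    fan_in = shape[-1] if len(shape) > 1 else shape[0]
    fan_out = shape[-2] if len(shape) > 1 else shape[0]
    limit = gain * np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def normal_param(rng: np.random.Generator, shape: tuple[int, ...], scale: float = 0.1) -> Tensor:
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


def zeros_param(shape: tuple[int, ...]) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


class Adam:
    """Adam optimiser over a flat iterable of trainable tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def clip_global_norm(self, max_norm: float) -> float:
        """Scale all gradients so their global L2 norm is at most max_norm."""
        total = np.sqrt(sum(float((p.grad**2).sum())
                            for p in self.params if p.grad is not None))
        if total > max_norm and total > 0:
            factor = max_norm / total
            for p in self.params:
                if p.grad is not None:
                    p.grad = p.grad * factor
        return total

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def collect_params(tree) -> list[Tensor]:
    """Flatten a nested dict/list structure of Tensors into a list."""
    out: list[Tensor] = []
    if isinstance(tree, Tensor):
        out.append(tree)
    elif isinstance(tree, Mapping):
        for v in tree.values():
            out.extend(collect_params(v))
    elif isinstance(tree, (list, tuple)):
        for v in tree:
            out.extend(collect_params(v))
    return out


def gradcheck(loss_fn: Callable[[], Tensor], params: Iterable[Tensor],
              eps: float = 1e-6, max_elems: int | None = None,
              rng: np.random.Generator | None = None) -> float:
    """Max relative error between backprop and central finite differences.

    ``loss_fn`` must rebuild the graph from the current parameter values on
    every call.  Returns max over checked elements of
    |g_ad - g_fd| / max(1e-8, |g_ad| + |g_fd|).
    """
    params = list(params)
    loss = loss_fn()
    for p in params:
        p.grad = None
    loss.backward()
    analytic = [np.zeros_like(p.data) if p.grad is None else p.grad.copy() for p in params]
    worst = 0.0
    for p, ga in zip(params, analytic):
        flat = p.data.reshape(-1)
        idxs = np.arange(flat.size)
        if max_elems is not None and flat.size > max_elems:
            r = rng if rng is not None else np.random.default_rng(0)
            idxs = r.choice(flat.size, size=max_elems, replace=False)
        for i in idxs:
            orig = flat[i]
            flat[i] = orig + eps
            lp = loss_fn().item()
            flat[i] = orig - eps
            lm = loss_fn().item()
            flat[i] = orig
            gfd = (lp - lm) / (2 * eps)
            gai = ga.reshape(-1)[i]
            err = abs(gai - gfd) / max(1e-8, abs(gai) + abs(gfd))
            worst = max(worst, err)
    return worst
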