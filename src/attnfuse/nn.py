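"""Layer and optimizer primitives on top of :mod:`attnfuse.autodiff`."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv3d

__all__ = ["Module", "Linear", "Conv3d", "SGD", "seeded_rng"]


def seeded_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(int(seed) % (2**31))


class Module:
    """Tiny parameter container: anything whose attributes hold Tensors
    with ``requires_grad`` or nested Modules."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def visit(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    visit(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    visit(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    visit(v)

        visit(self)
        return params

    def named_parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}

        def visit(obj, prefix):
            if isinstance(obj, Tensor):
                if obj.requires_grad:
                    out[prefix] = obj
            elif isinstance(obj, Module):
                for k, v in vars(obj).items():
                    visit(v, f"{prefix}.{k}" if prefix else k)
            elif isinstance(obj, (list, tuple)):
                for i, v in enumerate(obj):
                    visit(v, f"{prefix}.{i}")
            elif isinstance(obj, dict):
                for k, v in obj.items():
                    visit(v, f"{prefix}.{k}")

        visit(self, "")
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.named_parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state mismatch on keys: {sorted(missing)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    scale = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, scale, size=shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        self.weight = Tensor(_glorot(rng, n_in, n_out, (n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv3d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride=(1, 1, 1),
                 padding=(0, 0, 0), rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel**3
        self.weight = Tensor(
            _glorot(rng, fan_in, c_out, (c_out, c_in, kernel, kernel, kernel)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = tuple(stride)
        self.padding = tuple(padding)

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class SGD:
    """SGD with classical momentum and decoupled-from-nothing L2 weight decay
    (the decay term is added to the raw gradient inside the step, i.e. an L2
    penalty)."""

    def __init__(self, params: list[Tensor], lr: float = 0.01, momentum: float = 0.9,
                 weight_decay: float = 1e-4, clip_norm: float | None = 5.0):
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self.clip_norm = clip_norm
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else float(lr)
        scale = 1.0
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((p.grad**2).sum())
                                for p in self.params if p.grad is not None))
            if total > self.clip_norm:
                scale = self.clip_norm / total
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = scale * p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None
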