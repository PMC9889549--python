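"""Disease-oriented decoder: a learnable classification query attends to the
two fused modality matrices through two parallel multi-head attention layers;
the summed outputs pass through a fully connected layer to K class logits.

The multi-head attention follows the standard transformer formulation
(per-head projections, 1/sqrt(d_head) scaling, output projection).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, softmax
from .nn import Linear, Module

__all__ = [
    "MHAParams",
    "Prediction",
    "multi_head_attention",
    "decode",
    "cross_entropy_loss",
    "MultiHeadAttention",
    "DecoderHead",
]


@dataclass
class MHAParams:
    """Projection matrices for one multi-head attention layer; all (C, C),
    biases (C,) and zero by default."""

    w_query: np.ndarray
    w_key: np.ndarray
    w_value: np.ndarray
    w_out: np.ndarray
    b_query: np.ndarray | None = None
    b_key: np.ndarray | None = None
    b_value: np.ndarray | None = None
    b_out: np.ndarray | None = None

    def __post_init__(self):
        c = self.w_query.shape[0]
        for name in ("b_query", "b_key", "b_value", "b_out"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(c))

    @classmethod
    def random(cls, c: int, rng: np.random.Generator) -> "MHAParams":
        scale = 1.0 / np.sqrt(c)
        return cls(*(rng.normal(0, scale, size=(c, c)) for _ in range(4)))


@dataclass
class Prediction:
    """Class probabilities (softmax of the logits); probs sum to 1."""

    probs: np.ndarray
    logits: np.ndarray


def _check_heads(c: int, n_heads: int):
    if n_heads < 1:
        raise ValueError(f"n_heads must be >= 1, got {n_heads}")
    if c % n_heads != 0:
        raise ValueError(
            f"channel count C={c} is not divisible by n_heads={n_heads}"
        )


def _split_heads(x: Tensor, n_heads: int) -> Tensor:
    """(..., T, C) -> (..., heads, T, C/heads)"""
    *lead, t, c = x.shape
    x = x.reshape(*lead, t, n_heads, c // n_heads)
    return x.swapaxes(-2, -3)


def _merge_heads(x: Tensor) -> Tensor:
    """(..., heads, T, d) -> (..., T, heads*d)"""
    x = x.swapaxes(-2, -3)
    *lead, t, h, d = x.shape
    return x.reshape(*lead, t, h * d)


def multi_head_attention_tensor(query: Tensor, keys: Tensor, values: Tensor,
                                n_heads: int, params) -> Tensor:
    """query (..., K, C); keys/values (..., D', C) -> (..., K, C)."""
    c = query.shape[-1]
    _check_heads(c, n_heads)

    def t(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    q = _split_heads(query @ t(params.w_query) + t(params.b_query), n_heads)
    k = _split_heads(keys @ t(params.w_key) + t(params.b_key), n_heads)
    v = _split_heads(values @ t(params.w_value) + t(params.b_value), n_heads)
    logits = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(c // n_heads))
    att = softmax(logits, axis=-1)
    out = _merge_heads(att @ v)
    return out @ t(params.w_out) + t(params.b_out)


def multi_head_attention(query: np.ndarray, keys: np.ndarray, values: np.ndarray,
                         n_heads: int, params: MHAParams) -> np.ndarray:
    """Functional multi-head attention on plain arrays (K,C) x (D',C)."""
    out = multi_head_attention_tensor(Tensor(query), Tensor(keys), Tensor(values),
                                      n_heads, params)
    return out.data


def _softmax_np(x: np.ndarray, axis=-1) -> np.ndarray:
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def decode(fused, x_d: np.ndarray, params_m: MHAParams, params_s: MHAParams,
           w_fc: np.ndarray, b_fc: np.ndarray, n_heads: int = 6) -> Prediction:
    """Run the decoder on a fused representation.

    out = MHA(X_d, M, M) + MHA(X_d, S, S); logits = FC(flatten(out));
    probabilities by softmax.  X_d is (K, C); w_fc maps K*C -> K.
    """
    k, c = x_d.shape
    if w_fc.shape != (k * c, k):
        raise ValueError(
            f"FC weight must be ({k * c},{k}) for K={k} classes, got {w_fc.shape}"
        )
    out = (multi_head_attention(x_d, fused.M, fused.M, n_heads, params_m)
           + multi_head_attention(x_d, fused.S, fused.S, n_heads, params_s))
    logits = out.reshape(-1) @ w_fc + b_fc
    return Prediction(probs=_softmax_np(logits), logits=logits)


def cross_entropy_loss(pred, label: int) -> float:
    """Negative log-probability of the true class."""
    probs = pred.probs if isinstance(pred, Prediction) else np.asarray(pred, dtype=float)
    k = probs.shape[-1]
    label = int(label)
    if not 0 <= label < k:
        raise ValueError(f"label {label} out of range [0,{k})")
    return float(-np.log(probs[..., label]))


# ---------------------------------------------------------------------------
# trainable layers


class MultiHeadAttention(Module):
    def __init__(self, c: int, n_heads: int, rng: np.random.Generator):
        _check_heads(c, n_heads)
        scale = 1.0 / np.sqrt(c)
        self.w_query = Tensor(rng.normal(0, scale, (c, c)), requires_grad=True)
        self.w_key = Tensor(rng.normal(0, scale, (c, c)), requires_grad=True)
        self.w_value = Tensor(rng.normal(0, scale, (c, c)), requires_grad=True)
        self.w_out = Tensor(rng.normal(0, scale, (c, c)), requires_grad=True)
        self.b_query = Tensor(np.zeros(c), requires_grad=True)
        self.b_key = Tensor(np.zeros(c), requires_grad=True)
        self.b_value = Tensor(np.zeros(c), requires_grad=True)
        self.b_out = Tensor(np.zeros(c), requires_grad=True)
        self.n_heads = n_heads

    def __call__(self, query: Tensor, keys: Tensor, values: Tensor) -> Tensor:
        return multi_head_attention_tensor(query, keys, values, self.n_heads, self)


class DecoderHead(Module):
    """Learnable classification query + two parallel MHA layers + FC.

    When ``single_stream`` the head expects only one modality matrix and
    uses one MHA layer (the image-only / record-only model variants).
    """

    def __init__(self, n_classes: int, c: int, n_heads: int,
                 rng: np.random.Generator, single_stream: bool = False):
        self.x_d = Tensor(rng.normal(0, 0.1, (n_classes, c)), requires_grad=True)
        self.mha_m = MultiHeadAttention(c, n_heads, rng)
        self.mha_s = None if single_stream else MultiHeadAttention(c, n_heads, rng)
        self.fc = Linear(n_classes * c, n_classes, rng)
        self.n_classes = n_classes

    def __call__(self, m: Tensor | None, s: Tensor | None) -> Tensor:
        """m, s: (N, D', C) (either may be None in single-stream mode);
        returns logits (N, K)."""
        ref = m if m is not None else s
        n = ref.shape[0]
        query = self.x_d.reshape(1, *self.x_d.shape).broadcast_to((n, *self.x_d.shape))
        if m is not None and self.mha_s is not None and s is not None:
            out = self.mha_m(query, m, m) + self.mha_s(query, s, s)
        elif m is not None:
            out = self.mha_m(query, m, m)
        else:
            out = self.mha_m(query, s, s)
        return self.fc(out.reshape(n, -1))
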