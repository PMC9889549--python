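"""Intra-modal encoder: spatial and temporal self-attention over a volume's
feature map, and the fully connected embedding of the clinical-record vector.

Spatial attention relates the H'*W' positions within each slice of the
feature map; temporal attention relates the D' slices at each spatial
position ("temporal" meaning along the slice/depth axis of the acquisition,
not clock time).  Both use unscaled dot-product logits by default, with an
optional 1/sqrt(C) scaling behind the ``scaled`` flag.  Keys, queries,
values and the output projection are 1x1x1 convolutions, i.e. channel-mixing
matrices applied independently at each position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, softmax
from .nn import Linear, Module

__all__ = [
    "SelfAttentionParams",
    "EHREmbedParams",
    "SliceRepresentations",
    "spatial_attention",
    "temporal_attention",
    "combine_attention_streams",
    "embed_ehr",
    "SpatialAttention",
    "TemporalAttention",
    "EHREmbedding",
]


@dataclass
class SelfAttentionParams:
    """Projection weights for one self-attention block.

    Each w_* is (C, C); each b_* is (C,).  These are the 1x1x1 convolution
    filters producing key, query, value and the final output map.
    """

    w_key: np.ndarray
    w_query: np.ndarray
    w_value: np.ndarray
    w_out: np.ndarray
    b_key: np.ndarray | None = None
    b_query: np.ndarray | None = None
    b_value: np.ndarray | None = None
    b_out: np.ndarray | None = None

    def __post_init__(self):
        c = self.w_key.shape[0]
        for name in ("w_key", "w_query", "w_value", "w_out"):
            w = getattr(self, name)
            if w.shape != (c, c):
                raise ValueError(f"{name} must be ({c},{c}), got {w.shape}")
        for name in ("b_key", "b_query", "b_value", "b_out"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(c))

    @classmethod
    def random(cls, c: int, rng: np.random.Generator) -> "SelfAttentionParams":
        scale = 1.0 / np.sqrt(c)
        return cls(*(rng.normal(0, scale, size=(c, c)) for _ in range(4)))


@dataclass
class EHREmbedParams:
    weight: np.ndarray  # (F, C)
    bias: np.ndarray | None = None

    def __post_init__(self):
        if self.bias is None:
            self.bias = np.zeros(self.weight.shape[1])


@dataclass
class SliceRepresentations:
    """Per-slice disease representations for the two modalities.

    image_maps and ehr_maps are (D', C, H', W') and must agree in shape.
    """

    image_maps: np.ndarray
    ehr_maps: np.ndarray

    def __post_init__(self):
        if self.image_maps.shape != self.ehr_maps.shape:
            raise ValueError(
                f"modality shape mismatch: {self.image_maps.shape} vs {self.ehr_maps.shape}"
            )


def _check_finite(fm: np.ndarray, what: str):
    if not np.all(np.isfinite(fm)):
        raise ValueError(f"{what} contains non-finite values")


def _t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _attend(x: Tensor, params, scaled: bool):
    """Self-attention over the second-to-last axis of x (..., T, C).

    Returns (output (..., T, C) before the final projection, weights (..., T, T)).
    Row j of the weight matrix holds softmax_i of K(v_i)^T Q(v_j).
    """
    k = x @ _t(params.w_key) + _t(params.b_key)
    q = x @ _t(params.w_query) + _t(params.b_query)
    v = x @ _t(params.w_value) + _t(params.b_value)
    logits = q @ k.swapaxes(-1, -2)  # [..., j, i] = Q_j . K_i
    if scaled:
        logits = logits * (1.0 / np.sqrt(x.shape[-1]))
    weights = softmax(logits, axis=-1)
    return weights @ v, weights


def spatial_attention_tensor(x: Tensor, params, scaled: bool = False):
    """x: (N, D', P, C) with P = H'*W'.  Attends over P within each slice."""
    out, weights = _attend(x, params, scaled)
    out = out @ _t(params.w_out) + _t(params.b_out)
    return out, weights


def temporal_attention_tensor(x: Tensor, params, scaled: bool = False):
    """x: (N, D', P, C).  Attends over D' at each spatial position."""
    xt = x.swapaxes(1, 2)  # (N, P, D', C)
    out, weights = _attend(xt, params, scaled)
    out = out @ _t(params.w_out) + _t(params.b_out)
    return out.swapaxes(1, 2), weights


def _fm_to_ndpc(fm: np.ndarray) -> np.ndarray:
    c, d, h, w = fm.shape
    return fm.reshape(c, d, h * w).transpose(1, 2, 0)[None]  # (1, D', P, C)


def _ndpc_to_fm(x: np.ndarray, shape) -> np.ndarray:
    c, d, h, w = shape
    return x[0].transpose(2, 0, 1).reshape(c, d, h, w)


def spatial_attention(fm: np.ndarray, params: SelfAttentionParams,
                      scaled: bool = False, return_weights: bool = False):
    """Spatial self-attention on a feature map (C, D', H', W').

    Per slice d, the attention weight of position i on position j is
    softmax_i(K(v_i)^T Q(v_j)); the output at j is the weighted sum of
    V(v_i), passed through the output 1x1x1 convolution.  Output shape
    equals input shape.  If return_weights, also returns the (D', P, P)
    row-stochastic weight array.
    """
    _check_finite(fm, "feature map")
    out, weights = spatial_attention_tensor(Tensor(_fm_to_ndpc(fm)), params, scaled)
    result = _ndpc_to_fm(out.data, fm.shape)
    if return_weights:
        return result, weights.data[0]
    return result


def temporal_attention(fm: np.ndarray, params: SelfAttentionParams,
                       scaled: bool = False, return_weights: bool = False):
    """Temporal (inter-slice) self-attention on a feature map (C, D', H', W').

    At each spatial position, slices attend over the depth axis; weight
    matrix rows are softmax-normalized over the attended slice index.
    If return_weights, also returns the (P, D', D') weight array.
    """
    _check_finite(fm, "feature map")
    out, weights = temporal_attention_tensor(Tensor(_fm_to_ndpc(fm)), params, scaled)
    result = _ndpc_to_fm(out.data, fm.shape)
    if return_weights:
        return result, weights.data[0]
    return result


def combine_attention_streams(ms: np.ndarray, mt: np.ndarray) -> np.ndarray:
    """Sum the spatial- and temporal-attention outputs elementwise."""
    if ms.shape != mt.shape:
        raise ValueError(f"shape mismatch: {ms.shape} vs {mt.shape}")
    return ms + mt


def embed_ehr(ehr: np.ndarray, params: EHREmbedParams, d: int, h: int, w: int) -> np.ndarray:
    """Affine embedding of a clinical-record vector into C channels,
    broadcast across the (H', W') grid and replicated over D' slices
    (all slices share the weights)."""
    ehr = np.asarray(ehr, dtype=float)
    if ehr.shape[-1] != params.weight.shape[0]:
        raise ValueError(
            f"EHR length {ehr.shape[-1]} does not match embedding input {params.weight.shape[0]}"
        )
    vec = ehr @ params.weight + params.bias  # (C,)
    return np.broadcast_to(vec[None, :, None, None], (d, len(vec), h, w)).copy()


# ---------------------------------------------------------------------------
# trainable layer wrappers


class _SelfAttentionLayer(Module):
    def __init__(self, c: int, rng: np.random.Generator, scaled: bool = False):
        scale = 1.0 / np.sqrt(c)
        self.w_key = Tensor(rng.normal(0, scale, (c, c)), requires_grad=True)
        self.w_query = Tensor(rng.normal(0, scale, (c, c)), requires_grad=True)
        self.w_value = Tensor(rng.normal(0, scale, (c, c)), requires_grad=True)
        self.w_out = Tensor(rng.normal(0, scale, (c, c)), requires_grad=True)
        self.b_key = Tensor(np.zeros(c), requires_grad=True)
        self.b_query = Tensor(np.zeros(c), requires_grad=True)
        self.b_value = Tensor(np.zeros(c), requires_grad=True)
        self.b_out = Tensor(np.zeros(c), requires_grad=True)
        self.scaled = scaled

    def _params(self):
        class _P:
            pass

        p = _P()
        for name in ("w_key", "w_query", "w_value", "w_out",
                     "b_key", "b_query", "b_value", "b_out"):
            setattr(p, name, getattr(self, name))
        return p


class SpatialAttention(_SelfAttentionLayer):
    def __call__(self, x: Tensor):
        return spatial_attention_tensor(x, self._params(), self.scaled)


class TemporalAttention(_SelfAttentionLayer):
    def __call__(self, x: Tensor):
        return temporal_attention_tensor(x, self._params(), self.scaled)


class EHREmbedding(Module):
    """Fully connected layer embedding the F clinical features into C channels."""

    def __init__(self, n_features: int, c: int, rng: np.random.Generator):
        self.linear = Linear(n_features, c, rng)

    def __call__(self, ehr: Tensor, d: int, p: int) -> Tensor:
        vec = self.linear(ehr)  # (N, C)
        n, c = vec.shape
        return vec.reshape(n, 1, 1, c).broadcast_to((n, d, p, c))
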