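"""Inter-modal encoder: cross-attention between the image and clinical-record
slice representations via an affinity + aggregation pair, then compression to
the (D', C) matrices consumed by the decoder.

For each slice, two cross-attention modules run in parallel: each modality
queries with its own projection while keys and values come from the opposite
modality.  The affinity operation scores a query position against a
candidate set of key positions; aggregation forms the attention-weighted sum
of value vectors and adds the local (residual) representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, softmax
from .intra import SliceRepresentations, _t
from .nn import Module

__all__ = [
    "AffinityMap",
    "FusedRepresentation",
    "CrossAttentionParams",
    "affinity",
    "aggregate",
    "cross_attention_block",
    "compress",
    "CrossAttention",
]

CANDIDATE_MODES = ("exclude_self", "include_self", "criss_cross")

#: logit penalty that underflows to exactly 0 after the softmax exp
_MASK = -1e30


@dataclass
class AffinityMap:
    """Row-stochastic cross-attention weights.

    values is (P, P); entry [j, i] is the weight of candidate position i on
    query position j.  Positions outside the candidate set carry weight 0,
    and each row sums to 1 over its candidates.
    """

    values: np.ndarray
    mode: str = "exclude_self"


@dataclass
class FusedRepresentation:
    """Compressed per-modality matrices entering the decoder: both (D', C)."""

    M: np.ndarray
    S: np.ndarray

    def __post_init__(self):
        if self.M.shape != self.S.shape:
            raise ValueError(f"M/S shape mismatch: {self.M.shape} vs {self.S.shape}")
        if not (np.all(np.isfinite(self.M)) and np.all(np.isfinite(self.S))):
            raise ValueError("fused representation contains non-finite values")


def candidate_mask(p: int, h: int, w: int, mode: str) -> np.ndarray:
    """Additive logit mask (P, P): 0 on candidates, a large negative value
    elsewhere.  ``criss_cross`` keeps positions sharing a row or column with
    the query on the (h, w) grid, excluding the query itself."""
    if mode not in CANDIDATE_MODES:
        raise ValueError(f"unknown candidate mode {mode!r}; use one of {CANDIDATE_MODES}")
    if mode == "include_self":
        return np.zeros((p, p))
    if p == 1:
        raise ValueError(
            "a 1x1 grid leaves the self-excluding candidate set empty; "
            "use candidate mode 'include_self'"
        )
    if mode == "exclude_self":
        mask = np.zeros((p, p))
        np.fill_diagonal(mask, _MASK)
        return mask
    rows, cols = np.divmod(np.arange(p), w)
    same_row = rows[:, None] == rows[None, :]
    same_col = cols[:, None] == cols[None, :]
    allowed = (same_row | same_col) & ~np.eye(p, dtype=bool)
    return np.where(allowed, 0.0, _MASK)


def affinity(q_map: np.ndarray, k_map: np.ndarray, mode: str = "exclude_self") -> AffinityMap:
    """Affinity + softmax between two projected maps (C, H', W').

    For each position j, logits are the inner products of Q_j with every
    candidate key vector; the candidate set defaults to all positions except
    j itself.  Returns the row-softmaxed attention map A.
    """
    if q_map.shape != k_map.shape:
        raise ValueError(f"shape mismatch: {q_map.shape} vs {k_map.shape}")
    c, h, w = q_map.shape
    p = h * w
    q = q_map.reshape(c, p).T  # (P, C)
    k = k_map.reshape(c, p).T
    logits = q @ k.T + candidate_mask(p, h, w, mode)
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return AffinityMap(e / e.sum(axis=-1, keepdims=True), mode=mode)


def aggregate(a: AffinityMap | np.ndarray, v_map: np.ndarray, h_map: np.ndarray) -> np.ndarray:
    """Attention-weighted sum of value vectors plus the local residual.

    Output at position j is sum_i A[j, i] * V_i + H_j, where H is the raw
    (pre-projection) local representation of the querying modality.
    """
    a_values = a.values if isinstance(a, AffinityMap) else np.asarray(a, dtype=float)
    if v_map.shape != h_map.shape:
        raise ValueError(f"shape mismatch: {v_map.shape} vs {h_map.shape}")
    c, h, w = v_map.shape
    p = h * w
    if a_values.shape != (p, p):
        raise ValueError(f"attention map must be ({p},{p}), got {a_values.shape}")
    v = v_map.reshape(c, p)
    out = v @ a_values.T + h_map.reshape(c, p)
    return out.reshape(c, h, w)


@dataclass
class CrossAttentionParams:
    """One direction of cross-attention: query from the querying modality,
    key and value from the opposite modality.  All (C, C)."""

    w_query: np.ndarray
    w_key: np.ndarray
    w_value: np.ndarray

    @classmethod
    def random(cls, c: int, rng: np.random.Generator) -> "CrossAttentionParams":
        scale = 1.0 / np.sqrt(c)
        return cls(*(rng.normal(0, scale, size=(c, c)) for _ in range(3)))


def _project(fm: np.ndarray, w: np.ndarray) -> np.ndarray:
    c, h, wd = fm.shape
    return (fm.reshape(c, -1).T @ w).T.reshape(w.shape[1], h, wd)


def cross_attention_block(reps: SliceRepresentations, t: int,
                          params_m: CrossAttentionParams,
                          params_s: CrossAttentionParams,
                          mode: str = "exclude_self"):
    """Cross-attend slice t of the two modalities; returns (M'_t, S'_t).

    M'_t aggregates values projected from the EHR map under affinities
    between the image query and EHR key, with M_t as residual; S'_t is the
    mirror image with the roles of the modalities swapped.
    """
    m_t = reps.image_maps[t]  # (C, H', W')
    s_t = reps.ehr_maps[t]
    a_m = affinity(_project(m_t, params_m.w_query), _project(s_t, params_m.w_key), mode)
    m_new = aggregate(a_m, _project(s_t, params_m.w_value), m_t)
    a_s = affinity(_project(s_t, params_s.w_query), _project(m_t, params_s.w_key), mode)
    s_new = aggregate(a_s, _project(m_t, params_s.w_value), s_t)
    return m_new, s_new


def compress(m_slices, s_slices) -> FusedRepresentation:
    """Spatially average-pool each per-slice map (C, H', W') to a C-vector
    and stack over slices, yielding the decoder inputs M, S of shape (D', C)."""
    m_slices = list(m_slices)
    s_slices = list(s_slices)
    if not m_slices or not s_slices:
        raise ValueError("compress requires at least one slice per modality")
    m = np.stack([np.asarray(x).reshape(x.shape[0], -1).mean(axis=1) for x in m_slices])
    s = np.stack([np.asarray(x).reshape(x.shape[0], -1).mean(axis=1) for x in s_slices])
    return FusedRepresentation(M=m, S=s)


# ---------------------------------------------------------------------------
# trainable batched layer


class CrossAttention(Module):
    """Batched bidirectional cross-attention over (N, D', P, C) tensors."""

    def __init__(self, c: int, rng: np.random.Generator, mode: str = "exclude_self",
                 scaled: bool = False):
        scale = 1.0 / np.sqrt(c)
        self.scaled = scaled
        self.wq_m = Tensor(rng.normal(0, scale, (c, c)), requires_grad=True)
        self.wk_m = Tensor(rng.normal(0, scale, (c, c)), requires_grad=True)
        self.wv_m = Tensor(rng.normal(0, scale, (c, c)), requires_grad=True)
        self.wq_s = Tensor(rng.normal(0, scale, (c, c)), requires_grad=True)
        self.wk_s = Tensor(rng.normal(0, scale, (c, c)), requires_grad=True)
        self.wv_s = Tensor(rng.normal(0, scale, (c, c)), requires_grad=True)
        self.mode = mode

    def __call__(self, m: Tensor, s: Tensor, grid_hw: tuple[int, int]):
        p = m.shape[2]
        mask = Tensor(candidate_mask(p, *grid_hw, self.mode))
        gain = 1.0 / np.sqrt(m.shape[-1]) if self.scaled else 1.0
        a_m = softmax((m @ self.wq_m) @ (s @ self.wk_m).swapaxes(-1, -2) * gain + mask, axis=-1)
        m_new = a_m @ (s @ self.wv_m) + m
        a_s = softmax((s @ self.wq_s) @ (m @ self.wk_s).swapaxes(-1, -2) * gain + mask, axis=-1)
        s_new = a_s @ (m @ self.wv_s) + s
        return m_new, s_new, (a_m, a_s)
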