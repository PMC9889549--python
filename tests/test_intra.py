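"""Spatial/temporal self-attention against brute-force loop oracles, plus the
structural identities of the intra-modal encoder."""

import numpy as np
import pytest

from attnfuse.intra import (EHREmbedParams, SelfAttentionParams, SliceRepresentations,
                            combine_attention_streams, embed_ehr, spatial_attention,
                            temporal_attention)


def softmax_np(x):
    e = np.exp(x - x.max())
    return e / e.sum()


def spatial_oracle(fm, p):
    """Triple loop over (slice, query position, key position) per Eqs-style
    definition: weights softmax_i(K(v_i).Q(v_j)), output projected by w_out."""
    c, d, h, w = fm.shape
    hw = h * w
    out = np.zeros_like(fm)
    weights = np.zeros((d, hw, hw))
    for t in range(d):
        v = fm[:, t].reshape(c, hw)  # (C, P)
        k = p.w_key.T @ v + p.b_key[:, None]
        q = p.w_query.T @ v + p.b_query[:, None]
        val = p.w_value.T @ v + p.b_value[:, None]
        pre = np.zeros((c, hw))
        for j in range(hw):
            logits = np.array([k[:, i] @ q[:, j] for i in range(hw)])
            wrow = softmax_np(logits)
            weights[t, j] = wrow
            pre[:, j] = sum(wrow[i] * val[:, i] for i in range(hw))
        out[:, t] = (p.w_out.T @ pre + p.b_out[:, None]).reshape(c, h, w)
    return out, weights


def temporal_oracle(fm, p):
    c, d, h, w = fm.shape
    hw = h * w
    flat = fm.reshape(c, d, hw)
    out = np.zeros_like(flat)
    weights = np.zeros((hw, d, d))
    for pos in range(hw):
        v = flat[:, :, pos]  # (C, D)
        k = p.w_key.T @ v + p.b_key[:, None]
        q = p.w_query.T @ v + p.b_query[:, None]
        val = p.w_value.T @ v + p.b_value[:, None]
        pre = np.zeros((c, d))
        for j in range(d):
            logits = np.array([k[:, i] @ q[:, j] for i in range(d)])
            wrow = softmax_np(logits)
            weights[pos, j] = wrow
            pre[:, j] = sum(wrow[i] * val[:, i] for i in range(d))
        out[:, :, pos] = p.w_out.T @ pre + p.b_out[:, None]
    return out.reshape(c, d, h, w), weights


@pytest.mark.parametrize("shape", [(4, 2, 3, 3), (3, 1, 2, 4), (2, 3, 1, 2), (4, 4, 2, 2)])
def test_spatial_attention_matches_loop_oracle(shape, rng):
    for _ in range(5):
        fm = rng.normal(size=shape)
        p = SelfAttentionParams.random(shape[0], rng)
        got, weights = spatial_attention(fm, p, return_weights=True)
        want, w_want = spatial_oracle(fm, p)
        assert np.abs(got - want).max() <= 1e-5
        assert np.abs(weights - w_want).max() <= 1e-5
        assert np.allclose(weights.sum(axis=-1), 1.0, atol=1e-5)
        assert np.all(weights >= 0)


@pytest.mark.parametrize("shape", [(4, 3, 2, 2), (3, 2, 3, 1), (2, 4, 2, 2), (4, 1, 2, 3)])
def test_temporal_attention_matches_loop_oracle(shape, rng):
    for _ in range(5):
        fm = rng.normal(size=shape)
        p = SelfAttentionParams.random(shape[0], rng)
        got, weights = temporal_attention(fm, p, return_weights=True)
        want, w_want = temporal_oracle(fm, p)
        assert np.abs(got - want).max() <= 1e-5
        assert np.abs(weights - w_want).max() <= 1e-5
        assert np.allclose(weights.sum(axis=-1), 1.0, atol=1e-5)


def test_single_position_spatial_attention_is_identity_weight(rng):
    """On a 1x1 grid, the softmax over a single logit is exactly [[1.0]] and
    the pre-projection output equals V(v)."""
    c = 3
    fm = rng.normal(size=(c, 2, 1, 1))
    p = SelfAttentionParams.random(c, rng)
    p_id = SelfAttentionParams(p.w_key, p.w_query, p.w_value, np.eye(c))
    got, weights = spatial_attention(fm, p_id, return_weights=True)
    assert np.allclose(weights, 1.0)
    v = np.einsum("cf,cdhw->fdhw", p_id.w_value, fm)
    assert np.allclose(got, v, atol=1e-12)


def test_single_slice_temporal_attention_is_identity_weight(rng):
    c = 4
    fm = rng.normal(size=(c, 1, 2, 2))
    p = SelfAttentionParams.random(c, rng)
    p_id = SelfAttentionParams(p.w_key, p.w_query, p.w_value, np.eye(c))
    got, weights = temporal_attention(fm, p_id, return_weights=True)
    assert np.allclose(weights, 1.0)
    v = np.einsum("cf,cdhw->fdhw", p_id.w_value, fm)
    assert np.allclose(got, v, atol=1e-12)


def test_temporal_attention_depth_permutation_equivariance(rng):
    """No positional encoding: permuting slices permutes the output."""
    fm = rng.normal(size=(3, 5, 2, 2))
    p = SelfAttentionParams.random(3, rng)
    perm = np.array([3, 0, 4, 1, 2])
    out_perm = temporal_attention(fm[:, perm], p)
    out = temporal_attention(fm, p)
    assert np.allclose(out_perm, out[:, perm], atol=1e-10)


def test_scaled_mode_divides_logits(rng):
    """The opt-in scaled mode equals the default applied to K/sqrt(C)."""
    fm = rng.normal(size=(4, 2, 2, 2))
    p = SelfAttentionParams.random(4, rng)
    scaled = spatial_attention(fm, p, scaled=True)
    p_div = SelfAttentionParams(p.w_key / np.sqrt(4), p.w_query, p.w_value, p.w_out,
                                p.b_key / np.sqrt(4))
    assert np.allclose(scaled, spatial_attention(fm, p_div), atol=1e-10)


def test_combine_attention_streams(rng):
    a = rng.normal(size=(2, 3, 2, 2))
    b = rng.normal(size=(2, 3, 2, 2))
    assert np.array_equal(combine_attention_streams(a, np.zeros_like(a)), a)
    assert np.array_equal(combine_attention_streams(a, b), combine_attention_streams(b, a))
    assert np.allclose(combine_attention_streams(a, b), a + b)
    with pytest.raises(ValueError, match="shape"):
        combine_attention_streams(a, b[:, :2])


def test_non_finite_feature_map_rejected(rng):
    fm = rng.normal(size=(2, 2, 2, 2))
    fm[0, 0, 0, 0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        spatial_attention(fm, SelfAttentionParams.random(2, rng))


class TestEmbedEHR:
    def test_zero_vector_zero_bias_gives_zeros(self):
        p = EHREmbedParams(np.ones((3, 2)))
        out = embed_ehr(np.zeros(3), p, d=2, h=2, w=2)
        assert out.shape == (2, 2, 2, 2)
        assert np.all(out == 0)

    def test_identity_weight_broadcasts_vector(self):
        p = EHREmbedParams(np.eye(2))
        out = embed_ehr(np.array([1.0, 0.0]), p, d=3, h=2, w=2)
        assert np.all(out[:, 0] == 1.0) and np.all(out[:, 1] == 0.0)

    def test_linearity_without_bias(self, rng):
        p = EHREmbedParams(rng.normal(size=(4, 3)))
        a, b = rng.normal(size=4), rng.normal(size=4)
        assert np.allclose(embed_ehr(a + b, p, 2, 2, 2),
                           embed_ehr(a, p, 2, 2, 2) + embed_ehr(b, p, 2, 2, 2))

    def test_feature_length_mismatch(self, rng):
        p = EHREmbedParams(rng.normal(size=(4, 3)))
        with pytest.raises(ValueError, match="does not match"):
            embed_ehr(np.zeros(5), p, 1, 1, 1)


def test_slice_representations_shape_invariant(rng):
    with pytest.raises(ValueError, match="mismatch"):
        SliceRepresentations(rng.normal(size=(2, 3, 2, 2)), rng.normal(size=(2, 3, 2, 1)))
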