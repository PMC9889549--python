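"""Cross-attention affinity/aggregation against loop oracles and the
structural identities of the inter-modal encoder."""

import numpy as np
import pytest

from attnfuse.autodiff import Tensor
from attnfuse.cross import (AffinityMap, CrossAttention, CrossAttentionParams,
                            FusedRepresentation, affinity, aggregate, compress,
                            cross_attention_block)
from attnfuse.intra import SliceRepresentations


def affinity_oracle(q_map, k_map):
    """Per-position loop: logits of Q_j against every candidate i != j."""
    c, h, w = q_map.shape
    p = h * w
    q = q_map.reshape(c, p)
    k = k_map.reshape(c, p)
    out = np.zeros((p, p))
    for j in range(p):
        cands = [i for i in range(p) if i != j]
        logits = np.array([q[:, j] @ k[:, i] for i in cands])
        e = np.exp(logits - logits.max())
        out[j, cands] = e / e.sum()
    return out


@pytest.mark.parametrize("hw", [(2, 2), (3, 3), (1, 4), (3, 2)])
def test_affinity_matches_loop_oracle(hw, rng):
    h, w = hw
    for _ in range(5):
        q = rng.normal(size=(3, h, w))
        k = rng.normal(size=(3, h, w))
        a = affinity(q, k)
        assert np.abs(a.values - affinity_oracle(q, k)).max() <= 1e-5
        assert np.allclose(a.values.sum(axis=-1), 1.0, atol=1e-5)
        assert np.allclose(np.diag(a.values), 0.0)


def test_orthogonal_query_gives_uniform_rows():
    """Zero logits on every candidate: each row is 1/(H*W - 1)."""
    q = np.zeros((2, 2, 2))
    k = np.ones((2, 2, 2))
    a = affinity(q, k)
    off_diag = a.values[~np.eye(4, dtype=bool)]
    assert np.allclose(off_diag, 1.0 / 3.0)


def test_scaling_keys_sharpens_softmax(rng):
    q = rng.normal(size=(3, 2, 2))
    k = rng.normal(size=(3, 2, 2))
    prev_max = -np.inf
    for scale in [0.5, 1.0, 2.0, 4.0, 8.0]:
        a = affinity(q, k * scale)
        row_max = a.values.max(axis=-1).min()
        assert row_max >= prev_max - 1e-12
        prev_max = row_max


def test_single_position_grid_requires_self_inclusion():
    q = np.ones((2, 1, 1))
    with pytest.raises(ValueError, match="include_self"):
        affinity(q, q)
    a = affinity(q, q, mode="include_self")
    assert np.allclose(a.values, 1.0)


def test_criss_cross_mode_restricts_candidates(rng):
    q = rng.normal(size=(2, 3, 3))
    k = rng.normal(size=(2, 3, 3))
    a = affinity(q, k, mode="criss_cross").values
    rows, cols = np.divmod(np.arange(9), 3)
    allowed = (rows[:, None] == rows) | (cols[:, None] == cols)
    np.fill_diagonal(allowed, False)
    assert np.all(a[~allowed] == 0)
    assert np.allclose(a.sum(axis=-1), 1.0, atol=1e-5)


class TestAggregate:
    def test_zero_attention_returns_residual_exactly(self, rng):
        v = rng.normal(size=(3, 2, 2))
        h_map = rng.normal(size=(3, 2, 2))
        out = aggregate(np.zeros((4, 4)), v, h_map)
        assert np.array_equal(out, h_map)

    def test_one_hot_rows_select_value_vector(self, rng):
        v = rng.normal(size=(2, 2, 2))
        h_map = rng.normal(size=(2, 2, 2))
        a = np.zeros((4, 4))
        a[:, 2] = 1.0  # every position attends to position 2
        out = aggregate(a, v, h_map).reshape(2, 4)
        want = v.reshape(2, 4)[:, [2]] + h_map.reshape(2, 4)
        assert np.allclose(out, want)

    def test_matches_loop_oracle(self, rng):
        for _ in range(5):
            v = rng.normal(size=(3, 2, 2))
            h_map = rng.normal(size=(3, 2, 2))
            a = affinity(rng.normal(size=(3, 2, 2)), rng.normal(size=(3, 2, 2))).values
            got = aggregate(a, v, h_map).reshape(3, 4)
            vf, hf = v.reshape(3, 4), h_map.reshape(3, 4)
            want = np.array([sum(a[j, i] * vf[:, i] for i in range(4)) + hf[:, j]
                             for j in range(4)]).T
            assert np.abs(got - want).max() <= 1e-5

    def test_shape_checks(self, rng):
        with pytest.raises(ValueError, match="shape"):
            aggregate(np.zeros((4, 4)), rng.normal(size=(2, 2, 2)),
                      rng.normal(size=(2, 2, 1)))
        with pytest.raises(ValueError, match="attention map"):
            aggregate(np.zeros((3, 3)), rng.normal(size=(2, 2, 2)),
                      rng.normal(size=(2, 2, 2)))


def test_cross_attention_block_broadcast_ehr_gives_uniform_affinity(rng):
    """A spatially constant record map makes the image-query affinity rows
    constant, so M' is the uniform mean of the record values plus M."""
    c, h, w = 3, 2, 2
    m = rng.normal(size=(1, c, h, w))
    s = np.broadcast_to(rng.normal(size=(1, c, 1, 1)), (1, c, h, w)).copy()
    reps = SliceRepresentations(m, s)
    pm = CrossAttentionParams.random(c, rng)
    ps = CrossAttentionParams.random(c, rng)
    m_new, s_new = cross_attention_block(reps, 0, pm, ps)
    v_s = np.einsum("cf,chw->fhw", pm.w_value, s[0]).reshape(c, -1)
    want = v_s.mean(axis=1, keepdims=True) + m[0].reshape(c, -1)  # uniform pooling
    assert np.allclose(m_new.reshape(c, -1), want, atol=1e-10)


def test_cross_attention_block_zero_values_residual_only(rng):
    c = 3
    reps = SliceRepresentations(rng.normal(size=(2, c, 2, 2)),
                                rng.normal(size=(2, c, 2, 2)))
    zero = np.zeros((c, c))
    pm = CrossAttentionParams(rng.normal(size=(c, c)), rng.normal(size=(c, c)), zero)
    ps = CrossAttentionParams(rng.normal(size=(c, c)), rng.normal(size=(c, c)), zero)
    m_new, s_new = cross_attention_block(reps, 1, pm, ps)
    assert np.array_equal(m_new, reps.image_maps[1])
    assert np.array_equal(s_new, reps.ehr_maps[1])


def test_cross_attention_block_modality_swap_symmetry(rng):
    """Swapping the modality inputs together with the direction parameters
    swaps the outputs."""
    c = 3
    m = rng.normal(size=(1, c, 2, 2))
    s = rng.normal(size=(1, c, 2, 2))
    pm = CrossAttentionParams.random(c, rng)
    ps = CrossAttentionParams.random(c, rng)
    m1, s1 = cross_attention_block(SliceRepresentations(m, s), 0, pm, ps)
    s2, m2 = cross_attention_block(SliceRepresentations(s, m), 0, ps, pm)
    assert np.allclose(m1, m2, atol=1e-12)
    assert np.allclose(s1, s2, atol=1e-12)


def test_residual_dominance_as_values_shrink(rng):
    """As the V projections go to zero the block tends to the identity."""
    c = 4
    reps = SliceRepresentations(rng.normal(size=(1, c, 2, 2)),
                                rng.normal(size=(1, c, 2, 2)))
    pm = CrossAttentionParams.random(c, rng)
    ps = CrossAttentionParams.random(c, rng)
    pm_small = CrossAttentionParams(pm.w_query, pm.w_key, pm.w_value * 1e-3)
    ps_small = CrossAttentionParams(ps.w_query, ps.w_key, ps.w_value * 1e-3)
    m_new, s_new = cross_attention_block(reps, 0, pm_small, ps_small)
    assert np.abs(m_new - reps.image_maps[0]).max() <= 1e-2
    assert np.abs(s_new - reps.ehr_maps[0]).max() <= 1e-2


class TestCompress:
    def test_constant_map_pools_to_constant(self):
        m = [np.full((3, 2, 2), 1.5)]
        fused = compress(m, m)
        assert fused.M.shape == (1, 3)
        assert np.allclose(fused.M, 1.5)

    def test_pooled_values_match_mean_oracle(self, rng):
        m_slices = [rng.normal(size=(4, 3, 2)) for _ in range(3)]
        s_slices = [rng.normal(size=(4, 3, 2)) for _ in range(3)]
        fused = compress(m_slices, s_slices)
        for t in range(3):
            for c in range(4):
                assert abs(fused.M[t, c] - m_slices[t][c].mean()) <= 1e-6
                assert abs(fused.S[t, c] - s_slices[t][c].mean()) <= 1e-6

    @pytest.mark.parametrize("d,c", [(1, 2), (4, 5), (3, 1)])
    def test_output_shape(self, d, c, rng):
        slices = [rng.normal(size=(c, 2, 2)) for _ in range(d)]
        assert compress(slices, slices).M.shape == (d, c)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            compress([], [])


def test_batched_layer_matches_functional_block(rng):
    """The trainable batched cross-attention layer agrees with the
    per-slice functional implementation."""
    c, d, h, w = 3, 2, 2, 2
    layer = CrossAttention(c, rng)
    m = rng.normal(size=(1, d, h * w, c))
    s = rng.normal(size=(1, d, h * w, c))
    m_new, s_new, _ = layer(Tensor(m), Tensor(s), (h, w))
    pm = CrossAttentionParams(layer.wq_m.data, layer.wk_m.data, layer.wv_m.data)
    ps = CrossAttentionParams(layer.wq_s.data, layer.wk_s.data, layer.wv_s.data)
    for t in range(d):
        reps = SliceRepresentations(
            m[0].transpose(0, 2, 1).reshape(d, c, h, w),
            s[0].transpose(0, 2, 1).reshape(d, c, h, w))
        want_m, want_s = cross_attention_block(reps, t, pm, ps)
        got_m = m_new.data[0, t].T.reshape(c, h, w)
        got_s = s_new.data[0, t].T.reshape(c, h, w)
        assert np.abs(got_m - want_m).max() <= 1e-10
        assert np.abs(got_s - want_s).max() <= 1e-10


def test_fused_representation_invariants(rng):
    with pytest.raises(ValueError, match="mismatch"):
        FusedRepresentation(np.zeros((2, 3)), np.zeros((2, 4)))
    with pytest.raises(ValueError, match="non-finite"):
        FusedRepresentation(np.full((2, 2), np.nan), np.zeros((2, 2)))
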