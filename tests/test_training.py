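"""Training engine: LR schedule, normalization, fold splitting, determinism,
and the fusion-variant contracts."""

import numpy as np
import pytest
from dataclasses import replace

from attnfuse.autodiff import Tensor
from attnfuse.network import build_fusion_variant
from attnfuse.nn import SGD
from attnfuse.synthetic import SynthConfig, generate_dataset
from attnfuse.training import (TrainConfig, head_sweep, normalize_intensity,
                               poly_lr, stratified_kfold, train_model)

FAST = TrainConfig(epochs=2, batch_size=4, n_starts=1, seed=0)


class TestPolyLR:
    def test_initial_rate(self):
        assert poly_lr(0, 100) == 0.01

    def test_final_rate_is_zero(self):
        assert poly_lr(100, 100) == 0.0

    def test_midpoint_closed_form(self):
        # 0.01 * 0.5**0.9 = 0.005358867312681466
        assert poly_lr(50, 100, 0.01, 0.9) == pytest.approx(0.005358867312681466, abs=1e-15)

    def test_monotone_non_increasing(self):
        rates = [poly_lr(i, 200) for i in range(201)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_out_of_range_iteration_rejected(self):
        with pytest.raises(ValueError):
            poly_lr(101, 100)


class TestNormalizeIntensity:
    def test_linear_map(self):
        vol = np.array([[[2.0, 10.0, 6.0]]])
        out = normalize_intensity(vol)
        assert np.allclose(out, [[[0.0, 1.0, 0.5]]])

    def test_range_is_exactly_unit(self, rng):
        vol = rng.normal(size=(4, 5, 6)) * 100
        out = normalize_intensity(vol)
        assert out.min() == 0.0 and out.max() == 1.0

    def test_idempotent(self, rng):
        vol = rng.uniform(-5, 5, size=(3, 4, 4))
        once = normalize_intensity(vol)
        assert np.allclose(normalize_intensity(once), once)

    def test_constant_volume_maps_to_half_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = normalize_intensity(np.full((2, 2, 2), 7.0))
        assert np.all(out == 0.5)


class TestStratifiedKFold:
    def test_balanced_counts_60_3_5(self):
        labels = np.repeat([0, 1, 2], 20)
        assign = stratified_kfold(labels, 5, seed=0)
        for fold in range(5):
            idx = assign == fold
            assert idx.sum() == 12
            assert np.all(np.bincount(labels[idx], minlength=3) == 4)

    def test_exact_partition(self, rng):
        labels = rng.integers(0, 3, size=47)
        labels[:15] = np.arange(15) % 3  # ensure every class has >= 5
        assign = stratified_kfold(labels, 5, seed=1)
        assert assign.shape == (47,)
        assert set(assign) == set(range(5))

    def test_seed_reproducible(self, rng):
        labels = rng.integers(0, 2, size=40)
        a = stratified_kfold(labels, 4, seed=7)
        b = stratified_kfold(labels, 4, seed=7)
        assert np.array_equal(a, b)

    def test_class_smaller_than_folds_rejected(self):
        labels = np.array([0, 0, 0, 1, 1, 1, 1, 1])
        with pytest.raises(ValueError, match="smallest class"):
            stratified_kfold(labels, 5, seed=0)


class TestTrainModel:
    def test_same_seed_identical_loss_trace(self, tiny_dataset):
        _, a = train_model(tiny_dataset, FAST)
        _, b = train_model(tiny_dataset, FAST)
        assert np.abs(np.array(a.loss) - np.array(b.loss)).max() <= 1e-6
        assert a.lr == b.lr

    def test_lr_trace_matches_schedule(self, tiny_dataset):
        _, trace = train_model(tiny_dataset, FAST)
        total = len(trace.lr)
        want = [poly_lr(i, total, FAST.initial_lr, FAST.power) for i in range(total)]
        assert np.allclose(trace.lr, want)

    def test_weight_decay_changes_trace(self, tiny_dataset):
        _, a = train_model(tiny_dataset, FAST)
        _, b = train_model(tiny_dataset, replace(FAST, weight_decay=1e-10))
        assert np.abs(np.array(a.loss) - np.array(b.loss)).max() > 1e-7

    def test_predictions_roundtrip_through_serialization(self, tiny_dataset, tmp_path):
        model, _ = train_model(tiny_dataset, FAST)
        probs = model.predict_proba(tiny_dataset.volumes, tiny_dataset.ehr)
        model.save(tmp_path / "m.npz")

        fresh, _ = train_model(tiny_dataset, replace(FAST, seed=1))
        fresh.load_params(tmp_path / "m.npz")
        probs2 = fresh.predict_proba(tiny_dataset.volumes, tiny_dataset.ehr)
        assert np.allclose(probs, probs2, atol=1e-12)


class TestFusionVariants:
    @pytest.mark.parametrize("name", ["proposed", "early", "intermediate", "late",
                                      "image_only", "ehr_only"])
    def test_forward_returns_class_probabilities(self, name, tiny_dataset):
        net = build_fusion_variant(name, 2, tiny_dataset.ehr.shape[1],
                                   tiny_dataset.volumes.shape[1:], c=6, n_heads=2)
        probs = net.predict_proba(tiny_dataset.volumes[:3], tiny_dataset.ehr[:3])
        assert probs.shape == (3, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_unknown_variant_rejected(self):
        with pytest.raises(KeyError, match="unknown fusion variant"):
            build_fusion_variant("mid", 2, 4)

    def test_ehr_only_gradient_wrt_volume_is_zero(self, tiny_dataset):
        net = build_fusion_variant("ehr_only", 2, tiny_dataset.ehr.shape[1],
                                   tiny_dataset.volumes.shape[1:], c=6, n_heads=2)
        vol = Tensor(tiny_dataset.volumes[:2], requires_grad=True)
        logits = net.forward(vol, tiny_dataset.ehr[:2])
        (logits * logits).sum().backward()
        assert vol.grad is None or np.all(vol.grad == 0)

    def test_image_only_ignores_ehr_permutation(self, tiny_dataset):
        net = build_fusion_variant("image_only", 2, tiny_dataset.ehr.shape[1],
                                   tiny_dataset.volumes.shape[1:], c=6, n_heads=2)
        a = net.predict_proba(tiny_dataset.volumes, tiny_dataset.ehr)
        b = net.predict_proba(tiny_dataset.volumes, tiny_dataset.ehr[::-1])
        assert np.allclose(a, b)

    def test_ablation_flags_change_the_model(self, tiny_dataset):
        base = replace(FAST, sam=False, tam=False, cam=False)
        m0, t0 = train_model(tiny_dataset, base)
        m1, t1 = train_model(tiny_dataset, replace(base, cam=True))
        assert not np.allclose(t0.loss, t1.loss)


def test_head_sweep_reports_skipped_counts(tiny_dataset):
    cfg = replace(FAST, channels=6, epochs=1, n_folds=2, n_heads=2)
    table = head_sweep(tiny_dataset, [1, 2, 4], cfg)
    status = dict(zip(table.n_heads, table.status))
    assert status[1] == "ok" and status[2] == "ok"
    assert "not divisible" in status[4]
    ok = table[table.status == "ok"]
    assert ((ok.accuracy >= 0) & (ok.accuracy <= 1)).all()


def test_sgd_clip_norm_bounds_update():
    p = Tensor(np.zeros(3), requires_grad=True)
    p.grad = np.array([30.0, 0.0, 40.0])  # norm 50
    opt = SGD([p], momentum=0.0, weight_decay=0.0, clip_norm=5.0)
    opt.step(1.0)
    assert np.allclose(p.data, -np.array([3.0, 0.0, 4.0]))


def test_divergence_raises_with_diagnostics(tiny_dataset):
    cfg = replace(FAST, initial_lr=1e8, epochs=2, clip_norm=None)
    with pytest.raises(RuntimeError, match="diverged"):
        train_model(tiny_dataset, cfg)
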