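"""End-to-end networks: the proposed attention-fusion model and the
simplified comparison variants (single-modality, early / intermediate / late
fusion).

All variants share the same backbone family and record embedding so that
differences in performance reflect the fusion strategy, not capacity.
The component flags SAM (spatial attention), TAM (temporal attention) and
CAM (cross attention) switch the corresponding encoder blocks; a disabled
block is an identity pass-through, so the all-off configuration reduces to
the multi-head-attention decoder alone.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concatenate, softmax
from .backbone import build_backbone
from .cross import CrossAttention
from .decoder import DecoderHead, MultiHeadAttention
from .intra import EHREmbedding, SpatialAttention, TemporalAttention
from .nn import Linear, Module, seeded_rng

__all__ = ["RiskFusionNet", "ImageOnlyNet", "EHROnlyNet", "EarlyFusionNet",
           "IntermediateFusionNet", "LateFusionNet", "build_fusion_variant",
           "FUSION_VARIANTS"]


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


class _NetBase(Module):
    n_classes: int

    def forward(self, volumes, ehr) -> Tensor:
        raise NotImplementedError

    def predict_proba(self, volumes, ehr) -> np.ndarray:
        logits = self.forward(volumes, ehr)
        return softmax(logits, axis=-1).data

    def predict(self, volumes, ehr) -> np.ndarray:
        return self.predict_proba(volumes, ehr).argmax(axis=-1)


class _ImageStem(Module):
    """Backbone + flattening to the (N, D', P, C) attention layout.

    Backbone activations are standardized per channel with frozen statistics
    estimated on the training volumes (see :meth:`set_normalization`): raw
    desk-scale CNN outputs are dominated by a constant background response,
    and without centering the attention logits downstream are degenerate.
    """

    def __init__(self, volume_shape, c, backbone, seed):
        self.backbone = build_backbone(backbone, out_channels=c, seed=seed)
        self.c, self.d, self.h, self.w = self.backbone.output_shape(volume_shape)
        self.p = self.h * self.w
        self.norm_mean: np.ndarray | None = None
        self.norm_std: np.ndarray | None = None

    def set_normalization(self, volumes):
        """Freeze per-channel feature statistics computed on ``volumes``.

        The backbone calibrates its own per-stage statistics; a final
        standardization of the flattened feature map is kept so the
        attention layers always see zero-mean, unit-scale channels.
        """
        vols = np.asarray(volumes, dtype=float)
        self.backbone.calibrate(vols[:, None])
        feats = self._raw(volumes).data  # (N, D', P, C)
        self.norm_mean = feats.mean(axis=(0, 1, 2))
        std = feats.std(axis=(0, 1, 2))
        self.norm_std = np.where(std < 1e-8, 1.0, std)

    def _raw(self, volumes) -> Tensor:
        x = _as_tensor(volumes)
        n = x.shape[0]
        x = x.reshape(n, 1, *x.shape[1:])
        f = self.backbone(x)  # (N, C, D', H', W')
        return f.reshape(n, self.c, self.d, self.p).transpose(0, 2, 3, 1)

    def __call__(self, volumes) -> Tensor:
        f = self._raw(volumes)
        if self.norm_mean is not None:
            f = (f - Tensor(self.norm_mean)) * Tensor(1.0 / self.norm_std)
        return f


class RiskFusionNet(_NetBase):
    """The proposed model: intra-modal spatial/temporal self-attention,
    record embedding, bidirectional cross-attention, spatial compression and
    the classification-query decoder."""

    name = "proposed"

    def __init__(self, n_classes: int, n_ehr_features: int, volume_shape=(8, 16, 16),
                 c: int = 12, n_heads: int = 6, sam: bool = True, tam: bool = True,
                 cam: bool = True, backbone="small_cnn", seed: int = 0,
                 scaled_attention: bool = True, candidate_mode: str = "exclude_self"):
        rng = seeded_rng(seed)
        self.stem = _ImageStem(volume_shape, c, backbone, seed)
        self.sam_flag, self.tam_flag, self.cam_flag = bool(sam), bool(tam), bool(cam)
        self.spatial = SpatialAttention(c, rng, scaled_attention) if sam else None
        self.temporal = TemporalAttention(c, rng, scaled_attention) if tam else None
        self.ehr_embed = EHREmbedding(n_ehr_features, c, rng)
        if self.stem.p == 1:
            candidate_mode = "include_self"  # degenerate grid fallback
        self.cross = CrossAttention(c, rng, candidate_mode, scaled_attention) if cam else None
        self.decoder = DecoderHead(n_classes, c, n_heads, rng)
        self.n_classes = n_classes
        self.n_heads = n_heads

    def forward(self, volumes, ehr, return_attention: bool = False):
        x = self.stem(volumes)  # (N, D', P, C)
        attn = {}
        if self.spatial is not None:
            ms, w_sp = self.spatial(x)
            attn["spatial"] = w_sp
        else:
            ms = x
        if self.temporal is not None:
            mt, w_tp = self.temporal(x)
            attn["temporal"] = w_tp
        else:
            mt = x
        m = ms + mt
        s = self.ehr_embed(_as_tensor(ehr), self.stem.d, self.stem.p)
        if self.cross is not None:
            m, s, (a_m, a_s) = self.cross(m, s, (self.stem.h, self.stem.w))
            attn["cross_m"], attn["cross_s"] = a_m, a_s
        fused_m = m.mean(axis=2)  # (N, D', C)
        fused_s = s.mean(axis=2)
        logits = self.decoder(fused_m, fused_s)
        if return_attention:
            return logits, attn
        return logits


class ImageOnlyNet(_NetBase):
    """Image branch alone: backbone, intra-modal attention, decoder with a
    single attention stream.  The record vector is ignored entirely."""

    name = "image_only"

    def __init__(self, n_classes, n_ehr_features, volume_shape=(8, 16, 16), c=12,
                 n_heads=6, sam=True, tam=True, backbone="small_cnn", seed=0, **_):
        rng = seeded_rng(seed)
        self.stem = _ImageStem(volume_shape, c, backbone, seed)
        self.spatial = SpatialAttention(c, rng, scaled=True) if sam else None
        self.temporal = TemporalAttention(c, rng, scaled=True) if tam else None
        self.decoder = DecoderHead(n_classes, c, n_heads, rng, single_stream=True)
        self.n_classes = n_classes

    def forward(self, volumes, ehr=None) -> Tensor:
        x = self.stem(volumes)
        ms = self.spatial(x)[0] if self.spatial is not None else x
        mt = self.temporal(x)[0] if self.temporal is not None else x
        m = (ms + mt).mean(axis=2)
        return self.decoder(m, None)


class EHROnlyNet(_NetBase):
    """Record branch alone: embedding then the decoder attention; the volume
    never enters the graph."""

    name = "ehr_only"

    def __init__(self, n_classes, n_ehr_features, volume_shape=(8, 16, 16), c=12,
                 n_heads=6, seed=0, **_):
        rng = seeded_rng(seed)
        self.embed = Linear(n_ehr_features, c, rng)
        self.decoder = DecoderHead(n_classes, c, n_heads, rng, single_stream=True)
        self.n_classes = n_classes

    def forward(self, volumes, ehr) -> Tensor:
        vec = self.embed(_as_tensor(ehr))  # (N, C)
        s = vec.reshape(vec.shape[0], 1, vec.shape[1])
        return self.decoder(s, None)


class EarlyFusionNet(_NetBase):
    """Early fusion: the spatially pooled image feature is concatenated with
    the record vector at the input of a small classifier."""

    name = "early"

    def __init__(self, n_classes, n_ehr_features, volume_shape=(8, 16, 16), c=12,
                 seed=0, **_):
        rng = seeded_rng(seed)
        self.stem = _ImageStem(volume_shape, c, backbone="small_cnn", seed=seed)
        self.fc1 = Linear(c + n_ehr_features, c, rng)
        self.fc2 = Linear(c, n_classes, rng)
        self.n_classes = n_classes

    def forward(self, volumes, ehr) -> Tensor:
        x = self.stem(volumes)  # (N, D', P, C)
        pooled = x.mean(axis=(1, 2))  # (N, C)
        joint = concatenate([pooled, _as_tensor(ehr)], axis=1)
        return self.fc2(self.fc1(joint).relu())


class IntermediateFusionNet(_NetBase):
    """Intermediate fusion: each modality is linearly transformed to a common
    width and the two features are added before the classifier."""

    name = "intermediate"

    def __init__(self, n_classes, n_ehr_features, volume_shape=(8, 16, 16), c=12,
                 seed=0, **_):
        rng = seeded_rng(seed)
        self.stem = _ImageStem(volume_shape, c, backbone="small_cnn", seed=seed)
        self.proj_img = Linear(c, c, rng)
        self.proj_ehr = Linear(n_ehr_features, c, rng)
        self.fc = Linear(c, n_classes, rng)
        self.n_classes = n_classes

    def forward(self, volumes, ehr) -> Tensor:
        pooled = self.stem(volumes).mean(axis=(1, 2))
        fusedf = self.proj_img(pooled) + self.proj_ehr(_as_tensor(ehr))
        return self.fc(fusedf.relu())


class LateFusionNet(_NetBase):
    """Late fusion: both branches produce (D', C) matrices which are stacked
    and aggregated by standard single-head attention before the FC layer."""

    name = "late"

    def __init__(self, n_classes, n_ehr_features, volume_shape=(8, 16, 16), c=12,
                 seed=0, **_):
        rng = seeded_rng(seed)
        self.stem = _ImageStem(volume_shape, c, backbone="small_cnn", seed=seed)
        self.ehr_embed = EHREmbedding(n_ehr_features, c, rng)
        self.x_d = Tensor(rng.normal(0, 0.1, (n_classes, c)), requires_grad=True)
        self.attn = MultiHeadAttention(c, 1, rng)
        self.fc = Linear(n_classes * c, n_classes, rng)
        self.n_classes = n_classes

    def forward(self, volumes, ehr) -> Tensor:
        x = self.stem(volumes)
        m = x.mean(axis=2)  # (N, D', C)
        s = self.ehr_embed(_as_tensor(ehr), self.stem.d, 1).reshape(
            m.shape[0], self.stem.d, m.shape[2])
        joint = concatenate([m, s], axis=1)  # (N, 2D', C)
        n = m.shape[0]
        query = self.x_d.reshape(1, *self.x_d.shape).broadcast_to((n, *self.x_d.shape))
        out = self.attn(query, joint, joint)
        return self.fc(out.reshape(n, -1))


FUSION_VARIANTS = {
    "proposed": RiskFusionNet,
    "image_only": ImageOnlyNet,
    "ehr_only": EHROnlyNet,
    "early": EarlyFusionNet,
    "intermediate": IntermediateFusionNet,
    "late": LateFusionNet,
}


def build_fusion_variant(name: str, n_classes: int, n_ehr_features: int,
                         volume_shape=(8, 16, 16), **kwargs) -> _NetBase:
    """Instantiate a registered fusion strategy with shared hyperparameters."""
    if name not in FUSION_VARIANTS:
        raise KeyError(f"unknown fusion variant {name!r}; registered: {sorted(FUSION_VARIANTS)}")
    return FUSION_VARIANTS[name](n_classes, n_ehr_features, volume_shape, **kwargs)
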