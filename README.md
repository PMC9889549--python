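# attnfuse

Attention-based fusion of 3D brain volumes and clinical records for
multiclass disease-risk classification.

Predicting the stage of a neurodegenerative condition (e.g., CN/MCI/AD, or
NC/T1DM/T2DM) from a single modality is limited: structural imaging lacks
the clinical context held in the health record, and the record lacks
anatomical detail.  Simple fusion schemes — concatenating features early,
adding linearly transformed features, or attending once before the
classifier — ignore the *dependencies* within and between the modalities.
`attnfuse` implements an encoder–decoder architecture that models them
explicitly, for researchers studying multimodal fusion strategies on
image + tabular clinical data.

## The model

Given an MRI-like volume and a clinical feature vector **x**:

- a 3D CNN backbone produces a feature map `v ∈ ℝ^{C×D'×H'×W'}`;
- **spatial self-attention** captures intra-slice dependencies:
  `S_{j,i} = softmax_i( K(v_i)ᵀ Q(v_j) )` over the `H'·W'` positions of each
  slice, output `M̂_S(j) = Σ_i V(v_i) S_{j,i}` projected back to `C`
  channels; **temporal self-attention** does the same over the `D'` slices;
  the streams are summed into per-slice image representations `M_t`, and a
  fully connected layer embeds **x** into `ℝ^C` as `S_t`;
- **cross-attention** exchanges information between the modalities per
  slice: affinity `Aff_{i,j} = Q_j Ω_{i,j}ᵀ` scores each position against
  the candidate set from the *other* modality, softmax gives the attention
  map `A`, and aggregation `Agg_j = Σ_i A_{i,j} Ω̂_{i,j} + H_j` updates each
  modality residually; spatial pooling yields `M, S ∈ ℝ^{D'×C}`;
- a **disease-oriented decoder** refines a learnable classification query
  `X_d ∈ ℝ^{K×C}` with two parallel multi-head attention layers,
  `out = MHA(X_d, M, M) + MHA(X_d, S, S)`, and one fully connected layer
  maps the flattened output to `K` class probabilities `ŷ ∈ [0,1]^K`
  (cross-entropy training loss).

Training follows SGD with momentum 0.9, weight decay 1e-4 and polynomial
learning-rate decay `0.01·(1 − iter/total)^0.9`, evaluated by stratified
5-fold cross-validation with sensitivity / accuracy / specificity / macro
one-vs-rest AUROC reported as mean ± std over folds.  Everything runs on
plain numpy (a small built-in reverse-mode autodiff engine) — no GPU
required.  See `docs/methods.md` for assumptions and numerical choices.

A synthetic-data module generates paired NIfTI + CSV datasets whose class
signal can be planted in the image only, the record only, or — the
interesting case — in an XOR combination recoverable *only by fusing both
modalities*, which makes fusion quality directly measurable.

## Worked example

```python
from attnfuse import SynthConfig, generate_dataset, DiseaseRiskModel, TrainConfig

dataset = generate_dataset(SynthConfig(n_samples=60, n_classes=3,
                                       signal_mode="image_only", seed=0))
config = TrainConfig(epochs=40, n_folds=3, batch_size=8, seed=0)
results = DiseaseRiskModel(dataset, config).fit_cv()
print(results.summary())
```

```
Disease-risk fusion model
============================================================
variant: proposed   SAM=True TAM=True CAM=True
classes: 3   samples: 60   heads: 6   channels: 12
optimizer: SGD(lr0=0.01, momentum=0.9, wd=0.0001, poly power=0.9)
evaluation: 3-fold stratified CV
------------------------------------------------------------
metric              mean       std
sensitivity        0.968     0.022
accuracy           0.967     0.024
specificity        0.984     0.011
auroc              0.994     0.009
------------------------------------------------------------
final training loss: 0.0001 (320 steps)
```

Sixty synthetic subjects carry a three-class signal planted in the volume
(blob site and contrast); the cross-validated model recovers it almost
perfectly — mean accuracy 0.967 over three stratified folds with macro
one-vs-rest AUROC 0.994 — and the in-sample loss shows the optimizer drove
training cross-entropy to ~1e-4 in 320 steps.  `results.predict_proba`,
`results.loss_trace` and `results.save` give predictions, the per-step
loss/LR trace and a serialized model.

The same experiments are scriptable from the shell:

```bash
attnfuse simulate --config config.yaml --out data/
attnfuse train --data data/ --config config.yaml --out run/
attnfuse evaluate --data data/ --config config.yaml --out eval/
attnfuse ablate | head-sweep | compare-fusion | attn-map ...
```

Each command writes a `run_manifest.json` (config snapshot, seed, git
state, output index).  `attnfuse attn-map` exports a voxel saliency volume
(NIfTI) derived from the attention weights plus axial/coronal/sagittal
overlay PNGs.

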