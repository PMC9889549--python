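"""Synthetic paired volume + clinical-record datasets.

The generator emulates the study setting of paired structural brain volumes
and per-subject clinical feature vectors with a K-class diagnosis, at desk
scale.  The class signal is plantable in three ways:

``image_only``
    a Gaussian intensity blob whose location and contrast among K fixed
    (site, amplitude) pairs encode the label; the record vector is pure
    noise.  Contrast carries the code through spatially pooled readouts
    (attention models without positional encodings are insensitive to pure
    location codes), location keeps the blob localizable for saliency maps.
``ehr_only``
    a class-specific mean shift on the first K record features; the volume
    is pure noise.
``fusion_xor``
    the label is the modulo-K sum of one image-borne code (blob site) and
    one record-borne code (mean-shifted feature), each marginally uniform,
    so neither modality alone carries label information: only a model that
    fuses both can recover the class.

Volumes are generated in [0, 1] (additive Gaussian noise, then clipping), so
they already satisfy the intensity-normalization contract of the training
pipeline.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["SynthConfig", "PairedSample", "PairedDataset",
           "generate_dataset", "write_dataset", "read_dataset"]

SIGNAL_MODES = ("image_only", "ehr_only", "fusion_xor")


@dataclass(frozen=True)
class SynthConfig:
    """Conditions of one synthetic study.

    volume_shape is (D, H, W) voxels; signal_strength is a dimensionless
    effect size (record-feature shift in SDs; blob contrast scale) and
    noise_sd the additive Gaussian intensity noise.
    """

    n_samples: int = 300
    n_classes: int = 3
    volume_shape: tuple[int, int, int] = (8, 16, 16)
    n_ehr_features: int = 17
    signal_mode: str = "fusion_xor"
    signal_strength: float = 2.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError(f"need at least 2 classes, got {self.n_classes}")
        if self.n_samples < self.n_classes:
            raise ValueError("n_samples must be >= n_classes")
        if len(self.volume_shape) != 3 or any(s <= 0 for s in self.volume_shape):
            raise ValueError(f"volume_shape must be 3 positive dims, got {self.volume_shape}")
        if self.n_ehr_features < max(2, self.n_classes):
            raise ValueError("n_ehr_features must be >= max(2, n_classes)")
        if self.signal_mode not in SIGNAL_MODES:
            raise ValueError(f"unknown signal_mode {self.signal_mode!r}; use one of {SIGNAL_MODES}")
        if self.signal_strength < 0 or self.noise_sd < 0:
            raise ValueError("signal_strength and noise_sd must be >= 0")


@dataclass
class PairedSample:
    """One subject: volume (D,H,W) in [0,1], record vector (F,), label in [0,K)."""

    volume: np.ndarray
    ehr: np.ndarray
    label: int
    subject_id: str = ""


class PairedDataset:
    """In-memory collection of paired samples with aligned arrays."""

    def __init__(self, volumes: np.ndarray, ehr: np.ndarray, labels: np.ndarray,
                 subject_ids: list[str] | None = None,
                 config: SynthConfig | None = None):
        volumes = np.asarray(volumes, dtype=float)
        ehr = np.asarray(ehr, dtype=float)
        labels = np.asarray(labels, dtype=int)
        if not (len(volumes) == len(ehr) == len(labels)):
            raise ValueError("volumes, ehr, labels must have equal length")
        self.volumes = volumes
        self.ehr = ehr
        self.labels = labels
        self.subject_ids = subject_ids or [f"sub-{i:04d}" for i in range(len(labels))]
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicated subject ids")
        self.config = config

    def __len__(self):
        return len(self.labels)

    def __getitem__(self, i: int) -> PairedSample:
        return PairedSample(self.volumes[i], self.ehr[i], int(self.labels[i]),
                            self.subject_ids[i])

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    @property
    def n_classes(self) -> int:
        return self.config.n_classes if self.config else int(self.labels.max()) + 1

    def subset(self, idx) -> "PairedDataset":
        idx = np.asarray(idx)
        return PairedDataset(self.volumes[idx], self.ehr[idx], self.labels[idx],
                             [self.subject_ids[i] for i in idx], self.config)


def _blob_centers(k: int, shape) -> np.ndarray:
    """K well-separated blob centers: spread along the width, alternating
    between the upper and lower half of the in-plane grid."""
    d, h, w = shape
    centers = []
    for i in range(k):
        cw = (i + 0.5) / k * w
        ch = h * (0.3 if i % 2 == 0 else 0.7)
        cd = d * 0.5
        centers.append((cd, ch, cw))
    return np.array(centers)


def _add_blob(volume: np.ndarray, center, amplitude: float, shape):
    d, h, w = shape
    zz, yy, xx = np.meshgrid(np.arange(d), np.arange(h), np.arange(w), indexing="ij")
    sig_d, sig_hw = max(d / 6.0, 1.0), max(min(h, w) / 8.0, 1.0)
    dist2 = ((zz - center[0]) / sig_d) ** 2 + ((yy - center[1]) / sig_hw) ** 2 \
        + ((xx - center[2]) / sig_hw) ** 2
    volume += amplitude * np.exp(-0.5 * dist2)


def generate_dataset(config: SynthConfig) -> PairedDataset:
    """Generate a balanced paired dataset under ``config``.

    Labels are assigned round-robin (balanced within +/-1) and shuffled;
    identical configs give byte-identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    n, k = config.n_samples, config.n_classes
    d, h, w = config.volume_shape
    f = config.n_ehr_features

    labels = np.arange(n) % k
    rng.shuffle(labels)

    centers = _blob_centers(k, config.volume_shape)
    amplitude = min(0.75, 0.25 * config.signal_strength)
    background = 0.25

    volumes = np.full((n, d, h, w), background)
    ehr = rng.normal(0.0, 1.0, size=(n, f))

    if config.signal_mode == "image_only":
        image_code = labels.copy()
        ehr_code = None
    elif config.signal_mode == "ehr_only":
        image_code = None
        ehr_code = labels.copy()
    else:  # fusion_xor
        image_code = rng.integers(0, k, size=n)
        ehr_code = (labels - image_code) % k

    if image_code is not None:
        # code k -> site k with amplitude graded by (k+1)/K: the contrast
        # level is recoverable from pooled feature statistics, the site from
        # the voxel grid (saliency)
        for i in range(n):
            code = image_code[i]
            _add_blob(volumes[i], centers[code], amplitude * (code + 1) / k,
                      config.volume_shape)
    if ehr_code is not None:
        ehr[np.arange(n), ehr_code] += config.signal_strength

    volumes += rng.normal(0.0, config.noise_sd, size=volumes.shape)
    np.clip(volumes, 0.0, 1.0, out=volumes)

    dataset = PairedDataset(volumes, ehr, labels, config=config)
    # latent ground truth, for diagnostics and tests; not persisted by write_dataset
    dataset.image_code = image_code
    dataset.ehr_code = ehr_code
    return dataset


def write_dataset(dataset: PairedDataset, directory) -> Path:
    """Write volumes as one NIfTI per sample plus a single CSV of record
    features and labels, indexed by subject id; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for sample in dataset:
        fname = f"{sample.subject_id}.nii.gz"
        img = nib.Nifti1Image(sample.volume.astype(np.float32), affine=np.eye(4))
        nib.save(img, directory / fname)
        files.append(fname)
    n_feat = dataset.ehr.shape[1]
    table = pd.DataFrame(dataset.ehr, columns=[f"f{i + 1}" for i in range(n_feat)])
    table.insert(0, "label", dataset.labels)
    table.insert(0, "subject_id", dataset.subject_ids)
    table.to_csv(directory / "ehr.csv", index=False)
    manifest = {
        "volume_files": files,
        "ehr_csv": "ehr.csv",
        "volume_shape": list(dataset.volumes.shape[1:]),
        "n_samples": len(dataset),
        "config": asdict(dataset.config) if dataset.config else None,
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_dataset(directory) -> PairedDataset:
    """Read a dataset written by :func:`write_dataset`; validates subject-id
    uniqueness and volume shapes against the manifest."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {directory}")
    manifest = json.loads(manifest_path.read_text())
    table = pd.read_csv(directory / manifest["ehr_csv"])
    if table["subject_id"].duplicated().any():
        dupes = table.loc[table["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicated subject ids in CSV: {dupes}")
    if table.isna().any().any():
        raise ValueError("missing values in record table")
    expected_shape = tuple(manifest["volume_shape"])
    ids = table["subject_id"].tolist()
    volumes = []
    for sid in ids:
        path = directory / f"{sid}.nii.gz"
        if not path.exists():
            raise FileNotFoundError(f"volume file missing for subject {sid}")
        vol = np.asarray(nib.load(path).dataobj, dtype=float)
        if vol.shape != expected_shape:
            raise ValueError(
                f"volume shape {vol.shape} for {sid} does not match manifest {expected_shape}"
            )
        volumes.append(vol)
    feat_cols = [c for c in table.columns if c.startswith("f")]
    cfg = None
    if manifest.get("config"):
        raw = dict(manifest["config"])
        raw["volume_shape"] = tuple(raw["volume_shape"])
        cfg = SynthConfig(**raw)
    return PairedDataset(np.stack(volumes), table[feat_cols].to_numpy(float),
                         table["label"].to_numpy(int), ids, cfg)
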