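"""Attention-map export: turn the encoder's attention weights into a voxel
saliency volume and orthogonal-view overlay images.

Saliency at a feature-grid position is the attention mass it *receives*:
column sums of the spatial attention weights (averaged over slices and
query positions), modulated per slice by the received temporal attention
mass.  The grid map is trilinearly upsampled to the input resolution and
min-max normalized to [0, 1] (rendered blue-to-red in the overlays).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import nibabel as nib
import numpy as np
from scipy.ndimage import zoom

__all__ = ["attention_saliency", "export_attention_map"]


def attention_saliency(model, volume: np.ndarray, ehr: np.ndarray) -> np.ndarray:
    """Per-voxel saliency in [0, 1] with the input volume's shape.

    ``model`` is a trained model (or bare network) whose forward pass
    exposes attention weights; at least one of the spatial/temporal
    attention blocks must be active.
    """
    net = getattr(model, "net", model)
    if getattr(model, "ehr_mean", None) is not None:
        ehr = (np.asarray(ehr, dtype=float) - model.ehr_mean) / model.ehr_std
    volume = np.asarray(volume, dtype=float)
    out = net.forward(volume[None], np.asarray(ehr, dtype=float)[None],
                      return_attention=True)
    _, attn = out
    if "spatial" not in attn and "temporal" not in attn:
        raise ValueError(
            "model has no active attention blocks (SAM and TAM are both off); "
            "attention maps require at least one of them"
        )
    d, h, w = net.stem.d, net.stem.h, net.stem.w
    if "spatial" in attn:
        # (N, D', P, P): column sums = mass received per position
        sp = attn["spatial"].data[0]  # (D', P, P)
        spatial_mass = sp.sum(axis=1)  # (D', P): received mass per position
    else:
        spatial_mass = np.ones((d, h * w))
    if "temporal" in attn:
        tp = attn["temporal"].data[0]  # (P, D', D')
        temporal_mass = tp.sum(axis=1).mean(axis=0)  # (D',)
    else:
        temporal_mass = np.ones(d)
    grid = spatial_mass.reshape(d, h, w) * temporal_mass[:, None, None]
    factors = tuple(t / s for t, s in zip(volume.shape, grid.shape))
    sal = zoom(grid, factors, order=1)
    lo, hi = sal.min(), sal.max()
    if hi == lo:
        return np.zeros_like(sal)
    return (sal - lo) / (hi - lo)


def export_attention_map(model, volume: np.ndarray, ehr: np.ndarray,
                         out_dir, stem: str = "saliency") -> dict:
    """Write the saliency NIfTI plus axial/coronal/sagittal overlay PNGs.

    Returns a dict of written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sal = attention_saliency(model, volume, ehr)
    nii_path = out_dir / f"{stem}.nii.gz"
    nib.save(nib.Nifti1Image(sal.astype(np.float32), affine=np.eye(4)), nii_path)

    views = {
        "axial": (volume[volume.shape[0] // 2], sal[sal.shape[0] // 2]),
        "coronal": (volume[:, volume.shape[1] // 2], sal[:, sal.shape[1] // 2]),
        "sagittal": (volume[:, :, volume.shape[2] // 2], sal[:, :, sal.shape[2] // 2]),
    }
    paths = {"nifti": str(nii_path)}
    for name, (img, overlay) in views.items():
        fig, axes = plt.subplots(1, 3, figsize=(9, 3))
        axes[0].imshow(img, cmap="gray", vmin=0, vmax=1)
        axes[0].set_title("image")
        axes[1].imshow(overlay, cmap="jet", vmin=0, vmax=1)
        axes[1].set_title("attention")
        axes[2].imshow(img, cmap="gray", vmin=0, vmax=1)
        axes[2].imshow(overlay, cmap="jet", vmin=0, vmax=1, alpha=0.45)
        axes[2].set_title("overlay")
        for ax in axes:
            ax.axis("off")
        fig.suptitle(f"{name} view")
        png = out_dir / f"{stem}_{name}.png"
        fig.savefig(png, dpi=100, bbox_inches="tight")
        plt.close(fig)
        paths[name] = str(png)
    return paths
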