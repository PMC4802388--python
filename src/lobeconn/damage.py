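"""Surgical damage quantification and its link to post-operative topology.

The damage score (DS) of a subject weights the fraction of each resected
region by that region's pre-operative nodal importance:

    DS = sum over damaged regions i of  fraction_i * M_i

where M_i is the pre-operative nodal clustering coefficient (C_i-based DS)
or nodal efficiency (E_i-based DS).  Fractions are stored in [0, 1]; the
"percentage" wording is a x100 display convention only.  A mean over the
damaged regions is available as a variant (``mode='mean'``), the sum being
the default.  DS values are then correlated with the post-operative
small-worldness AUC across subjects (Pearson).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .cohort import LesionProfile, Parcellation
from .stats import pearson_corr

__all__ = [
    "overlap_fractions",
    "compute_ds",
    "ds_vs_sigma",
    "write_lesion_volumes",
    "read_lesion_volumes",
]


def overlap_fractions(
    atlas_volume: np.ndarray,
    lacuna_mask: np.ndarray,
    subject_id: str = "",
    lacuna_volume_cm3: float = 0.0,
    n_rois: int | None = None,
) -> LesionProfile:
    """Per-region damage fractions from 3D label volumes.

    ``atlas_volume`` holds integer labels 1..N (0 = background) and
    ``lacuna_mask`` is a binary resection mask of the same shape;
    ``fraction_i = |ROI_i intersect lacuna| / |ROI_i|``.  An atlas label with
    no voxels is an error naming the region.
    """
    atlas = np.asarray(atlas_volume)
    mask = np.asarray(lacuna_mask)
    if atlas.shape != mask.shape:
        raise ValueError(f"shape mismatch: atlas {atlas.shape} vs mask {mask.shape}")
    if not np.issubdtype(atlas.dtype, np.integer):
        raise ValueError("atlas must hold integer labels")
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("lacuna mask must be binary")
    n = int(n_rois if n_rois is not None else atlas.max())
    labels = atlas.reshape(-1)
    roi_sizes = np.bincount(labels, minlength=n + 1)[1 : n + 1]
    empty = np.flatnonzero(roi_sizes == 0)
    if empty.size:
        raise ValueError(f"atlas ROI {int(empty[0]) + 1} has no voxels")
    overlap = np.bincount(labels, weights=mask.reshape(-1), minlength=n + 1)[1 : n + 1]
    return LesionProfile(subject_id, overlap / roi_sizes, lacuna_volume_cm3)


def compute_ds(
    profile: LesionProfile,
    preop_nodal_metric: np.ndarray,
    mode: str = "sum",
) -> float:
    """Damage score: aggregate of fraction_i x metric_i over damaged regions."""
    metric = np.asarray(preop_nodal_metric, dtype=float)
    fractions = np.asarray(profile.fractions, dtype=float)
    if metric.shape != fractions.shape:
        raise ValueError(
            f"nodal metric has shape {metric.shape}, lesion profile {fractions.shape}"
        )
    damaged = profile.damaged_rois
    if damaged.size and np.any(~np.isfinite(metric[damaged])):
        bad = damaged[~np.isfinite(metric[damaged])][0]
        raise ValueError(f"missing pre-operative metric for damaged ROI {int(bad)}")
    if mode == "sum":
        return float(np.sum(fractions[damaged] * metric[damaged]))
    if mode == "mean":
        if damaged.size == 0:
            return 0.0
        return float(np.mean(fractions[damaged] * metric[damaged]))
    raise ValueError(f"mode must be 'sum' or 'mean', got {mode!r}")


def ds_vs_sigma(
    damage_scores: dict[str, np.ndarray],
    postop_sigma_auc: np.ndarray,
) -> dict[str, tuple[float, float]]:
    """Pearson (r, p) of each damage-score basis against post-op Sigma AUC.

    ``damage_scores`` maps a basis label (e.g. "C_i", "E_i") to a per-subject
    DS vector aligned with ``postop_sigma_auc``.
    """
    sigma = np.asarray(postop_sigma_auc, dtype=float)
    if len(sigma) < 3:
        raise ValueError("need at least 3 post-operative subjects")
    out = {}
    for basis, ds in damage_scores.items():
        out[basis] = pearson_corr(np.asarray(ds, dtype=float), sigma)
    return out


def write_lesion_volumes(
    atlas: np.ndarray, mask: np.ndarray, out_dir: str | Path, stem: str
) -> tuple[Path, Path]:
    """Write an (atlas, lacuna) pair as uncompressed NIfTI with unit affine."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    atlas_path = out / f"{stem}_atlas.nii"
    mask_path = out / f"{stem}_lacuna.nii"
    nib.save(nib.Nifti1Image(np.asarray(atlas, dtype=np.int32), affine), atlas_path)
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.int32), affine), mask_path)
    return atlas_path, mask_path


def read_lesion_volumes(atlas_path: str | Path, mask_path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    import nibabel as nib

    atlas = np.asarray(nib.load(str(atlas_path)).dataobj, dtype=np.int32)
    mask = np.asarray(nib.load(str(mask_path)).dataobj, dtype=np.int32)
    return atlas, mask
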