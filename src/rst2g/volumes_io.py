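"""Study data model and volume I/O for dynamic contrast-enhanced MRI.

A patient study is a set of co-registered volumes: one pre-contrast
acquisition, one or more post-contrast acquisitions, and a binary tumour
mask. The residual volume — the voxel-wise difference between a chosen
post-contrast phase and the pre-contrast baseline — highlights contrast
uptake and is computed here, after per-volume min–max normalisation, so it
lies in [-1, 1].

Volumes are stored as (slice, row, col) arrays with spacing in mm per axis
in the same order. On disk the only supported dialect is NIfTI
(``.nii`` / ``.nii.gz``); loaders refuse inputs that are not already
co-registered (shape or spacing mismatch) rather than resampling silently.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume", "DCEStudy", "SliceBatch",
    "AlignmentError", "ValidationError",
    "compute_residual", "normalize_volume",
    "read_volume", "write_volume", "write_mask",
    "load_study", "load_manifest", "assemble_slice_batches",
]

_SPACING_RTOL = 1e-4


class ValidationError(ValueError):
    """Raised when a volume or study violates its invariants."""


class AlignmentError(ValidationError):
    """Raised when volumes that must be co-registered do not line up."""


@dataclasses.dataclass(frozen=True)
class Volume:
    """A single MR volume: (slice, row, col) voxels plus mm spacing."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    patient_id: str = ""

    def __post_init__(self):
        vox = np.asarray(self.voxels, dtype=np.float32)
        if vox.ndim != 3 or min(vox.shape) < 1:
            raise ValidationError(f"volume must be rank-3, got shape {vox.shape}")
        if not np.all(np.isfinite(vox)):
            raise ValidationError("volume contains non-finite voxels")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValidationError(f"spacing must be three positive floats, got {spacing}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def with_voxels(self, voxels: np.ndarray) -> "Volume":
        return Volume(voxels, self.spacing, self.patient_id)


def _check_aligned(a: Volume, b: Volume, what: str) -> None:
    if a.shape != b.shape:
        raise AlignmentError(f"{what}: shape mismatch {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing, rtol=_SPACING_RTOL):
        raise AlignmentError(f"{what}: spacing mismatch {a.spacing} vs {b.spacing}")


def compute_residual(pre: Volume, post: Volume) -> Volume:
    """Voxel-wise contrast-uptake image: post − pre. May be negative."""
    _check_aligned(pre, post, "residual")
    return Volume(post.voxels - pre.voxels, pre.spacing, pre.patient_id)


def normalize_volume(v: Volume) -> Volume:
    """Min–max rescale to [0, 1]; a constant volume maps to all zeros."""
    lo = float(v.voxels.min())
    hi = float(v.voxels.max())
    if hi == lo:
        return v.with_voxels(np.zeros_like(v.voxels))
    return v.with_voxels((v.voxels - lo) / (hi - lo))


def _check_binary(mask: Volume) -> None:
    values = np.unique(mask.voxels)
    if not np.all(np.isin(values, (0.0, 1.0))):
        raise ValidationError(
            f"mask must be strictly binary; found values {values[:10]}")


@dataclasses.dataclass(frozen=True)
class DCEStudy:
    """One patient's co-registered pre/post/residual volumes and tumour mask."""

    pre: Volume
    posts: tuple[Volume, ...]
    residual: Volume
    mask: Volume
    phase_index_used: int = 0

    def __post_init__(self):
        if not 1 <= len(self.posts) <= 5:
            raise ValidationError("a study needs between 1 and 5 post-contrast volumes")
        if not 0 <= self.phase_index_used < len(self.posts):
            raise ValidationError(
                f"phase_index_used={self.phase_index_used} out of range "
                f"for {len(self.posts)} post-contrast phases")
        for i, post in enumerate(self.posts):
            _check_aligned(self.pre, post, f"post-contrast phase {i}")
        _check_aligned(self.pre, self.residual, "residual")
        _check_aligned(self.pre, self.mask, "mask")
        _check_binary(self.mask)
        object.__setattr__(self, "posts", tuple(self.posts))

    @property
    def patient_id(self) -> str:
        return self.pre.patient_id

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pre.shape

    @property
    def tumor_volume_voxels(self) -> int:
        return int(self.mask.voxels.sum())

    @classmethod
    def from_phases(cls, pre: Volume, posts: Sequence[Volume], mask: Volume,
                    phase_index: int = 0, normalize: bool = True) -> "DCEStudy":
        """Build a study: normalise each phase, then subtract to get the residual.

        Normalising pre and post before subtraction bounds the residual in
        [-1, 1] regardless of scanner intensity scale.
        """
        if not 0 <= phase_index < len(posts):
            raise ValidationError(
                f"phase_index={phase_index} out of range for {len(posts)} phases")
        if normalize:
            pre = normalize_volume(pre)
            posts = [normalize_volume(p) for p in posts]
        residual = compute_residual(pre, posts[phase_index])
        return cls(pre=pre, posts=tuple(posts), residual=residual,
                   mask=mask, phase_index_used=phase_index)


@dataclasses.dataclass(frozen=True)
class SliceBatch:
    """A window of B consecutive slices per branch, shaped (B, 1, H, W).

    The batch axis doubles as the slice axis: the network treats the B
    entries as spatially adjacent slices of one volume. ``n_padded`` records
    how many trailing slices are edge replications so stitching can drop them.
    """

    pre: np.ndarray
    post: np.ndarray
    res: np.ndarray
    slice_indices: tuple[int, ...]
    n_padded: int = 0

    def __post_init__(self):
        arrays = (self.pre, self.post, self.res)
        shapes = {a.shape for a in arrays}
        if len(shapes) != 1:
            raise ValidationError(f"branch tensors differ in shape: {shapes}")
        shape = arrays[0].shape
        if len(shape) != 4 or shape[1] != 1:
            raise ValidationError(f"batch tensors must be (B,1,H,W), got {shape}")
        if shape[0] != len(self.slice_indices) or shape[0] < 1:
            raise ValidationError("slice_indices length must equal batch size")
        idx = self.slice_indices
        core = idx[:len(idx) - self.n_padded]
        if any(b - a != 1 for a, b in zip(core, core[1:])):
            raise ValidationError(f"slice indices not consecutive: {idx}")
        if any(p != core[-1] for p in idx[len(core):]):
            raise ValidationError("padded indices must replicate the edge slice")

    @property
    def batch_size(self) -> int:
        return self.pre.shape[0]


def assemble_slice_batches(study: DCEStudy, batch_size: int,
                           pad: bool = True) -> list[SliceBatch]:
    """Cut a study into consecutive, non-overlapping windows of B slices.

    A short final window is padded by replicating the last slice; the pad
    count is recorded on the batch so volume stitching can drop those slices.
    With ``pad=False`` the slice count must be divisible by B.
    """
    if batch_size < 1:
        raise ValidationError("batch_size must be >= 1")
    n = study.shape[0]
    if batch_size > n and not pad:
        raise ValidationError(
            f"batch_size {batch_size} exceeds slice count {n} and padding is disabled")
    if n % batch_size != 0 and not pad:
        raise ValidationError(
            f"slice count {n} not divisible by batch_size {batch_size} "
            "and padding is disabled")

    def slab(vol: Volume, idx: np.ndarray) -> np.ndarray:
        return vol.voxels[idx][:, None, :, :].astype(np.float32)

    batches = []
    for start in range(0, n, batch_size):
        stop = min(start + batch_size, n)
        idx = np.arange(start, stop)
        n_padded = batch_size - len(idx)
        if n_padded:
            idx = np.concatenate([idx, np.full(n_padded, n - 1, dtype=idx.dtype)])
        batches.append(SliceBatch(
            pre=slab(study.pre, idx),
            post=slab(study.posts[study.phase_index_used], idx),
            res=slab(study.residual, idx),
            slice_indices=tuple(int(i) for i in idx),
            n_padded=n_padded,
        ))
    return batches


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path: str | Path, patient_id: str = "") -> Volume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    voxels = np.asarray(img.dataobj, dtype=np.float32)
    if voxels.ndim != 3:
        raise ValidationError(f"{path}: expected a rank-3 NIfTI, got rank {voxels.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(voxels, spacing, patient_id or path.stem.split(".")[0])


def write_volume(vol: Volume, path: str | Path) -> Path:
    """Write as NIfTI; the affine encodes spacing on the diagonal so a
    round trip preserves voxels bit-exactly and spacing to float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(vol.voxels.astype(np.float32), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    return path


def write_mask(mask: Volume, path: str | Path) -> Path:
    _check_binary(mask)
    return write_volume(mask, path)


def load_study(pre_path: str | Path, post_paths: Sequence[str | Path],
               mask_path: str | Path, patient_id: str = "",
               phase_index: int = 0, normalize: bool = True) -> DCEStudy:
    """Read one patient's NIfTI files and assemble the study.

    Rejects non-co-registered phases and non-binary masks with descriptive
    errors; applies normalisation and residual computation per arguments.
    """
    pre = read_volume(pre_path, patient_id)
    posts = [read_volume(p, patient_id) for p in post_paths]
    mask = read_volume(mask_path, patient_id)
    return DCEStudy.from_phases(pre, posts, mask,
                                phase_index=phase_index, normalize=normalize)


def load_manifest(manifest_path: str | Path, phase_index: int = 0,
                  normalize: bool = True) -> list[DCEStudy]:
    """Load a cohort from a CSV/JSON manifest.

    Columns/keys: ``patient_id``, ``pre``, ``posts`` (``;``-separated paths
    in CSV, list in JSON) and ``mask``. Relative paths resolve against the
    manifest's directory.
    """
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    if manifest_path.suffix.lower() == ".json":
        rows = json.loads(manifest_path.read_text())
    else:
        frame = pd.read_csv(manifest_path)
        rows = frame.to_dict("records")
    studies = []
    for row in rows:
        posts = row["posts"]
        if isinstance(posts, str):
            posts = [p for p in posts.split(";") if p]
        studies.append(load_study(
            pre_path=root / row["pre"],
            post_paths=[root / p for p in posts],
            mask_path=root / row["mask"],
            patient_id=str(row["patient_id"]),
            phase_index=phase_index,
            normalize=normalize,
        ))
    return studies
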