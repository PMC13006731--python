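"""Synthetic DCE-MRI phantom cohorts with known ground truth.

Each phantom emulates the structure of a breast DCE study: a smooth
anatomical background with soft-tissue texture, an ellipsoidal lesion that
enhances after contrast injection, and independent Gaussian acquisition
noise on the pre- and post-contrast volumes. The tumour mask is the exact
ellipsoid membership, so segmentation accuracy against it is well defined.

The generator is deliberately simple — single focal lesion, multiplicative
enhancement rather than pharmacokinetic uptake curves, no coil or bias-field
artifacts — which is what makes its ground truth exact. Defaults are sized
so a cohort trains in minutes on a CPU while preserving the qualitative
contrast behaviour of real acquisitions: tumour enhancement well above the
mild background (parenchymal) enhancement, and noise small relative to the
contrast step.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes_io import DCEStudy, Volume, ValidationError, write_volume, write_mask

__all__ = ["PhantomSpec", "generate_phantom", "generate_cohort", "write_cohort"]


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Geometry and signal parameters of one synthetic study.

    ``enhancement_factor`` f scales the tumour post-contrast:
    post = pre * (1 + f) inside the lesion; ``background_enhancement``
    applies the same rule to everything else. Noise is additive Gaussian,
    drawn independently for pre and post (residual noise variance 2*sd^2).
    """

    shape: tuple[int, int, int] = (16, 32, 32)
    background_level: float = 0.4
    tissue_texture_sd: float = 0.08
    texture_smoothing: float = 3.0        # low-pass kernel width, voxels
    tumor_center: tuple[float, float, float] = (8.0, 16.0, 16.0)
    tumor_radii: tuple[float, float, float] = (4.0, 7.0, 7.0)
    enhancement_factor: float = 1.5
    background_enhancement: float = 0.1
    noise_sd: float = 0.02
    spacing: tuple[float, float, float] = (2.0, 1.0, 1.0)
    seed: int = 0
    patient_id: str = "phantom-000"

    def __post_init__(self):
        if any(r <= 0 for r in self.tumor_radii):
            raise ValidationError("tumor radii must be positive")
        if self.enhancement_factor < 0 or self.background_enhancement < 0:
            raise ValidationError("enhancement factors must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        for c, r, n in zip(self.tumor_center, self.tumor_radii, self.shape):
            if c - r < 0 or c + r > n - 1:
                raise ValidationError(
                    f"tumor ellipsoid (center {self.tumor_center}, radii "
                    f"{self.tumor_radii}) extends outside volume {self.shape}")


def _ellipsoid_mask(shape: tuple[int, int, int],
                    center: Sequence[float], radii: Sequence[float]) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    dist2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return (dist2 <= 1.0).astype(np.float32)


def generate_phantom(spec: PhantomSpec) -> DCEStudy:
    """Render one deterministic study from a spec.

    The pre-contrast volume is ``background_level`` plus low-pass-filtered
    Gaussian texture; enhancement is applied multiplicatively before noise
    so the noiseless residual is exactly ``factor * pre`` inside the lesion.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)

    texture = rng.normal(0.0, 1.0, size=shape)
    if spec.texture_smoothing > 0:
        texture = ndimage.gaussian_filter(texture, sigma=spec.texture_smoothing)
        sd = texture.std()
        if sd > 0:
            texture /= sd
    anatomy = spec.background_level + spec.tissue_texture_sd * texture
    anatomy = np.clip(anatomy, 0.0, None).astype(np.float32)

    mask = _ellipsoid_mask(shape, spec.tumor_center, spec.tumor_radii)
    gain = 1.0 + spec.background_enhancement + \
        (spec.enhancement_factor - spec.background_enhancement) * mask
    post_clean = anatomy * gain.astype(np.float32)

    noise_pre = rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)
    noise_post = rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)

    pre = Volume(anatomy + noise_pre, spec.spacing, spec.patient_id)
    post = Volume(post_clean + noise_post, spec.spacing, spec.patient_id)
    mask_vol = Volume(mask, spec.spacing, spec.patient_id)
    # raw (unnormalised) residual so the zero-enhancement identity holds exactly
    return DCEStudy.from_phases(pre, [post], mask_vol,
                                phase_index=0, normalize=False)


_DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "radius_row": (5.0, 9.0),
    "radius_slice": (3.0, 5.0),
    "enhancement_factor": (1.0, 2.0),
    "background_enhancement": (0.05, 0.15),
    "noise_sd": (0.01, 0.03),
    "center_jitter": (0.0, 3.0),
}


def generate_cohort(n_patients: int,
                    shape: tuple[int, int, int] = (16, 32, 32),
                    spec_ranges: dict[str, tuple[float, float]] | None = None,
                    seed: int = 0) -> list[DCEStudy]:
    """Draw a reproducible cohort with varied tumour geometry.

    Tumour radii are drawn from ``spec_ranges`` so tumour volume varies
    across patients (enabling volume-stratified splitting); centres jitter
    around the volume midpoint. Patient ids are unique and ordered.
    """
    if n_patients < 2:
        raise ValidationError("a cohort needs at least 2 patients")
    ranges = dict(_DEFAULT_RANGES)
    if spec_ranges:
        ranges.update(spec_ranges)
    for key, (lo, hi) in ranges.items():
        if hi < lo:
            raise ValidationError(f"empty range for {key}: ({lo}, {hi})")

    rng = np.random.default_rng(seed)
    studies = []
    for i in range(n_patients):
        r_row = rng.uniform(*ranges["radius_row"])
        r_col = rng.uniform(*ranges["radius_row"])
        r_slc = rng.uniform(*ranges["radius_slice"])
        jit = ranges["center_jitter"]
        center = tuple(
            n / 2.0 + rng.uniform(-1, 1) * rng.uniform(*jit) * 0.34
            for n in shape)
        # keep the ellipsoid strictly inside the volume
        radii = tuple(max(min(r, c - 0.05, s - 1.05 - c), 0.5)
                      if min(c - 0.05, s - 1.05 - c) >= 0.5
                      else min(c, s - 1 - c) - 0.01
                      for r, c, s in zip((r_slc, r_row, r_col), center, shape))
        spec = PhantomSpec(
            shape=shape,
            tumor_center=center,
            tumor_radii=radii,
            enhancement_factor=rng.uniform(*ranges["enhancement_factor"]),
            background_enhancement=rng.uniform(*ranges["background_enhancement"]),
            noise_sd=rng.uniform(*ranges["noise_sd"]),
            seed=int(rng.integers(0, 2 ** 31 - 1)),
            patient_id=f"phantom-{i:03d}",
        )
        studies.append(generate_phantom(spec))
    return studies


def write_cohort(studies: Sequence[DCEStudy], out_dir: str | Path) -> Path:
    """Emit a cohort as NIfTI files plus a ``manifest.csv`` naming them."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for study in studies:
        pid = study.patient_id
        pre_name = f"{pid}_pre.nii.gz"
        mask_name = f"{pid}_mask.nii.gz"
        post_names = [f"{pid}_post{j}.nii.gz" for j in range(len(study.posts))]
        write_volume(study.pre, out_dir / pre_name)
        for name, post in zip(post_names, study.posts):
            write_volume(post, out_dir / name)
        write_mask(study.mask, out_dir / mask_name)
        rows.append({"patient_id": pid, "pre": pre_name,
                     "posts": ";".join(post_names), "mask": mask_name})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
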