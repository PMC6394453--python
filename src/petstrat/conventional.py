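"""Conventional whole-burden PET parameters: SUVmax/SUVmean, MTV, TLG, and
baseline→follow-up percent change.

MTV is taken directly from the delineated mask (the VOI *is* the metabolic
volume — no thresholded sub-segmentation), and TLG is the product
MTV × SUVmean, which equals the voxel-wise SUV integral over the VOI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import PetVolume, Units, VoiMask


class EmptyMaskError(ValueError):
    """The VOI contains no voxels."""


class UndefinedChangeError(ValueError):
    """Percent change is undefined for a zero baseline value."""


@dataclass(frozen=True)
class ConventionalFeatures:
    suv_max: float
    suv_mean: float
    mtv_ml: float
    tlg: float


def _masked_values(vol: PetVolume, mask: VoiMask) -> np.ndarray:
    if vol.units is not Units.SUV:
        raise ValueError("conventional features are defined on SUV volumes")
    if mask.voxels.shape != vol.shape:
        raise ValueError("mask grid does not match volume grid")
    vals = vol.values[mask.voxels]
    if vals.size == 0:
        raise EmptyMaskError("VOI mask is empty")
    return vals


def suv_stats(vol: PetVolume, mask: VoiMask) -> tuple[float, float]:
    """Maximum and arithmetic-mean SUV over the in-mask voxels."""
    vals = _masked_values(vol, mask)
    return float(vals.max()), float(vals.mean())


def metabolic_tumor_volume(mask: VoiMask) -> float:
    """MTV in ml: voxel count × voxel volume."""
    if mask.n_voxels == 0:
        raise EmptyMaskError("VOI mask is empty")
    voxel_ml = float(np.prod(mask.spacing)) / 1000.0
    return mask.n_voxels * voxel_ml


def total_lesion_glycolysis(mtv_ml: float, suv_mean: float) -> float:
    """TLG = MTV × SUVmean."""
    if mtv_ml <= 0 or suv_mean <= 0:
        raise ValueError("TLG requires positive MTV and SUVmean")
    return mtv_ml * suv_mean


def percent_change(baseline_value: float, followup_value: float) -> float:
    """((follow-up / baseline) − 1) × 100."""
    if baseline_value == 0:
        raise UndefinedChangeError("percent change undefined for zero baseline")
    return (followup_value / baseline_value - 1.0) * 100.0


def extract_conventional(vol: PetVolume, mask: VoiMask) -> ConventionalFeatures:
    suv_max, suv_mean = suv_stats(vol, mask)
    mtv = metabolic_tumor_volume(mask)
    return ConventionalFeatures(
        suv_max=suv_max,
        suv_mean=suv_mean,
        mtv_ml=mtv,
        tlg=total_lesion_glycolysis(mtv, suv_mean),
    )
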