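"""PET volume / VOI mask I/O and SUV conversion.

Volumes and masks travel as NIfTI-1/2 files; acquisition metadata needed for
SUV conversion (injected activity, injection and scan times, body weight)
lives in a small JSON sidecar.  Feature tables are plain CSV.

SUV here is the body-weight-normalised standardized uptake value: tissue
activity concentration divided by decay-corrected injected dose per kilogram
of body weight, with the usual 1 g/ml tissue-density convention so that
kg→ml is a numeric identity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from datetime import datetime
from enum import Enum
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .records import BASELINE, FEATURE_NAMES, FeatureRecord

#: Physical half-life of fluorine-18, minutes.
F18_HALF_LIFE_MIN = 109.77

#: Tolerance for declaring two voxel grids aligned, in mm per axis.
SPACING_ATOL_MM = 1e-3


class Units(str, Enum):
    """What the scalar values of a volume mean."""

    ACTIVITY_CONC = "activity_conc"  # kBq/ml
    SUV = "suv"  # dimensionless (g/ml)


class FormatError(ValueError):
    """File missing, unparsable, or not a 3D scalar image."""


class AlignmentError(ValueError):
    """Mask and volume do not live on the same voxel grid."""


class ParameterError(ValueError):
    """Physically invalid acquisition parameter (non-positive dose/weight)."""


@dataclass(frozen=True)
class PetVolume:
    values: np.ndarray  # 3D, float64, finite, >= 0
    spacing: tuple[float, float, float]  # mm per axis
    units: Units = Units.SUV

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3:
            raise FormatError(f"expected a 3D scalar image, got ndim={v.ndim}")
        if not np.all(np.isfinite(v)):
            raise FormatError("volume contains non-finite values")
        if v.min() < 0:
            raise FormatError("volume contains negative values")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise FormatError(f"spacing must be 3 positive reals, got {self.spacing}")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "spacing", sp)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in ml (= cm³); spacing is in mm."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclass(frozen=True)
class VoiMask:
    voxels: np.ndarray  # 3D bool
    spacing: tuple[float, float, float]
    label: str = "lesion"

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=bool)
        if v.ndim != 3:
            raise FormatError(f"mask must be 3D, got ndim={v.ndim}")
        sp = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in sp):
            raise FormatError("mask spacing must be positive")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "spacing", sp)

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


@dataclass(frozen=True)
class AcquisitionMeta:
    """What is needed to turn activity concentration into SUV."""

    injected_activity_mbq: float
    injection_time: datetime
    scan_time: datetime
    body_weight_kg: float
    isotope_half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        if self.injected_activity_mbq <= 0:
            raise ParameterError("injected activity must be > 0 MBq")
        if self.body_weight_kg <= 0:
            raise ParameterError("body weight must be > 0 kg")
        if self.scan_time < self.injection_time:
            raise ParameterError("scan time precedes injection time")
        if self.isotope_half_life_min <= 0:
            raise ParameterError("half-life must be positive")

    @property
    def uptake_minutes(self) -> float:
        return (self.scan_time - self.injection_time).total_seconds() / 60.0

    def decay_corrected_dose_kbq(self) -> float:
        """Injected dose decayed to scan time, in kBq."""
        decay = 2.0 ** (-self.uptake_minutes / self.isotope_half_life_min)
        return self.injected_activity_mbq * 1000.0 * decay

    @classmethod
    def from_json(cls, path: str | Path) -> "AcquisitionMeta":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            injected_activity_mbq=float(d["injected_activity_MBq"]),
            injection_time=datetime.fromisoformat(d["injection_time"]),
            scan_time=datetime.fromisoformat(d["scan_time"]),
            body_weight_kg=float(d["body_weight_kg"]),
            isotope_half_life_min=float(d.get("isotope_half_life_min", F18_HALF_LIFE_MIN)),
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "injected_activity_MBq": self.injected_activity_mbq,
                    "injection_time": self.injection_time.isoformat(),
                    "scan_time": self.scan_time.isoformat(),
                    "body_weight_kg": self.body_weight_kg,
                    "isotope_half_life_min": self.isotope_half_life_min,
                },
                fh,
                indent=2,
            )


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, ...]]:
    p = Path(path)
    if not p.exists():
        raise FormatError(f"no such file: {p}")
    try:
        img = nib.load(str(p))
        data = np.asarray(img.get_fdata(dtype=np.float64))
        zooms = img.header.get_zooms()
    except FormatError:
        raise
    except Exception as exc:  # nibabel raises a zoo of error types
        raise FormatError(f"could not parse {p} as NIfTI: {exc}") from exc
    return data, tuple(float(z) for z in zooms[:3])


def read_volume(path: str | Path, units: Units = Units.ACTIVITY_CONC) -> PetVolume:
    """Read a 3D PET volume from NIfTI; orientation is recorded by nibabel but
    the grid is not resampled."""
    data, spacing = _load_nifti(path)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D image, got shape {data.shape}")
    return PetVolume(values=data, spacing=spacing, units=units)


def write_volume(vol: PetVolume, path: str | Path) -> None:
    affine = np.diag(list(vol.spacing) + [1.0])
    nib.save(nib.Nifti1Image(vol.values.astype(np.float64), affine), str(path))


def read_mask(path: str | Path, reference: PetVolume, label: str = "lesion") -> VoiMask:
    """Read a binary VOI mask and check it shares the reference volume's grid."""
    data, spacing = _load_nifti(path)
    if data.shape != reference.shape:
        raise AlignmentError(
            f"mask shape {data.shape} does not match volume shape {reference.shape}"
        )
    if any(abs(a - b) > SPACING_ATOL_MM for a, b in zip(spacing, reference.spacing)):
        raise AlignmentError(
            f"mask spacing {spacing} does not match volume spacing {reference.spacing}"
        )
    return VoiMask(voxels=data != 0, spacing=reference.spacing, label=label)


def write_mask(mask: VoiMask, path: str | Path) -> None:
    affine = np.diag(list(mask.spacing) + [1.0])
    nib.save(nib.Nifti1Image(mask.voxels.astype(np.uint8), affine), str(path))


def to_suv(vol: PetVolume, meta: AcquisitionMeta) -> PetVolume:
    """Convert activity concentration (kBq/ml) to body-weight SUV.

    SUV(v) = c(v) / (D_corr / W) with D_corr the decay-corrected injected
    dose in kBq and W the body weight in grams (1 g/ml density convention).
    """
    if vol.units is not Units.ACTIVITY_CONC:
        raise ParameterError("to_suv expects a volume in activity-concentration units")
    dose_per_g = meta.decay_corrected_dose_kbq() / (meta.body_weight_kg * 1000.0)
    return PetVolume(values=vol.values / dose_per_g, spacing=vol.spacing, units=Units.SUV)


def from_suv(vol: PetVolume, meta: AcquisitionMeta) -> PetVolume:
    """Inverse of :func:`to_suv` (SUV back to kBq/ml)."""
    if vol.units is not Units.SUV:
        raise ParameterError("from_suv expects a volume in SUV units")
    dose_per_g = meta.decay_corrected_dose_kbq() / (meta.body_weight_kg * 1000.0)
    return PetVolume(
        values=vol.values * dose_per_g, spacing=vol.spacing, units=Units.ACTIVITY_CONC
    )


def merge_masks(masks: list[VoiMask]) -> VoiMask:
    """Voxel-wise union of per-lesion masks into one whole-burden VOI."""
    if not masks:
        raise ValueError("merge_masks needs at least one mask")
    first = masks[0]
    union = first.voxels.copy()
    for m in masks[1:]:
        if m.voxels.shape != first.voxels.shape:
            raise AlignmentError("masks to merge must share a grid shape")
        if any(abs(a - b) > SPACING_ATOL_MM for a, b in zip(m.spacing, first.spacing)):
            raise AlignmentError("masks to merge must share voxel spacing")
        union |= m.voxels
    return VoiMask(voxels=union, spacing=first.spacing, label="merged")


# ---------------------------------------------------------------------------
# feature tables

_DELTA_COLUMNS = tuple(f"delta_{name}_pct" for name in FEATURE_NAMES)
FEATURE_TABLE_COLUMNS = ("patient_id", "timepoint") + FEATURE_NAMES + _DELTA_COLUMNS


def records_to_frame(records: list[FeatureRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row: dict[str, object] = {"patient_id": rec.patient_id, "timepoint": rec.timepoint}
        for name in FEATURE_NAMES:
            row[name] = rec.features.get(name, math.nan)
        if rec.timepoint == BASELINE and rec.deltas:
            for name, value in rec.deltas.items():
                row[f"delta_{name}_pct"] = value
        rows.append(row)
    return pd.DataFrame(rows, columns=list(FEATURE_TABLE_COLUMNS))


def write_feature_table(records: list[FeatureRecord] | pd.DataFrame, path: str | Path) -> None:
    """CSV with one row per patient-timepoint, fixed column order, empty cells
    for missing values; floats kept to 12 significant digits."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df = df.reindex(columns=list(FEATURE_TABLE_COLUMNS))
    df.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
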