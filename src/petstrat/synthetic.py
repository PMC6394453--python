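"""Synthetic phantoms and cohorts.

Two generators make every downstream stage testable without patient data:

* :func:`generate_phantom` builds 3D SUV volumes containing spherical
  lesions with controllable intratumoral texture (uniform, checkerboard,
  Gaussian-noise or radial-gradient fills) plus additive Gaussian grid noise
  clipped at zero.  Lesion geometry is deliberately spherical — the texture
  features under study are intensity-based, so heterogeneity comes from the
  fill pattern, not the shape.

* :func:`generate_cohort` draws a cohort whose members belong to a latent
  low/high-risk group: features come from group-conditional log-normals and
  event times from exponential distributions with hazard λ·HR^group, so the
  proportional-hazards assumption holds exactly and Cox recovery of the
  generative hazard ratio is an unambiguous oracle.  A fraction of patients
  lacks follow-up feature records, mirroring incomplete follow-up imaging.

All randomness flows through one explicitly seeded numpy Generator per call;
no global random state is touched.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import yaml

from .conventional import percent_change
from .records import BASELINE, FOLLOWUP, FEATURE_NAMES, FeatureRecord, SurvivalRecord
from .volume_io import PetVolume, Units, VoiMask


class LesionPattern(str, Enum):
    UNIFORM = "uniform"
    GAUSSIAN_NOISE = "gaussian_noise"
    CHECKERBOARD = "checkerboard"
    RADIAL_GRADIENT = "radial_gradient"


@dataclass(frozen=True)
class LesionSpec:
    center: tuple[int, int, int]  # voxel coordinates
    radius_mm: float
    pattern: LesionPattern = LesionPattern.UNIFORM
    mean_suv: float = 5.0
    amplitude: float = 0.0


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (64, 64, 32)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    background_suv: float = 0.5
    lesions: tuple[LesionSpec, ...] = ()
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_suv < 0 or self.noise_sd < 0:
            raise ValueError("background SUV and noise SD must be >= 0")
        max_sp = max(self.spacing)
        for les in self.lesions:
            if les.mean_suv <= self.background_suv:
                raise ValueError("lesion mean SUV must exceed the background SUV")
            if les.radius_mm < 2 * max_sp:
                raise ValueError("lesion radius must be at least 2 voxels across")
            for c, s, sp in zip(les.center, self.grid_shape, self.spacing):
                r_vox = les.radius_mm / sp
                if c - r_vox < 0 or c + r_vox > s - 1:
                    raise ValueError(f"lesion at {les.center} does not fit within the grid")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        lesions = tuple(
            LesionSpec(
                center=tuple(l["center"]),
                radius_mm=float(l["radius_mm"]),
                pattern=LesionPattern(l.get("pattern", "uniform")),
                mean_suv=float(l.get("mean_suv", 5.0)),
                amplitude=float(l.get("amplitude", 0.0)),
            )
            for l in d.get("lesions", [])
        )
        return cls(
            grid_shape=tuple(d.get("grid_shape", (64, 64, 32))),
            spacing=tuple(d.get("spacing", (2.0, 2.0, 2.0))),
            background_suv=float(d.get("background_suv", 0.5)),
            lesions=lesions,
            noise_sd=float(d.get("noise_sd", 0.0)),
            seed=int(d.get("seed", 0)),
        )


def generate_phantom(spec: PhantomSpec) -> tuple[PetVolume, list[VoiMask]]:
    """Render a phantom SUV volume and one mask per lesion.

    Deterministic for a fixed spec (seed included).  Grid noise is drawn
    first over the whole volume, lesion fills are applied in listed order;
    where lesions overlap, the earlier lesion keeps ownership of the shared
    voxels (a warning is emitted) while every mask still covers its full
    sphere.  The final volume is clipped at 0.
    """
    rng = np.random.default_rng(spec.seed)
    vol = np.full(spec.grid_shape, spec.background_suv, dtype=np.float64)
    if spec.noise_sd > 0:
        vol += rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)

    coords = np.meshgrid(*(np.arange(s) for s in spec.grid_shape), indexing="ij")
    claimed = np.zeros(spec.grid_shape, dtype=bool)
    masks: list[VoiMask] = []
    for idx, les in enumerate(spec.lesions):
        dist_sq = sum(
            ((c - cc) * sp) ** 2 for c, cc, sp in zip(coords, les.center, spec.spacing)
        )
        sphere = dist_sq <= les.radius_mm**2
        own = sphere & ~claimed
        if (sphere & claimed).any():
            warnings.warn(
                f"lesion {idx} overlaps an earlier lesion; shared voxels keep "
                "the earlier lesion's fill",
                stacklevel=2,
            )
        if les.pattern is LesionPattern.UNIFORM:
            fill = np.full(int(own.sum()), les.mean_suv)
        elif les.pattern is LesionPattern.CHECKERBOARD:
            parity = (coords[0] + coords[1] + coords[2])[own] % 2
            fill = les.mean_suv + les.amplitude * np.where(parity == 0, 1.0, -1.0)
        elif les.pattern is LesionPattern.GAUSSIAN_NOISE:
            fill = les.mean_suv + rng.normal(0.0, les.amplitude, size=int(own.sum()))
        elif les.pattern is LesionPattern.RADIAL_GRADIENT:
            frac = np.sqrt(dist_sq[own]) / les.radius_mm  # 0 at center, 1 at edge
            fill = les.mean_suv + les.amplitude * (1.0 - frac)
        else:  # pragma: no cover
            raise ValueError(f"unknown pattern {les.pattern}")
        vol[own] = fill
        claimed |= sphere
        masks.append(VoiMask(voxels=sphere, spacing=spec.spacing, label=f"lesion_{idx}"))

    np.clip(vol, 0.0, None, out=vol)
    return PetVolume(values=vol, spacing=spec.spacing, units=Units.SUV), masks


# ---------------------------------------------------------------------------
# cohort generation

#: Group-conditional log-normal parameters (meanlog, sdlog) per feature.
#: Locations are loosely calibrated to whole-burden FDG-PET magnitudes in
#: advanced medullary thyroid cancer; complexity, TLG and contrast carry the
#: group signal (the prognostic parameters), the rest are identical across
#: groups.
DEFAULT_FEATURE_DISTRIBUTIONS: dict[str, dict[str, tuple[float, float]]] = {
    "suv_max": {"low": (math.log(7.0), 0.35), "high": (math.log(7.0), 0.35)},
    "suv_mean": {"low": (math.log(3.2), 0.25), "high": (math.log(3.2), 0.25)},
    "mtv_ml": {"low": (math.log(300.0), 0.8), "high": (math.log(300.0), 0.8)},
    "tlg": {"low": (math.log(700.0), 0.5), "high": (math.log(9000.0), 0.5)},
    "std_dev": {"low": (math.log(1.1), 0.35), "high": (math.log(1.1), 0.35)},
    "kurtosis": {"low": (math.log(0.9), 0.5), "high": (math.log(0.9), 0.5)},
    "entropy": {"low": (math.log(4.0), 0.15), "high": (math.log(4.0), 0.15)},
    "homogeneity": {"low": (math.log(0.4), 0.2), "high": (math.log(0.4), 0.2)},
    "busyness": {"low": (math.log(0.8), 0.6), "high": (math.log(0.8), 0.6)},
    "coarseness": {"low": (math.log(0.1), 0.5), "high": (math.log(0.1), 0.5)},
    "complexity": {"low": (math.log(30.0), 0.4), "high": (math.log(150.0), 0.4)},
    "contrast": {"low": (math.log(7.0), 0.45), "high": (math.log(22.0), 0.45)},
}

#: Multiplicative baseline→follow-up change, log-normal (meanlog, sdlog),
#: calibrated to the observed cohort-level declines under TKI therapy
#: (everything falls except homogeneity, which rises).
DEFAULT_FOLLOWUP_CHANGE: dict[str, tuple[float, float]] = {
    "suv_max": (math.log(0.72), 0.2),
    "suv_mean": (math.log(0.70), 0.2),
    "mtv_ml": (math.log(0.77), 0.2),
    "tlg": (math.log(0.29), 0.3),
    "std_dev": (math.log(0.67), 0.2),
    "kurtosis": (math.log(0.99), 0.2),
    "entropy": (math.log(0.83), 0.1),
    "homogeneity": (math.log(1.25), 0.1),
    "busyness": (math.log(0.26), 0.3),
    "coarseness": (math.log(0.83), 0.2),
    "complexity": (math.log(0.61), 0.3),
    "contrast": (math.log(0.62), 0.3),
}


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters of a synthetic TKI-treated cohort.

    Defaults emulate an 18-patient advanced-MTC cohort: ~55% high-risk,
    overall-survival hazard ≈ 0.17/year in the low-risk group (median ≈ 4 y),
    hazard ratio 6 for the high-risk group, per-patient administrative
    censoring between 3 and 10.3 years of follow-up, and 2/18 patients
    without follow-up imaging.
    """

    n_patients: int = 18
    feature_distributions: dict = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_DISTRIBUTIONS)
    )
    followup_change: dict = field(default_factory=lambda: dict(DEFAULT_FOLLOWUP_CHANGE))
    fraction_high: float = 0.55
    baseline_hazard: float = 0.17  # OS events per year, low-risk group
    pfs_hazard_multiplier: float = 2.0  # progression hazard relative to death hazard
    hazard_ratio: float = 6.0
    censor_time: float = 10.3  # years, longest administrative follow-up
    min_followup: float = 3.0  # years, shortest administrative follow-up
    followup_drop_fraction: float = 2.0 / 18.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 4:
            raise ValueError("cohort needs at least 4 patients")
        if not 0 < self.fraction_high < 1:
            raise ValueError("fraction_high must be in (0, 1)")
        if self.hazard_ratio <= 0 or self.baseline_hazard <= 0 or self.censor_time <= 0:
            raise ValueError("hazards, hazard ratio and censor time must be positive")
        if not 0 < self.min_followup <= self.censor_time:
            raise ValueError("min_followup must lie in (0, censor_time]")
        if not 0 <= self.followup_drop_fraction < 1:
            raise ValueError("followup_drop_fraction must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in (
            "n_patients",
            "fraction_high",
            "baseline_hazard",
            "pfs_hazard_multiplier",
            "hazard_ratio",
            "censor_time",
            "min_followup",
            "followup_drop_fraction",
            "seed",
        ):
            if key in d:
                kwargs[key] = d[key]
        if "feature_distributions" in d:
            kwargs["feature_distributions"] = {
                name: {grp: tuple(v) for grp, v in groups.items()}
                for name, groups in d["feature_distributions"].items()
            }
        if "followup_change" in d:
            kwargs["followup_change"] = {
                name: tuple(v) for name, v in d["followup_change"].items()
            }
        return cls(**kwargs)


def generate_cohort(spec: CohortSpec) -> tuple[list[FeatureRecord], list[SurvivalRecord]]:
    """Draw a synthetic cohort: feature records (baseline + follow-up with
    percent-change deltas) and survival records whose hazard depends on the
    latent group with the specified hazard ratio."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    group = rng.binomial(1, spec.fraction_high, size=n)
    tries = 0
    while group.min() == group.max():
        tries += 1
        if tries > 100:
            raise RuntimeError("could not draw a cohort with both risk groups present")
        warnings.warn("degenerate single-group cohort drawn; regenerating group labels")
        group = rng.binomial(1, spec.fraction_high, size=n)

    baseline: dict[str, np.ndarray] = {}
    followup: dict[str, np.ndarray] = {}
    for name in FEATURE_NAMES:
        dist = spec.feature_distributions[name]
        mu = np.where(group == 1, dist["high"][0], dist["low"][0])
        sd = np.where(group == 1, dist["high"][1], dist["low"][1])
        baseline[name] = rng.lognormal(mu, sd)
        mu_c, sd_c = spec.followup_change[name]
        followup[name] = baseline[name] * rng.lognormal(mu_c, sd_c, size=n)
    # homogeneity is bounded by 1 in the real feature space
    baseline["homogeneity"] = np.minimum(baseline["homogeneity"], 1.0)
    followup["homogeneity"] = np.minimum(followup["homogeneity"], 1.0)

    hr_g = spec.hazard_ratio ** group.astype(float)
    os_raw = rng.exponential(1.0 / (spec.baseline_hazard * hr_g))
    prog_raw = rng.exponential(1.0 / (spec.pfs_hazard_multiplier * spec.baseline_hazard * hr_g))
    pfs_raw = np.minimum(prog_raw, os_raw)

    # per-patient administrative censoring: staggered accrual means follow-up
    # ranges from min_followup to censor_time years
    admin = (
        rng.uniform(spec.min_followup, spec.censor_time, size=n)
        if spec.censor_time > spec.min_followup
        else np.full(n, spec.censor_time)
    )
    os_years = np.minimum(os_raw, admin)
    os_event = os_raw < admin
    pfs_years = np.minimum(pfs_raw, admin)
    pfs_event = pfs_raw < admin

    age = np.clip(rng.normal(52.0, 12.0, size=n), 18.0, 85.0)
    sex = rng.binomial(1, 1.0 / 3.0, size=n)  # 1 = female

    n_drop = int(round(spec.followup_drop_fraction * n))
    dropped = set(rng.choice(n, size=n_drop, replace=False).tolist()) if n_drop else set()

    feature_records: list[FeatureRecord] = []
    survival_records: list[SurvivalRecord] = []
    for i in range(n):
        pid = f"P{i + 1:03d}"
        base_feats = {name: float(baseline[name][i]) for name in FEATURE_NAMES}
        if i in dropped:
            feature_records.append(FeatureRecord(pid, BASELINE, base_feats))
        else:
            fup_feats = {name: float(followup[name][i]) for name in FEATURE_NAMES}
            deltas = {
                name: percent_change(base_feats[name], fup_feats[name])
                for name in FEATURE_NAMES
            }
            feature_records.append(FeatureRecord(pid, BASELINE, base_feats, deltas=deltas))
            feature_records.append(FeatureRecord(pid, FOLLOWUP, fup_feats))
        survival_records.append(
            SurvivalRecord(
                patient_id=pid,
                pfs_years=float(pfs_years[i]),
                pfs_event=bool(pfs_event[i]),
                os_years=float(os_years[i]),
                os_event=bool(os_event[i]),
                covariates={
                    "group": float(group[i]),
                    "age": float(age[i]),
                    "sex": float(sex[i]),
                },
            )
        )
    return feature_records, survival_records


def survival_to_frame(records: list[SurvivalRecord]):
    """Survival records as a DataFrame with the canonical CSV schema."""
    import pandas as pd

    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "pfs_years": r.pfs_years,
            "pfs_event": int(r.pfs_event),
            "os_years": r.os_years,
            "os_event": int(r.os_event),
        }
        row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)
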