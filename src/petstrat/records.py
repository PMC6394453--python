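"""Shared per-patient record types used across the feature and survival layers."""

from __future__ import annotations

from dataclasses import dataclass, field

#: Fixed 12-parameter vocabulary: 4 conventional + 8 texture features.
FEATURE_NAMES: tuple[str, ...] = (
    "suv_max",
    "suv_mean",
    "mtv_ml",
    "tlg",
    "std_dev",
    "kurtosis",
    "entropy",
    "homogeneity",
    "busyness",
    "coarseness",
    "complexity",
    "contrast",
)

BASELINE = "baseline"
FOLLOWUP = "followup"


@dataclass
class FeatureRecord:
    """Feature values for one patient at one timepoint.

    ``deltas`` holds baseline→follow-up percent changes, keyed by feature
    name; it is only populated on baseline records of patients for whom a
    follow-up scan exists.
    """

    patient_id: str
    timepoint: str  # BASELINE or FOLLOWUP
    features: dict[str, float]
    deltas: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.timepoint not in (BASELINE, FOLLOWUP):
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        unknown = set(self.features) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature names: {sorted(unknown)}")
        if self.deltas is not None and self.timepoint != BASELINE:
            raise ValueError("deltas are carried on baseline records only")


@dataclass
class SurvivalRecord:
    """Per-patient survival endpoints (years from treatment start) and covariates."""

    patient_id: str
    pfs_years: float
    pfs_event: bool
    os_years: float
    os_event: bool
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pfs_years < 0 or self.os_years < 0:
            raise ValueError("survival durations must be non-negative")
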