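"""Pipeline orchestration: per-patient feature extraction over the merged
whole-burden VOI at each timepoint, percent-change deltas, and the
feature→outcome stratification report (ROC/Youden cutoff, Kaplan–Meier,
log-rank, univariate and multivariate Cox)."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import conventional, survival, texture
from .records import BASELINE, FOLLOWUP, FEATURE_NAMES, FeatureRecord
from .volume_io import PetVolume, VoiMask, merge_masks, read_mask, read_volume, Units

log = logging.getLogger("petstrat")

ENDPOINTS = ("pfs", "os")


@dataclass
class PipelineConfig:
    gray_levels: int = texture.DEFAULT_GRAY_LEVELS
    epsilon: float = texture.DEFAULT_EPSILON
    endpoints: tuple[str, ...] = ENDPOINTS
    features: tuple[str, ...] = FEATURE_NAMES
    alpha: float = 0.05  # ROC significance gate for KM/Cox follow-through
    seed: int | None = None
    out_dir: str = "results"

    def __post_init__(self) -> None:
        bad = set(self.features) - set(FEATURE_NAMES) - {f"delta_{n}_pct" for n in FEATURE_NAMES}
        if bad:
            raise ValueError(f"unknown features in config: {sorted(bad)}")
        if set(self.endpoints) - set(ENDPOINTS):
            raise ValueError(f"endpoints must be a subset of {ENDPOINTS}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        kwargs = {k: d[k] for k in
                  ("gray_levels", "epsilon", "alpha", "seed", "out_dir") if k in d}
        if "endpoints" in d:
            kwargs["endpoints"] = tuple(d["endpoints"])
        if "features" in d:
            kwargs["features"] = tuple(d["features"])
        return cls(**kwargs)


def extract_patient_features(
    vol: PetVolume,
    masks: list[VoiMask],
    gray_levels: int = texture.DEFAULT_GRAY_LEVELS,
    epsilon: float = texture.DEFAULT_EPSILON,
) -> dict[str, float]:
    """All 12 parameters of one scan, computed on the merged whole-burden VOI."""
    merged = merge_masks(masks)
    conv = conventional.extract_conventional(vol, merged)
    tex = texture.extract_texture(vol, merged, gray_levels=gray_levels, epsilon=epsilon)
    out = {
        "suv_max": conv.suv_max,
        "suv_mean": conv.suv_mean,
        "mtv_ml": conv.mtv_ml,
        "tlg": conv.tlg,
    }
    out.update(tex.as_dict())
    return out


@dataclass
class PatientScans:
    """File-system pointers for one patient: a baseline scan with ≥1 mask,
    optionally a follow-up scan with its own masks."""

    patient_id: str
    baseline_volume: str
    baseline_masks: list[str]
    followup_volume: str | None = None
    followup_masks: list[str] = field(default_factory=list)


def _load_and_extract(volume_path: str, mask_paths: list[str], cfg: PipelineConfig,
                      units: Units) -> dict[str, float]:
    vol = read_volume(volume_path, units=units)
    masks = [read_mask(p, vol, label=Path(p).stem) for p in mask_paths]
    return extract_patient_features(vol, masks, cfg.gray_levels, cfg.epsilon)


def run_extract(
    patients: list[PatientScans],
    config: PipelineConfig | None = None,
    units: Units = Units.SUV,
) -> list[FeatureRecord]:
    """Extract baseline (+ follow-up + delta) features for a cohort.

    Per-patient failures are logged and skipped so one bad mask never kills
    a cohort run; if every patient fails, a RuntimeError is raised.
    """
    cfg = config or PipelineConfig()
    records: list[FeatureRecord] = []
    n_failed = 0
    for pat in patients:
        try:
            base = _load_and_extract(pat.baseline_volume, pat.baseline_masks, cfg, units)
            deltas = None
            fup = None
            if pat.followup_volume is not None:
                fup = _load_and_extract(pat.followup_volume, pat.followup_masks, cfg, units)
                deltas = {
                    name: conventional.percent_change(base[name], fup[name])
                    for name in FEATURE_NAMES
                    if base[name] != 0
                }
            records.append(FeatureRecord(pat.patient_id, BASELINE, base, deltas=deltas))
            if fup is not None:
                records.append(FeatureRecord(pat.patient_id, FOLLOWUP, fup))
            log.info("extracted %s (follow-up: %s)", pat.patient_id, fup is not None)
        except Exception as exc:
            n_failed += 1
            log.error("skipping %s: %s", pat.patient_id, exc)
    if patients and not records:
        raise RuntimeError("feature extraction failed for every patient")
    if n_failed:
        log.warning("%d/%d patients skipped", n_failed, len(patients))
    return records


# ---------------------------------------------------------------------------
# stratification report


def run_stratify(
    features: pd.DataFrame,
    survival_table: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Per feature × endpoint stratification report.

    For each feature and endpoint: ROC AUC and Mann–Whitney p, Youden
    cutoff with sensitivity/specificity, high/low group sizes, Kaplan–Meier
    median survival per group, log-rank p, and univariate Cox HR with 95% CI.
    Features whose ROC reaches ``config.alpha`` additionally enter one
    multivariate Cox model per endpoint (dichotomized at their cutoffs).
    Raw p-values are reported without multiplicity correction.
    """
    cfg = config or PipelineConfig()
    base = features[features["timepoint"] == BASELINE] if "timepoint" in features else features
    merged = base.merge(survival_table, on="patient_id", how="inner")
    if len(merged) < 4:
        raise ValueError("need at least 4 patients after joining features and survival")

    rows = []
    mv_terms: dict[str, list[tuple[str, np.ndarray]]] = {ep: [] for ep in cfg.endpoints}
    for endpoint in cfg.endpoints:
        times = merged[f"{endpoint}_years"].to_numpy(float)
        events = merged[f"{endpoint}_event"].to_numpy().astype(bool)
        if events.all() or not events.any():
            raise ValueError(f"endpoint {endpoint} has a single outcome class")
        for feat in cfg.features:
            values = merged[feat].to_numpy(float)
            if np.isnan(values).any():
                ok = ~np.isnan(values)
                curve = survival.roc_auc(values[ok], events[ok])
            else:
                ok = np.ones(values.size, dtype=bool)
                curve = survival.roc_auc(values, events)
            cut = survival.youden_cutoff(curve, feature_name=feat, endpoint=endpoint)
            row = {
                "feature": feat,
                "endpoint": endpoint,
                "roc_p": cut.p_value,
                "cutoff": cut.cutoff,
                "sensitivity_pct": cut.sensitivity,
                "specificity_pct": cut.specificity,
                "auc": cut.auc,
                "n_above": cut.n_above,
                "n_below": cut.n_below,
            }
            high = survival.assign_groups(values[ok], cut.cutoff)
            t_ok, e_ok = times[ok], events[ok]
            if 0 < high.sum() < high.size and e_ok.sum() > 0:
                km_hi = survival.km_estimate(t_ok[high], e_ok[high])
                km_lo = survival.km_estimate(t_ok[~high], e_ok[~high])
                _, lr_p = survival.logrank_test(t_ok[high], e_ok[high], t_ok[~high], e_ok[~high])
                cox = survival.cox_fit(high.astype(float)[:, None], t_ok, e_ok, terms=[feat])
                row.update(
                    median_above=km_hi.median,
                    median_below=km_lo.median,
                    logrank_p=lr_p,
                    cox_hr=float(cox.hazard_ratio[0]),
                    cox_ci_low=float(cox.ci95[0, 0]),
                    cox_ci_high=float(cox.ci95[0, 1]),
                    cox_p=float(cox.p_value[0]),
                    cox_flags="; ".join(cox.flags),
                )
                if cut.p_value < cfg.alpha and not cut.degenerate:
                    mv_terms[endpoint].append((feat, high.astype(float)))
            else:
                row.update(
                    median_above=math.nan, median_below=math.nan, logrank_p=math.nan,
                    cox_hr=math.nan, cox_ci_low=math.nan, cox_ci_high=math.nan,
                    cox_p=math.nan, cox_flags="degenerate grouping; KM/Cox skipped",
                )
            rows.append(row)

    report = pd.DataFrame(rows)
    mv_rows = []
    for endpoint, terms in mv_terms.items():
        if not terms:
            continue
        times = merged[f"{endpoint}_years"].to_numpy(float)
        events = merged[f"{endpoint}_event"].to_numpy().astype(bool)
        names = [t[0] for t in terms]
        X = np.column_stack([t[1] for t in terms])
        if len(merged) > X.shape[1]:
            cox = survival.cox_fit(X, times, events, terms=names)
            for i, name in enumerate(names):
                mv_rows.append(
                    {
                        "endpoint": endpoint,
                        "term": name,
                        "hr": float(cox.hazard_ratio[i]),
                        "ci95_low": float(cox.ci95[i, 0]),
                        "ci95_high": float(cox.ci95[i, 1]),
                        "p": float(cox.p_value[i]),
                        "flags": "; ".join(cox.flags),
                    }
                )
    multivariate = pd.DataFrame(
        mv_rows, columns=["endpoint", "term", "hr", "ci95_low", "ci95_high", "p", "flags"]
    )
    return {"univariate": report, "multivariate": multivariate}


def cohort_change_summary(features: pd.DataFrame) -> pd.DataFrame:
    """Cohort-level summary: per parameter, baseline and follow-up mean
    (range) and the percent change of the cohort means, rounded to one
    decimal for presentation."""
    base = features[features["timepoint"] == BASELINE]
    fup = features[features["timepoint"] == FOLLOWUP]
    rows = []
    for name in FEATURE_NAMES:
        b = base[name].dropna()
        f = fup[name].dropna()
        row = {
            "parameter": name,
            "baseline_mean": b.mean(),
            "baseline_min": b.min(),
            "baseline_max": b.max(),
            "followup_mean": f.mean() if len(f) else math.nan,
            "followup_min": f.min() if len(f) else math.nan,
            "followup_max": f.max() if len(f) else math.nan,
        }
        if len(f) and b.mean() != 0:
            row["change_pct"] = round(conventional.percent_change(b.mean(), f.mean()), 1)
        else:
            row["change_pct"] = math.nan
        rows.append(row)
    return pd.DataFrame(rows)


def report_to_markdown(report: dict[str, pd.DataFrame]) -> str:
    """Stratification report in a compact Markdown layout."""
    uni = report["univariate"]
    lines = [
        "# Outcome stratification report",
        "",
        "Raw p-values; no multiple-testing correction applied.",
        "",
        "## ROC / Kaplan-Meier / univariate Cox",
        "",
        uni.to_markdown(index=False, floatfmt=".3g"),
        "",
    ]
    mv = report["multivariate"]
    lines += ["## Multivariate Cox (ROC-significant features, dichotomized)", ""]
    lines.append(mv.to_markdown(index=False, floatfmt=".3g") if len(mv) else "_no feature reached the ROC significance gate_")
    lines.append("")
    return "\n".join(lines)


def write_report(report: dict[str, pd.DataFrame], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report["univariate"].to_csv(out / "stratification_univariate.csv", index=False)
    report["multivariate"].to_csv(out / "stratification_multivariate.csv", index=False)
    (out / "stratification_report.md").write_text(report_to_markdown(report))
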