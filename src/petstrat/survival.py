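"""Survival endpoints, ROC/Youden dichotomization, Kaplan–Meier, log-rank,
Cox proportional hazards, and tumor-marker doubling time.

The Cox fit is a Newton maximization of the partial likelihood with Breslow
(default) or Efron handling of tied event times; Wald standard errors come
from the observed information.  Kaplan–Meier curves, log-rank tests and the
reverse-KM median follow-up are delegated to lifelines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

DAYS_PER_YEAR = 365.25


class DataError(ValueError):
    """Chronologically impossible or otherwise invalid survival input."""


# ---------------------------------------------------------------------------
# endpoint construction


def build_endpoints(
    start: date,
    progression: date | None,
    death: date | None,
    censor: date,
) -> dict:
    """PFS/OS durations in years from treatment start.

    PFS runs to RECIST progression (event) or the censor date; OS runs to
    death (event) or the censor date.
    """
    for name, d in (("progression", progression), ("death", death), ("censor", censor)):
        if d is not None and d < start:
            raise DataError(f"{name} date precedes treatment start")
    pfs_end = progression if progression is not None else censor
    os_end = death if death is not None else censor
    return {
        "pfs_years": (pfs_end - start).days / DAYS_PER_YEAR,
        "pfs_event": progression is not None,
        "os_years": (os_end - start).days / DAYS_PER_YEAR,
        "os_event": death is not None,
    }


# ---------------------------------------------------------------------------
# ROC / Youden


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    values: np.ndarray
    labels: np.ndarray
    auc: float
    p_value: float  # two-sided Mann-Whitney test of AUC = 0.5


@dataclass
class CutoffResult:
    feature_name: str
    endpoint: str
    cutoff: float
    sensitivity: float  # percent
    specificity: float  # percent
    auc: float
    p_value: float
    n_above: int
    n_below: int
    degenerate: bool = False

    @property
    def youden_j(self) -> float:
        return self.sensitivity / 100.0 + self.specificity / 100.0 - 1.0


def roc_auc(values, labels) -> RocCurve:
    """ROC curve and AUC for predicting the binary outcome from the feature.

    AUC is the tie-aware Mann–Whitney concordance probability (ties count
    one half), computed from ranks.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(int)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("values and labels must be equal-length 1D arrays")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present for ROC analysis")
    ranks = stats.rankdata(v)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    if np.all(v == v[0]):
        p = 1.0
    else:
        p = float(
            stats.mannwhitneyu(v[y == 1], v[y == 0], alternative="two-sided").pvalue
        )
    fpr, tpr, thr = _sk_roc_curve(y, v)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, values=v, labels=y, auc=float(auc), p_value=p)


def youden_cutoff(curve: RocCurve, feature_name: str = "", endpoint: str = "") -> CutoffResult:
    """Cutoff maximizing Youden's J = sensitivity + specificity − 1.

    Candidate cutoffs are the midpoints between consecutive sorted unique
    feature values plus ±infinity; "positive" means value > cutoff.  Ties in
    J are broken toward the lowest cutoff.
    """
    v, y = curve.values, curve.labels
    uniq = np.unique(v)
    candidates = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]))
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    best_j, best_cut, best_sens, best_spec = -np.inf, candidates[0], 0.0, 0.0
    for cut in candidates:
        pred = v > cut
        sens = float((pred & (y == 1)).sum()) / n_pos
        spec = float((~pred & (y == 0)).sum()) / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-15:
            best_j, best_cut, best_sens, best_spec = j, float(cut), sens, spec
    n_above = int((v > best_cut).sum())
    degenerate = uniq.size == 1
    return CutoffResult(
        feature_name=feature_name,
        endpoint=endpoint,
        cutoff=best_cut,
        sensitivity=best_sens * 100.0,
        specificity=best_spec * 100.0,
        auc=curve.auc,
        p_value=curve.p_value,
        n_above=n_above,
        n_below=int(v.size - n_above),
        degenerate=degenerate,
    )


def assign_groups(values, cutoff: float) -> np.ndarray:
    """High-risk indicator: strictly greater than the cutoff; ties go low."""
    if not np.isfinite(cutoff) and not np.isinf(cutoff):
        raise ValueError("cutoff must not be NaN")
    return np.asarray(values, dtype=float) > cutoff


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank


@dataclass(frozen=True)
class KmEstimate:
    times: np.ndarray  # event/censor grid
    survival: np.ndarray  # S(t) at those times
    median: float  # inf when S never reaches 0.5

    @property
    def median_defined(self) -> bool:
        return math.isfinite(self.median)


def km_estimate(times, events) -> KmEstimate:
    """Product-limit survival estimate; median is the smallest t with S(t) ≤ 0.5."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    if t.size == 0:
        raise ValueError("need at least one observation")
    if (t < 0).any():
        raise DataError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    return KmEstimate(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        median=float(kmf.median_survival_time_),
    )


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-sided log-rank chi-square test; returns (statistic, p)."""
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if int(np.asarray(events_a).sum() + np.asarray(events_b).sum()) == 0:
        raise ValueError("log-rank needs at least one event")
    res = _ll_logrank(ta, tb, event_observed_A=np.asarray(events_a).astype(bool),
                      event_observed_B=np.asarray(events_b).astype(bool))
    return float(res.test_statistic), float(res.p_value)


def median_followup_reverse_km(times, events) -> float:
    """Median follow-up by the reverse Kaplan–Meier method (censoring as event)."""
    e = np.asarray(events).astype(bool)
    return km_estimate(times, ~e).median


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxResult:
    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    converged: bool
    ties: str
    log_likelihood: float
    flags: list[str] = field(default_factory=list)

    @property
    def hazard_ratio(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci95(self) -> np.ndarray:
        """exp(β ± 1.96·SE), shape (n_terms, 2)."""
        half = 1.959963984540054 * self.se
        lo = np.exp(np.clip(self.coef - half, -700, 700))
        hi = np.exp(np.clip(self.coef + half, -700, 700))
        return np.column_stack([lo, hi])

    @property
    def p_value(self) -> np.ndarray:
        z = self.coef / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def summary(self) -> pd.DataFrame:
        ci = self.ci95
        return pd.DataFrame(
            {
                "term": self.terms,
                "coef": self.coef,
                "hr": self.hazard_ratio,
                "ci95_low": ci[:, 0],
                "ci95_high": ci[:, 1],
                "p": self.p_value,
            }
        )


def cox_loglik(beta, X, times, events, ties: str = "breslow"):
    """Log partial likelihood with gradient and Hessian.

    Breslow: every death at a tied time shares the full risk-set denominator.
    Efron: the k-th of d tied deaths removes k/d of the tied mass.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(times):
        X = X.T
    n, p = X.shape
    order = np.argsort(times, kind="stable")
    X = X[order]
    t = np.asarray(times, float)[order]
    e = np.asarray(events).astype(bool)[order]

    xb = X @ beta
    xb = np.clip(xb, -500, 500)  # guard against overflow under separation
    w = np.exp(xb)
    r0 = np.cumsum(w[::-1])[::-1]  # S0 over risk set {j : t_j >= t_i}
    r1 = np.cumsum((X * w[:, None])[::-1], axis=0)[::-1]
    r2 = np.cumsum((X[:, :, None] * X[:, None, :] * w[:, None, None])[::-1], axis=0)[::-1]

    ll = float((xb[e]).sum())
    grad = X[e].sum(axis=0)
    hess = np.zeros((p, p))

    uniq, first = np.unique(t, return_index=True)
    for ut, i0 in zip(uniq, first):
        in_group = (t == ut) & e
        d = int(in_group.sum())
        if d == 0:
            continue
        S0, S1, S2 = r0[i0], r1[i0], r2[i0]
        if ties == "breslow" or d == 1:
            ll -= d * math.log(S0)
            grad -= d * S1 / S0
            hess -= d * (S2 / S0 - np.outer(S1, S1) / S0**2)
        elif ties == "efron":
            s0 = w[in_group].sum()
            s1 = (X[in_group] * w[in_group, None]).sum(axis=0)
            s2 = (
                X[in_group][:, :, None]
                * X[in_group][:, None, :]
                * w[in_group, None, None]
            ).sum(axis=0)
            for k in range(d):
                f = k / d
                D0 = S0 - f * s0
                D1 = S1 - f * s1
                D2 = S2 - f * s2
                ll -= math.log(D0)
                grad -= D1 / D0
                hess -= D2 / D0 - np.outer(D1, D1) / D0**2
        else:
            raise ValueError(f"unknown ties method {ties!r}")
    return ll, grad, hess


def cox_fit(X, times, events, terms: list[str] | None = None, ties: str = "breslow",
            tol: float = 1e-8, max_iter: int = 60) -> CoxResult:
    """Newton maximization of the Cox partial likelihood.

    Converges when the gradient's max-norm falls below ``tol``.  Monotone
    likelihood (perfect separation) or non-convergence is flagged on the
    result rather than silently reported as an estimate.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(times):
        X = X.T
    n, p = X.shape
    e = np.asarray(events).astype(bool)
    if int(e.sum()) == 0:
        raise ValueError("Cox fit needs at least one event")
    if n <= p:
        raise ValueError("need more observations than covariates")
    if terms is None:
        terms = [f"x{i}" for i in range(p)]

    beta = np.zeros(p)
    ll, grad, hess = cox_loglik(beta, X, times, events, ties)
    converged = False
    flags: list[str] = []
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            flags.append("singular information matrix")
            break
        # step halving keeps the likelihood non-decreasing
        scale = 1.0
        for _ in range(30):
            new_beta = beta + scale * step
            new_ll, new_grad, new_hess = cox_loglik(new_beta, X, times, events, ties)
            if new_ll >= ll - 1e-12:
                break
            scale /= 2.0
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
    else:
        if np.max(np.abs(grad)) < tol:
            converged = True
    if np.max(np.abs(beta)) > 20:
        converged = False
        flags.append("monotone likelihood / perfect separation suspected")
    if not converged and "monotone likelihood / perfect separation suspected" not in flags:
        flags.append("Newton iterations did not converge")

    try:
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        flags.append("information matrix not invertible")
    return CoxResult(
        terms=list(terms), coef=beta, se=se, converged=converged, ties=ties,
        log_likelihood=ll, flags=flags,
    )


# ---------------------------------------------------------------------------
# tumor-marker doubling time


@dataclass(frozen=True)
class DoublingTime:
    doubling_time_years: float  # inf when the marker is flat; negative when declining
    slope_per_year: float
    declining: bool
    flat: bool


def doubling_time(times_years, marker_values) -> DoublingTime:
    """ln 2 over the least-squares slope of ln(marker) against time."""
    t = np.asarray(times_years, dtype=float)
    m = np.asarray(marker_values, dtype=float)
    if t.size < 2 or np.unique(t).size < 2:
        raise ValueError("need at least two marker values at distinct times")
    if (m <= 0).any():
        raise ValueError("marker values must be positive for log-linear fitting")
    slope = float(np.polyfit(t, np.log(m), 1)[0])
    if abs(slope) < 1e-10:  # numerically flat marker trajectory
        return DoublingTime(math.inf, 0.0, declining=False, flat=True)
    dt = math.log(2) / slope
    return DoublingTime(float(dt), float(slope), declining=slope < 0, flat=False)
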