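"""Naive, loop-based reference implementations used as independent oracles.

Everything here is written for clarity, not speed: explicit triple loops
over voxels and neighbors, O(n²) pairwise comparisons, and direct formula
transcriptions.  These stay deliberately independent of the vectorized
implementations they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

NEIGHBORS_26 = [
    off for off in itertools.product((-1, 0, 1), repeat=3) if off != (0, 0, 0)
]


def glcm_oracle(levels: np.ndarray, mask: np.ndarray, gray_levels: int) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix by explicit pair enumeration
    over all 26 directed offsets (= 13 directions, both orderings)."""
    counts = np.zeros((gray_levels, gray_levels), dtype=float)
    shape = levels.shape
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x]:
                    continue
                for dz, dy, dx in NEIGHBORS_26:
                    zz, yy, xx = z + dz, y + dy, x + dx
                    if 0 <= zz < shape[0] and 0 <= yy < shape[1] and 0 <= xx < shape[2]:
                        if mask[zz, yy, xx]:
                            counts[levels[z, y, x] - 1, levels[zz, yy, xx] - 1] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no pairs")
    return counts / total


def glcm_features_oracle(m: np.ndarray) -> tuple[float, float]:
    entropy = 0.0
    homogeneity = 0.0
    g = m.shape[0]
    for i in range(g):
        for j in range(g):
            if m[i, j] > 0:
                entropy -= m[i, j] * math.log2(m[i, j])
            homogeneity += m[i, j] / (1 + abs(i - j))
    return entropy, homogeneity


def ngtdm_oracle(levels: np.ndarray, mask: np.ndarray, gray_levels: int):
    """(s, p, n_valid) by explicit neighbor gathering."""
    s = np.zeros(gray_levels)
    n_i = np.zeros(gray_levels)
    n_valid = 0
    shape = levels.shape
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x]:
                    continue
                nb = []
                for dz, dy, dx in NEIGHBORS_26:
                    zz, yy, xx = z + dz, y + dy, x + dx
                    if 0 <= zz < shape[0] and 0 <= yy < shape[1] and 0 <= xx < shape[2]:
                        if mask[zz, yy, xx]:
                            nb.append(levels[zz, yy, xx])
                if not nb:
                    continue
                n_valid += 1
                lvl = levels[z, y, x]
                s[lvl - 1] += abs(lvl - sum(nb) / len(nb))
                n_i[lvl - 1] += 1
    if n_valid == 0:
        raise ValueError("all voxels isolated")
    return s, n_i / n_valid, n_valid


def ngtdm_features_oracle(s: np.ndarray, p: np.ndarray, n_valid: int, epsilon: float = 1e-9):
    """(busyness, coarseness, complexity, contrast) by direct formula loops."""
    g = len(p)
    occupied = [i for i in range(g) if p[i] > 0]
    n_gp = len(occupied)

    ps = sum(p[i] * s[i] for i in occupied)
    coarseness = 1.0 / (epsilon + ps)

    if n_gp > 1:
        acc = 0.0
        for i in occupied:
            for j in occupied:
                acc += p[i] * p[j] * ((i + 1) - (j + 1)) ** 2
        contrast = acc / (n_gp * (n_gp - 1)) * (sum(s) / n_valid)
    else:
        contrast = 0.0

    den = 0.0
    for i in occupied:
        for j in occupied:
            if i != j:
                den += abs((i + 1) * p[i] - (j + 1) * p[j])
    busyness = ps / den if den > 0 else 0.0

    complexity = 0.0
    for i in occupied:
        for j in occupied:
            complexity += (
                abs((i + 1) - (j + 1)) * (p[i] * s[i] + p[j] * s[j]) / (n_valid * (p[i] + p[j]))
            )
    return busyness, coarseness, complexity, contrast


def auc_pairwise_oracle(values, labels) -> float:
    """Mann-Whitney concordance by O(n²) pair enumeration; ties count 1/2."""
    pos = [v for v, y in zip(values, labels) if y]
    neg = [v for v, y in zip(values, labels) if not y]
    acc = 0.0
    for vp in pos:
        for vn in neg:
            if vp > vn:
                acc += 1.0
            elif vp == vn:
                acc += 0.5
    return acc / (len(pos) * len(neg))


def youden_exhaustive_oracle(values, labels) -> tuple[float, float]:
    """(best J, lowest cutoff achieving it) by scanning every candidate
    threshold: −inf, all midpoints between sorted unique values, +inf."""
    v = np.asarray(values, float)
    y = np.asarray(labels).astype(bool)
    uniq = np.unique(v)
    candidates = [-math.inf]
    candidates += [(a + b) / 2 for a, b in zip(uniq[:-1], uniq[1:])]
    candidates += [math.inf]
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    best_j, best_cut = -math.inf, candidates[0]
    for cut in candidates:
        tp = sum(1 for vv, yy in zip(v, y) if yy and vv > cut)
        tn = sum(1 for vv, yy in zip(v, y) if not yy and vv <= cut)
        j = tp / n_pos + tn / n_neg - 1.0
        if j > best_j + 1e-15:
            best_j, best_cut = j, cut
    return best_j, best_cut


def breslow_loglik_oracle(beta: float, x, times, events) -> float:
    """Cox log partial likelihood (Breslow ties) for a single covariate,
    by direct risk-set summation."""
    n = len(times)
    ll = 0.0
    for i in range(n):
        if not events[i]:
            continue
        risk = sum(math.exp(beta * x[j]) for j in range(n) if times[j] >= times[i])
        ll += beta * x[i] - math.log(risk)
    return ll


def km_oracle(times, events):
    """Product-limit estimate by hand: returns list of (t, S(t)) at event times."""
    order = np.argsort(times)
    t = np.asarray(times, float)[order]
    e = np.asarray(events).astype(bool)[order]
    out = []
    surv = 1.0
    for ut in np.unique(t[e]):
        at_risk = int((t >= ut).sum())
        deaths = int(((t == ut) & e).sum())
        surv *= 1.0 - deaths / at_risk
        out.append((float(ut), surv))
    return out
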