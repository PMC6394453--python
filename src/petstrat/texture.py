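"""Intratumoral texture features in 3D.

Three families, all computed on the quantized SUVs of a single VOI:

* first-order (histogram): population standard deviation and Fisher excess
  kurtosis of the raw in-mask SUVs;
* second-order: gray-level co-occurrence matrix (GLCM) pooled over all 13
  unique direction offsets at Chebyshev distance 1, symmetrized, and its
  Entropy (bits) and Homogeneity;
* higher-order: neighborhood gray-tone difference matrix (NGTDM) over the
  26-connected neighborhood, and the Amadasun–King features Busyness,
  Coarseness, Complexity and Contrast.

Gray levels come from fixed-bin-count quantization over the in-mask min–max
range (G = 64 by default).  Neighbor statistics use in-mask neighbors only,
with a variable neighbor count at VOI edges, so the surrounding background
never contaminates tumor texture and features are independent of how much
background padding surrounds the lesion.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import PetVolume, Units, VoiMask
from .conventional import EmptyMaskError

#: Stabiliser in the Coarseness denominator; a perfectly uniform VOI has
#: coarseness 1/EPSILON, reported with a degenerate flag.
DEFAULT_EPSILON = 1e-9

DEFAULT_GRAY_LEVELS = 64

#: The 13 unique displacement vectors at Chebyshev distance 1 in 3D
#: (each direction counted once; symmetrization supplies the opposite).
OFFSETS_13: tuple[tuple[int, int, int], ...] = tuple(
    off
    for off in itertools.product((-1, 0, 1), repeat=3)
    if off > (0, 0, 0)
)


@dataclass(frozen=True)
class QuantizedVoi:
    levels: np.ndarray  # int array, 1..G inside mask, 0 outside
    gray_levels: int
    mask: VoiMask
    calibration: tuple[float, float]  # (min, max) SUV used for binning


@dataclass(frozen=True)
class Glcm:
    m: np.ndarray  # G×G, symmetric, sums to 1
    n_pairs: int  # directed voxel pairs counted (before symmetrization)


@dataclass(frozen=True)
class Ngtdm:
    s: np.ndarray  # per-level sum of |level − neighborhood mean|, shape (G,)
    p: np.ndarray  # per-level occupancy probability among valid voxels
    n_valid: int  # voxels with at least one in-mask neighbor
    gray_levels: int


@dataclass(frozen=True)
class TextureFeatures:
    std_dev: float
    kurtosis: float
    entropy_bits: float
    homogeneity: float
    busyness: float
    coarseness: float
    complexity: float
    contrast: float
    degenerate: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {
            "std_dev": self.std_dev,
            "kurtosis": self.kurtosis,
            "entropy": self.entropy_bits,
            "homogeneity": self.homogeneity,
            "busyness": self.busyness,
            "coarseness": self.coarseness,
            "complexity": self.complexity,
            "contrast": self.contrast,
        }


def quantize(vol: PetVolume, mask: VoiMask, gray_levels: int = DEFAULT_GRAY_LEVELS) -> QuantizedVoi:
    """Fixed-bin-count quantization of in-mask SUVs to levels 1..G.

    level = min(G, floor((x − min) / ((max − min)/G)) + 1); a constant VOI
    (max == min) maps every voxel to level 1.
    """
    if vol.units is not Units.SUV:
        raise ValueError("quantize expects an SUV volume")
    if gray_levels < 2:
        raise ValueError("need at least 2 gray levels")
    inside = mask.voxels
    if not inside.any():
        raise EmptyMaskError("cannot quantize an empty VOI")
    vals = vol.values[inside]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(vol.shape, dtype=np.int32)
    if hi == lo:
        levels[inside] = 1
    else:
        width = (hi - lo) / gray_levels
        lv = np.floor((vals - lo) / width).astype(np.int32) + 1
        levels[inside] = np.minimum(lv, gray_levels)
    return QuantizedVoi(levels=levels, gray_levels=gray_levels, mask=mask, calibration=(lo, hi))


def first_order(vol: PetVolume, mask: VoiMask) -> tuple[float, float, bool]:
    """Population standard deviation and Fisher excess kurtosis of in-mask SUVs.

    Returns (std_dev, kurtosis, degenerate); a zero-variance VOI reports
    kurtosis 0 with the degenerate flag set.
    """
    vals = vol.values[mask.voxels]
    if vals.size < 2:
        raise EmptyMaskError("first-order statistics need at least 2 voxels")
    centered = vals - vals.mean()
    m2 = float(np.mean(centered**2))
    if m2 == 0.0:
        return 0.0, 0.0, True
    m4 = float(np.mean(centered**4))
    return float(np.sqrt(m2)), m4 / m2**2 - 3.0, False


def build_glcm(q: QuantizedVoi) -> Glcm:
    """Pooled symmetric GLCM over the 13 unique 3D offsets at distance 1.

    A pair contributes only when both voxels are in-mask; counts from all
    directions are summed into one matrix and normalized once.
    """
    g = q.gray_levels
    levels = q.levels
    inside = q.mask.voxels
    counts = np.zeros((g, g), dtype=np.int64)
    for dz, dy, dx in OFFSETS_13:
        src = tuple(slice(max(d, 0), s + min(d, 0)) for d, s in zip((dz, dy, dx), levels.shape))
        dst = tuple(slice(max(-d, 0), s + min(-d, 0)) for d, s in zip((dz, dy, dx), levels.shape))
        valid = inside[src] & inside[dst]
        a = levels[src][valid] - 1
        b = levels[dst][valid] - 1
        np.add.at(counts, (a, b), 1)
    n_pairs = int(counts.sum())
    if n_pairs == 0:
        raise ValueError("no in-mask voxel pairs; VOI voxels are isolated")
    sym = counts + counts.T
    return Glcm(m=sym / sym.sum(), n_pairs=n_pairs)


def glcm_features(g: Glcm) -> tuple[float, float]:
    """(entropy in bits, homogeneity) of a normalized co-occurrence matrix."""
    m = g.m
    nz = m[m > 0]
    entropy = float(-(nz * np.log2(nz)).sum()) + 0.0  # avoid -0.0 for a single-cell matrix
    n = m.shape[0]
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    homogeneity = float((m / (1.0 + np.abs(i - j))).sum())
    return entropy, homogeneity


def build_ngtdm(q: QuantizedVoi) -> Ngtdm:
    """NGTDM over the 26-neighborhood with in-mask neighbors only.

    For each in-mask voxel with level i and at least one in-mask neighbor,
    the absolute deviation |i − Ā| from its neighborhood mean level Ā is
    accumulated into s(i); p_i is the fraction of such valid voxels at level i.
    """
    g = q.gray_levels
    inside = q.mask.voxels
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nb_sum = ndimage.correlate(q.levels.astype(np.float64) * inside, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.correlate(inside.astype(np.float64), kernel, mode="constant", cval=0.0)
    valid = inside & (nb_cnt > 0.5)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("all VOI voxels are isolated; NGTDM undefined")
    lv = q.levels[valid]
    nb_mean = nb_sum[valid] / nb_cnt[valid]
    dev = np.abs(lv - nb_mean)
    s = np.bincount(lv, weights=dev, minlength=g + 1)[1:].astype(np.float64)
    n_i = np.bincount(lv, minlength=g + 1)[1:]
    return Ngtdm(s=s, p=n_i / n_valid, n_valid=n_valid, gray_levels=g)


def ngtdm_features(t: Ngtdm, epsilon: float = DEFAULT_EPSILON) -> tuple[float, float, float, float]:
    """(busyness, coarseness, complexity, contrast) per Amadasun–King.

    With occupied levels i (p_i > 0), N_gp their count and N = n_valid:

    * coarseness  = 1 / (ε + Σ p_i s_i)
    * contrast    = [ΣΣ p_i p_j (i−j)² / (N_gp(N_gp−1))] · [Σ s_i / N]
    * busyness    = Σ p_i s_i / ΣΣ_{i≠j} |i·p_i − j·p_j|
    * complexity  = ΣΣ |i−j| (p_i s_i + p_j s_j) / (N (p_i + p_j))

    with the 0-conventions for a single occupied level / zero denominator.
    """
    occ = t.p > 0
    levels = np.arange(1, t.gray_levels + 1, dtype=np.float64)[occ]
    p = t.p[occ]
    s = t.s[occ]
    n_gp = levels.size
    n = t.n_valid

    ps = float((p * s).sum())
    coarseness = 1.0 / (epsilon + ps)

    diff = levels[:, None] - levels[None, :]
    if n_gp > 1:
        contrast = float((p[:, None] * p[None, :] * diff**2).sum()) / (n_gp * (n_gp - 1)) * (
            float(s.sum()) / n
        )
    else:
        contrast = 0.0

    ip = levels * p
    busy_den = float(np.abs(ip[:, None] - ip[None, :]).sum())  # i==j terms are 0
    busyness = ps / busy_den if busy_den > 0 else 0.0

    psum = p[:, None] + p[None, :]
    num = p[:, None] * s[:, None] + p[None, :] * s[None, :]
    complexity = float((np.abs(diff) * num / (n * psum)).sum())

    return busyness, coarseness, complexity, contrast


def extract_texture(
    vol: PetVolume,
    mask: VoiMask,
    gray_levels: int = DEFAULT_GRAY_LEVELS,
    epsilon: float = DEFAULT_EPSILON,
) -> TextureFeatures:
    """Quantize once and compute all eight texture features of a VOI."""
    std_dev, kurt, fo_degenerate = first_order(vol, mask)
    q = quantize(vol, mask, gray_levels)
    glcm = build_glcm(q)
    entropy, homogeneity = glcm_features(glcm)
    t = build_ngtdm(q)
    busyness, coarseness, complexity, contrast = ngtdm_features(t, epsilon)
    degenerate: dict = {}
    if fo_degenerate:
        degenerate["kurtosis"] = "zero-variance VOI"
    if int((t.p > 0).sum()) == 1:
        degenerate["coarseness"] = "single gray level; coarseness is 1/epsilon"
    return TextureFeatures(
        std_dev=std_dev,
        kurtosis=kurt,
        entropy_bits=entropy,
        homogeneity=homogeneity,
        busyness=busyness,
        coarseness=coarseness,
        complexity=complexity,
        contrast=contrast,
        degenerate=degenerate,
    )
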