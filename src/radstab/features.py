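"""3D volumetric texture features from gray-level matrices.

Implements the 25 features used throughout the package, grouped by matrix:

* **GLCOM** (gray-level co-occurrence matrix, voxel displacement 1, all 13
  symmetric 3D directions pooled into one symmetric matrix): Energy,
  Contrast, Entropy, Homogeneity, Correlation, Variance, Dissimilarity.
* **GLSZM** (gray-level size zone matrix, 26-connected isointense zones):
  SZE, LZE, GLN, ZSNU, ZP, LGZE, HGZE, SZLGE, SZHGE, LZLGE, LZHGE, GLV, ZSV.
* **GLNDM** (gray-level neighborhood difference matrix, Amadasun–King
  statistics over 3×3×3 neighborhoods): Coarseness, Contrast, Busyness,
  Complexity, Strength.

Intensities inside the VOI are first discretized to ``G`` integer levels by
fixed bin number: ``level = floor(G * (x - min) / (max - min))`` clipped to
``G - 1``, with min/max taken inside the VOI, so features are invariant to
affine intensity shifts.  GLCOM features use the 0-based levels directly;
GLSZM and GLNDM weight levels shifted to ``1..G`` so inverse gray-level
weights (LGZE etc.) are always defined.

Conventions that the literature leaves open are collected in
:class:`FeatureConfig` (entropy log base, homogeneity variant, per-direction
GLCOM averaging) with the defaults noted there; degenerate VOIs (constant
intensity, a single voxel) follow the documented conventions instead of
producing NaNs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import scipy.ndimage as ndi

from .core import (
    BinaryMask,
    ConfigurationError,
    EmptyMaskError,
    FeatureTable,
    ImageVolume,
    require_compatible,
)

__all__ = [
    "GLCOM_FEATURES",
    "GLSZM_FEATURES",
    "GLNDM_FEATURES",
    "ALL_FEATURES",
    "DEFAULT_SCHEMES",
    "FeatureConfig",
    "DiscretizedVOI",
    "GLCOMatrix",
    "GLSZMatrix",
    "GLNDMatrix",
    "discretize",
    "glcom",
    "glcom_features",
    "glszm",
    "glszm_features",
    "glndm",
    "glndm_features",
    "extract_features",
]

GLCOM_FEATURES = [
    "GLCOM_Energy",
    "GLCOM_Contrast",
    "GLCOM_Entropy",
    "GLCOM_Homogeneity",
    "GLCOM_Correlation",
    "GLCOM_Variance",
    "GLCOM_Dissimilarity",
]
GLSZM_FEATURES = [
    "GLSZM_SZE",
    "GLSZM_LZE",
    "GLSZM_GLN",
    "GLSZM_ZSNU",
    "GLSZM_ZP",
    "GLSZM_LGZE",
    "GLSZM_HGZE",
    "GLSZM_SZLGE",
    "GLSZM_SZHGE",
    "GLSZM_LZLGE",
    "GLSZM_LZHGE",
    "GLSZM_GLV",
    "GLSZM_ZSV",
]
GLNDM_FEATURES = [
    "GLNDM_Coarseness",
    "GLNDM_Contrast",
    "GLNDM_Busyness",
    "GLNDM_Complexity",
    "GLNDM_Strength",
]
ALL_FEATURES = GLCOM_FEATURES + GLSZM_FEATURES + GLNDM_FEATURES

DEFAULT_SCHEMES = (32, 64, 128, 256)

# 13 displacement-1 direction offsets covering all 26 neighbors symmetrically:
# the lexicographically positive half of {-1,0,1}^3 \ {0}.
_OFFSETS13 = [
    off
    for off in itertools.product((-1, 0, 1), repeat=3)
    if off > (0, 0, 0)
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class FeatureConfig:
    """Texture conventions that vary across the radiomics literature.

    entropy_base
        Logarithm base for GLCOM entropy; 2 (bits) is the dominant choice.
    homogeneity
        ``"inverse_difference"`` → Σ p/(1+|i−j|) (default) or
        ``"inverse_difference_squared"`` → Σ p/(1+(i−j)²).
    glcom_aggregation
        ``"sum"`` pools counts from all 13 directions into one matrix
        (default); ``"direction_average"`` computes features per direction
        and averages them.
    epsilon
        Guard added to GLNDM Coarseness/Strength denominators.
    coarseness_cap
        Upper cap for Coarseness on homogeneous VOIs (all s_g = 0).
    """

    entropy_base: float = 2.0
    homogeneity: str = "inverse_difference"
    glcom_aggregation: str = "sum"
    epsilon: float = 1e-6
    coarseness_cap: float = 1e6

    def __post_init__(self) -> None:
        if self.homogeneity not in (
            "inverse_difference",
            "inverse_difference_squared",
        ):
            raise ConfigurationError(f"unknown homogeneity variant {self.homogeneity!r}")
        if self.glcom_aggregation not in ("sum", "direction_average"):
            raise ConfigurationError(
                f"unknown GLCOM aggregation {self.glcom_aggregation!r}"
            )


DEFAULT_CONFIG = FeatureConfig()


@dataclass
class DiscretizedVOI:
    """VOI intensities rescaled to integer levels ``0..G-1``.

    ``levels`` is cropped to the mask bounding box; voxels outside the mask
    carry the sentinel −1.
    """

    levels: np.ndarray  # int array, -1 outside mask
    mask: np.ndarray  # bool, same (cropped) shape
    G: int
    n_voxels: int

    @property
    def inside(self) -> np.ndarray:
        """1D array of in-mask levels."""
        return self.levels[self.mask]


def _crop_bbox(mask: np.ndarray, pad: int = 0):
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + pad, mask.shape)
    return tuple(slice(a, b) for a, b in zip(lo, hi))


def discretize(v: ImageVolume, m: BinaryMask, G: int) -> DiscretizedVOI:
    """Fixed-bin-number discretization of the VOI intensities.

    ``level = floor(G (x − min) / (max − min))`` clipped to ``G − 1`` with
    min/max taken inside the mask; a constant VOI maps entirely to level 0.
    """
    if G < 2:
        raise ConfigurationError(f"need G >= 2 gray levels, got {G}")
    require_compatible(m, v)
    if m.n_voxels == 0:
        raise EmptyMaskError("cannot discretize an empty VOI")
    box = _crop_bbox(m.data)
    sub = v.data[box]
    msk = m.data[box]
    vals = sub[msk]
    mn, mx = float(vals.min()), float(vals.max())
    levels = np.full(sub.shape, -1, dtype=np.int32)
    if mx > mn:
        lv = np.floor(G * (vals - mn) / (mx - mn)).astype(np.int32)
        np.clip(lv, 0, G - 1, out=lv)
    else:
        lv = np.zeros(vals.shape, dtype=np.int32)
    levels[msk] = lv
    return DiscretizedVOI(levels=levels, mask=msk, G=G, n_voxels=int(msk.sum()))


# ---------------------------------------------------------------------------
# GLCOM


@dataclass
class GLCOMatrix:
    """Symmetric co-occurrence counts over all displacement-1 neighbor pairs."""

    counts: np.ndarray  # G×G, symmetric
    G: int

    @property
    def p(self) -> np.ndarray:
        """Normalized joint probabilities (zeros if no pair exists)."""
        tot = self.counts.sum()
        return self.counts / tot if tot > 0 else np.zeros_like(self.counts)


def _shift_slices(shape, off):
    sa, sb = [], []
    for n, o in zip(shape, off):
        if o >= 0:
            sa.append(slice(0, n - o))
            sb.append(slice(o, n))
        else:
            sa.append(slice(-o, n))
            sb.append(slice(0, n + o))
    return tuple(sa), tuple(sb)


def _glcom_counts(d: DiscretizedVOI, offsets) -> np.ndarray:
    G = d.G
    counts = np.zeros((G, G), dtype=np.float64)
    for off in offsets:
        sa, sb = _shift_slices(d.levels.shape, off)
        ok = d.mask[sa] & d.mask[sb]
        if not ok.any():
            continue
        a = d.levels[sa][ok].astype(np.int64)
        b = d.levels[sb][ok].astype(np.int64)
        c = np.bincount(a * G + b, minlength=G * G).reshape(G, G)
        counts += c
        counts += c.T
    return counts


def glcom(d: DiscretizedVOI) -> GLCOMatrix:
    """Co-occurrence matrix pooled over all 26 ordered displacement-1 offsets.

    Both voxels of a pair must lie inside the mask; a single-voxel VOI with
    no in-mask neighbor yields an all-zero matrix.
    """
    return GLCOMatrix(_glcom_counts(d, _OFFSETS13), d.G)


def glcom_features(
    M: GLCOMatrix, config: FeatureConfig = DEFAULT_CONFIG
) -> dict[str, float]:
    """The seven co-occurrence features, on 0-based gray levels.

    An all-zero matrix (no valid neighbor pair) maps every feature to 0
    except nothing else — entropy/energy/etc. are all zero by convention.
    Correlation is 0 whenever the marginal variance vanishes.
    """
    p = M.p
    tot = p.sum()
    if tot <= 0:
        return {name: 0.0 for name in GLCOM_FEATURES}
    i = np.arange(M.G, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = ii - jj
    p_i = p.sum(axis=1)  # marginal (symmetric matrix → rows == cols)
    mu = float((i * p_i).sum())
    var = float(((i - mu) ** 2 * p_i).sum())
    energy = float((p**2).sum())
    contrast = float((diff**2 * p).sum())
    nz = p[p > 0]
    entropy = float(-(nz * (np.log(nz) / np.log(config.entropy_base))).sum())
    if config.homogeneity == "inverse_difference":
        homog = float((p / (1.0 + np.abs(diff))).sum())
    else:
        homog = float((p / (1.0 + diff**2)).sum())
    dissim = float((np.abs(diff) * p).sum())
    if var > 0:
        corr = float((((ii - mu) * (jj - mu) * p).sum()) / var)
    else:
        corr = 0.0
    return {
        "GLCOM_Energy": energy,
        "GLCOM_Contrast": contrast,
        "GLCOM_Entropy": entropy,
        "GLCOM_Homogeneity": homog,
        "GLCOM_Correlation": corr,
        "GLCOM_Variance": var,
        "GLCOM_Dissimilarity": dissim,
    }


# ---------------------------------------------------------------------------
# GLSZM


@dataclass
class GLSZMatrix:
    """Zone counts ``Z[(g, s)]`` for 26-connected isointense zones.

    ``g`` is the 1-based gray level (levels shifted by +1), ``s`` the zone
    size in voxels; ``n_p`` is the VOI voxel count.
    """

    zones: dict[tuple[int, int], int]
    G: int
    n_p: int

    @property
    def n_z(self) -> int:
        return sum(self.zones.values())


def glszm(d: DiscretizedVOI) -> GLSZMatrix:
    """Size-zone matrix: connected components of equal level within the mask."""
    zones: dict[tuple[int, int], int] = {}
    inside = d.inside
    for g in np.unique(inside):
        bw = (d.levels == g) & d.mask
        box = _crop_bbox(bw)
        lab, nlab = ndi.label(bw[box], structure=_STRUCT26)
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            key = (int(g) + 1, int(s))
            zones[key] = zones.get(key, 0) + 1
    return GLSZMatrix(zones=zones, G=d.G, n_p=d.n_voxels)


def glszm_features(M: GLSZMatrix) -> dict[str, float]:
    """The thirteen size-zone features with 1-based gray-level weights."""
    if M.n_z < 1:
        raise EmptyMaskError("size-zone matrix has no zones")
    items = np.array([(g, s, c) for (g, s), c in M.zones.items()], dtype=np.float64)
    g, s, z = items[:, 0], items[:, 1], items[:, 2]
    n_z = float(z.sum())
    # marginals for the non-uniformity features
    g_marg: dict[float, float] = {}
    s_marg: dict[float, float] = {}
    for gi, si, zi in items:
        g_marg[gi] = g_marg.get(gi, 0.0) + zi
        s_marg[si] = s_marg.get(si, 0.0) + zi
    w = z / n_z
    mu_g = float((g * w).sum())
    mu_s = float((s * w).sum())
    return {
        "GLSZM_SZE": float((z / s**2).sum() / n_z),
        "GLSZM_LZE": float((z * s**2).sum() / n_z),
        "GLSZM_GLN": float(sum(v**2 for v in g_marg.values()) / n_z),
        "GLSZM_ZSNU": float(sum(v**2 for v in s_marg.values()) / n_z),
        "GLSZM_ZP": float(n_z / M.n_p),
        "GLSZM_LGZE": float((z / g**2).sum() / n_z),
        "GLSZM_HGZE": float((z * g**2).sum() / n_z),
        "GLSZM_SZLGE": float((z / (s**2 * g**2)).sum() / n_z),
        "GLSZM_SZHGE": float((z * g**2 / s**2).sum() / n_z),
        "GLSZM_LZLGE": float((z * s**2 / g**2).sum() / n_z),
        "GLSZM_LZHGE": float((z * s**2 * g**2).sum() / n_z),
        "GLSZM_GLV": float(((g - mu_g) ** 2 * w).sum()),
        "GLSZM_ZSV": float(((s - mu_s) ** 2 * w).sum()),
    }


# ---------------------------------------------------------------------------
# GLNDM


@dataclass
class GLNDMatrix:
    """Neighborhood-difference accumulators per 1-based gray level.

    ``s[g]`` sums |level − neighborhood mean| over valid voxels of level g,
    ``n[g]`` counts them, and ``n_valid`` is the number of VOI voxels with at
    least one in-mask 26-neighbor (the neighborhood mean excludes the center
    and out-of-mask voxels).
    """

    s: np.ndarray  # length G+1, index = 1-based level (index 0 unused)
    n: np.ndarray
    G: int
    n_valid: int

    @property
    def p(self) -> np.ndarray:
        if self.n_valid == 0:
            return np.zeros_like(self.s)
        return self.n / self.n_valid

    @property
    def present(self) -> np.ndarray:
        """1-based levels with at least one valid voxel."""
        return np.nonzero(self.n > 0)[0]


_KERNEL26 = np.ones((3, 3, 3), dtype=np.float64)
_KERNEL26[1, 1, 1] = 0.0


def glndm(d: DiscretizedVOI) -> GLNDMatrix:
    """Neighborhood difference matrix over 3×3×3 in-mask neighborhoods."""
    lv1 = np.where(d.mask, d.levels + 1, 0).astype(np.float64)  # 1-based
    nb_sum = ndi.convolve(lv1, _KERNEL26, mode="constant", cval=0.0)
    nb_cnt = ndi.convolve(d.mask.astype(np.float64), _KERNEL26, mode="constant")
    valid = d.mask & (nb_cnt > 0.5)
    s = np.zeros(d.G + 1, dtype=np.float64)
    n = np.zeros(d.G + 1, dtype=np.int64)
    if valid.any():
        g = lv1[valid].astype(np.int64)
        abar = nb_sum[valid] / nb_cnt[valid]
        np.add.at(s, g, np.abs(g - abar))
        np.add.at(n, g, 1)
    return GLNDMatrix(s=s, n=n, G=d.G, n_valid=int(valid.sum()))


def glndm_features(
    M: GLNDMatrix, config: FeatureConfig = DEFAULT_CONFIG
) -> dict[str, float]:
    """Amadasun–King texture statistics (Coarseness … Strength).

    Degenerate conventions: with one present level Contrast and Busyness are
    0; Coarseness is capped; a VOI with no valid neighborhoods returns the
    same degenerate values as a constant VOI.
    """
    eps, cap = config.epsilon, config.coarseness_cap
    pres = M.present
    if M.n_valid == 0 or len(pres) == 0:
        return {
            "GLNDM_Coarseness": cap,
            "GLNDM_Contrast": 0.0,
            "GLNDM_Busyness": 0.0,
            "GLNDM_Complexity": 0.0,
            "GLNDM_Strength": 0.0,
        }
    p = M.p[pres]
    s = M.s[pres]
    g = pres.astype(np.float64)
    n_gp = len(pres)
    nv = float(M.n_valid)

    coarseness = min(1.0 / (eps + float((p * s).sum())), cap)

    gi, gj = np.meshgrid(g, g, indexing="ij")
    pi, pj = np.meshgrid(p, p, indexing="ij")
    si, sj = np.meshgrid(s, s, indexing="ij")

    if n_gp > 1:
        contrast = float((pi * pj * (gi - gj) ** 2).sum()) / (n_gp * (n_gp - 1))
        contrast *= float(s.sum()) / nv
        denom = float(np.abs(gi * pi - gj * pj).sum())
        busyness = float((p * s).sum()) / denom if denom > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0

    complexity = float(
        (np.abs(gi - gj) * (pi * si + pj * sj) / ((pi + pj) * nv)).sum()
    )
    strength = float(((pi + pj) * (gi - gj) ** 2).sum()) / (eps + float(s.sum()))

    return {
        "GLNDM_Coarseness": coarseness,
        "GLNDM_Contrast": contrast,
        "GLNDM_Busyness": busyness,
        "GLNDM_Complexity": complexity,
        "GLNDM_Strength": strength,
    }


# ---------------------------------------------------------------------------
# Driver


def compute_feature_vector(
    d: DiscretizedVOI, config: FeatureConfig = DEFAULT_CONFIG
) -> dict[str, float]:
    """All 25 features from one discretized VOI."""
    if config.glcom_aggregation == "sum":
        fc = glcom_features(glcom(d), config)
    else:
        per_dir = []
        for off in _OFFSETS13:
            m = GLCOMatrix(_glcom_counts(d, [off]), d.G)
            per_dir.append(glcom_features(m, config))
        fc = {
            name: float(np.mean([f[name] for f in per_dir]))
            for name in GLCOM_FEATURES
        }
    out = dict(fc)
    out.update(glszm_features(glszm(d)))
    out.update(glndm_features(glndm(d), config))
    return out


def extract_features(
    v: ImageVolume,
    m: BinaryMask,
    schemes: Iterable[int] = DEFAULT_SCHEMES,
    lesion_id: str = "lesion",
    source: str = "ground_truth",
    config: FeatureConfig = DEFAULT_CONFIG,
) -> FeatureTable:
    """Discretize the VOI once per scheme and emit all 25 features per G."""
    records = []
    for G in schemes:
        d = discretize(v, m, int(G))
        vec = compute_feature_vector(d, config)
        for name in ALL_FEATURES:
            records.append(
                {
                    "lesion_id": lesion_id,
                    "source": source,
                    "gray_levels": int(G),
                    "feature": name,
                    "value": vec[name],
                }
            )
    return FeatureTable.from_records(records)
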