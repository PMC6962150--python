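"""Independent brute-force references used as oracles in tests.

Everything here is written as plainly as possible (explicit loops over
voxels, neighbors and matrix entries) and deliberately shares no code with
the package implementation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

OFFSETS26 = [
    off
    for off in itertools.product((-1, 0, 1), repeat=3)
    if off != (0, 0, 0)
]


def naive_glcm(levels: np.ndarray, mask: np.ndarray, G: int) -> np.ndarray:
    """Ordered co-occurrence counts over all 26 displacement-1 neighbors."""
    counts = np.zeros((G, G))
    shape = levels.shape
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        for off in OFFSETS26:
            nb = tuple(i + o for i, o in zip(idx, off))
            if any(c < 0 or c >= s for c, s in zip(nb, shape)):
                continue
            if not mask[nb]:
                continue
            counts[levels[idx], levels[nb]] += 1
    return counts


def naive_glszm(levels: np.ndarray, mask: np.ndarray) -> dict:
    """Zone counts {(1-based level, size): n} by BFS over 26-neighbors."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones: dict[tuple[int, int], int] = {}
    for start in np.ndindex(shape):
        if not mask[start] or seen[start]:
            continue
        g = levels[start]
        stack, size = [start], 0
        seen[start] = True
        while stack:
            cur = stack.pop()
            size += 1
            for off in OFFSETS26:
                nb = tuple(i + o for i, o in zip(cur, off))
                if any(c < 0 or c >= s for c, s in zip(nb, shape)):
                    continue
                if mask[nb] and not seen[nb] and levels[nb] == g:
                    seen[nb] = True
                    stack.append(nb)
        key = (int(g) + 1, size)
        zones[key] = zones.get(key, 0) + 1
    return zones


def naive_glndm(levels: np.ndarray, mask: np.ndarray, G: int):
    """(s, n, n_valid) accumulators with 1-based levels, loops only."""
    s = np.zeros(G + 1)
    n = np.zeros(G + 1, dtype=int)
    shape = levels.shape
    n_valid = 0
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        nb_levels = []
        for off in OFFSETS26:
            nb = tuple(i + o for i, o in zip(idx, off))
            if any(c < 0 or c >= sh for c, sh in zip(nb, shape)):
                continue
            if mask[nb]:
                nb_levels.append(levels[nb] + 1)
        if not nb_levels:
            continue
        n_valid += 1
        g = int(levels[idx]) + 1
        s[g] += abs(g - sum(nb_levels) / len(nb_levels))
        n[g] += 1
    return s, n, n_valid


# --------------------------------------------------------------------------
# Feature formulas, written out longhand from the definitions


def naive_glcm_features(counts: np.ndarray) -> dict:
    G = counts.shape[0]
    total = counts.sum()
    out = {
        "GLCOM_Energy": 0.0,
        "GLCOM_Contrast": 0.0,
        "GLCOM_Entropy": 0.0,
        "GLCOM_Homogeneity": 0.0,
        "GLCOM_Correlation": 0.0,
        "GLCOM_Variance": 0.0,
        "GLCOM_Dissimilarity": 0.0,
    }
    if total == 0:
        return out
    p = counts / total
    mu = 0.0
    for i in range(G):
        for j in range(G):
            mu += i * p[i, j]
    var = 0.0
    for i in range(G):
        for j in range(G):
            var += (i - mu) ** 2 * p[i, j]
    energy = contrast = entropy = homog = dissim = cov = 0.0
    for i in range(G):
        for j in range(G):
            pij = p[i, j]
            energy += pij**2
            contrast += (i - j) ** 2 * pij
            homog += pij / (1 + abs(i - j))
            dissim += abs(i - j) * pij
            cov += (i - mu) * (j - mu) * pij
            if pij > 0:
                entropy -= pij * math.log2(pij)
    out["GLCOM_Energy"] = energy
    out["GLCOM_Contrast"] = contrast
    out["GLCOM_Entropy"] = entropy
    out["GLCOM_Homogeneity"] = homog
    out["GLCOM_Dissimilarity"] = dissim
    out["GLCOM_Variance"] = var
    out["GLCOM_Correlation"] = cov / var if var > 0 else 0.0
    return out


def naive_glszm_features(zones: dict, n_p: int) -> dict:
    n_z = sum(zones.values())
    sze = lze = lgze = hgze = szlge = szhge = lzlge = lzhge = 0.0
    for (g, s), z in zones.items():
        sze += z / s**2
        lze += z * s**2
        lgze += z / g**2
        hgze += z * g**2
        szlge += z / (s**2 * g**2)
        szhge += z * g**2 / s**2
        lzlge += z * s**2 / g**2
        lzhge += z * s**2 * g**2
    g_marg: dict[int, float] = {}
    s_marg: dict[int, float] = {}
    for (g, s), z in zones.items():
        g_marg[g] = g_marg.get(g, 0) + z
        s_marg[s] = s_marg.get(s, 0) + z
    mu_g = sum(g * z for (g, s), z in zones.items()) / n_z
    mu_s = sum(s * z for (g, s), z in zones.items()) / n_z
    glv = sum((g - mu_g) ** 2 * z for (g, s), z in zones.items()) / n_z
    zsv = sum((s - mu_s) ** 2 * z for (g, s), z in zones.items()) / n_z
    return {
        "GLSZM_SZE": sze / n_z,
        "GLSZM_LZE": lze / n_z,
        "GLSZM_GLN": sum(v**2 for v in g_marg.values()) / n_z,
        "GLSZM_ZSNU": sum(v**2 for v in s_marg.values()) / n_z,
        "GLSZM_ZP": n_z / n_p,
        "GLSZM_LGZE": lgze / n_z,
        "GLSZM_HGZE": hgze / n_z,
        "GLSZM_SZLGE": szlge / n_z,
        "GLSZM_SZHGE": szhge / n_z,
        "GLSZM_LZLGE": lzlge / n_z,
        "GLSZM_LZHGE": lzhge / n_z,
        "GLSZM_GLV": glv,
        "GLSZM_ZSV": zsv,
    }


def naive_glndm_features(s, n, n_valid, eps=1e-6, cap=1e6) -> dict:
    present = [g for g in range(len(n)) if n[g] > 0]
    if n_valid == 0 or not present:
        return {
            "GLNDM_Coarseness": cap,
            "GLNDM_Contrast": 0.0,
            "GLNDM_Busyness": 0.0,
            "GLNDM_Complexity": 0.0,
            "GLNDM_Strength": 0.0,
        }
    p = {g: n[g] / n_valid for g in present}
    ngp = len(present)
    ps_sum = sum(p[g] * s[g] for g in present)
    coarse = min(1.0 / (eps + ps_sum), cap)
    contrast = busy = cplx = strength = 0.0
    if ngp > 1:
        acc = 0.0
        for i in present:
            for j in present:
                acc += p[i] * p[j] * (i - j) ** 2
        contrast = acc / (ngp * (ngp - 1)) * sum(s[g] for g in present) / n_valid
        denom = 0.0
        for i in present:
            for j in present:
                denom += abs(i * p[i] - j * p[j])
        busy = ps_sum / denom if denom > 0 else 0.0
    for i in present:
        for j in present:
            cplx += abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / ((p[i] + p[j]) * n_valid)
            strength += (p[i] + p[j]) * (i - j) ** 2
    strength /= eps + sum(s[g] for g in present)
    return {
        "GLNDM_Coarseness": coarse,
        "GLNDM_Contrast": contrast,
        "GLNDM_Busyness": busy,
        "GLNDM_Complexity": cplx,
        "GLNDM_Strength": strength,
    }


def naive_all_features(levels, mask, G, n_p) -> dict:
    out = naive_glcm_features(naive_glcm(levels, mask, G))
    out.update(naive_glszm_features(naive_glszm(levels, mask), n_p))
    out.update(naive_glndm_features(*naive_glndm(levels, mask, G)))
    return out


# --------------------------------------------------------------------------
# Surface distance


def naive_surface(mask: np.ndarray) -> list[tuple[int, int, int]]:
    """Foreground voxels with a background 6-neighbor, by direct checking."""
    shape = mask.shape
    out = []
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        for off in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            nb = tuple(i + o for i, o in zip(idx, off))
            if any(c < 0 or c >= s for c, s in zip(nb, shape)) or not mask[nb]:
                out.append(idx)
                break
    return out


def naive_smasd(a: np.ndarray, b: np.ndarray) -> float:
    """All-pairs symmetric mean absolute surface distance, voxel units."""
    sa = naive_surface(a)
    sb = naive_surface(b)

    def mind(x, surf):
        return min(
            math.dist(x, y)
            for y in surf
        )

    tot = sum(mind(x, sb) for x in sa) + sum(mind(y, sa) for y in sb)
    return tot / (len(sa) + len(sb))


def random_voi(rng: np.random.Generator, max_side: int = 6, G: int = 8):
    """A random small discretized VOI: (levels, mask) with >= 1 voxel."""
    shape = tuple(rng.integers(2, max_side + 1, size=3))
    mask = rng.random(shape) < rng.uniform(0.3, 0.9)
    if not mask.any():
        mask[tuple(rng.integers(0, s) for s in shape)] = True
    levels = rng.integers(0, G, size=shape).astype(np.int32)
    levels[~mask] = -1
    return levels, mask
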