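"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: plain loops,
dictionaries and enumeration only.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_measures_bruteforce(patch, levels, directions=(0, 45, 90, 135), distance=1, symmetric=True):
    """Eight Haralick measures by explicit enumeration of every pixel pair."""
    patch = np.asarray(patch, dtype=int)
    h, w = patch.shape
    pairs = []
    for angle in directions:
        dr, dc = _OFFSETS[angle]
        dr, dc = dr * distance, dc * distance
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    a, b = patch[r, c], patch[r2, c2]
                    if a < 0 or b < 0:
                        continue
                    pairs.append((a, b))
                    if symmetric:
                        pairs.append((b, a))
    if not pairs:
        return None
    total = len(pairs)
    counts: dict[tuple[int, int], int] = {}
    for pair in pairs:
        counts[pair] = counts.get(pair, 0) + 1
    probs = {k: v / total for k, v in counts.items()}

    me = sum(x * p for (x, _), p in probs.items())
    var = sum((x - me) ** 2 * p for (x, _), p in probs.items())
    hom = sum(p / (1 + (x - z) ** 2) for (x, z), p in probs.items())
    con = sum((x - z) ** 2 * p for (x, z), p in probs.items())
    dis = sum(abs(x - z) * p for (x, z), p in probs.items())
    ent = -sum(p * math.log(p) for p in probs.values())
    asm = sum(p * p for p in probs.values())
    mx = sum(x * p for (x, _), p in probs.items())
    mz = sum(z * p for (_, z), p in probs.items())
    sx = math.sqrt(sum((x - mx) ** 2 * p for (x, _), p in probs.items()))
    sz = math.sqrt(sum((z - mz) ** 2 * p for (_, z), p in probs.items()))
    if sx * sz == 0:
        cor = float("nan")
    else:
        cor = sum((x - mx) * (z - mz) * p for (x, z), p in probs.items()) / (sx * sz)
    return {"ME": me, "VAR": var, "HOM": hom, "CON": con, "DIS": dis, "ENT": ent, "ASM": asm, "COR": cor}


def mann_whitney_exact_p(a, b):
    """Exact two-sided p by enumerating every assignment of pooled ranks."""
    a = list(a)
    b = list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "exact oracle requires tie-free data"
    n1 = len(a)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    rank_sum = sum(ranks[v] for v in a)
    u_obs = rank_sum - n1 * (n1 + 1) / 2
    n = len(pooled)
    u_all = []
    for combo in combinations(range(1, n + 1), n1):
        u = sum(combo) - n1 * (n1 + 1) / 2
        u_all.append(u)
    mean_u = n1 * (n - n1) / 2
    extreme = sum(1 for u in u_all if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12)
    return extreme / len(u_all)


def otsu_bruteforce(values, nbins=256):
    """Threshold maximizing between-class variance over all bin edges."""
    values = np.asarray(values, dtype=float)
    hist, edges = np.histogram(values, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    best_t, best_var = centers[0], -1.0
    total = hist.sum()
    for k in range(1, nbins):
        w0 = hist[:k].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:k] * centers[:k]).sum() / w0
        mu1 = (hist[k:] * centers[k:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, centers[k - 1]
    return best_t
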