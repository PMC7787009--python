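"""Brute-force definitional implementations used as independent oracles.

Everything here is written from first principles (explicit loops, textbook
formulas) and deliberately shares no code with the package under test.
"""

from __future__ import annotations

from itertools import product
from math import floor, sqrt

import numpy as np


def pearson_bf(a, b) -> float:
    a = list(map(float, a))
    b = list(map(float, b))
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    da = sqrt(sum((x - ma) ** 2 for x in a))
    db = sqrt(sum((y - mb) ** 2 for y in b))
    return num / (da * db)


def _ranks(v) -> list[float]:
    """Average ranks (ties share the mean of their rank positions)."""
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_bf(a, b) -> float:
    return pearson_bf(_ranks(list(a)), _ranks(list(b)))


def kendall_bf(a, b) -> float:
    """Kendall tau-b via explicit concordant/discordant pair counting."""
    a = list(a)
    b = list(b)
    n = len(a)
    concordant = discordant = ties_a = ties_b = 0
    for i in range(n):
        for j in range(i + 1, n):
            da = a[i] - a[j]
            db = b[i] - b[j]
            if da == 0 and db == 0:
                continue
            if da == 0:
                ties_a += 1
            elif db == 0:
                ties_b += 1
            elif da * db > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) / 2
    denom = sqrt((n0 - _tie_term(a)) * (n0 - _tie_term(b)))
    return (concordant - discordant) / denom


def _tie_term(v) -> float:
    counts = {}
    for x in v:
        counts[x] = counts.get(x, 0) + 1
    return sum(c * (c - 1) / 2 for c in counts.values())


def cosine_bf(a, b) -> float:
    num = sum(x * y for x, y in zip(a, b))
    return num / (sqrt(sum(x * x for x in a)) * sqrt(sum(y * y for y in b)))


def euclidean_bf(a, b) -> float:
    return sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))


def correlation_rdm_bf(patterns: np.ndarray) -> np.ndarray:
    """1 - Pearson r per condition pair, by pairwise loops."""
    n = patterns.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                d[i, j] = 1.0 - pearson_bf(patterns[i], patterns[j])
    return d


def offdiag_bf(matrix: np.ndarray) -> list[float]:
    n = matrix.shape[0]
    return [matrix[i, j] for i in range(n) for j in range(i + 1, n)]


def searchlight_count_bf(image, kernel, strides) -> int:
    n = 1
    for X, k, s in zip(image, kernel, strides):
        n *= floor((X - k) / s) + 1
    return n


def units_to_voxels_bf(unit_values, image, kernel, strides) -> np.ndarray:
    """Per-voxel scan over every kernel placement."""
    out = np.zeros(image)
    nux, nuy, nuz = (floor((X - k) / s) + 1 for X, k, s in zip(image, kernel, strides))
    for vx, vy, vz in product(*(range(d) for d in image)):
        vals = []
        for ux, uy, uz in product(range(nux), range(nuy), range(nuz)):
            ox, oy, oz = ux * strides[0], uy * strides[1], uz * strides[2]
            if (ox <= vx < ox + kernel[0] and oy <= vy < oy + kernel[1]
                    and oz <= vz < oz + kernel[2]):
                v = unit_values[ux, uy, uz]
                if np.isfinite(v):
                    vals.append(v)
        out[vx, vy, vz] = sum(vals) / len(vals) if vals else 0.0
    return out


def bh_step_up_bf(p_values, alpha):
    """Benjamini-Hochberg rejection set by the textbook step-up rule."""
    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    k = 0
    for rank, i in enumerate(order, start=1):
        if p[i] <= rank * alpha / m:
            k = rank
    reject = [False] * m
    for rank, i in enumerate(order, start=1):
        if rank <= k:
            reject[i] = True
    return reject


def bonferroni_bf(p_values, alpha):
    m = len(p_values)
    return [p <= alpha / m for p in p_values]
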