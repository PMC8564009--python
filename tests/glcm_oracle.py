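"""Independent brute-force oracle for co-occurrence matrices and statistics.

Pure pixel-pair enumeration with explicit Python loops; intentionally kept
separate from (and slower than) the library's vectorized implementation.
"""

from __future__ import annotations

import math

import numpy as np

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_force_glcm(
    levels: np.ndarray,
    n_levels: int,
    distance: int = 1,
    angles_deg: tuple[int, ...] = (0,),
    symmetric: bool = False,
    average_over_angles: bool = False,
) -> np.ndarray:
    mats = []
    h, w = levels.shape
    for angle in angles_deg:
        dr, dc = OFFSETS[angle]
        dr, dc = dr * distance, dc * distance
        counts = np.zeros((n_levels, n_levels))
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    a, b = levels[r, c], levels[r2, c2]
                    if a >= 0 and b >= 0:
                        counts[a, b] += 1
        if symmetric:
            counts = counts + counts.T
        mats.append(counts / counts.sum())
    out = mats[0]
    if average_over_angles:
        out = sum(mats) / len(mats)
    return out


def brute_force_statistics(g: np.ndarray) -> tuple[float, float, float, float]:
    n = g.shape[0]
    homogeneity = contrast = energy = cross = 0.0
    mu_x = mu_y = 0.0
    for i in range(n):
        for j in range(n):
            homogeneity += g[i, j] / (1 + (i - j) ** 2)
            contrast += (i - j) ** 2 * g[i, j]
            energy += g[i, j] ** 2
            cross += i * j * g[i, j]
            mu_x += i * g[i, j]
            mu_y += j * g[i, j]
    var_x = var_y = 0.0
    for i in range(n):
        for j in range(n):
            var_x += (i - mu_x) ** 2 * g[i, j]
            var_y += (j - mu_y) ** 2 * g[i, j]
    sigma = math.sqrt(var_x) * math.sqrt(var_y)
    correlation = 0.0 if sigma <= 1e-15 else (cross - mu_x * mu_y) / sigma
    return homogeneity, contrast, energy, correlation
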