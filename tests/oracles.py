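"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: GLCMs are built by
enumerating pixel pairs with Python loops and dictionaries, the Haralick
statistics are evaluated directly from their defining sums, and PCA
scores come from an explicit eigen-decomposition of the correlation
matrix.
"""

from __future__ import annotations

import math

import numpy as np


def brute_glcm(levels, mask, offsets, n_levels, symmetric=True):
    """Pair-enumeration GLCM; returns (p, n_pairs)."""
    rows = len(levels)
    cols = len(levels[0])
    counts: dict[tuple[int, int], float] = {}
    n_pairs = 0
    for dr, dc in offsets:
        for r in range(rows):
            for c in range(cols):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < rows and 0 <= c2 < cols:
                    if mask[r][c] and mask[r2][c2]:
                        i, j = int(levels[r][c]), int(levels[r2][c2])
                        counts[(i, j)] = counts.get((i, j), 0.0) + 1.0
                        if symmetric:
                            counts[(j, i)] = counts.get((j, i), 0.0) + 1.0
                        n_pairs += 1
    total = sum(counts.values())
    p = np.zeros((n_levels, n_levels))
    for (i, j), v in counts.items():
        p[i, j] = v / total
    return p, n_pairs


def brute_haralick(p):
    """The 13 Haralick statistics from their defining sums (bits for
    entropies; info-correlation-2 in the classic natural-log form)."""
    ng = p.shape[0]
    cells = [(i, j, p[i, j]) for i in range(ng) for j in range(ng)]
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i, j] for i in range(ng)) for j in range(ng)]

    def log2(x):
        return math.log(x, 2)

    energy = sum(v * v for _, _, v in cells)
    p_diff = [sum(v for i, j, v in cells if abs(i - j) == k) for k in range(ng)]
    contrast = sum(k * k * p_diff[k] for k in range(ng))
    mu_x = sum(i * px[i] for i in range(ng))
    mu_y = sum(j * py[j] for j in range(ng))
    var_x = sum((i - mu_x) ** 2 * px[i] for i in range(ng))
    var_y = sum((j - mu_y) ** 2 * py[j] for j in range(ng))
    if var_x > 0 and var_y > 0:
        correlation = (
            sum(i * j * v for i, j, v in cells) - mu_x * mu_y
        ) / math.sqrt(var_x * var_y)
    else:
        correlation = 0.0
    variance = sum((i - mu_x) ** 2 * v for i, j, v in cells)
    idm = sum(v / (1 + (i - j) ** 2) for i, j, v in cells)
    p_sum = [
        sum(v for i, j, v in cells if i + j == k) for k in range(2 * ng - 1)
    ]
    sum_average = sum(k * p_sum[k] for k in range(2 * ng - 1))
    sum_variance = sum(
        (k - sum_average) ** 2 * p_sum[k] for k in range(2 * ng - 1)
    )
    sum_entropy = -sum(q * log2(q) for q in p_sum if q > 0)
    entropy = -sum(v * log2(v) for _, _, v in cells if v > 0)
    diff_mean = sum(k * p_diff[k] for k in range(ng))
    diff_variance = sum((k - diff_mean) ** 2 * p_diff[k] for k in range(ng))
    diff_entropy = -sum(q * log2(q) for q in p_diff if q > 0)
    hx = -sum(q * log2(q) for q in px if q > 0)
    hy = -sum(q * log2(q) for q in py if q > 0)
    hxy1 = -sum(
        v * log2(px[i] * py[j]) for i, j, v in cells if v > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * log2(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if px[i] * py[j] > 0
    )
    info1 = (entropy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    # convert bit entropies to nats for the classic exponential form
    arg = 1.0 - math.exp(-2.0 * math.log(2.0) * (hxy2 - entropy))
    info2 = math.sqrt(min(1.0, max(0.0, arg)))
    return {
        "energy": energy,
        "contrast": contrast,
        "correlation": correlation,
        "variance": variance,
        "inverse_difference_moment": idm,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "sum_entropy": sum_entropy,
        "entropy": entropy,
        "difference_variance": diff_variance,
        "difference_entropy": diff_entropy,
        "info_correlation_1": info1,
        "info_correlation_2": info2,
    }


def brute_pca_scores(X, n_components=3):
    """Scores/loadings/evr from an explicit eigh of the correlation matrix."""
    X = np.asarray(X, dtype=float)
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    scale = np.where(scale > 1e-12, scale, 1.0)
    Z = (X - center) / scale
    C = Z.T @ Z / (len(X) - 1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    loadings = evecs[:, :n_components].copy()
    for k in range(n_components):
        col = loadings[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, k] = -col
    scores = Z @ loadings
    evr = evals[:n_components] / evals.sum()
    return scores, loadings, evr
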