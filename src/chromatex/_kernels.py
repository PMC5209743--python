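"""Numba inner loops for co-occurrence accumulation and texture features.

One jitted feature kernel serves both the whole-image and the
sliding-window paths, so there is a single source of truth for the
texture arithmetic.  Entropies are reported in bits (log base 2); the
second information measure of correlation converts to nats internally
to keep the classic exponential form consistent.
"""

from __future__ import annotations

import numpy as np
from numba import njit

N_FEATURES = 13

_LN2 = float(np.log(2.0))


@njit(cache=True)
def accumulate_glcm(levels, mask, offsets, symmetric, counts):
    """Accumulate raw pair counts into ``counts`` (Ng x Ng).

    A pair contributes only when both pixels are in-mask.  Returns the
    number of distinct (ordered-by-offset) pairs counted; with
    ``symmetric`` each pair also increments the transposed cell, so the
    matrix total is twice the returned value.
    """
    rows, cols = levels.shape
    n_pairs = 0
    for k in range(offsets.shape[0]):
        dr = offsets[k, 0]
        dc = offsets[k, 1]
        for r in range(rows):
            r2 = r + dr
            if r2 < 0 or r2 >= rows:
                continue
            for c in range(cols):
                c2 = c + dc
                if c2 < 0 or c2 >= cols:
                    continue
                if mask[r, c] and mask[r2, c2]:
                    i = levels[r, c]
                    j = levels[r2, c2]
                    counts[i, j] += 1.0
                    if symmetric:
                        counts[j, i] += 1.0
                    n_pairs += 1
    return n_pairs


@njit(cache=True)
def haralick_features(p, out):
    """The 13 Haralick statistics of a normalized GLCM ``p``, into ``out``.

    Order: energy, contrast, correlation, variance, inverse difference
    moment, sum average, sum variance, sum entropy, entropy, difference
    variance, difference entropy, info correlation 1, info correlation 2.
    Degenerate conventions: 0*log(0) = 0; correlation and the first
    information measure are 0 when their denominators vanish; the second
    information measure is clamped to [0, 1] before the square root.
    """
    ng = p.shape[0]
    px = np.zeros(ng)
    py = np.zeros(ng)
    p_sum = np.zeros(2 * ng - 1)   # p_{x+y}, index i+j
    p_diff = np.zeros(ng)          # p_{x-y}, index |i-j|

    asm = 0.0
    entropy = 0.0
    idm = 0.0
    ij_moment = 0.0
    for i in range(ng):
        for j in range(ng):
            v = p[i, j]
            px[i] += v
            py[j] += v
            p_sum[i + j] += v
            p_diff[abs(i - j)] += v
            asm += v * v
            idm += v / (1.0 + (i - j) * (i - j))
            ij_moment += i * j * v
            if v > 0.0:
                entropy -= v * np.log2(v)

    mu_x = 0.0
    mu_y = 0.0
    for i in range(ng):
        mu_x += i * px[i]
        mu_y += i * py[i]
    var_x = 0.0
    var_y = 0.0
    hx = 0.0
    hy = 0.0
    for i in range(ng):
        var_x += (i - mu_x) ** 2 * px[i]
        var_y += (i - mu_y) ** 2 * py[i]
        if px[i] > 0.0:
            hx -= px[i] * np.log2(px[i])
        if py[i] > 0.0:
            hy -= py[i] * np.log2(py[i])

    if var_x > 0.0 and var_y > 0.0:
        correlation = (ij_moment - mu_x * mu_y) / np.sqrt(var_x * var_y)
    else:
        correlation = 0.0
    variance = var_x  # sum of squares about the marginal mean

    contrast = 0.0
    diff_mean = 0.0
    diff_entropy = 0.0
    for k in range(ng):
        contrast += k * k * p_diff[k]
        diff_mean += k * p_diff[k]
        if p_diff[k] > 0.0:
            diff_entropy -= p_diff[k] * np.log2(p_diff[k])
    diff_variance = 0.0
    for k in range(ng):
        diff_variance += (k - diff_mean) ** 2 * p_diff[k]

    sum_average = 0.0
    sum_entropy = 0.0
    for k in range(2 * ng - 1):
        sum_average += k * p_sum[k]
        if p_sum[k] > 0.0:
            sum_entropy -= p_sum[k] * np.log2(p_sum[k])
    sum_variance = 0.0
    for k in range(2 * ng - 1):
        sum_variance += (k - sum_average) ** 2 * p_sum[k]

    hxy1 = 0.0
    for i in range(ng):
        for j in range(ng):
            v = p[i, j]
            if v > 0.0:
                hxy1 -= v * np.log2(px[i] * py[j])
    hxy2 = 0.0
    for i in range(ng):
        for j in range(ng):
            prod = px[i] * py[j]
            if prod > 0.0:
                hxy2 -= prod * np.log2(prod)

    hmax = max(hx, hy)
    if hmax > 0.0:
        info_corr_1 = (entropy - hxy1) / hmax
    else:
        info_corr_1 = 0.0
    arg = 1.0 - np.exp(-2.0 * _LN2 * (hxy2 - entropy))
    if arg < 0.0:
        arg = 0.0
    elif arg > 1.0:
        arg = 1.0
    info_corr_2 = np.sqrt(arg)

    out[0] = asm
    out[1] = contrast
    out[2] = correlation
    out[3] = variance
    out[4] = idm
    out[5] = sum_average
    out[6] = sum_variance
    out[7] = sum_entropy
    out[8] = entropy
    out[9] = diff_variance
    out[10] = diff_entropy
    out[11] = info_corr_1
    out[12] = info_corr_2


@njit(cache=True)
def texture_map_kernel(levels, mask, n_levels, window, distance, min_pairs):
    """Sliding-window texture maps: a symmetric four-direction GLCM per
    in-mask pixel from its window x window neighborhood.

    Returns (maps, valid): maps is (13, rows, cols) with NaN outside the
    validity mask; a pixel is valid when its window holds at least
    ``min_pairs`` in-mask pixel pairs.
    """
    rows, cols = levels.shape
    half = window // 2
    maps = np.full((N_FEATURES, rows, cols), np.nan)
    valid = np.zeros((rows, cols), dtype=np.bool_)
    offsets = np.empty((4, 2), dtype=np.int64)
    offsets[0, 0] = 0
    offsets[0, 1] = distance
    offsets[1, 0] = distance
    offsets[1, 1] = 0
    offsets[2, 0] = distance
    offsets[2, 1] = distance
    offsets[3, 0] = distance
    offsets[3, 1] = -distance
    p = np.zeros((n_levels, n_levels))
    feats = np.empty(N_FEATURES)
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c]:
                continue
            r0 = max(0, r - half)
            r1 = min(rows, r + half + 1)
            c0 = max(0, c - half)
            c1 = min(cols, c + half + 1)
            p[:, :] = 0.0
            n_pairs = accumulate_glcm(
                levels[r0:r1, c0:c1], mask[r0:r1, c0:c1], offsets, True, p
            )
            if n_pairs < min_pairs:
                continue
            p /= 2.0 * n_pairs
            haralick_features(p, feats)
            for f in range(N_FEATURES):
                maps[f, r, c] = feats[f]
            valid[r, c] = True
    return maps, valid
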