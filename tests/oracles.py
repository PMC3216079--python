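"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's vectorized code paths and any scipy
shortcut: per-pixel scalar loops for classification, explicit rank-and-sum
evaluation for Kruskal–Wallis, loop-based sums of squares for the two-way
ANOVA behind the ICC, and Monte-Carlo simulation for t-test power.
"""

from __future__ import annotations

import math

import numpy as np

UNCOLORED, YELLOW, BLUE = 0, 1, 2


def brute_force_classify(image, bbox, yellow, blue):
    """Scalar per-pixel evaluation of the mean ± k·SD classification rule."""
    labels = np.empty((bbox.h, bbox.w), dtype=np.uint8)
    for j in range(bbox.h):
        for i in range(bbox.w):
            p = [float(c) for c in image[bbox.y + j, bbox.x + i]]
            in_y = all(
                abs(p[c] - yellow.mean[c]) <= yellow.k * yellow.sd[c] for c in range(3)
            )
            in_b = all(
                abs(p[c] - blue.mean[c]) <= blue.k * blue.sd[c] for c in range(3)
            )
            if in_y and in_b:
                dy = sum(
                    ((p[c] - yellow.mean[c]) / (yellow.sd[c] if yellow.sd[c] > 0 else 1.0)) ** 2
                    for c in range(3)
                )
                db = sum(
                    ((p[c] - blue.mean[c]) / (blue.sd[c] if blue.sd[c] > 0 else 1.0)) ** 2
                    for c in range(3)
                )
                labels[j, i] = YELLOW if dy <= db else BLUE
            elif in_y:
                labels[j, i] = YELLOW
            elif in_b:
                labels[j, i] = BLUE
            else:
                labels[j, i] = UNCOLORED
    return labels


def kruskal_wallis_oracle(groups):
    """Ties-corrected Kruskal–Wallis H by explicit mid-rank assignment."""
    pooled = [(v, gi) for gi, g in enumerate(groups) for v in g]
    pooled.sort(key=lambda t: t[0])
    n = len(pooled)
    ranks = [0.0] * n
    i = 0
    tie_sizes = []
    while i < n:
        j = i
        while j < n and pooled[j][0] == pooled[i][0]:
            j += 1
        mid = (i + 1 + j) / 2.0  # average of ranks i+1 .. j
        for m in range(i, j):
            ranks[m] = mid
        tie_sizes.append(j - i)
        i = j
    rank_sums = [0.0] * len(groups)
    for (v, gi), r in zip(pooled, ranks):
        rank_sums[gi] += r
    h = 12.0 / (n * (n + 1)) * sum(
        rank_sums[gi] ** 2 / len(groups[gi]) for gi in range(len(groups))
    ) - 3.0 * (n + 1)
    correction = 1.0 - sum(t**3 - t for t in tie_sizes) / (n**3 - n)
    return h / correction


def icc_oracle(values):
    """ICC(2,1) assembled from loop-computed two-way ANOVA sums of squares."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    grand = sum(values[i, j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(values[i, j] for j in range(k)) / k for i in range(n)]
    col = [sum(values[i, j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((r - grand) ** 2 for r in row)
    ssc = n * sum((c - grand) ** 2 for c in col)
    sst = sum((values[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


def monte_carlo_power(n, delta, sd, alpha, reps=100_000, seed=12345):
    """Empirical rejection rate of the two-sided pooled two-sample t-test."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, sd, size=(reps, n))
    b = rng.normal(delta, sd, size=(reps, n))
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    sp = np.sqrt((va + vb) / 2.0)
    t = (b.mean(axis=1) - a.mean(axis=1)) / (sp * math.sqrt(2.0 / n))
    from scipy import stats

    tcrit = stats.t.ppf(1.0 - alpha / 2.0, 2 * n - 2)
    return float(np.mean(np.abs(t) > tcrit))
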