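"""Independent brute-force oracles used by the test suite.

Everything here is written with plain Python loops and kept deliberately
separate from the implementation paths it checks.
"""

from itertools import combinations
from math import comb, floor, log2, sqrt


def round_tenth(x: float) -> float:
    """Round to one decimal, halves away from zero."""
    s = -1.0 if x < 0 else 1.0
    return s * floor(abs(x) * 10.0 + 0.5) / 10.0


def brute_levels(values):
    deci = [[int(round_tenth(v) * 10 + (0.5 if round_tenth(v) >= 0 else -0.5)) for v in row] for row in values]
    lo = min(min(row) for row in deci)
    return [[d - lo for d in row] for row in deci]


def brute_mean_var(values):
    flat = [v for row in values for v in row]
    n = len(flat)
    mean = sum(flat) / n
    var = sum((v - mean) ** 2 for v in flat) / n
    return mean, var


def brute_shape_moments(levels):
    flat = [v for row in levels for v in row]
    n = len(flat)
    mean = sum(flat) / n
    m2 = sum((v - mean) ** 2 for v in flat) / n
    if m2 == 0:
        return 0.0, 0.0
    m3 = sum((v - mean) ** 3 for v in flat) / n
    m4 = sum((v - mean) ** 4 for v in flat) / n
    return m3 / m2**1.5, m4 / m2**2


def brute_entropy(levels):
    flat = [v for row in levels for v in row]
    n = len(flat)
    counts = {}
    for v in flat:
        counts[v] = counts.get(v, 0) + 1
    return -sum((c / n) * log2(c / n) for c in counts.values())


def brute_glcm(levels, offset):
    dr, dc = offset
    rows, cols = len(levels), len(levels[0])
    n_levels = max(max(row) for row in levels) + 1
    counts = [[0] * n_levels for _ in range(n_levels)]
    pairs = 0
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols:
                counts[levels[r][c]][levels[r2][c2]] += 1
                pairs += 1
    return [[v / pairs for v in row] for row in counts], pairs


def brute_glcm_stats(p):
    n = len(p)
    contrast = sum((i - j) ** 2 * p[i][j] for i in range(n) for j in range(n))
    homog = sum(p[i][j] / (1 + abs(i - j)) for i in range(n) for j in range(n))
    energy = sum(p[i][j] ** 2 for i in range(n) for j in range(n))
    pr = [sum(p[i][j] for j in range(n)) for i in range(n)]
    pc = [sum(p[i][j] for i in range(n)) for j in range(n)]
    mu_r = sum(i * pr[i] for i in range(n))
    mu_c = sum(j * pc[j] for j in range(n))
    var_r = sum((i - mu_r) ** 2 * pr[i] for i in range(n))
    var_c = sum((j - mu_c) ** 2 * pc[j] for j in range(n))
    if var_r <= 0 or var_c <= 0:
        corr = 0.0
    else:
        cov = sum((i - mu_r) * (j - mu_c) * p[i][j] for i in range(n) for j in range(n))
        corr = cov / sqrt(var_r * var_c)
    return contrast, homog, energy, corr


def brute_nine_features(values, offset=(0, 20)):
    """The full feature vector by loops, in the documented fixed order."""
    mean, var = brute_mean_var(values)
    levels = brute_levels(values)
    skew, kurt = brute_shape_moments(levels)
    H = brute_entropy(levels)
    p, _ = brute_glcm(levels, offset)
    contrast, homog, energy, corr = brute_glcm_stats(p)
    return [mean, var, skew, kurt, H, contrast, homog, energy, corr]


def exhaustive_kmeans_wcss(points, k=2):
    """Global minimum within-cluster sum of squares over all 2-partitions."""
    assert k == 2
    n = len(points)
    dim = len(points[0])

    def wcss(idx_a, idx_b):
        total = 0.0
        for idx in (idx_a, idx_b):
            cent = [sum(points[i][d] for i in idx) / len(idx) for d in range(dim)]
            total += sum(sum((points[i][d] - cent[d]) ** 2 for d in range(dim)) for i in idx)
        return total

    best = None
    for mask in range(1, 2 ** (n - 1)):
        a = [i for i in range(n) if (mask >> i) & 1]
        b = [i for i in range(n) if not (mask >> i) & 1]
        if a and b:
            v = wcss(a, b)
            best = v if best is None else min(best, v)
    return best


def exact_rank_sum_p(a, b):
    """Two-sided exact Mann–Whitney p by pair counting over all arrangements.

    U is the pair-count statistic of the first sample (ties count 1/2);
    p = P(|U − n1·n2/2| ≥ |U_obs − n1·n2/2|).
    """
    pooled = list(a) + list(b)
    n1, n2 = len(a), len(b)

    def u_of(idx_a):
        idx_b = [i for i in range(n1 + n2) if i not in idx_a]
        u = 0.0
        for i in idx_a:
            for j in idx_b:
                if pooled[i] > pooled[j]:
                    u += 1.0
                elif pooled[i] == pooled[j]:
                    u += 0.5
        return u

    mu = n1 * n2 / 2.0
    dev = abs(u_of(tuple(range(n1))) - mu)
    hits = sum(1 for idx in combinations(range(n1 + n2), n1) if abs(u_of(idx) - mu) >= dev - 1e-9)
    return hits / comb(n1 + n2, n1)
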