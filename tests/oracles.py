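"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately written the slow, obvious way (loops,
exact rational arithmetic, generic root finders) and never calls the code
paths it is used to verify.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from scipy.optimize import brentq
from scipy.stats import studentized_range, t as t_dist


def auc_pair_enumeration(scores, labels) -> float:
    """AUC as the fraction of concordant (pos, neg) pairs, ties worth 1/2."""
    scores = list(map(float, scores))
    labels = list(map(int, labels))
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def fisher_two_sided_enumeration(table) -> float:
    """Two-sided Fisher p by exact hypergeometric enumeration (rationals)."""
    (a, b), (c, d) = [[int(v) for v in row] for row in table]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x: int) -> Fraction:
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return Fraction(0)
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), math.comb(n, c1))

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(0, min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs:
            total += px
    return float(min(total, Fraction(1)))


def normfinder_bruteforce(values, group_labels) -> dict:
    """Pure-loop variance-decomposition stability scores.

    Mirrors the documented model: per-sample centering, per-gene/group
    residual variances with the centering bias correction, group-mean
    deviations shrunk by a method-of-moments factor, stability =
    mean over groups of |shrunken deviation| + sqrt(intra variance / n_g).
    Returns {gene index: stability}.
    """
    y = [list(map(float, row)) for row in values]
    l = len(y)
    n_total = len(y[0])
    groups = []
    for g in group_labels:
        if g not in groups:
            groups.append(g)
    G = len(groups)

    # per-sample centering
    x = [[0.0] * n_total for _ in range(l)]
    for j in range(n_total):
        mean_j = sum(y[i][j] for i in range(l)) / l
        for i in range(l):
            x[i][j] = y[i][j] - mean_j

    cols = {g: [j for j, lab in enumerate(group_labels) if lab == g] for g in groups}
    xbar = [[0.0] * G for _ in range(l)]
    v = [[0.0] * G for _ in range(l)]
    n_g = [len(cols[g]) for g in groups]
    for i in range(l):
        for k, g in enumerate(groups):
            js = cols[g]
            m = sum(x[i][j] for j in js) / len(js)
            xbar[i][k] = m
            v[i][k] = sum((x[i][j] - m) ** 2 for j in js) / (len(js) - 1)

    s2 = [[0.0] * G for _ in range(l)]
    for k in range(G):
        col_sum = sum(v[i][k] for i in range(l))
        for i in range(l):
            raw = (v[i][k] - col_sum / (l * (l - 1))) * l / (l - 2)
            s2[i][k] = max(0.0, raw)
    z = [[s2[i][k] / n_g[k] for k in range(G)] for i in range(l)]

    d = [[0.0] * G for _ in range(l)]
    for i in range(l):
        row_mean = sum(xbar[i]) / G
        for k in range(G):
            d[i][k] = xbar[i][k] - row_mean

    num = sum(d[i][k] ** 2 - (1 - 1 / G) * z[i][k] for i in range(l) for k in range(G))
    g2 = max(0.0, num / (l * (G - 1)))

    stability = {}
    for i in range(l):
        acc = 0.0
        for k in range(G):
            denom = g2 + z[i][k]
            shrink = g2 / denom if denom > 0 else 0.0
            acc += abs(d[i][k] * shrink) + math.sqrt(z[i][k])
        stability[i] = acc / G
    return stability


def tukey_p_oracle(groups_data, i: int, j: int) -> float:
    """Tukey-Kramer pairwise p via the studentized range distribution."""
    k = len(groups_data)
    ns = [len(g) for g in groups_data]
    means = [float(np.mean(g)) for g in groups_data]
    df = sum(ns) - k
    mse = sum(
        sum((x - means[gi]) ** 2 for x in groups_data[gi]) for gi in range(k)
    ) / df
    se = math.sqrt(mse / 2 * (1 / ns[i] + 1 / ns[j]))
    q = abs(means[i] - means[j]) / se
    return float(studentized_range.sf(q, k, df))


def partial_corr_recursion(x, y, z) -> float:
    """Single-covariate partial correlation via the textbook recursion."""
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    r_xy = float(np.corrcoef(x, y)[0, 1])
    r_xz = float(np.corrcoef(x, z)[0, 1])
    r_yz = float(np.corrcoef(y, z)[0, 1])
    return (r_xy - r_xz * r_yz) / math.sqrt((1 - r_xz**2) * (1 - r_yz**2))


def partial_corr_p_oracle(r: float, n: int, k: int) -> float:
    df = n - k - 2
    t = r * math.sqrt(df / (1 - r * r))
    return float(2 * t_dist.sf(abs(t), df))


def free_t_root_oracle(total_t_nmol: float, shbg_nmol: float, albumin_g_l: float) -> float:
    """Free testosterone by numeric root finding on the raw mass balance."""
    ka, ks, mw = 3.6e4, 1.0e9, 69_000.0
    t = total_t_nmol * 1e-9
    s = shbg_nmol * 1e-9
    alb = albumin_g_l / mw

    def balance(ft):
        return ft * (1.0 + ka * alb) + ks * ft * s / (1.0 + ks * ft) - t

    if t == 0:
        return 0.0
    ft = brentq(balance, 0.0, t, xtol=1e-30, rtol=8.9e-16)
    return ft * 1e9


def least_squares_line(xs, ys) -> tuple[float, float]:
    """Closed-form simple-regression slope/intercept."""
    xs = [float(v) for v in xs]
    ys = [float(v) for v in ys]
    n = len(xs)
    mx, my = sum(xs) / n, sum(ys) / n
    sxx = sum((x - mx) ** 2 for x in xs)
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    slope = sxy / sxx
    return slope, my - slope * mx


def ks_statistic_oracle(values) -> float:
    """Sup-difference KS statistic against a normal with estimated params."""
    from scipy.stats import norm

    x = sorted(float(v) for v in values)
    n = len(x)
    mu = sum(x) / n
    sd = math.sqrt(sum((v - mu) ** 2 for v in x) / (n - 1))
    best = 0.0
    for i, v in enumerate(x, start=1):
        f = norm.cdf(v, mu, sd)
        best = max(best, abs(i / n - f), abs((i - 1) / n - f))
    return best
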