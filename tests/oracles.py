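"""Independent brute-force oracles shared by the test modules.

Everything here is deliberately naive — explicit loops, enumeration, dense
sampling, closed forms — and shares no code path with the package.
"""

import math
from itertools import combinations

import numpy as np
from scipy import special


def si_oracle(points):
    L = sum(math.dist(points[i], points[i + 1]) for i in range(len(points) - 1))
    if L == 0:
        return 0.0
    return math.dist(points[0], points[-1]) / L


def mean_reduction_oracle(points, place):
    total, n_mov = 0.0, 0
    for t in range(1, len(points)):
        red = math.dist(points[t - 1], place) - math.dist(points[t], place)
        if red != 0.0:
            n_mov += 1
            total += red
    return total / n_mov if n_mov else 0.0


def fraction_oracle(points, place, R=0.5):
    g, n = 0, 0
    for t in range(1, len(points)):
        red = math.dist(points[t - 1], place) - math.dist(points[t], place)
        if red != 0.0:
            n += 1
            if red > 0:
                g += 1
    if n == 0:
        return 0.0
    return (g / n - R) / (1 - R)


def ray_hits_disk_oracle(p, heading_deg, center, radius, reach=3000.0, steps=60000):
    """Dense sampling along the forward ray."""
    h = math.radians(heading_deg)
    ux, uz = math.sin(h), math.cos(h)
    for s in np.linspace(0.0, reach, steps):
        if math.dist((p[0] + s * ux, p[1] + s * uz), center) <= radius:
            return True
    return False


def binom_tail_oracle(k, n, p):
    """Upper-tail binomial probability by explicit enumeration."""
    return sum(math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))


def ks_stat_oracle(high, ref):
    """sup over pooled points of (CDF_ref - CDF_high), by counting."""
    best = -math.inf
    for x in list(high) + list(ref):
        ca = sum(1 for v in high if v <= x) / len(high)
        cb = sum(1 for v in ref if v <= x) / len(ref)
        best = max(best, cb - ca)
    return best


def ks_pvalue_permutation_oracle(high, ref):
    """Exact one-sided permutation p-value (the conditional exact null)."""
    pooled = list(high) + list(ref)
    n1 = len(high)
    d_obs = ks_stat_oracle(high, ref)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        chosen = set(idx)
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        total += 1
        if ks_stat_oracle(a, b) >= d_obs - 1e-12:
            hits += 1
    return hits / total


def pooled_t_oracle(a, b):
    """Hand-evaluated pooled-variance t statistic and upper-tail p."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    sa = sum((x - ma) ** 2 for x in a)
    sb = sum((x - mb) ** 2 for x in b)
    df = na + nb - 2
    sp2 = (sa + sb) / df
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return t, float(special.stdtr(df, -t))
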