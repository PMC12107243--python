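"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths (and, where possible, the
libraries) they are checked against: ranks are computed by sorting,
quartiles by direct linear interpolation on the order statistics, BH by
the literal step-up definition, and the metric maps by explicit pair
enumeration.
"""

import math

import numpy as np


def midranks(x):
    x = np.asarray(x, float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def pearson(x, y):
    x = np.asarray(x, float) - np.mean(x)
    y = np.asarray(y, float) - np.mean(y)
    return float(np.sum(x * y) / math.sqrt(np.sum(x * x) * np.sum(y * y)))


def spearman_oracle(x, y):
    """Mid-rank Pearson rho and the two-sided t-approximation p value."""
    from scipy.stats import t as tdist
    rho = pearson(midranks(x), midranks(y))
    n = len(x)
    tval = rho * math.sqrt((n - 2) / max(1 - rho ** 2, 1e-300))
    return rho, float(min(1.0, 2 * tdist.sf(abs(tval), n - 2)))


def bh_oracle(p):
    """Literal BH step-up: p_(i) * m / i, cumulative-min from the largest."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def quartile_fences_oracle(values, k=1.5):
    """Tukey fences with type-7 (linear interpolation) quartiles."""
    v = np.sort(np.asarray(values, float))
    n = len(v)

    def q(p):
        h = (n - 1) * p
        lo = int(math.floor(h))
        hi = min(lo + 1, n - 1)
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    q1, q3 = q(0.25), q(0.75)
    return q1 - k * (q3 - q1), q3 + k * (q3 - q1)


def fisher_z_oracle(r):
    return 0.5 * math.log((1 + r) / (1 - r))


def masked_sum_oracle(weights, labels, same_network):
    """Per-voxel sum over pairs in/out of the voxel's network, by loops."""
    n = len(labels)
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if (labels[i] == labels[j]) == same_network:
                out[i] += weights[i, j]
    return out
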