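"""Independent brute-force oracles used to cross-check the implementation.

Deliberately written in the most literal way possible (explicit loops,
direct transcription of definitions) and kept free of any nrbgrn imports.
"""

import numpy as np
from scipy import stats


def tom_brute_force(a: np.ndarray) -> np.ndarray:
    """ω_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij), triple loop."""
    n = a.shape[0]
    omega = np.eye(n)
    k = [sum(a[i, u] for u in range(n) if u != i) for i in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            omega[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return omega


def mutual_rank_brute_force(w: np.ndarray) -> np.ndarray:
    """Percentile-convention mutual rank via explicit sort-and-rank.

    rank 1 = strongest partner; tied weights get the mean of the positions
    they span; percentile r = (N − rank + 1)/N; MR = sqrt(r_i(j) · r_j(i)).
    """
    n = w.shape[0]
    big = n - 1
    pct = np.zeros((n, n))
    for i in range(n):
        partners = [j for j in range(n) if j != i]
        for j in partners:
            # mean rank among tied weights, 1-based from the strongest
            stronger = sum(1 for u in partners if w[i, u] > w[i, j])
            tied = sum(1 for u in partners if w[i, u] == w[i, j])
            rank = stronger + (tied + 1) / 2.0
            pct[i, j] = (big - rank + 1.0) / big
    mr = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i != j:
                mr[i, j] = np.sqrt(pct[i, j] * pct[j, i])
    return mr


def bh_step_up_brute_force(p):
    """Literal Benjamini–Hochberg step-up: padj_(i) = min_{j≥i} m·p_(j)/j."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running = min(running, m * p[i] / (pos + 1))
        adj[i] = running
    return adj


def welch_test_brute_force(a, b):
    """Welch's t statistic and two-sided p from the textbook formulas."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, 2.0 * stats.t.sf(abs(t), df)
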