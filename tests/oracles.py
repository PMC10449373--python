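"""Independent brute-force oracles used to pin the fast implementations.

These deliberately use naive enumeration (window scans, walk enumeration,
exhaustive permutations) so they share no code path with the package.
"""

from itertools import permutations, product

import numpy as np


def brute_force_ls(x, y, D):
    """Exhaustive local similarity: scan every aligned window pair.

    Returns (score, sign, delay) maximizing |sum of products| over all
    window starts (sx, sy) with |sx - sy| <= D and all window lengths,
    normalized by the full series length.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    best = (0.0, 1, 0)
    for sx in range(n):
        for sy in range(n):
            if abs(sx - sy) > D:
                continue
            s = 0.0
            for k in range(n - max(sx, sy)):
                s += x[sx + k] * y[sy + k]
                if abs(s) > best[0] + 1e-12:
                    best = (abs(s), 1 if s > 0 else -1, sx - sy)
    return best[0] / n, best[1], best[2]


def walk_enumeration_wi(a, steps):
    """WI^n by explicit walk enumeration over the one-step effect matrix.

    ``a[i, j]`` is the one-step effect of node j on node i.  The m-step
    effect of j on i sums the products of step effects over every walk of
    length m from j to i (revisits allowed); sigma_m[j] excludes walks
    ending where they started.  Returns (sigma, wi): sigma has shape
    (steps, k).
    """
    a = np.asarray(a, dtype=float)
    k = a.shape[0]
    sigma = np.zeros((steps, k))
    for m in range(1, steps + 1):
        for seq in product(range(k), repeat=m + 1):
            i, j = seq[0], seq[-1]
            if i == j:
                continue
            prod_val = 1.0
            for t in range(m):
                prod_val *= a[seq[t], seq[t + 1]]
                if prod_val == 0.0:
                    break
            sigma[m - 1, j] += prod_val
    return sigma, sigma.sum(axis=0) / steps


def pseudo_f_two_groups(d, labels):
    """Classical distance-based pseudo-F for a one-way two-group design.

    Uses the sum-of-squared-distance identities (total and within-group)
    rather than projection matrices.
    """
    d = np.asarray(d, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    groups = np.unique(labels)
    ss_total = (d[np.triu_indices(n, 1)] ** 2).sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.nonzero(labels == g)[0]
        sub = d[np.ix_(idx, idx)]
        ss_within += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
    ss_between = ss_total - ss_within
    df_b = len(groups) - 1
    df_w = n - len(groups)
    return (ss_between / df_b) / (ss_within / df_w), ss_between / ss_total


def exhaustive_permanova_p(d, labels):
    """Exact one-way PERMANOVA p by enumerating every row permutation."""
    labels = np.asarray(labels)
    n = len(labels)
    f_obs, _ = pseudo_f_two_groups(d, labels)
    count = 0
    total = 0
    for perm in permutations(range(n)):
        f_perm, _ = pseudo_f_two_groups(d, labels[list(perm)])
        count += f_perm >= f_obs - 1e-12
        total += 1
    return count / total


def exhaustive_mean_diff_p(values, labels):
    """Exact two-sided permutation p for a difference of group means."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    m1 = labels == groups[0]
    obs = abs(values[m1].mean() - values[~m1].mean())
    n1 = int(m1.sum())
    count = total = 0
    for perm in permutations(range(len(values))):
        v = values[list(perm)]
        diff = abs(v[:n1].mean() - v[n1:].mean())
        count += diff >= obs - 1e-12
        total += 1
    return count / total
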