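"""Independent brute-force enumeration oracles for the exact tests.

These share no code with the package: statistics are computed from raw
values and null distributions enumerated with itertools.
"""

import itertools

import numpy as np
from scipy.stats import rankdata, spearmanr


def u_from_values(x, y):
    x = np.asarray(x)[:, None]
    y = np.asarray(y)[None, :]
    return float((x > y).sum() + 0.5 * (x == y).sum())


def bf_mann_whitney_p(x, y):
    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = u_from_values(x, y)
    n_le = n_ge = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        rest = [i for i in range(len(pooled)) if i not in idx]
        u = u_from_values([pooled[i] for i in idx], [pooled[i] for i in rest])
        total += 1
        n_le += u <= u_obs + 1e-12
        n_ge += u >= u_obs - 1e-12
    return min(1.0, 2.0 * min(n_le / total, n_ge / total))


def bf_wilcoxon_p(diffs):
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n_le = n_ge = total = 0
    for signs in itertools.product([1, -1], repeat=len(d)):
        w = sum(r for r, s in zip(ranks, signs) if s > 0)
        total += 1
        n_le += w <= w_obs + 1e-9
        n_ge += w >= w_obs - 1e-9
    return min(1.0, 2.0 * min(n_le / total, n_ge / total))


def bf_spearman(x, y):
    rho_obs = spearmanr(x, y).statistic
    y = np.asarray(y)
    hits = total = 0
    for perm in itertools.permutations(range(len(y))):
        rho = spearmanr(x, y[list(perm)]).statistic
        total += 1
        hits += abs(rho) >= abs(rho_obs) - 1e-12
    return rho_obs, hits / total
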