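"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (pure-python loops, exhaustive
enumeration) kept separate from the package code paths they check.
"""

import itertools
import math


def midranks(values):
    """Average ranks (1-based) with ties sharing their mid-rank."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def pearson_oracle(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def spearman_oracle(x, y):
    """Product-moment correlation of mid-ranks."""
    return pearson_oracle(midranks(x), midranks(y))


def mann_whitney_u_oracle(g1, g2):
    """U statistic of group1 from mid-ranks of the pooled sample."""
    pooled = list(g1) + list(g2)
    r = midranks(pooled)
    r1 = sum(r[: len(g1)])
    return r1 - len(g1) * (len(g1) + 1) / 2


def mann_whitney_exact_p(g1, g2):
    """Exact two-sided p by enumerating every group-1 assignment of the
    pooled ranks (tie-free samples)."""
    n1, n2 = len(g1), len(g2)
    pooled = list(g1) + list(g2)
    u_obs = mann_whitney_u_oracle(g1, g2)
    lo, hi = min(u_obs, n1 * n2 - u_obs), max(u_obs, n1 * n2 - u_obs)
    count = total = 0
    for comb in itertools.combinations(range(n1 + n2), n1):
        sel = [pooled[i] for i in comb]
        rest = [pooled[i] for i in range(n1 + n2) if i not in comb]
        u = mann_whitney_u_oracle(sel, rest)
        total += 1
        if u <= lo + 1e-12 or u >= hi - 1e-12:
            count += 1
    return count / total


def responder_curve_oracle(post, fup, grid, n_min):
    """Naive responder curve: f(t), n(t) with None where undefined."""
    f, n = [], []
    for t in grid:
        sub = [i for i in range(len(post)) if post[i] < t]
        n.append(len(sub))
        if len(sub) >= n_min:
            f.append(sum(1 for i in sub if fup[i] < post[i]) / len(sub))
        else:
            f.append(None)
    return f, n


def elbow_exhaustive_p(post, fup, grid, n_min, statistic="weighted"):
    """Add-one permutation p of the max-distance statistic against the
    mean permuted curve, by full enumeration of fup arrangements."""
    n = len(post)
    perms = list(itertools.permutations(range(n)))
    curves = []
    for perm in perms:
        f, counts = responder_curve_oracle(post, [fup[i] for i in perm],
                                           grid, n_min)
        curves.append(f)
    defined = [i for i in range(len(grid)) if counts[i] >= n_min]
    ref = {i: sum(c[i] for c in curves) / len(curves) for i in defined}

    def dmax(f):
        best = -math.inf
        for i in defined:
            w = counts[i] / n if statistic == "weighted" else 1.0
            best = max(best, w * (f[i] - ref[i]))
        return best

    f_obs, _ = responder_curve_oracle(post, fup, grid, n_min)
    d_obs = dmax(f_obs)
    exceed = sum(1 for c in curves if dmax(c) >= d_obs - 1e-12)
    return (1 + exceed) / (1 + len(perms)), d_obs
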