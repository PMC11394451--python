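"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive quantities from first principles (linear
programming, exhaustive path enumeration, exhaustive subset search) so the
fast implementations in :mod:`equicna` are checked against a second,
structurally unrelated route.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog


def dip_lp(values: np.ndarray) -> float:
    """Exact dip statistic straight from its definition.

    The dip of an empirical CDF ``F_n`` is ``min_G sup_x |F_n(x) - G(x)|``
    over all unimodal distribution functions G (convex up to some mode m,
    concave after, with an atom at the mode permitted).  For a fixed mode
    placement the optimal G may be taken piecewise linear with knots at the
    data points and a single jump at the mode, so the inner problem is a
    small LP; the dip is the minimum over all mode placements (each sample
    point and each open gap between adjacent points).
    """
    x = np.sort(np.asarray(values, dtype=float))
    u, counts = np.unique(x, return_counts=True)
    n = x.size
    m = u.size
    if n < 2 or m == 1:
        return 0.0
    cum = np.cumsum(counts) / n  # F_n(u_j)
    lo = np.concatenate([[0.0], cum[:-1]])  # F_n(u_j^-)

    best = np.inf
    # point modes k = 0..m-1 (jump allowed at u_k), gap modes between k,k+1
    for kind, k in itertools.chain(
        (("point", k) for k in range(m)), (("gap", k) for k in range(m - 1))
    ):
        res = _mode_lp(u, cum, lo, kind, k)
        if res is not None:
            best = min(best, res)
    return float(best)


def _mode_lp(u, cum, lo, kind, k):
    m = u.size
    # variables: g_0..g_{m-1}, [l_k if point mode], d
    extra = 1 if kind == "point" else 0
    nv = m + extra + 1
    d_ix = nv - 1
    lk_ix = m  # only valid when extra
    A, b = [], []

    def row():
        return np.zeros(nv)

    # tube constraints: g_j >= cum_j - d ; left-limit <= lo_j + d
    for j in range(m):
        r = row()
        r[j] = -1.0
        r[d_ix] = -1.0
        A.append(r)
        b.append(-cum[j])
        r = row()
        if kind == "point" and j == k:
            r[lk_ix] = 1.0
        else:
            r[j] = 1.0
        r[d_ix] = -1.0
        A.append(r)
        b.append(lo[j])
    # monotonicity
    for j in range(m - 1):
        r = row()
        r[j] = 1.0
        r[j + 1] = -1.0
        A.append(r)
        b.append(0.0)
    if kind == "point":
        # g_{k-1} <= l_k <= g_k
        r = row()
        r[lk_ix] = 1.0
        r[k] = -1.0
        A.append(r)
        b.append(0.0)
        if k > 0:
            r = row()
            r[k - 1] = 1.0
            r[lk_ix] = -1.0
            A.append(r)
            b.append(0.0)

    def val_ix(j):
        """Variable holding G's value at knot j on the convex side."""
        if kind == "point" and j == k:
            return lk_ix
        return j

    # convex side: slopes nondecreasing over knots 0..k
    left_knots = list(range(k + 1))
    for a in range(len(left_knots) - 2):
        j0, j1, j2 = left_knots[a], left_knots[a + 1], left_knots[a + 2]
        h0 = u[j1] - u[j0]
        h1 = u[j2] - u[j1]
        # (v1 - v0)/h0 <= (v2 - v1)/h1  =>  -h1*v0 + (h0+h1)*v1 - h0*v2 <= 0
        r = row()
        r[val_ix(j0)] += -h1
        r[val_ix(j1)] += h0 + h1
        r[val_ix(j2)] += -h0
        A.append(r)
        b.append(0.0)
    # concave side: knots start at k (point mode, value g_k) or k+1 (gap)
    start = k if kind == "point" else k + 1
    right_knots = list(range(start, m))
    for a in range(len(right_knots) - 2):
        j0, j1, j2 = right_knots[a], right_knots[a + 1], right_knots[a + 2]
        h0 = u[j1] - u[j0]
        h1 = u[j2] - u[j1]
        # slopes nonincreasing: (v1-v0)/h0 >= (v2-v1)/h1
        r = row()
        r[j0] += h1
        r[j1] += -(h0 + h1)
        r[j2] += h0
        A.append(r)
        b.append(0.0)

    bounds = [(0.0, 1.0)] * m + [(0.0, 1.0)] * extra + [(0.0, 0.5)]
    c = np.zeros(nv)
    c[d_ix] = 1.0
    res = linprog(c, A_ub=np.array(A), b_ub=np.array(b), bounds=bounds, method="highs")
    if not res.success:
        return None
    return res.fun


def wright_inbreeding(parents: dict) -> dict:
    """Inbreeding by exhaustive Wright path counting.

    F_i = sum over common ancestors A of sire and dam, over pairs of
    ancestor paths meeting only at A, of (1/2)^(L1+L2+1) * (1 + F_A).
    Exponential in pedigree size; fine for <= ~12 individuals.
    """

    order = _topo(parents)
    F: dict = {}

    def paths_up(node):
        """All ancestor paths (node, ..., ancestor) as tuples."""
        out = [(node,)]
        s, d = parents.get(node, (None, None))
        for p in (s, d):
            if p is not None:
                out.extend((node,) + t for t in paths_up(p))
        return out

    for ind in order:
        s, d = parents.get(ind, (None, None))
        if s is None or d is None:
            F[ind] = 0.0
            continue
        tot = 0.0
        for p1 in paths_up(s):
            for p2 in paths_up(d):
                if p1[-1] != p2[-1]:
                    continue
                # paths must share only the common ancestor
                if set(p1[:-1]) & set(p2):
                    continue
                if set(p2[:-1]) & set(p1):
                    continue
                a = p1[-1]
                tot += 0.5 ** (len(p1) + len(p2) - 1) * (1.0 + F[a])
        F[ind] = tot
    return F


def wright_kinship(parents: dict, i, j) -> float:
    """Coancestry f_ij by path counting: f_ij = a_ij / 2 with Wright's
    numerator relationship from exhaustive path enumeration."""
    F = wright_inbreeding(parents)

    def paths_up(node):
        out = [(node,)]
        s, d = parents.get(node, (None, None))
        for p in (s, d):
            if p is not None:
                out.extend((node,) + t for t in paths_up(p))
        return out

    if i == j:
        return 0.5 * (1.0 + F[i])
    tot = 0.0
    for p1 in paths_up(i):
        for p2 in paths_up(j):
            if p1[-1] != p2[-1]:
                continue
            if set(p1[:-1]) & set(p2) or set(p2[:-1]) & set(p1):
                continue
            a = p1[-1]
            tot += 0.5 ** (len(p1) + len(p2) - 2) * (1.0 + F[a])
    return 0.5 * tot


def lineage_hit_probability(parents: dict, ind, blockers: frozenset) -> float:
    """P(a random gene lineage from ``ind`` passes through ``blockers``).

    A gene copy follows one parent at random at each step; unknown parents
    terminate the lineage.  Independent of the package's contribution
    propagation (downward recursion instead of upward accumulation).
    """
    if ind in blockers:
        return 1.0
    s, d = parents.get(ind, (None, None))
    p = 0.0
    if s is not None:
        p += 0.5 * lineage_hit_probability(parents, s, blockers)
    if d is not None:
        p += 0.5 * lineage_hit_probability(parents, d, blockers)
    return p


def exhaustive_min_ancestors(parents: dict, group, threshold: float, max_size: int):
    """Smallest ancestor set explaining >= threshold of the group gene
    pool, by exhaustive search over subsets up to ``max_size``."""
    ancestors = set()
    frontier = list(group)
    while frontier:
        node = frontier.pop()
        for p in parents.get(node, (None, None)):
            if p is not None and p not in ancestors:
                ancestors.add(p)
                frontier.append(p)
    ancestors -= set(group)
    cand = sorted(ancestors)
    for size in range(1, max_size + 1):
        for subset in itertools.combinations(cand, size):
            S = frozenset(subset)
            expl = sum(lineage_hit_probability(parents, g, S) for g in group) / len(group)
            if expl >= threshold - 1e-12:
                return size
    return None


def _topo(parents: dict) -> list:
    import graphlib

    ts = graphlib.TopologicalSorter()
    for child, (s, d) in parents.items():
        preds = [p for p in (s, d) if p is not None]
        ts.add(child, *preds)
    return list(ts.static_order())
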