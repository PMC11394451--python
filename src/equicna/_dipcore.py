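"""Numerical kernel for the dip statistic of unimodality.

The dip of a sample is the smallest sup-norm distance between its empirical
CDF and any unimodal distribution function (convex up to a mode, concave
after it, an atom at the mode permitted).  The kernel computes it exactly
by scanning candidate mode placements ("splits"):

* per side, the binding band constraints reduce to violations by the
  greatest convex minorant of the upper ECDF corners (convex side) or the
  least concave majorant of the lower corners (concave side);
* the sides are coupled at the mode: convexity can force the left branch
  above what the concave branch can accept.  The coupling constraints are
  extrapolation lines through one upper and one lower band anchor; the
  minimal feasible distance is found by monotone bisection;
* tied observations add band-width floors, except at a mode knot, where
  the CDF may jump.

Hull predecessors/successors are precomputed once as pointer chains (the
hull of any prefix is the chain walked back from its last point), so each
candidate split touches only hull vertices.  Everything is numba-compiled;
a pure-Python fallback keeps the module importable without numba.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _prefix_violations(u, a, c, w):
    """V[k] = max violation of the convex band over the prefix of length k.

    Violation at an interior knot j: c_j minus the greatest convex minorant
    of the upper anchors (u_i, a_i) evaluated at u_j.  Nondecreasing in k.
    """
    m = u.size
    V = np.zeros(m + 1)
    hull = np.empty(m, np.int64)
    nh = 0
    run = 0.0
    for k in range(m):
        if k >= 2 and w[k - 1] > run:
            # previous endpoint turns interior; if it stays a hull vertex
            # its violation is its own tie weight
            run = w[k - 1]
        while nh >= 2:
            i0 = hull[nh - 2]
            i1 = hull[nh - 1]
            if (a[i1] - a[i0]) * (u[k] - u[i0]) >= (a[k] - a[i0]) * (u[i1] - u[i0]):
                nh -= 1
            else:
                break
        if nh >= 1:
            p = hull[nh - 1]
            if k - p >= 2:
                x0 = u[p]
                y0 = a[p]
                sl = (a[k] - y0) / (u[k] - x0)
                for j in range(p + 1, k):
                    v = c[j] - (y0 + sl * (u[j] - x0))
                    if v > run:
                        run = v
        hull[nh] = k
        nh += 1
        V[k + 1] = run
    return V


@njit(cache=True)
def _suffix_violations(u, a, c, w):
    """V[s] = max violation of the concave band over the suffix from s.

    Violation at an interior knot j: least concave majorant of the lower
    anchors (u_i, c_i) evaluated at u_j, minus a_j.  Nonincreasing in s.
    """
    m = u.size
    V = np.zeros(m + 1)
    hull = np.empty(m, np.int64)
    nh = 0
    run = 0.0
    for k in range(m - 1, -1, -1):
        if k <= m - 3 and w[k + 1] > run:
            run = w[k + 1]
        while nh >= 2:
            i0 = hull[nh - 2]
            i1 = hull[nh - 1]
            if (c[i1] - c[i0]) * (u[k] - u[i0]) >= (c[k] - c[i0]) * (u[i1] - u[i0]):
                nh -= 1
            else:
                break
        if nh >= 1:
            p = hull[nh - 1]
            if p - k >= 2:
                x0 = u[p]
                y0 = c[p]
                sl = (c[k] - y0) / (u[k] - x0)
                for j in range(k + 1, p):
                    v = (y0 + sl * (u[j] - x0)) - a[j]
                    if v > run:
                        run = v
        hull[nh] = k
        nh += 1
        V[k] = run
    return V


@njit(cache=True)
def _hull_chains(u, a, c):
    """Predecessor/successor pointers for the four hulls used by junctions.

    prev_la[k]: previous vertex of the lower hull of (u, a) over [0..k]
    prev_uc[k]: previous vertex of the upper hull of (u, c) over [0..k]
    next_ua[k]: next vertex of the lower hull of (u, a) over [k..m-1]
    next_lc[k]: next vertex of the upper hull of (u, c) over [k..m-1]
    (-1 marks a chain end).  The hull of any prefix [0..k] is the chain
    walked back from k; of any suffix [k..m-1] the chain walked forward.
    """
    m = u.size
    prev_la = np.full(m, -1, np.int64)
    prev_uc = np.full(m, -1, np.int64)
    next_ua = np.full(m, -1, np.int64)
    next_lc = np.full(m, -1, np.int64)
    stack = np.empty(m, np.int64)

    ns = 0
    for k in range(m):
        while ns >= 2:
            i0, i1 = stack[ns - 2], stack[ns - 1]
            if (a[i1] - a[i0]) * (u[k] - u[i0]) >= (a[k] - a[i0]) * (u[i1] - u[i0]):
                ns -= 1
            else:
                break
        prev_la[k] = stack[ns - 1] if ns >= 1 else -1
        stack[ns] = k
        ns += 1
    ns = 0
    for k in range(m):
        while ns >= 2:
            i0, i1 = stack[ns - 2], stack[ns - 1]
            if (c[i1] - c[i0]) * (u[k] - u[i0]) <= (c[k] - c[i0]) * (u[i1] - u[i0]):
                ns -= 1
            else:
                break
        prev_uc[k] = stack[ns - 1] if ns >= 1 else -1
        stack[ns] = k
        ns += 1
    ns = 0
    for k in range(m - 1, -1, -1):
        while ns >= 2:
            i0, i1 = stack[ns - 2], stack[ns - 1]
            if (a[i1] - a[i0]) * (u[k] - u[i0]) <= (a[k] - a[i0]) * (u[i1] - u[i0]):
                ns -= 1
            else:
                break
        next_ua[k] = stack[ns - 1] if ns >= 1 else -1
        stack[ns] = k
        ns += 1
    ns = 0
    for k in range(m - 1, -1, -1):
        while ns >= 2:
            i0, i1 = stack[ns - 2], stack[ns - 1]
            if (c[i1] - c[i0]) * (u[k] - u[i0]) >= (c[k] - c[i0]) * (u[i1] - u[i0]):
                ns -= 1
            else:
                break
        next_lc[k] = stack[ns - 1] if ns >= 1 else -1
        stack[ns] = k
        ns += 1
    return prev_la, prev_uc, next_ua, next_lc


@njit(cache=True)
def _lmin_full(u, a, c, kL, jx, D, prev_la, point_mode):
    """Greatest lower bound on the convex branch's value at jx.

    Exact: for every lower anchor j the steepest line from an upper anchor
    i < j is found on the lower hull of (u, a) over [0..j-1] (walked via
    predecessor pointers), and the line is extrapolated to jx.
    """
    best = -1e300
    if not point_mode:
        best = c[kL] - D
    for j in range(1, kL + 1):
        if point_mode and j == kL:
            continue
        yj = c[j] - D
        sbest = -1e300
        i = j - 1
        while i >= 0:
            s = (yj - (a[i] + D)) / (u[j] - u[i])
            if s > sbest:
                sbest = s
            i = prev_la[i]
        v = yj + sbest * (jx - u[j])
        if v > best:
            best = v
    return best


@njit(cache=True)
def _rmax_full(u, a, c, kR, m, jx, D, next_lc, point_mode):
    """Least upper bound on the concave branch's value at jx (mirror)."""
    best = 1e300
    if not point_mode:
        best = a[kR] + D
    for j in range(m - 2, kR - 1, -1):
        if point_mode and j == kR:
            continue
        yj = a[j] + D
        sbest = -1e300
        l = j + 1
        while l >= 0:
            s = ((c[l] - D) - yj) / (u[l] - u[j])
            if s > sbest:
                sbest = s
            l = next_lc[l]
        v = yj - sbest * (u[j] - jx)
        if v < best:
            best = v
    return best


@njit(cache=True)
def _lmin_hullpairs(u, a, c, kL, jx, D, prev_la, prev_uc, point_mode):
    """Lower bound on LMIN from hull-vertex pairs only (subset of the
    constraints, hence sound for rejecting a split)."""
    best = -1e300
    if not point_mode:
        best = c[kL] - D
    j = kL if not point_mode else prev_uc[kL]
    while j >= 0:
        if j >= 1 and u[j] < jx:
            yj = c[j] - D
            sbest = -1e300
            i = j - 1
            while i >= 0:
                s = (yj - (a[i] + D)) / (u[j] - u[i])
                if s > sbest:
                    sbest = s
                i = prev_la[i]
            v = yj + sbest * (jx - u[j])
            if v > best:
                best = v
        j = prev_uc[j]
    return best


@njit(cache=True)
def _rmax_hullpairs(u, a, c, kR, m, jx, D, next_ua, next_lc, point_mode):
    best = 1e300
    if not point_mode:
        best = a[kR] + D
    j = kR if not point_mode else next_ua[kR]
    while j >= 0:
        if j <= m - 2 and u[j] > jx:
            yj = a[j] + D
            sbest = -1e300
            l = j + 1
            while l >= 0:
                s = ((c[l] - D) - yj) / (u[l] - u[j])
                if s > sbest:
                    sbest = s
                l = next_lc[l]
            v = yj - sbest * (u[j] - jx)
            if v < best:
                best = v
        j = next_ua[j]
    return best


@njit(cache=True)
def _feasible_full(u, a, c, kL, kR, m, D, prev_la, next_lc, point_mode):
    jxL = u[kL]
    jxR = u[kR]
    lm = _lmin_full(u, a, c, kL, jxL, D, prev_la, point_mode)
    rm = _rmax_full(u, a, c, kR, m, jxR, D, next_lc, point_mode)
    if point_mode:
        if lm > a[kL] + D:
            return False
        if c[kR] - D > rm:
            return False
    return lm <= rm


@njit(cache=True)
def _junction_D(
    u, a, c, kL, kR, m, base_D, cap_D, prev_la, prev_uc, next_ua, next_lc, point_mode
):
    """Minimal D for one mode placement including the junction coupling.

    Returns base_D when the junction is slack there; any value >= cap_D
    means "this placement cannot beat cap_D".  Bisection over the monotone
    feasibility predicate is exact.
    """
    # a split matching the incumbent to ~1e-10 relative cannot improve it;
    # checking feasibility just below cap rejects ties cheaply and keeps
    # bisection for strict improvements only
    cap_eff = cap_D - 1e-10 * (1.0 + cap_D)
    if base_D < cap_D <= 0.25 * c[m - 1] + 1.0:
        # sound cheap rejection from the hull-pair subset of constraints
        lm = _lmin_hullpairs(u, a, c, kL, u[kL], cap_eff, prev_la, prev_uc, point_mode)
        rm = _rmax_hullpairs(u, a, c, kR, m, u[kR], cap_eff, next_ua, next_lc, point_mode)
        bad = lm > rm
        if point_mode and not bad:
            bad = (lm > a[kL] + cap_eff) or (c[kR] - cap_eff > rm)
        if bad:
            return cap_D
    if _feasible_full(u, a, c, kL, kR, m, base_D, prev_la, next_lc, point_mode):
        return base_D
    hi_d = 0.25 * c[m - 1] + 1.0  # dip <= 1/4 keeps D far below this
    if cap_eff < hi_d:
        hi_d = cap_eff
        if not _feasible_full(u, a, c, kL, kR, m, hi_d, prev_la, next_lc, point_mode):
            return cap_D
    lo_d = base_D
    for _ in range(60):
        mid = 0.5 * (lo_d + hi_d)
        if _feasible_full(u, a, c, kL, kR, m, mid, prev_la, next_lc, point_mode):
            hi_d = mid
        else:
            lo_d = mid
        if hi_d - lo_d <= 1e-14 * (1.0 + hi_d):
            break
    return hi_d


@njit(cache=True)
def _dip_unique(u, w):
    """Dip statistic from unique sorted values u with tie counts w."""
    m = u.size
    n = 0.0
    for i in range(m):
        n += w[i]
    if m <= 1 or n < 2:
        return 0.0
    c = np.empty(m)
    a = np.empty(m)
    acc = 0.0
    for i in range(m):
        a[i] = acc
        acc += w[i]
        c[i] = acc
    wf = w.astype(np.float64)

    Vc = _prefix_violations(u, a, c, wf)
    Vv = _suffix_violations(u, a, c, wf)
    prev_la, prev_uc, next_ua, next_lc = _hull_chains(u, a, c)
    wmax = wf.max()

    nsplit = m + 1
    base = np.empty(nsplit)
    for k in range(nsplit):
        b = Vc[k]
        if Vv[k] > b:
            b = Vv[k]
        if wmax > b:
            b = wmax
        base[k] = b  # units: 2*D
    order = np.argsort(base)
    best = 1e300
    for t in range(nsplit):
        k = order[t]
        if base[k] >= best:
            break
        if k == 0 or k == m:
            D = 0.5 * base[k]
        else:
            D = _junction_D(
                u, a, c, k - 1, k, m, 0.5 * base[k], 0.5 * best,
                prev_la, prev_uc, next_ua, next_lc, False,
            )
        if 2.0 * D < best:
            best = 2.0 * D

    if wmax > 1.0:
        # a jump at a tied mode knot can beat every gap placement
        basep = np.empty(m)
        for k in range(m):
            b = Vc[k + 1]
            if Vv[k] > b:
                b = Vv[k]
            wo = 0.0
            for j in range(m):
                if j != k and wf[j] > wo:
                    wo = wf[j]
            if wo > b:
                b = wo
            basep[k] = b
        orderp = np.argsort(basep)
        for t in range(m):
            k = orderp[t]
            if basep[k] >= best:
                break
            D = _junction_D(
                u, a, c, k, k, m, 0.5 * basep[k], 0.5 * best,
                prev_la, prev_uc, next_ua, next_lc, True,
            )
            if 2.0 * D < best:
                best = 2.0 * D

    return 0.5 * best / n


@njit(cache=True)
def dip_sorted(x):
    """Dip statistic of a sorted 1-D float64 sample."""
    n = x.size
    if n < 2:
        return 0.0
    u = np.empty(n)
    w = np.empty(n)
    m = 0
    i = 0
    while i < n:
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        u[m] = x[i]
        w[m] = j - i + 1
        m += 1
        i = j + 1
    return _dip_unique(u[:m], w[:m])


@njit(cache=True)
def null_dips(samples):
    """Dip of each row of a (reps, n) matrix (rows are sorted in place)."""
    reps = samples.shape[0]
    out = np.empty(reps)
    for r in range(reps):
        row = np.sort(samples[r])
        out[r] = dip_sorted(row)
    return out
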