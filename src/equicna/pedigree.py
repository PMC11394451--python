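"""Pedigree-based population genetics for CNA case characterisation.

Affected animals are characterised against their studbook pedigree to ask
whether the aberration clusters in families: individual inbreeding F
(probability the two alleles at a locus are identical by descent),
pairwise coancestry f_ij (probability two random gametes from i and j
carry IBD alleles), the minimum number of ancestors explaining a given
fraction of the group's gene pool (a50), and shared ancestors within a
fixed number of generations.

F uses the Meuwissen & Luo within-family-variance recursion; f_ij the
tabular (recursive kinship) method.  a50 uses the marginal-contribution
greedy selection: each round picks the ancestor with the largest expected
genetic contribution not yet explained by the ancestors already chosen,
cutting the chosen ancestor's parent links so later rounds cannot count
the same gene flow twice.
"""

from __future__ import annotations

import graphlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import read_pedigree_csv, write_pedigree_csv

__all__ = [
    "Pedigree",
    "inbreeding",
    "coancestry",
    "kinship_matrix",
    "ancestors_explaining",
    "common_ancestors",
    "metrics_report",
]


class Pedigree:
    """Parent map with topological ordering.

    Unknown parents are ``None`` and are treated as unique unrelated
    founders.  Construction fails on cycles and on sex-inconsistent
    parental roles (when sexes are provided).
    """

    def __init__(
        self,
        parents: Mapping,
        birth_dates: Optional[Mapping] = None,
        sexes: Optional[Mapping] = None,
    ):
        self.parents = {}
        for ind, (sire, dam) in parents.items():
            self.parents[ind] = (sire, dam)
        # parents referenced but not listed become founders
        for sire, dam in list(self.parents.values()):
            for p in (sire, dam):
                if p is not None and p not in self.parents:
                    self.parents[p] = (None, None)
        ts = graphlib.TopologicalSorter()
        for ind, (sire, dam) in self.parents.items():
            ts.add(ind, *[p for p in (sire, dam) if p is not None])
        try:
            self.order = list(ts.static_order())
        except graphlib.CycleError as e:
            raise ValueError(f"pedigree contains a cycle: {e}") from None
        self.index = {ind: i for i, ind in enumerate(self.order)}
        self.birth_dates = dict(birth_dates or {})
        self.sexes = dict(sexes or {})
        for ind, (sire, dam) in self.parents.items():
            if sire is not None and self.sexes.get(sire) == "female":
                raise ValueError(f"{sire} recorded female but used as sire of {ind}")
            if dam is not None and self.sexes.get(dam) == "male":
                raise ValueError(f"{dam} recorded male but used as dam of {ind}")

    def __len__(self):
        return len(self.parents)

    def __contains__(self, ind):
        return ind in self.parents

    @property
    def founders(self) -> list:
        return [i for i, (s, d) in self.parents.items() if s is None and d is None]

    def ancestors(self, ind, max_generations: Optional[int] = None) -> dict:
        """Ancestors of ``ind`` with their minimum generation distance
        (parents = generation 1)."""
        out = {}
        frontier = [(ind, 0)]
        while frontier:
            node, g = frontier.pop()
            if max_generations is not None and g >= max_generations:
                continue
            for p in self.parents.get(node, (None, None)):
                if p is None:
                    continue
                if p not in out or out[p] > g + 1:
                    out[p] = g + 1
                    frontier.append((p, g + 1))
        return out

    @classmethod
    def from_csv(cls, source) -> "Pedigree":
        df = read_pedigree_csv(source)
        parents = {}
        dates = {}
        sexes = {}
        for _, row in df.iterrows():
            parents[row["id"]] = (row["sire"] or None, row["dam"] or None)
            if "birth_date" in row and row.get("birth_date"):
                dates[row["id"]] = row["birth_date"]
            if "sex" in row and row.get("sex"):
                sexes[row["id"]] = row["sex"]
        return cls(parents, dates, sexes)

    def to_csv(self, path_or_buf) -> None:
        rows = []
        for ind in self.order:
            s, d = self.parents[ind]
            row = {"id": ind, "sire": s or "", "dam": d or ""}
            if self.birth_dates.get(ind):
                row["birth_date"] = self.birth_dates[ind]
            if self.sexes.get(ind):
                row["sex"] = self.sexes[ind]
            rows.append(row)
        write_pedigree_csv(rows, path_or_buf)


def inbreeding(ped: Pedigree) -> dict:
    """Inbreeding coefficients by the Meuwissen-Luo recursion.

    For an individual with sire s and dam d, ``1 + F = sum_j L_j^2 D_j``
    over the ancestors j of a virtual progeny vector started at s and d
    with weight 1/2 each, where D_j is the within-family (Mendelian
    sampling) variance coefficient.  Founders have F = 0.
    """
    order = ped.order
    idx = ped.index
    n = len(order)
    F = np.zeros(n)
    D = np.ones(n)
    sires = np.full(n, -1)
    dams = np.full(n, -1)
    for i, ind in enumerate(order):
        s, d = ped.parents[ind]
        sires[i] = idx[s] if s is not None else -1
        dams[i] = idx[d] if d is not None else -1

    L = np.zeros(n)
    for i in range(n):
        s, d = sires[i], dams[i]
        if s >= 0 and d >= 0:
            D[i] = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            D[i] = 0.75 - 0.25 * F[max(s, d)]
        else:
            D[i] = 1.0
        if s < 0 or d < 0:
            F[i] = 0.0
            continue
        # accumulate a_ss' for the virtual progeny of (s, d)
        L[: i + 1] = 0.0
        L[s] += 0.5
        L[d] += 0.5
        # the virtual progeny itself contributes L^2 * D = 1 * D
        total = 0.5 - 0.25 * (F[s] + F[d])
        for j in range(max(s, d), -1, -1):
            if L[j] == 0.0:
                continue
            total += L[j] * L[j] * D[j]
            js, jd = sires[j], dams[j]
            if js >= 0:
                L[js] += 0.5 * L[j]
            if jd >= 0:
                L[jd] += 0.5 * L[j]
            L[j] = 0.0
        F[i] = total - 1.0
    return {ind: float(F[i]) for i, ind in enumerate(order)}


def kinship_matrix(ped: Pedigree, individuals: Optional[Sequence] = None) -> pd.DataFrame:
    """Tabular-method kinship (coancestry) matrix.

    f(i,i) = (1 + F_i)/2; for topological order i after j,
    f(i,j) = (f(sire_i, j) + f(dam_i, j)) / 2 with unknown parents
    contributing 0.
    """
    order = ped.order
    idx = ped.index
    n = len(order)
    K = np.zeros((n, n))
    for i, ind in enumerate(order):
        s, d = ped.parents[ind]
        si = idx[s] if s is not None else -1
        di = idx[d] if d is not None else -1
        for j in range(i):
            v = 0.0
            if si >= 0:
                v += 0.5 * K[si, j]
            if di >= 0:
                v += 0.5 * K[di, j]
            K[i, j] = K[j, i] = v
        fs = K[si, di] if (si >= 0 and di >= 0) else 0.0
        K[i, i] = 0.5 * (1.0 + fs)
    df = pd.DataFrame(K, index=order, columns=order)
    if individuals is not None:
        df = df.loc[list(individuals), list(individuals)]
    return df


def coancestry(ped: Pedigree, i, j) -> float:
    """Coancestry f_ij of two individuals (tabular method)."""
    for ind in (i, j):
        if ind not in ped:
            raise KeyError(f"unknown individual {ind!r}")
    return float(kinship_matrix(ped).loc[i, j])


def _contributions(ped: Pedigree, group: Sequence, cut: set) -> dict:
    """Expected genetic contribution of every ancestor to the pooled group
    gene pool, with gene flow through ``cut`` ancestors blocked above them."""
    contrib = {ind: 0.0 for ind in ped.order}
    share = 1.0 / len(group)
    for g in group:
        contrib[g] += share
    for ind in reversed(ped.order):
        c = contrib[ind]
        if c == 0.0 or ind in cut:
            continue
        s, d = ped.parents[ind]
        if s is not None:
            contrib[s] += 0.5 * c
        if d is not None:
            contrib[d] += 0.5 * c
    return contrib


def ancestors_explaining(
    ped: Pedigree, group: Sequence, threshold: float = 0.5
) -> dict:
    """Smallest greedy ancestor set explaining ``threshold`` of the group
    gene pool (marginal-contribution selection, ties broken by id).

    Returns the ordered selection with marginal and cumulative
    contributions, and ``count`` = selection size when the cumulative
    contribution first reaches the threshold.
    """
    if not group:
        raise ValueError("reference group must be non-empty")
    for g in group:
        if g not in ped:
            raise KeyError(f"unknown individual {g!r}")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    selected = []
    cut: set = set()
    cumulative = 0.0
    rows = []
    candidates = set(ped.order) - set(group)
    while cumulative < threshold - 1e-12:
        contrib = _contributions(ped, group, cut)
        best = None
        for a in sorted(candidates - cut):
            c = contrib.get(a, 0.0)
            if best is None or c > best[1] + 1e-15:
                best = (a, c)
        if best is None or best[1] <= 1e-12:
            break  # gene pool not fully explainable by non-group ancestors
        a, marg = best
        selected.append(a)
        cut.add(a)
        cumulative += marg
        rows.append({"ancestor": a, "marginal": marg, "cumulative": cumulative})
    return {
        "selection": rows,
        "count": len(rows) if cumulative >= threshold - 1e-12 else None,
        "explained": cumulative,
        "threshold": threshold,
    }


def common_ancestors(ped: Pedigree, group: Sequence, max_generations: int = 4) -> set:
    """Ancestors within ``max_generations`` shared by at least two group
    members (parents are generation 1)."""
    if len(group) < 2:
        raise ValueError("need a group of at least 2 individuals")
    seen: dict = {}
    for g in group:
        for a in ped.ancestors(g, max_generations):
            seen[a] = seen.get(a, 0) + 1
    return {a for a, k in seen.items() if k >= 2}


def metrics_report(
    ped: Pedigree,
    cases: Iterable,
    foals_per_dam: Optional[Mapping] = None,
    dam_ages: Optional[Mapping] = None,
) -> pd.DataFrame:
    """Per-case characterisation table: F%, dam's F%, foals per dam, dam
    age at foaling, and the case's mean coancestry with the other cases
    (percentages to 2 decimals)."""
    cases = list(cases)
    F = inbreeding(ped)
    K = kinship_matrix(ped)
    rows = []
    for ind in cases:
        dam = ped.parents[ind][1]
        others = [c for c in cases if c != ind]
        mean_f = float(np.mean([K.loc[ind, o] for o in others])) if others else np.nan
        rows.append(
            {
                "id": ind,
                "born": ped.birth_dates.get(ind, ""),
                "F_pct": round(100 * F[ind], 2),
                "F_dam_pct": round(100 * F[dam], 2) if dam is not None else None,
                "foals_per_dam": (foals_per_dam or {}).get(ind),
                "dam_age": (dam_ages or {}).get(ind),
                "mean_fij_pct": round(100 * mean_f, 2) if others else None,
            }
        )
    return pd.DataFrame(rows)
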