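"""Hartigan & Hartigan's dip test of unimodality.

The dip statistic measures how far an empirical distribution function is
from the nearest unimodal distribution function (in sup norm).  It is the
region statistic used, alongside HET% and mean LRR, to recognise the
trimodal B-allele-frequency pattern of a trisomic region on a genotyping
array: for two chromosomal copies the BAF values kept by the HET window
form a single central mode, while three copies split them into modes near
1/3 and 2/3, inflating the dip.

P-values are obtained by Monte Carlo against the uniform null (the least
favourable unimodal distribution), with an add-one correction so that
``p = (1 + #{null dips >= observed}) / (n_null + 1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from ._dipcore import dip_sorted, null_dips

__all__ = ["DipResult", "dip_statistic", "dip_pvalue", "null_dip_distribution"]

_NULL_CACHE: dict = {}
_NULL_CACHE_MAX = 32


@dataclass(frozen=True)
class DipResult:
    """Dip statistic and Monte-Carlo p-value for one sample."""

    dip: float
    p_value: float
    n: int
    method: str = "monte_carlo"
    n_null: int = 10_000
    seed: Optional[int] = None
    warnings: tuple = field(default_factory=tuple)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["warnings"] = list(self.warnings)
        return d


def _clean(values) -> np.ndarray:
    x = np.asarray(values, dtype=np.float64).ravel()
    return x[np.isfinite(x)]


def dip_statistic(values) -> float:
    """Dip statistic of a sample.

    Parameters
    ----------
    values : array-like
        Observations; non-finite entries are dropped.

    Returns
    -------
    float
        ``min_G sup_x |F_n(x) - G(x)|`` over unimodal distribution
        functions G, in ``[1/(2n), 0.25]`` for samples with at least two
        distinct values (0 for degenerate samples).

    Raises
    ------
    ValueError
        If fewer than two finite observations remain.
    """
    x = _clean(values)
    if x.size < 2:
        raise ValueError(
            f"dip statistic undefined for n={x.size}; need at least 2 finite values"
        )
    return float(dip_sorted(np.sort(x)))


def null_dip_distribution(n: int, n_null: int, seed) -> np.ndarray:
    """Sorted dips of ``n_null`` uniform(0,1) samples of size ``n``.

    This is the Monte-Carlo null used by :func:`dip_pvalue`; it is exposed
    (and cached) so that calibration studies can share one null set.
    """
    key = (int(n), int(n_null), int(seed) if seed is not None else None)
    hit = _NULL_CACHE.get(key)
    if hit is not None:
        return hit
    rng = np.random.default_rng(seed)
    draws = rng.random((int(n_null), int(n)))
    dips = np.sort(null_dips(draws))
    if len(_NULL_CACHE) >= _NULL_CACHE_MAX:
        _NULL_CACHE.pop(next(iter(_NULL_CACHE)))
    _NULL_CACHE[key] = dips
    return dips


def dip_pvalue(values, n_null: int = 10_000, seed=None) -> DipResult:
    """Dip test with a Monte-Carlo uniform-null p-value.

    Parameters
    ----------
    values : array-like
        Observations; non-finite entries are dropped.
    n_null : int
        Number of uniform null samples (>= 100).
    seed : int or None
        Seed for the null draws; fixing it makes the result deterministic.

    Returns
    -------
    DipResult
    """
    if n_null < 100:
        raise ValueError(f"n_null={n_null} too small; need >= 100")
    x = _clean(values)
    warns = []
    n = int(x.size)
    if n < 2 or np.all(x == x[0]):
        warns.append(
            "degenerate sample (fewer than 2 distinct values); p reported as 1"
        )
        warnings.warn(warns[-1], stacklevel=2)
        return DipResult(0.0, 1.0, n, n_null=n_null, seed=seed, warnings=tuple(warns))
    if n < 4:
        warns.append("n < 4: dip test has no power; p reported as 1")
        warnings.warn(warns[-1], stacklevel=2)
        d = float(dip_sorted(np.sort(x)))
        return DipResult(d, 1.0, n, n_null=n_null, seed=seed, warnings=tuple(warns))
    d = float(dip_sorted(np.sort(x)))
    null = null_dip_distribution(n, n_null, seed)
    n_ge = int(null.size - np.searchsorted(null, d, side="left"))
    p = (1.0 + n_ge) / (n_null + 1.0)
    return DipResult(d, float(p), n, n_null=n_null, seed=seed, warnings=tuple(warns))
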