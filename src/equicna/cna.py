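"""SNP-array copy-number analysis of the sex chromosomes.

Second, confirmatory tier of the screen.  Markers are restricted to three
autosomal controls (ECA5, ECA15, ECA25), the pseudoautosomal region (PAR:
first 1.86 Mb of ECAX, shared with ECAY), the X-specific remainder of ECAX
(NONPAR) and ECAY.  Per region three statistics are computed:

HET%      percentage of markers with BAF strictly between 0.25 and 0.75;
          ~30% for two copies, ~0 for one copy, elevated for three (both
          heterozygous classes AB B and A BB fall inside the window);
mean LRR  ~0 for two copies, ~-0.45 for one, ~+0.13 for three (array
          response to a gain is strongly compressed);
dip p     Hartigan dip test on the windowed BAF values; two copies give a
          single central mode (p near 1), three copies give modes near 1/3
          and 2/3 (p near 0).

A 65,XXY male shows diploid-like autosomes and NONPAR (two X), trisomic
PAR (two X + one Y) and a single Y — the signature the classifier keys on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .io import read_final_report, write_final_report  # noqa: F401  (module surface)
from .strscreen import SexPanelResult

logger = logging.getLogger("equicna")

__all__ = [
    "RegionPartition",
    "RegionStats",
    "KaryotypeCall",
    "ClassifierThresholds",
    "read_final_report",
    "partition_regions",
    "region_stats",
    "classify_karyotype",
    "compare_tissues",
    "screen_parents",
    "stats_table",
]

AUTOSOMAL_CONTROLS = ("ECA5", "ECA15", "ECA25")
SEX_REGIONS = ("PAR", "NONPAR", "Y")
ALL_REGIONS = AUTOSOMAL_CONTROLS + SEX_REGIONS


@dataclass(frozen=True)
class RegionPartition:
    """Genomic intervals defining the analysis regions.

    The PAR boundary is 1-based inclusive: an ECAX position equal to
    ``par_boundary_bp`` belongs to PAR ("within the first 1.86 Mb").
    """

    par_boundary_bp: int = 1_860_000
    x_length_bp: int = 128_210_000
    autosomes: tuple = ("5", "15", "25")

    def assign(self, chrom: np.ndarray, position: np.ndarray) -> np.ndarray:
        region = np.full(chrom.shape, "", dtype=object)
        for a in self.autosomes:
            region[chrom == a] = f"ECA{a}"
        on_x = chrom == "X"
        region[on_x & (position <= self.par_boundary_bp)] = "PAR"
        region[
            on_x & (position > self.par_boundary_bp) & (position <= self.x_length_bp)
        ] = "NONPAR"
        region[chrom == "Y"] = "Y"
        return region


@dataclass(frozen=True)
class RegionStats:
    """The statistic triple for one region of one sample/tissue."""

    region: str
    n_markers: int
    het_pct: Optional[float]
    mean_lrr: Optional[float]
    dip_p: Optional[float]
    insufficient: bool
    warnings: tuple = field(default_factory=tuple)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["warnings"] = list(self.warnings)
        return d


@dataclass(frozen=True)
class KaryotypeCall:
    """Copy-number calls per region plus the final karyotype label."""

    sample_id: str
    tissue: str
    x_nonpar_copies: Optional[int]
    par_copies: Optional[int]
    y_present: bool
    y_copy_warning: bool
    label: str
    warnings: tuple
    evidence: Mapping[str, RegionStats]

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "tissue": self.tissue,
            "x_nonpar_copies": self.x_nonpar_copies,
            "par_copies": self.par_copies,
            "y_present": self.y_present,
            "y_copy_warning": self.y_copy_warning,
            "label": self.label,
            "warnings": list(self.warnings),
            "evidence": {r: s.to_dict() for r, s in self.evidence.items()},
        }


def partition_regions(
    records: pd.DataFrame, partition: Optional[RegionPartition] = None
) -> dict:
    """Split SNP records into the analysis regions.

    Every ECAX record lands in exactly one of PAR/NONPAR; records on other
    chromosomes than the controls and the sex pair are dropped (counted in
    the log).
    """
    partition = partition or RegionPartition()
    region = partition.assign(
        records["chrom"].to_numpy(dtype=object), records["position"].to_numpy()
    )
    dropped = int((region == "").sum())
    if dropped:
        logger.info("partition_regions: dropped %d records outside analysis regions", dropped)
    out = {}
    for name in ALL_REGIONS:
        out[name] = records[region == name]
    return out


def _grid_null_size(n: int, ratio: float) -> int:
    """Round a null sample size onto a geometric grid so Monte-Carlo nulls
    can be shared across regions of similar size."""
    import math

    if n < 8:
        return n
    k = round(math.log(n / 8.0) / math.log(ratio))
    return max(8, int(round(8.0 * ratio**k)))


def _dip_p_gridded(windowed: np.ndarray, n_null: int, seed, grid_ratio: float):
    """Dip p-value against a shared null of similar size.

    The null dips are drawn at the nearest grid size and compared on the
    sqrt(n)-scaled statistic (the dip's sampling scale), so one null set
    serves all regions within one grid step; with ``grid_ratio`` <= 1 the
    exact-size null is used.
    """
    from .dip import null_dip_distribution
    from ._dipcore import dip_sorted

    n = windowed.size
    d = float(dip_sorted(np.sort(windowed)))
    if grid_ratio is None or grid_ratio <= 1.0:
        ng = n
    else:
        ng = _grid_null_size(n, grid_ratio)
    null = null_dip_distribution(ng, n_null, seed)
    scaled = d * np.sqrt(n / ng)
    n_ge = int(null.size - np.searchsorted(null, scaled, side="left"))
    return (1.0 + n_ge) / (n_null + 1.0)


def region_stats(
    records: pd.DataFrame,
    region: str = "",
    min_markers: int = 50,
    dip_n_null: int = 2000,
    dip_seed: Optional[int] = 0,
    window: tuple = (0.25, 0.75),
    dip_null_grid_ratio: float = 1.05,
) -> RegionStats:
    """HET%, mean LRR and windowed-BAF dip p-value for one region.

    HET counts markers with BAF strictly inside ``window`` among markers
    with a non-missing BAF; the dip test runs on those windowed values.
    When no usable BAF values fall in the window the dip is undefined and
    p is reported as 1 with a warning.  ``dip_null_grid_ratio`` controls
    null sharing across similar sample sizes (set <= 1 for exact-size
    nulls).
    """
    name = region or (records["region"].iloc[0] if "region" in records and len(records) else "")
    baf = records["baf"].to_numpy(dtype=float)
    lrr = records["lrr"].to_numpy(dtype=float)
    usable = np.isfinite(baf)
    n_usable = int(usable.sum())
    warns = []
    insufficient = n_usable < min_markers
    if insufficient:
        warns.append(f"only {n_usable} usable markers (<{min_markers})")
    if n_usable == 0:
        return RegionStats(name, 0, None, None, None, True, tuple(warns))
    lo, hi = window
    windowed = baf[usable & (baf > lo) & (baf < hi)]
    het_pct = 100.0 * windowed.size / n_usable
    mean_lrr = float(np.nanmean(lrr)) if np.isfinite(lrr).any() else None
    if windowed.size < 4 or np.all(windowed == windowed[0]):
        warns.append("dip test undefined on <4 distinct windowed BAF values; p set to 1")
        dip_p = 1.0
    else:
        dip_p = _dip_p_gridded(windowed, dip_n_null, dip_seed, dip_null_grid_ratio)
    return RegionStats(name, n_usable, het_pct, mean_lrr, dip_p, insufficient, tuple(warns))


@dataclass(frozen=True)
class ClassifierThresholds:
    """Numeric cut-offs behind the qualitative published patterns.

    Diploid regions sit near HET ~30%, LRR ~0, dip p ~1; a missing copy
    collapses HET and pulls LRR toward -0.45; a gained PAR copy lifts HET
    well above the autosomal level, lifts LRR slightly, and makes the
    windowed BAF bimodal.  The PAR trisomy rule is *relative* to the
    autosomal controls because a diploid sample's absolute statistics move
    with array quality.
    """

    disomic_het_min: float = 15.0
    disomic_lrr_abs: float = 0.15
    disomic_dip_min: float = 0.5
    monosomic_het_max: float = 5.0
    monosomic_lrr_max: float = -0.2
    trisomic_dip_max: float = 0.45
    trisomic_lrr_min: float = 0.08
    par_het_margin: float = 5.0
    par_lrr_margin: float = 0.05
    # HET elevation that is trisomic evidence on its own: with few PAR
    # markers the dip loses power when the 1/3 and 2/3 clusters are
    # unbalanced, but a HET% this far above the diploid controls cannot
    # come from two copies
    par_het_strong: float = 15.0
    y_het_max: float = 10.0
    y_lrr_min: float = -0.6
    y_two_copy_lrr: float = -0.10


def _nonpar_copies(s: RegionStats, t: ClassifierThresholds) -> Optional[int]:
    if s.het_pct is None or s.mean_lrr is None:
        return None
    if s.het_pct < t.monosomic_het_max and s.mean_lrr <= t.monosomic_lrr_max:
        return 1
    if (
        s.het_pct >= t.disomic_het_min
        and s.dip_p is not None
        and s.dip_p <= t.trisomic_dip_max
        and s.mean_lrr >= t.trisomic_lrr_min
    ):
        return 3
    # trisomy excluded above, so disomy needs only normal heterozygosity
    # and a diploid-level LRR
    if s.het_pct >= t.disomic_het_min and abs(s.mean_lrr) <= t.disomic_lrr_abs:
        return 2
    return None


def _par_copies(
    s: RegionStats, auto_het: float, auto_lrr: float, t: ClassifierThresholds
) -> Optional[int]:
    if s.het_pct is None or s.mean_lrr is None:
        return None
    if s.het_pct < t.monosomic_het_max and s.mean_lrr <= t.monosomic_lrr_max:
        return 1
    # trisomy = raised DNA abundance plus at least one strong zygosity
    # signal: moderate HET elevation confirmed bimodal, overwhelming HET
    # elevation alone, or unambiguous bimodality alone (the dip loses
    # power when the 1/3 and 2/3 clusters are unbalanced and HET loses
    # contrast when the region's markers are poorly informative)
    het_margin = s.het_pct - auto_het
    dip = s.dip_p
    trisomy_evidence = (
        (het_margin >= t.par_het_margin and dip is not None and dip <= t.trisomic_dip_max)
        or het_margin >= t.par_het_strong
        or (dip is not None and dip <= 0.1 and het_margin >= -t.par_het_margin)
    )
    if s.mean_lrr >= auto_lrr + t.par_lrr_margin and trisomy_evidence:
        return 3
    if abs(s.mean_lrr - auto_lrr) <= t.disomic_lrr_abs:
        return 2
    return None


def classify_karyotype(
    stats: Mapping[str, RegionStats],
    sex_panel: Optional[SexPanelResult] = None,
    thresholds: Optional[ClassifierThresholds] = None,
    sample_id: str = "",
    tissue: str = "",
) -> KaryotypeCall:
    """Karyotype call from the region statistic grid.

    Requires at least one usable autosomal control plus the PAR, NONPAR
    and Y statistics.  Y copy number is never called as two from LRR
    alone: an LRR high enough to suggest a second Y only raises
    ``y_copy_warning`` (confirmation needs an orthogonal method such as
    FISH).
    """
    t = thresholds or ClassifierThresholds()
    autos = [
        stats[r]
        for r in AUTOSOMAL_CONTROLS
        if r in stats and not stats[r].insufficient and stats[r].het_pct is not None
    ]
    if not autos:
        raise ValueError("no usable autosomal control region")
    for r in SEX_REGIONS:
        if r not in stats:
            raise ValueError(f"missing region statistics for {r}")
    if all(stats[r].n_markers == 0 for r in SEX_REGIONS):
        raise ValueError("all sex regions empty: no call possible")
    auto_het = float(np.mean([s.het_pct for s in autos]))
    auto_lrr = float(np.mean([s.mean_lrr for s in autos]))

    warns = []
    nonpar = _nonpar_copies(stats["NONPAR"], t)
    par = _par_copies(stats["PAR"], auto_het, auto_lrr, t)
    ys = stats["Y"]

    panel_y = bool(sex_panel.any_y) if sex_panel is not None else False
    array_y = (
        ys.het_pct is not None
        and ys.mean_lrr is not None
        and ys.het_pct < t.y_het_max
        and ys.mean_lrr >= t.y_lrr_min
    )
    y_present = panel_y or array_y
    y_copy_warning = bool(
        y_present and ys.mean_lrr is not None and ys.mean_lrr > t.y_two_copy_lrr
    )
    if y_copy_warning:
        warns.append(
            "ECAY mean LRR close to 0: a second Y copy cannot be excluded from "
            "array data alone"
        )

    label = "ambiguous"
    if nonpar == 2 and par == 3 and y_present:
        label = "65,XXY"
    elif nonpar == 2 and par == 2 and not y_present:
        label = "64,XX"
    elif nonpar == 1 and par == 2 and y_present:
        label = "64,XY"
    elif nonpar == 1 and par == 1 and not y_present:
        label = "63,X"
    elif nonpar == 2 and par == 3 and not y_present:
        label = "65,XXX?"
        warns.append("PAR gain without Y: possible 65,XXX; confirm cytogenetically")
    else:
        warns.append(
            f"region pattern unresolved (NONPAR={nonpar}, PAR={par}, Y={'+' if y_present else '-'})"
            "; possible mosaic or low-quality sample"
        )
    for r in SEX_REGIONS:
        if stats[r].insufficient:
            warns.append(f"{r}: marker count below threshold; interpret with caution")
    return KaryotypeCall(
        sample_id=sample_id or getattr(sex_panel, "individual_id", ""),
        tissue=tissue or getattr(sex_panel, "tissue", ""),
        x_nonpar_copies=nonpar,
        par_copies=par,
        y_present=y_present,
        y_copy_warning=y_copy_warning,
        label=label,
        warnings=tuple(warns),
        evidence=dict(stats),
    )


def compare_tissues(call_blood: KaryotypeCall, call_hair: KaryotypeCall) -> dict:
    """Blood/hair concordance: identical calls confirm a constitutional
    karyotype; discordance suggests blood chimerism (hair, of ectodermal
    origin, is taken as the constitutional tissue)."""
    if call_blood.sample_id != call_hair.sample_id:
        raise ValueError("tissue comparison requires the same sample")
    if call_blood.tissue == call_hair.tissue:
        raise ValueError("tissue comparison requires two different tissues")
    concordant = call_blood.label == call_hair.label
    return {
        "sample_id": call_blood.sample_id,
        "concordant": concordant,
        "verdict": (
            f"constitutional {call_blood.label} confirmed in "
            f"{call_blood.tissue} and {call_hair.tissue}"
            if concordant
            else "blood chimerism suspected; constitutional karyotype deferred to hair"
        ),
        "final_label": call_blood.label if concordant else call_hair.label,
    }


def screen_parents(father_call: KaryotypeCall, mother_call: KaryotypeCall) -> dict:
    """Inheritance verdict from the progenitors' array calls."""
    normal = father_call.label == "64,XY" and mother_call.label == "64,XX"
    if normal:
        verdict = "de novo"
    elif "ambiguous" in (father_call.label, mother_call.label):
        verdict = "unresolved"
    else:
        verdict = "possible inherited/parental abnormality"
    return {
        "father": father_call.label,
        "mother": mother_call.label,
        "verdict": verdict,
    }


def stats_table(stats_by_sample: Mapping[str, Mapping[str, RegionStats]]) -> pd.DataFrame:
    """Render region statistics as a publication-style table (2 decimals)."""
    rows = []
    for sample, stats in stats_by_sample.items():
        for stat_name in ("HET (%)", "LRR", "BAF dip test"):
            row = {"sample": sample, "statistic": stat_name}
            for region in ALL_REGIONS:
                s = stats.get(region)
                if s is None:
                    row[region] = None
                    continue
                val = {
                    "HET (%)": s.het_pct,
                    "LRR": s.mean_lrr,
                    "BAF dip test": s.dip_p,
                }[stat_name]
                row[region] = None if val is None else round(val, 2)
            rows.append(row)
    return pd.DataFrame(rows)
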