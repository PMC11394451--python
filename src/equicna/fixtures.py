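"""Worked-example data: the five published 65,XXY screening cases.

Five PRE (Pura Raza Español) colts flagged by STR parentage screening and
confirmed 65,XXY by SNP-array region statistics.  The sex-linked STR panel
results and the SNP region-statistic grid are bundled verbatim so the
screening logic can be exercised end to end without any confidential raw
data.
"""

from __future__ import annotations

from .cna import RegionStats
from .strscreen import ParentagePanelResult, SexPanelResult

__all__ = ["sex_panels", "parentage_panels", "region_stats_grid", "HORSES"]

HORSES = ("Horse 1", "Horse 2", "Horse 3", "Horse 4", "Horse 5")

# sex-linked STR panel: X-linked genotypes (fragment bp) and Y presence
_SEX_PANEL = {
    "Horse 1": {
        "TKY38": (105, 129), "UCDEQ502": (164,), "LEX003": (194, 210),
        "LEX026": (312, 314), "TKY270": (168,),
    },
    "Horse 2": {
        "TKY38": (129,), "UCDEQ502": (164, 174), "LEX003": (214, 216),
        "LEX026": (316,), "TKY270": (168, 170),
    },
    "Horse 3": {
        "TKY38": (111, 129), "UCDEQ502": (164,), "LEX003": (206, 210),
        "LEX026": (308,), "TKY270": (168, 172),
    },
    "Horse 4": {
        "TKY38": (107, 129), "UCDEQ502": (116, 174), "LEX003": (208, 210),
        "LEX026": (314,), "TKY270": (170, 172),
    },
    "Horse 5": {
        "TKY38": (105, 129), "UCDEQ502": (162, 164), "LEX003": (212, 214),
        "LEX026": (300, 314), "TKY270": (170, 172),
    },
}

# SNP region statistics: region -> (HET %, mean LRR, dip p)
_REGION_GRID = {
    "Horse 1": {
        "ECA5": (31.61, 0.04, 0.95), "ECA15": (31.78, 0.08, 0.99),
        "ECA25": (29.59, 0.04, 0.99), "PAR": (40.00, 0.14, 0.25),
        "NONPAR": (32.83, 0.03, 0.99), "Y": (0.00, -0.05, 1.0),
    },
    "Horse 2": {
        "ECA5": (24.95, 0.03, 1.0), "ECA15": (30.87, 0.06, 1.0),
        "ECA25": (26.92, -0.01, 0.89), "PAR": (63.89, 0.10, 0.04),
        "NONPAR": (26.47, 0.07, 0.93), "Y": (4.13, -0.22, 0.84),
    },
    "Horse 3": {
        "ECA5": (22.87, 0.02, 0.97), "ECA15": (25.19, 0.02, 0.99),
        "ECA25": (27.55, -0.03, 0.97), "PAR": (50.00, 0.13, 0.11),
        "NONPAR": (29.19, 0.04, 1.0), "Y": (3.25, -0.16, 0.92),
    },
    "Horse 4": {
        "ECA5": (31.87, 0.04, 0.96), "ECA15": (32.95, 0.06, 0.98),
        "ECA25": (29.99, 0.03, 1.0), "PAR": (58.33, 0.12, 0.0),
        "NONPAR": (28.63, 0.03, 1.0), "Y": (2.44, -0.38, 1.0),
    },
    "Horse 5": {
        "ECA5": (30.87, 0.02, 0.98), "ECA15": (29.87, 0.04, 0.94),
        "ECA25": (23.04, 0.01, 0.79), "PAR": (52.78, 0.12, 0.09),
        "NONPAR": (32.56, 0.03, 0.99), "Y": (2.44, -0.39, 1.0),
    },
}

# marker counts of the pruned array set, used as nominal region sizes for
# the pre-computed statistic grid (PAR/NONPAR split the 3431 ECAX markers)
_REGION_N = {"ECA5": 2891, "ECA15": 2692, "ECA25": 1107, "PAR": 50, "NONPAR": 3381, "Y": 172}


def sex_panels(tissue: str = "blood") -> dict:
    """The five sex-linked panel results (all Y markers amplified)."""
    out = {}
    for horse in HORSES:
        out[horse] = SexPanelResult(
            individual_id=horse,
            tissue=tissue,
            x_genotypes=dict(_SEX_PANEL[horse]),
            amex=True,
            amey=True,
            ecayh12=True,
            sry=True,
        )
    return out


def parentage_panels() -> dict:
    """First-tier parentage-panel view of the five cases.

    Only the screen-relevant content is reconstructed: the X-linked LEX003
    genotype (identical to the sex panel's) and the amelogenin calls; the
    autosomal genotypes of the cases were unremarkable two-allele calls.
    """
    out = {}
    for horse in HORSES:
        out[horse] = ParentagePanelResult(
            individual_id=horse,
            genotypes={"LEX3": tuple(_SEX_PANEL[horse]["LEX003"])},
            amex=True,
            amey=True,
        )
    return out


def region_stats_grid() -> dict:
    """The five cases' region statistics as RegionStats maps.

    These are pre-computed statistics (the raw genotypes are confidential),
    so they enter the classifier through its RegionStats interface rather
    than through the final-report reader.
    """
    out = {}
    for horse in HORSES:
        stats = {}
        for region, (het, lrr, dip) in _REGION_GRID[horse].items():
            stats[region] = RegionStats(
                region=region,
                n_markers=_REGION_N[region],
                het_pct=het,
                mean_lrr=lrr,
                dip_p=dip,
                insufficient=False,
            )
        out[horse] = stats
    return out
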