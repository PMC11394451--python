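"""STR-based screening for sex-chromosome copy-number aberrations.

First screening tier of the pipeline: every foal is parentage-tested with a
17-marker autosomal STR panel plus the sex-dimorphic amelogenin fragment
(AMEX/AMEY).  An individual is flagged as a CNA candidate when its genetic
sex contradicts the recorded phenotypic sex, when the single X-linked
marker of the panel (LEX003, historically written "LEX33") is heterozygous
in an animal that also amplifies Y markers (two X copies plus a Y), or when
any marker shows three or more alleles (chimerism signal).

Flagged animals are re-typed with a dedicated sex-linked panel: five
X-linked STRs (TKY38, UCDEQ502, LEX003, LEX026, TKY270), AMEX, and three
Y-linked fragments (AMEY, EcaYH12, SRY), whose joint pattern narrows the
candidate karyotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .io import format_flag, format_genotype, parse_flag, parse_genotype

__all__ = [
    "X_PANEL_MARKERS",
    "Y_PANEL_MARKERS",
    "MARKER_ALIASES",
    "ParentagePanelResult",
    "SexPanelResult",
    "ScreenFlag",
    "amelogenin_sex",
    "flag_candidate",
    "interpret_sex_panel",
    "count_het_x",
    "expected_false_negative_rate",
    "read_sex_panels_csv",
    "write_sex_panels_csv",
]

X_PANEL_MARKERS = ("TKY38", "UCDEQ502", "LEX003", "LEX026", "TKY270")
Y_PANEL_MARKERS = ("AMEY", "EcaYH12", "SRY")

# historical synonyms seen in lab reports
MARKER_ALIASES = {"LEX33": "LEX003", "LEX3": "LEX003"}


def canonical_marker(name: str) -> str:
    return MARKER_ALIASES.get(name, name)


@dataclass(frozen=True)
class ParentagePanelResult:
    """Parentage-test result for one individual: 17 autosomal-panel STR
    genotypes plus amelogenin presence calls."""

    individual_id: str
    genotypes: Mapping[str, tuple]  # marker -> tuple of allele lengths (bp)
    amex: bool
    amey: bool

    def __post_init__(self):
        for marker, alleles in self.genotypes.items():
            if any(a <= 0 for a in alleles):
                raise ValueError(f"{marker}: allele lengths must be positive")

    def allele_count(self, marker: str) -> int:
        if marker in self.genotypes:
            return len(set(self.genotypes[marker]))
        return len(set(self.genotypes[canonical_marker(marker)]))

    def multi_allelic_markers(self) -> list:
        return sorted(m for m in self.genotypes if self.allele_count(m) >= 3)

    def lex003(self) -> tuple:
        for name in ("LEX003", "LEX33", "LEX3"):
            if name in self.genotypes:
                return tuple(sorted(set(self.genotypes[name])))
        raise KeyError("panel does not include the X-linked marker LEX003")


@dataclass(frozen=True)
class SexPanelResult:
    """Dedicated sex-linked panel result for one individual and tissue."""

    individual_id: str
    tissue: str
    x_genotypes: Mapping[str, tuple]  # five X-linked STRs -> allele lengths
    amex: bool
    amey: bool
    ecayh12: bool
    sry: bool

    def __post_init__(self):
        for marker in X_PANEL_MARKERS:
            if marker not in self.x_genotypes:
                raise ValueError(f"sex panel is missing X-linked marker {marker}")
            n = len(set(self.x_genotypes[marker]))
            if n not in (1, 2):
                raise ValueError(
                    f"{marker}: X-linked genotype must carry 1 or 2 distinct alleles, got {n}"
                )

    @property
    def y_flags(self) -> dict:
        return {"AMEY": self.amey, "EcaYH12": self.ecayh12, "SRY": self.sry}

    @property
    def any_y(self) -> bool:
        return any(self.y_flags.values())

    @property
    def all_y(self) -> bool:
        return all(self.y_flags.values())


@dataclass(frozen=True)
class ScreenFlag:
    """Outcome of the first-tier screen for one individual."""

    individual_id: str
    flagged: bool
    reasons: tuple
    genetic_sex: str  # "male" | "female" | "undetermined"
    notes: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.flagged != bool(self.reasons):
            raise ValueError("flagged must hold exactly when reasons are present")


def amelogenin_sex(amex: bool, amey: bool) -> tuple[str, list]:
    """Genetic sex from the amelogenin presence pattern.

    (+,+) male; (+,-) female; (-,-) undetermined (amplification failure);
    (-,+) undetermined with a warning (AMEX dropout is not a valid pattern).
    """
    notes = []
    if amex and amey:
        return "male", notes
    if amex and not amey:
        return "female", notes
    if not amex and amey:
        notes.append("AMEY amplified without AMEX: probable dropout, sex undetermined")
        return "undetermined", notes
    notes.append("no amelogenin amplification; sex undetermined")
    return "undetermined", notes


def flag_candidate(
    panel: ParentagePanelResult,
    phenotypic_sex: Optional[str],
    lex003_genotype: Optional[Sequence] = None,
) -> ScreenFlag:
    """First-tier CNA flag from the parentage panel.

    Flags when genetic sex contradicts phenotypic sex, when LEX003 is
    heterozygous while Y markers amplify (two X copies plus Y), or when any
    marker shows three or more alleles.
    """
    if phenotypic_sex not in ("male", "female"):
        raise ValueError(f"phenotypic sex required ('male'/'female'), got {phenotypic_sex!r}")
    genetic_sex, notes = amelogenin_sex(panel.amex, panel.amey)
    reasons = []
    if genetic_sex != "undetermined" and genetic_sex != phenotypic_sex:
        reasons.append("sex_mismatch")
    lex = tuple(lex003_genotype) if lex003_genotype is not None else panel.lex003()
    if len(set(lex)) >= 2 and panel.amey:
        reasons.append("x_het_with_y")
    if panel.multi_allelic_markers():
        reasons.append("triallelic_marker")
        notes = list(notes) + [f"markers with >=3 alleles: {panel.multi_allelic_markers()}"]
    return ScreenFlag(
        individual_id=panel.individual_id,
        flagged=bool(reasons),
        reasons=tuple(reasons),
        genetic_sex=genetic_sex,
        notes=tuple(notes),
    )


def count_het_x(panel: SexPanelResult) -> int:
    """Number of the five X-linked STRs showing two distinct alleles."""
    return sum(1 for m in X_PANEL_MARKERS if len(set(panel.x_genotypes[m])) == 2)


def interpret_sex_panel(panel: SexPanelResult) -> dict:
    """Candidate karyotypes compatible with one sex-panel result.

    Returns a dict with 'candidates' (ranked list, most probable first),
    'rationale', 'het_x' and 'warnings'.  X heterozygosity demonstrates two
    distinct X copies; Y-marker amplification demonstrates at least one Y.
    A single-line explanation is ranked above mosaic/chimeric alternatives,
    which STRs alone cannot exclude.
    """
    warnings = []
    if panel.sry and not panel.amey:
        warnings.append("SRY positive but AMEY negative: contradictory Y flags")
    het = count_het_x(panel)
    y = panel.any_y
    if het >= 1 and y:
        candidates = ["65,XXY", "64,XX/64,XY chimera", "64,XY/65,XXY"]
        rationale = (
            f"{het} X-linked STR(s) heterozygous (two distinct X copies) with "
            "Y-marker amplification; a constitutional 65,XXY is the most "
            "probable arrangement, but mosaic and chimeric forms cannot be "
            "excluded by STRs alone"
        )
    elif het == 0 and y:
        candidates = ["64,XY", "65,XXY (homozygous X, undetectable)"]
        rationale = (
            "no X heterozygosity with Y amplification: compatible with a "
            "normal male; an XXY carrying two identical X haplotypes would "
            "look the same"
        )
    elif het >= 1 and not y:
        candidates = ["64,XX"]
        rationale = "X heterozygosity without Y markers: two X copies, no Y"
    else:
        candidates = ["64,XX (homozygous X)", "63,X"]
        rationale = (
            "no X heterozygosity and no Y markers: a homozygous 64,XX and an "
            "X monosomy cannot be distinguished"
        )
    return {
        "individual_id": panel.individual_id,
        "tissue": panel.tissue,
        "candidates": candidates,
        "most_probable": candidates[0],
        "het_x": het,
        "rationale": rationale,
        "warnings": warnings,
    }


def expected_false_negative_rate(het: float) -> float:
    """Expected miss rate of the one-X-marker screen in XXY individuals.

    The parentage panel carries a single X-linked marker; an XXY animal is
    only flagged when that marker is heterozygous, so a fraction ``1 - het``
    (its homozygosity) presents like a normal male and escapes the screen.
    With LEX003 heterozygosity ~0.75 this is ~25%.
    """
    if not 0.0 <= het <= 1.0:
        raise ValueError("heterozygosity must lie in [0, 1]")
    return 1.0 - het


# ---------------------------------------------------------------------------
# CSV interfaces (Table-style rendering)

def write_sex_panels_csv(panels: Sequence[SexPanelResult], path_or_buf) -> None:
    rows = []
    for p in panels:
        row = {"individual": p.individual_id, "tissue": p.tissue}
        for m in X_PANEL_MARKERS:
            row[m] = format_genotype(p.x_genotypes[m])
        row["AMEX"] = format_flag(p.amex)
        for m in Y_PANEL_MARKERS:
            row[m] = format_flag(p.y_flags[m])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path_or_buf, index=False)


def read_sex_panels_csv(source) -> list:
    df = pd.read_csv(source, dtype=str)
    panels = []
    for _, row in df.iterrows():
        panels.append(
            SexPanelResult(
                individual_id=row["individual"],
                tissue=row.get("tissue", "blood"),
                x_genotypes={m: parse_genotype(row[m]) for m in X_PANEL_MARKERS},
                amex=parse_flag(row["AMEX"]),
                amey=parse_flag(row["AMEY"]),
                ecayh12=parse_flag(row["EcaYH12"]),
                sry=parse_flag(row["SRY"]),
            )
        )
    return panels
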