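"""Synthetic SNP-array and STR data for sex-chromosome CNA screening.

Real screening data for this problem are confidential studbook records, so
the pipeline is exercised on simulated cohorts.  The generator emulates a
medium-density equine genotyping array restricted to the chromosomes the
screen uses — the autosomal controls ECA5/ECA15/ECA25 and the sex pair —
with per-chromosome marker counts matching the screen's pruned marker set
(2891 / 2692 / 1107 for the autosomes, 3431 on ECAX of which the first
1.86 Mb are pseudoautosomal, 172 on ECAY).

Signal model per marker, per cell line: the individual draws alleles at
the line's copy number from the marker's population B-allele frequency;
the noiseless BAF is the allelic ratio (k of CN copies are "B"), mixed
across cell lines by cell fraction for mosaics/chimeras, plus Gaussian
noise clipped to [0, 1].  LRR is Gaussian around a copy-number-conditioned
mean; the trisomic mean defaults to +0.13 rather than log2(3/2) because
array LRR response is compressed.  Y-linked markers in Y-less genomes
mostly fail (missing calls) and otherwise return uniform noise.

STR panels are generated from the same copy numbers, so e.g. two X copies
can produce heterozygous X-linked STR calls while one copy cannot, and a
blood chimera can show three-allele calls in blood but not hair.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .karyotype import KARYOTYPES, KaryotypeSpec
from .strscreen import ParentagePanelResult, SexPanelResult, X_PANEL_MARKERS

__all__ = [
    "SimConfig",
    "STRLocusModel",
    "make_marker_map",
    "simulate_individual",
    "simulate_cohort",
    "simulate_pedigree",
    "SimulatedIndividual",
    "TissueData",
    "default_sex_panel_loci",
    "default_parentage_loci",
]

# approximate chromosome lengths (bp); only relative scale matters
CHROM_LENGTH_BP = {
    "5": 99_680_000,
    "15": 91_570_000,
    "25": 39_540_000,
    "X": 128_210_000,
    "Y": 9_500_000,
}

DEFAULT_MARKER_COUNTS = {"5": 2891, "15": 2692, "25": 1107, "X": 3431, "Y": 172}


@dataclass(frozen=True)
class STRLocusModel:
    """Population model of one STR locus (fragment lengths and frequencies)."""

    name: str
    chromosome_class: str  # autosomal | x_linked | y_linked | sex_dimorphic
    alleles: tuple
    frequencies: tuple

    def __post_init__(self):
        if len(self.alleles) != len(self.frequencies):
            raise ValueError(f"{self.name}: alleles and frequencies differ in length")
        if abs(sum(self.frequencies) - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: frequencies must sum to 1")
        if any(f < 0 for f in self.frequencies):
            raise ValueError(f"{self.name}: negative frequency")

    @property
    def heterozygosity(self) -> float:
        return 1.0 - sum(f * f for f in self.frequencies)

    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.frequencies)


def default_sex_panel_loci() -> dict:
    """X-linked loci of the dedicated sex panel.

    LEX003 uses four equifrequent alleles so its heterozygosity is exactly
    0.75, the rate reported for the breed and the quantity driving the
    one-marker screen's expected false-negative rate.
    """
    return {
        "TKY38": STRLocusModel("TKY38", "x_linked", (105, 107, 111, 129), (0.3, 0.2, 0.2, 0.3)),
        "UCDEQ502": STRLocusModel(
            "UCDEQ502", "x_linked", (116, 162, 164, 174), (0.05, 0.25, 0.45, 0.25)
        ),
        "LEX003": STRLocusModel(
            "LEX003", "x_linked", (194, 206, 210, 214), (0.25, 0.25, 0.25, 0.25)
        ),
        "LEX026": STRLocusModel(
            "LEX026", "x_linked", (300, 308, 312, 314, 316), (0.15, 0.2, 0.25, 0.25, 0.15)
        ),
        "TKY270": STRLocusModel("TKY270", "x_linked", (168, 170, 172), (0.35, 0.35, 0.3)),
    }


def default_parentage_loci() -> dict:
    """The 17-marker parentage panel; LEX3 (= LEX003) is its only X-linked
    locus, the rest are autosomal with generic 4-6 allele models."""
    autosomal = [
        ("VHL20", (87, 89, 93, 95, 97, 101)),
        ("HTG4", (127, 129, 131, 133)),
        ("AHT4", (144, 146, 148, 150, 152, 158)),
        ("HMS7", (167, 169, 171, 173, 175)),
        ("HTG6", (84, 86, 88, 90)),
        ("AHT5", (126, 128, 130, 132, 134)),
        ("HMS6", (157, 159, 161, 163)),
        ("ASB23", (176, 180, 182, 184, 186)),
        ("ASB2", (216, 218, 220, 222, 224, 226)),
        ("HTG10", (83, 87, 89, 91, 93)),
        ("HTG7", (118, 120, 122, 124)),
        ("HMS3", (146, 150, 152, 154, 156)),
        ("HMS2", (215, 217, 219, 221, 223)),
        ("ASB17", (95, 97, 99, 103, 105, 107)),
        ("HMS1", (166, 168, 170, 172)),
        ("CA425", (224, 226, 228, 230, 232)),
    ]
    loci = {}
    for name, alleles in autosomal:
        k = len(alleles)
        freqs = tuple(np.full(k, 1.0 / k))
        loci[name] = STRLocusModel(name, "autosomal", alleles, freqs)
    loci["LEX3"] = default_sex_panel_loci()["LEX003"]
    loci["LEX3"] = replace(loci["LEX3"], name="LEX3")
    return loci


@dataclass(frozen=True)
class SimConfig:
    """Array and noise model configuration.

    ``lrr_mean_by_cn`` maps copy number to mean LRR; defaults reflect array
    behaviour (0 copies: failed/background ~ -2; 1 copy ~ -0.45; 2 copies
    0; 3 copies ~ +0.13, compressed well below log2(3/2)).
    ``allele_freq_beta`` shapes the symmetric population B-allele frequency
    distribution on ``allele_freq_bounds``.
    """

    marker_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_COUNTS)
    )
    par_boundary_bp: int = 1_860_000
    x_length_bp: int = 128_210_000
    baf_noise_sd: float = 0.03
    lrr_noise_sd: float = 0.15
    lrr_mean_by_cn: Mapping[int, float] = field(
        default_factory=lambda: {0: -2.0, 1: -0.45, 2: 0.0, 3: 0.13}
    )
    allele_freq_beta: tuple = (0.7, 0.7)
    allele_freq_bounds: tuple = (0.05, 0.95)
    # PAR SNPs on genotyping arrays are ascertained for informativeness
    # (the region matters for sex-chromosome QC); the defaults give a
    # PAR/autosome heterozygosity ratio ~1.9, the level seen in published
    # trisomic worked examples
    par_allele_freq_beta: tuple = (1.2, 1.2)
    par_allele_freq_bounds: tuple = (0.10, 0.90)
    min_par_markers: int = 50
    y_missing_rate: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.baf_noise_sd <= 0 or self.lrr_noise_sd <= 0:
            raise ValueError("noise standard deviations must be positive")
        cns = sorted(self.lrr_mean_by_cn)
        means = [self.lrr_mean_by_cn[c] for c in cns]
        if any(b <= a for a, b in zip(means, means[1:])):
            raise ValueError("lrr_mean_by_cn must be strictly increasing in copy number")
        for chrom, count in self.marker_counts.items():
            if count <= 0:
                raise ValueError(f"marker count for {chrom} must be positive")

    def lrr_mean(self, cn: int) -> float:
        if cn in self.lrr_mean_by_cn:
            return self.lrr_mean_by_cn[cn]
        # extrapolate gently above the table (rare; e.g. 4 copies)
        top = max(self.lrr_mean_by_cn)
        return self.lrr_mean_by_cn[top] + 0.08 * (cn - top)

    def mean_heterozygosity(self) -> float:
        """E[2p(1-p)] of the population B-allele frequency distribution."""
        a, b = self.allele_freq_beta
        lo, hi = self.allele_freq_bounds
        mq = a / (a + b)
        vq = a * b / ((a + b) ** 2 * (a + b + 1.0))
        mp = lo + (hi - lo) * mq
        vp = (hi - lo) ** 2 * vq
        return 2.0 * (mp - (vp + mp * mp))


def _child_rng(master_seed: int, *key: str) -> np.random.Generator:
    """Deterministic per-(individual, layer, tissue) generator via a stable hash."""
    digest = hashlib.blake2s("|".join(str(k) for k in key).encode()).digest()
    words = tuple(int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4))
    return np.random.default_rng(np.random.SeedSequence(int(master_seed), spawn_key=words))


def make_marker_map(config: SimConfig) -> pd.DataFrame:
    """Marker skeleton: name, chrom, position, region, pop_b_freq.

    Positions are unique, sorted within chromosome.  ECAX markers split
    into the pseudoautosomal region (PAR, positions <= par_boundary_bp,
    at least ``min_par_markers`` of them) and the X-specific remainder.
    Population B-allele frequencies are drawn once per marker.
    """
    rng = _child_rng(config.seed, "marker_map")
    frames = []
    for chrom in sorted(config.marker_counts):
        count = int(config.marker_counts[chrom])
        length = CHROM_LENGTH_BP.get(chrom, 50_000_000)
        if chrom == "X":
            length = config.x_length_bp
            frac = config.par_boundary_bp / config.x_length_bp
            n_par = max(config.min_par_markers, int(round(count * frac)))
            if n_par >= count:
                raise ValueError("X marker count too small to satisfy min_par_markers")
            pos_par = _unique_positions(rng, n_par, 1, config.par_boundary_bp)
            pos_rest = _unique_positions(
                rng, count - n_par, config.par_boundary_bp + 1, length
            )
            pos = np.concatenate([pos_par, pos_rest])
            region = np.where(pos <= config.par_boundary_bp, "PAR", "NONPAR")
        else:
            pos = _unique_positions(rng, count, 1, length)
            region = np.repeat("Y" if chrom == "Y" else f"ECA{chrom}", count)
        a, b = config.allele_freq_beta
        lo, hi = config.allele_freq_bounds
        pfreq = lo + (hi - lo) * rng.beta(a, b, size=count)
        if chrom == "X":
            pa, pb = config.par_allele_freq_beta
            plo, phi = config.par_allele_freq_bounds
            is_par = region == "PAR"
            pfreq[is_par] = plo + (phi - plo) * rng.beta(pa, pb, size=int(is_par.sum()))
        frames.append(
            pd.DataFrame(
                {
                    "snp_name": [f"ECA{chrom}_{p}" for p in pos],
                    "chrom": chrom,
                    "position": pos,
                    "region": region,
                    "pop_b_freq": pfreq,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _unique_positions(rng, n, lo, hi) -> np.ndarray:
    if hi - lo + 1 < n:
        raise ValueError("interval too small for unique positions")
    pos = np.unique(rng.integers(lo, hi + 1, size=int(n * 1.2) + 8))
    while pos.size < n:
        extra = rng.integers(lo, hi + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=n, replace=False))


@dataclass
class TissueData:
    records: Optional[pd.DataFrame]
    sex_panel: SexPanelResult
    parentage_panel: ParentagePanelResult


@dataclass
class SimulatedIndividual:
    individual_id: str
    spec: KaryotypeSpec
    phenotypic_sex: str
    tissues: dict  # tissue -> TissueData


def _marker_cn(marker_map: pd.DataFrame, x: int, y: int) -> np.ndarray:
    region = marker_map["region"].to_numpy()
    cn = np.full(len(marker_map), 2, dtype=np.int64)
    cn[region == "PAR"] = x + y
    cn[region == "NONPAR"] = x
    cn[region == "Y"] = y
    return cn


def _line_b_counts(alleles: np.ndarray, cn: np.ndarray, base_cn: np.ndarray, shared: bool):
    """B-allele count per marker for one cell line.

    ``alleles`` is (n_markers, 4) Bernoulli draws of the zygote.  For a
    shared-zygote (mosaic) line whose copy number exceeds the base line's,
    the gained copy duplicates the first allele (mitotic nondisjunction);
    losses drop the last allele.
    """
    n = alleles.shape[0]
    k = np.zeros(n, dtype=np.int64)
    cap = np.minimum(cn, alleles.shape[1])
    for c in range(1, alleles.shape[1] + 1):
        k[cap >= c] += alleles[cap >= c, c - 1]
    if shared:
        gained = cn > base_cn
        if np.any(gained):
            k[gained] += alleles[gained, 0] * (cn - base_cn)[gained]
            base_cap = np.minimum(base_cn, alleles.shape[1])
            # replace the independent extra columns counted above by duplicates
            for c in range(1, alleles.shape[1] + 1):
                over = gained & (base_cap < c) & (cap >= c)
                k[over] -= alleles[over, c - 1]
    return k


def simulate_individual(
    spec: KaryotypeSpec,
    config: SimConfig,
    tissues: Sequence[str] = ("blood", "hair"),
    individual_id: str = "sim1",
    marker_map: Optional[pd.DataFrame] = None,
    include_snp: bool = True,
    sex_loci: Optional[dict] = None,
    parentage_loci: Optional[dict] = None,
) -> SimulatedIndividual:
    """Generate per-tissue SNP records and STR panels for one individual.

    Non-chimeric individuals carry the same genotype in every tissue with
    independent technical noise; chimeric lines mix only in blood (the
    second line of a blood chimera is confined to the haematopoietic
    compartment), so blood and hair disagree.
    """
    if not tissues:
        raise ValueError("at least one tissue required")
    if marker_map is None and include_snp:
        marker_map = make_marker_map(config)
    sex_loci = sex_loci or default_sex_panel_loci()
    parentage_loci = parentage_loci or default_parentage_loci()

    geno_rng = _child_rng(config.seed, individual_id, "genotype")
    geno2_rng = _child_rng(config.seed, individual_id, "genotype2")

    phenotypic_sex = "male" if spec.y_copies >= 1 else "female"

    if include_snp:
        pfreq = marker_map["pop_b_freq"].to_numpy()
        nm = len(marker_map)
        zygote = geno_rng.random((nm, 4)) < pfreq[:, None]
        zygote2 = geno2_rng.random((nm, 4)) < pfreq[:, None] if spec.chimera else None

    str_geno = _draw_str_genotypes(spec, geno_rng, geno2_rng, sex_loci, parentage_loci)

    out = {}
    for tissue in tissues:
        lines = _tissue_lines(spec, tissue)
        records = None
        if include_snp:
            noise_rng = _child_rng(config.seed, individual_id, "tissue", tissue)
            records = _snp_records(
                individual_id, marker_map, zygote, zygote2, lines, config, noise_rng, spec
            )
        sp, pp = _panels_for_tissue(individual_id, tissue, spec, lines, str_geno)
        out[tissue] = TissueData(records=records, sex_panel=sp, parentage_panel=pp)
    return SimulatedIndividual(individual_id, spec, phenotypic_sex, out)


def _tissue_lines(spec: KaryotypeSpec, tissue: str):
    """Cell lines present in a tissue: chimera second line only in blood."""
    lines = spec.lines
    if spec.chimera and tissue != "blood":
        x, y, _ = lines[0]
        return [(x, y, 1.0)]
    return lines


def _snp_records(
    individual_id, marker_map, zygote, zygote2, lines, config, rng, spec
) -> pd.DataFrame:
    nm = len(marker_map)
    num = np.zeros(nm)  # weighted allelic-ratio numerator
    wgt = np.zeros(nm)  # weight of lines contributing DNA
    lrr_mean = np.zeros(nm)
    base_cn = _marker_cn(marker_map, lines[0][0], lines[0][1])
    for li, (x, y, frac) in enumerate(lines):
        if frac == 0.0:
            continue
        cn = _marker_cn(marker_map, x, y)
        if li == 0:
            k = _line_b_counts(zygote, cn, cn, shared=False)
        elif spec.chimera:
            k = _line_b_counts(zygote2, cn, cn, shared=False)
        else:
            k = _line_b_counts(zygote, cn, base_cn, shared=True)
        has_dna = cn > 0
        ratio = np.zeros(nm)
        ratio[has_dna] = k[has_dna] / cn[has_dna]
        num[has_dna] += frac * ratio[has_dna]
        wgt[has_dna] += frac
        lrr_mean += frac * np.array([config.lrr_mean(c) for c in range(5)])[np.minimum(cn, 4)]
    baf_clean = np.where(wgt > 0, num / np.where(wgt > 0, wgt, 1.0), np.nan)

    baf = np.clip(baf_clean + rng.normal(0.0, config.baf_noise_sd, nm), 0.0, 1.0)
    lrr = lrr_mean + rng.normal(0.0, config.lrr_noise_sd, nm)

    # markers with no DNA in any line: mostly missing, else uniform noise
    void = wgt == 0.0
    if np.any(void):
        miss = void & (rng.random(nm) < config.y_missing_rate)
        noisy = void & ~miss
        baf[noisy] = rng.random(int(noisy.sum()))
        lrr[noisy] = config.lrr_mean(0) + rng.normal(0.0, config.lrr_noise_sd, int(noisy.sum()))
        baf[miss] = np.nan
        lrr[miss] = np.nan

    return pd.DataFrame(
        {
            "sample_id": individual_id,
            "snp_name": marker_map["snp_name"].to_numpy(),
            "chrom": marker_map["chrom"].to_numpy(),
            "position": marker_map["position"].to_numpy(),
            "baf": baf,
            "lrr": lrr,
        }
    )


def _draw_locus_alleles(rng, locus: STRLocusModel, n: int) -> list:
    cum = locus.cumulative()
    idx = np.searchsorted(cum, rng.random(n), side="right")
    idx = np.minimum(idx, len(locus.alleles) - 1)
    return [locus.alleles[i] for i in idx]


def _draw_str_genotypes(spec, geno_rng, geno2_rng, sex_loci, parentage_loci) -> dict:
    """Per-line allele draws for every STR locus (keyed by line index)."""
    out = {}
    for li, (x, y, _) in enumerate(spec.lines):
        rng = geno2_rng if (spec.chimera and li == 1) else geno_rng
        if not spec.chimera and li == 1:
            # shared zygote: reuse line-0 alleles, duplicating/dropping copies
            base = out[0]
            line = {}
            for name, alleles in base["x"].items():
                if x >= len(alleles):
                    line[name] = alleles + alleles[:1] * (x - len(alleles))
                else:
                    line[name] = alleles[:x] if x > 0 else []
            aut = {m: list(a) for m, a in base["aut"].items()}
            out[li] = {"x": line, "aut": aut, "y": y >= 1}
            continue
        xg = {name: _draw_locus_alleles(rng, locus, x) for name, locus in sex_loci.items()}
        aut = {}
        for name, locus in parentage_loci.items():
            if locus.chromosome_class == "x_linked":
                aut[name] = _draw_locus_alleles(rng, locus, x)
            else:
                aut[name] = _draw_locus_alleles(rng, locus, 2)
        out[li] = {"x": xg, "aut": aut, "y": y >= 1}
    return out


def _panels_for_tissue(individual_id, tissue, spec, lines, str_geno):
    line_ids = list(range(len(spec.lines)))
    if spec.chimera and tissue != "blood":
        line_ids = [0]
    x_present = any(spec.lines[i][0] >= 1 for i in line_ids)
    y_present = any(spec.lines[i][1] >= 1 for i in line_ids)

    def merged(kind, name):
        alleles = []
        for i in line_ids:
            alleles.extend(str_geno[i][kind][name])
        return tuple(sorted(set(alleles)))

    # the sex-panel table format reports at most two alleles per X STR;
    # with >2 distinct fragments the two shortest are retained (binning
    # convention) — extra-allele evidence is carried by the parentage panel
    xg = {}
    for m in X_PANEL_MARKERS:
        g = merged("x", m)
        xg[m] = g[:2] if g else (0,)
    sp = SexPanelResult(
        individual_id=individual_id,
        tissue=tissue,
        x_genotypes=xg,
        amex=x_present,
        amey=y_present,
        ecayh12=y_present,
        sry=y_present,
    )
    aut = {m: merged("aut", m) for m in str_geno[0]["aut"]}
    pp = ParentagePanelResult(
        individual_id=individual_id,
        genotypes=aut,
        amex=x_present,
        amey=y_present,
    )
    return sp, pp


# ---------------------------------------------------------------------------
# Cohorts

@dataclass
class CohortMember:
    individual_id: str
    spec: KaryotypeSpec
    phenotypic_sex: str
    flag_panel: ParentagePanelResult  # blood parentage panel (first tier)
    config: SimConfig = field(repr=False)
    _marker_map: Optional[pd.DataFrame] = field(default=None, repr=False)

    def simulate_full(self, tissues=("blood", "hair"), include_snp=True) -> SimulatedIndividual:
        return simulate_individual(
            self.spec,
            self.config,
            tissues=tissues,
            individual_id=self.individual_id,
            marker_map=self._marker_map,
            include_snp=include_snp,
        )


def simulate_cohort(
    n: int,
    composition: Mapping,
    config: SimConfig,
    male_fraction: float = 0.49,
    marker_map: Optional[pd.DataFrame] = None,
) -> list:
    """A screened cohort: STR first-tier panels for everyone.

    ``composition`` maps karyotype labels (or KaryotypeSpec) to counts; the
    remainder are normal 64,XX / 64,XY at the enrolment sex ratio (49%
    males).  SNP data for any member can be generated on demand via
    ``CohortMember.simulate_full`` using the member's deterministic seed.
    """
    specs = []
    for key, count in composition.items():
        if count < 0:
            raise ValueError("composition counts must be non-negative")
        spec = key if isinstance(key, KaryotypeSpec) else KARYOTYPES.get(key) or KaryotypeSpec.from_label(key)
        specs.extend([spec] * int(count))
    if len(specs) > n:
        raise ValueError("composition exceeds cohort size")
    fill = n - len(specs)
    fill_rng = _child_rng(config.seed, "cohort", "sexes")
    males = fill_rng.random(fill) < male_fraction
    specs.extend(KARYOTYPES["64,XY"] if m else KARYOTYPES["64,XX"] for m in males)

    sex_loci = default_sex_panel_loci()
    parentage_loci = default_parentage_loci()
    members = []
    for i, spec in enumerate(specs):
        ind_id = f"H{i+1:06d}"
        geno_rng = _child_rng(config.seed, ind_id, "genotype")
        geno2_rng = _child_rng(config.seed, ind_id, "genotype2")
        str_geno = _draw_str_genotypes(spec, geno_rng, geno2_rng, sex_loci, parentage_loci)
        lines = spec.lines
        _, pp = _panels_for_tissue(ind_id, "blood", spec, lines, str_geno)
        members.append(
            CohortMember(
                individual_id=ind_id,
                spec=spec,
                phenotypic_sex="male" if spec.y_copies >= 1 else "female",
                flag_panel=pp,
                config=config,
                _marker_map=marker_map,
            )
        )
    return members


# ---------------------------------------------------------------------------
# Pedigrees

def simulate_pedigree(
    n_founders: int,
    n_generations: int,
    mating_scheme: str = "random",
    seed: int = 0,
    offspring_per_generation: Optional[int] = None,
):
    """Random or full-sib pedigrees for exercising the pedigree statistics.

    Founders are generation 0 with unknown parents.  The random scheme
    draws a sire and a dam independently from the previous generation; the
    full_sib scheme mates full siblings whenever possible.
    """
    from .pedigree import Pedigree

    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    rng = np.random.default_rng(seed)
    k = offspring_per_generation or n_founders
    parents = {}
    sexes = {}
    gen = []
    for i in range(n_founders):
        ind = f"F{i}"
        parents[ind] = (None, None)
        sexes[ind] = "male" if i % 2 == 0 else "female"
        gen.append(ind)
    counter = 0
    for g in range(1, n_generations + 1):
        males = [i for i in gen if sexes[i] == "male"]
        females = [i for i in gen if sexes[i] == "female"]
        if not males or not females:
            break
        new = []
        for j in range(k):
            if mating_scheme == "full_sib" and g > 1:
                # mate within the first sib pair available
                sire, dam = males[0], females[0]
            elif mating_scheme == "random":
                sire = males[rng.integers(len(males))]
                dam = females[rng.integers(len(females))]
            else:
                sire, dam = males[j % len(males)], females[j % len(females)]
            ind = f"G{g}_{counter}"
            counter += 1
            parents[ind] = (sire, dam)
            # alternate sexes so every generation can mate
            sexes[ind] = "male" if j % 2 == 0 else "female"
            new.append(ind)
        gen = new
    return Pedigree(parents, sexes=sexes)
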