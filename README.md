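# equicna

Genomic screening for sex-chromosome copy-number aberrations (CNAs) in the
domestic horse.

Sex-chromosome aneuploidies — X monosomy (63,X), the equine analogue of
Klinefelter syndrome (65,XXY), sex-reversal syndromes and blood chimerism —
are a leading genetic cause of infertility in horses, and most carriers look
phenotypically normal until breeding age. Karyotyping every foal is not
feasible, but the molecular data that breeding programs already generate can
be screened instead. `equicna` implements that two-step screen as a tested,
reusable pipeline:

1. **STR flagging.** Every foal's parentage test (17 STR markers plus the
   sex-dimorphic amelogenin fragment AMEX/AMEY) is checked for
   - a mismatch between genetic and phenotypic sex,
   - a heterozygous call at the panel's only X-linked marker (LEX003) in an
     animal that also amplifies Y markers — two distinct X copies plus a Y,
   - three or more alleles at any marker (a chimerism signal).
2. **SNP confirmation.** Flagged candidates are genotyped on a medium-density
   array; markers are grouped into three autosomal control chromosomes
   (ECA5/15/25), the X pseudoautosomal region (**PAR**, first 1.86 Mb of
   ECAX, shared with ECAY), the X-specific remainder (**NONPAR**) and ECAY.
   Per region three statistics are computed:
   - **HET%** — share of markers with B-allele frequency (BAF) strictly in
     (0.25, 0.75): ~30% for two copies, ~0 for one, elevated for three;
   - **mean LRR** — log R ratio: ~0 (two copies), ~−0.45 (one), ~+0.13
     (three; array response to gains is compressed);
   - **dip p** — Hartigan & Hartigan's dip test of unimodality on the
     windowed BAF: two copies give one central mode, three copies split it
     into modes near 1/3 and 2/3.

   A rule-based classifier turns the region grid into a karyotype call;
   blood/hair concordance rules out blood chimerism and the parents' arrays
   decide whether the aberration is de novo. Confirmed cases are
   characterised against the studbook pedigree (inbreeding F, coancestry
   f_ij, ancestors explaining 50% of the gene pool, shared ancestors within
   four generations).

The dip statistic is computed exactly from its definition
(`min_G sup_x |F_n(x) − G(x)|` over unimodal distribution functions G) with
a Monte-Carlo uniform null for p-values. Because real screening genotypes
are confidential studbook data, the package ships a synthetic-cohort
generator (`equicna.simulate`) that emulates the array's signal model for
arbitrary karyotypes, mosaics and chimeras, plus the published worked
examples of five confirmed 65,XXY stallions (`equicna.fixtures`).

## Worked example

The five bundled case profiles, embedded in a screened population of
27,330 foals:

```python
from equicna.pipeline import run_screen

report = run_screen({"fixtures": True, "cohort_total": 27330})
print(report.summary)
```

```
{'n_total': 27330, 'n_flagged': 5, 'flagged_pct': 0.018,
 'diagnosis_counts': {'65,XXY': 5}, 'n_abnormal': 5,
 'reciprocal_incidence': 5500}
```

All five animals are flagged (0.018% of the population — about 1 case in
5500), and the SNP region statistics confirm 65,XXY for each. Drilling into
the first case:

```python
h1 = report.individuals["Horse 1"]
h1["flag_reasons"]                                # ['x_het_with_y']
h1["final_label"]                                 # '65,XXY'
h1["calls"]["blood"]["y_copy_warning"]            # True
h1["calls"]["blood"]["evidence"]["PAR"]
# {'region': 'PAR', 'n_markers': 50, 'het_pct': 40.0,
#  'mean_lrr': 0.14, 'dip_p': 0.25, 'insufficient': False, ...}
```

Horse 1's PAR shows the trisomic signature (HET 40% vs ~31% on the
autosomes, LRR +0.14, dip p 0.25), its X-specific region stays diploid and
its Y LRR of −0.05 is high enough that a second Y copy cannot be excluded
from array data alone — hence the warning (that question needs FISH).

The same machinery runs on synthetic cohorts:

```python
report = run_screen({
    "seed": 1,
    "cohort": {"n": 500, "composition": {"65,XXY": 3, "63,X": 2}},
})
```

or from the shell: `equicna simulate|flag|cna|pedigree|screen|fixtures`
(see `equicna --help`).

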