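# Methods

This note documents the models and numerical choices behind `equicna`: the
two-step screen itself, the dip statistic, the synthetic data generator the
tests run on, the classifier's decision rules, and the pedigree statistics.

## The screen

Breeding programs type every foal with a 17-marker STR parentage panel plus
the amelogenin sex fragment. That data is free evidence for a first CNA
screen: the amelogenin pattern gives a genetic sex to check against the
veterinary record, and the panel's single X-linked marker (LEX003) can only
be heterozygous when two distinct X copies are present — so a heterozygous
LEX003 in an animal that also amplifies Y markers implies at least XXY.
Three-or-more-allele calls at any marker point to mixed genomes
(chimerism). The screen is deliberately cheap and insensitive: with one
X-linked marker of heterozygosity *h* it misses a fraction `1 − h` of XXY
carriers (those homozygous at that marker); at the breed's LEX003
heterozygosity of 0.75 the expected false-negative rate is 25%
(`strscreen.expected_false_negative_rate`).

Flagged candidates move to a SNP array analysis restricted to five
chromosome sets: ECA5 (2891 markers), ECA15 (2692) and ECA25 (1107) as
autosomal controls, ECAX (3431) split at 1.86 Mb into the pseudoautosomal
region (PAR, shared with ECAY; boundary 1-based inclusive) and the
X-specific remainder (NONPAR, to 128.21 Mb), and ECAY (172). Per region the
statistic triple is

* `HET%` = 100 × (markers with BAF strictly in (0.25, 0.75)) / (markers
  with a non-missing BAF),
* `mean LRR` over non-missing LRR,
* `dip p` = dip test on exactly the BAF values counted by HET ("windowed"),

and regions with fewer than 50 usable markers are marked `insufficient`
(statistics still reported). Computing the dip on the windowed values, not
all BAF, is the reading consistent with the published autosomal dip p ≈ 1:
on all BAF every diploid region would be trimodal (0, ½, 1). The
all-values alternative can be had by widening `window`.

Copy-number signatures: two copies → HET ≈ 30%, LRR ≈ 0, unimodal window;
one copy → HET ≈ 0, LRR ≈ −0.45; three copies → HET well above the
autosomal level, LRR ≈ +0.13 (array gain response is strongly compressed
relative to log2(3/2) ≈ 0.58), windowed BAF bimodal at 1/3 and 2/3. A
65,XXY male is diploid on the autosomes and NONPAR (two X), trisomic in PAR
(two X + one Y) and hemizygous on Y.

## Dip statistic and p-value

The dip of a sample is the smallest sup-norm distance between its
empirical CDF and any unimodal distribution function — convex up to a
mode, concave after it, an atom *at* the mode permitted (the class
includes point masses). `equicna._dipcore` computes it exactly by scanning
mode placements between (and, for tied data, at) the order statistics.
For each placement the binding constraints reduce to:

* convex side: violations of the band `[F_n(x_j) − d, F_n(x_j^-) + d]` by
  the greatest convex minorant of the upper band corners;
* concave side: mirrored, via the least concave majorant of the lower
  corners;
* a junction coupling — convexity can force the left branch at the mode
  above what the concave branch can accept; the coupling constraints are
  lines through one upper and one lower anchor extrapolated to the mode,
  and the minimal feasible `d` is found by bisection over a monotone
  feasibility predicate (exact to ~1e−13);
* tie floors: a value repeated `w` times forces `d ≥ w/(2n)` except at a
  mode knot, where the CDF may jump.

The implementation is validated in the test suite against an independent
exact reference: a linear-programming formulation of the definition itself
(variables = CDF values at the knots, constraints = band, monotonicity,
convexity/concavity per mode placement). Agreement is ~1e−13 across
thousands of random samples including heavy ties.

One consequence worth knowing: for two well-separated clusters the dip is
governed by the cluster *masses* and the gap geometry, not the cluster
widths — an atom at the mode can sit at one cluster's edge and absorb it.
At the ~29 windowed PAR values of a trisomic sample the test therefore
loses power exactly when the 1/3 and 2/3 clusters are unbalanced. The
classifier (below) accounts for this.

P-values are Monte Carlo against the uniform null — the least favourable
unimodal distribution — with an add-one correction,
`p = (1 + #{null dips ≥ observed}) / (n_null + 1)`, `n_null` = 10,000 by
default, deterministic given a seed. `dip_pvalue` draws nulls at exactly
the sample's n. `region_stats`, which computes hundreds of p-values per
cohort, shares one null set across regions of similar size: null sizes are
rounded onto a geometric grid (ratio 1.05) and observed dips compared on
the `sqrt(n)`-scaled statistic (the dip's sampling scale). The induced
error is well below a percent at the decision thresholds; exact-size nulls
can be forced with `dip_null_grid_ratio=None`. The null calibration
(rejection rate 5% ± 2 points at α = 0.05) is checked in the acceptance
tests.

## Synthetic cohorts

Real screening genotypes are confidential studbook data, so all
distributional tests run on simulation. The generator
(`equicna.simulate`) emulates the pruned array described above, not the
raw instrument:

* **Marker map.** Per-chromosome counts default to the pruned set
  (2891/2692/1107/3431/172); positions are uniform, unique, sorted; the
  PAR receives at least 50 markers. Each marker gets a population
  B-allele frequency drawn once per map: autosomal/NONPAR/Y markers from
  `0.05 + 0.9·Beta(0.7, 0.7)` (mean per-marker heterozygosity 2pq ≈ 0.33,
  matching the published autosomal HET range of ~23–33%), PAR markers
  from `0.10 + 0.8·Beta(1.2, 1.2)`. The separate PAR distribution
  reflects array ascertainment: under trisomy the windowed fraction is
  3pq = 1.5 × 2pq exactly, yet the published PAR/autosome HET ratios are
  1.85–2.3 — only possible if the array's PAR content is more polymorphic
  than its genome-wide average. The default gives a ratio ≈ 1.9.
* **Genotypes.** A zygote draws up to four Bernoulli(B-frequency) alleles
  per marker; a cell line with copy number CN uses the first CN. Mosaic
  (shared-zygote) lines duplicate the first allele on gains
  (nondisjunction) and drop the last on losses; chimeric lines draw an
  independent zygote. Linkage disequilibrium is not modelled — the region
  statistics are marginal per marker.
* **Signal.** Noiseless BAF is the B-allele ratio k/CN, mixed across cell
  lines by cell fraction (intensity mixing is approximately linear), plus
  `Normal(0, 0.03)` clipped to [0, 1]. LRR is
  `Normal(mean_by_CN[·], 0.15)` with means −2.0 / −0.45 / 0.0 / +0.13 for
  CN 0–3, mixed linearly across lines. Markers with no DNA in any line
  (ECAY in a Y-less genome) fail with probability 0.9 and otherwise
  return uniform BAF noise at background LRR — classifiers must tolerate
  both. Noise SDs and the CN-3 LRR are not instrument measurements; they
  are calibrated once so that simulated region statistics land in the
  published ranges (autosomal HET 23–33%, monosomic LRR ≈ −0.4, trisomic
  PAR LRR ≈ +0.13 with dip p ≤ ~0.25).
* **Tissues.** Every tissue shares the genotype with independent
  technical noise; only chimeras differ genetically between tissues (the
  second line is confined to blood). STR panels derive from the same copy
  numbers: one X copy can never produce a heterozygous X-STR call, and a
  blood chimera shows extra alleles in blood but not hair. The sex-panel
  table format caps each X STR at two reported alleles (binning
  convention); extra-allele evidence travels through the parentage panel.
* **Seeding.** One master seed; each (individual, layer, tissue) derives
  its generator from a stable BLAKE2 hash, so cohorts are byte-reproducible
  and any member's SNP data can be regenerated lazily and independently.
* **Cohorts.** Composition is exact; the remainder fills with normal
  64,XX/64,XY at the enrolment sex ratio (49% male). A 27,330-member
  STR-only cohort simulates and flags in ~10 s.

What passing simulation tests does *not* show: robustness to genotyping
error and allelic dropout in STRs (not modelled — flag specificity on real
data will be lower), to array batch effects or GC waves in LRR, to
population structure in allele frequencies, or to low-fraction mosaicism
(mixing is modelled, but detection thresholds for small fractions are not
calibrated). The classifier reports unresolved patterns as `ambiguous`
rather than guessing a mosaic fraction.

## Classifier

All rules operate relative to the mean of the usable autosomal controls
(written Ā) where that matters; defaults live in `ClassifierThresholds`.

* NONPAR: one copy if HET < 5% and LRR ≤ −0.2; three copies if HET ≥ 15%,
  dip p ≤ 0.45 and LRR ≥ +0.08; otherwise two copies if HET ≥ 15% and
  |LRR| ≤ 0.15 (once trisomy is excluded, disomy needs no dip evidence —
  a large unimodal region occasionally yields a mid-range dip p by
  chance).
* PAR: one copy as above. Three copies need the LRR gain margin
  (≥ Ā + 0.05, a ~4-SE margin at 50 markers) **and** any one of: HET
  margin ≥ 5 points with dip p ≤ 0.45; HET margin ≥ 15 points alone; dip
  p ≤ 0.1 alone. The three routes cover the two failure modes of the
  statistics at ~50 PAR markers — the dip's insensitivity to unbalanced
  clusters, and HET's map-level luck in marker informativeness — while
  the LRR margin keeps the false-positive rate of the combined rule below
  ~0.1%. Otherwise two copies if |LRR − Ā| ≤ 0.15.
* Y: present if the sex panel amplifies Y markers, or if HET < 10% with
  LRR ≥ −0.6. Y copy number is never called as two from LRR alone; LRR >
  −0.10 only raises `y_copy_warning` (resolution requires an orthogonal
  method such as FISH).
* Labels: NONPAR 2 + PAR 3 + Y → `65,XXY`; NONPAR 2 + PAR 2 − Y →
  `64,XX`; NONPAR 1 + PAR 2 + Y → `64,XY`; NONPAR 1 + PAR 1 − Y →
  `63,X`; anything else `ambiguous` with reasons (possible mosaic or
  quality failure). No multiple-testing correction is applied: each
  region is a diagnostic feature, not a discovery test.

On the five bundled worked-example grids the classifier returns `65,XXY`
for all five with the Y-copy warning on the first case only; on simulated
cohorts it recovers ≥95% (in practice ~100%) of 64,XX / 64,XY / 63,X /
65,XXY individuals at default noise with no false XXY among normals
(checked in `tests/test_acceptance.py`). A final diagnosis is only issued
when two tissues concord, unless single-tissue mode is explicitly
requested (banked-DNA cases), which adds a caveat to the report.

## Pedigree statistics

Inbreeding uses the Meuwissen–Luo recursion: for an individual with both
parents known, `1 + F` is accumulated as `Σ L_j² D_j` over a virtual
progeny's ancestor weights, with Mendelian-sampling coefficients
`D = 0.5 − 0.25(F_s + F_d)` (0.75 − 0.25·F with one known parent, 1 for
founders). Coancestry is the tabular kinship recursion. Both are verified
against exhaustive Wright path counting (tolerance 1e−12) in the tests.
Unknown parents are unique unrelated founders.

The ancestors explaining 50% of a group's gene pool (a50) use the
marginal-contribution greedy selection on the pooled gene pool: each round
propagates the group's gene shares up the pedigree with previously
selected ancestors' parent links cut, picks the largest marginal
contributor (ties by id), and stops when the cumulative contribution
reaches the threshold. Pooling (rather than averaging per-individual
counts) makes the result a property of the group's joint gene pool.
Common-ancestor queries count parents as generation 1 and report ancestors
within the horizon shared by at least two group members.

## Problem sizes used

Defaults throughout are the study conditions: cohort 27,330 with the five
worked-example profiles embedded; classifier recovery 50 simulated
individuals per karyotype on the full-size marker map; dip calibration
1,000 uniform samples of n = 200 against a 2,000-replicate null;
dip-oracle agreement on 50 random samples; pedigree oracle on 200 random
pedigrees of ≤ 12 individuals. Module tests use a downsized array
(400/400/200/800/80 markers) where the full map adds nothing.
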