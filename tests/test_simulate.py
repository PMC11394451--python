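"""Synthetic cohort generator: marker maps, signal model, panels, cohorts."""

import numpy as np
import pytest

from equicna.karyotype import KARYOTYPES, KaryotypeSpec
from equicna.simulate import (
    SimConfig,
    default_sex_panel_loci,
    make_marker_map,
    simulate_cohort,
    simulate_individual,
    simulate_pedigree,
)
from equicna.cna import partition_regions, region_stats


class TestKaryotypeSpec:
    def test_label_parsing_round_trip(self):
        spec = KaryotypeSpec.from_label("65,XXY")
        assert (spec.x_copies, spec.y_copies) == (2, 1)
        mosaic = KaryotypeSpec.from_label("63,X/64,XX", mosaic_fraction=0.3)
        assert mosaic.mixed and mosaic.alt_x_copies == 2 and not mosaic.chimera
        chim = KaryotypeSpec.from_label("64,XX/64,XY chimera")
        assert chim.chimera

    def test_inconsistent_label_rejected(self):
        with pytest.raises(ValueError):
            KaryotypeSpec("64,XY", 2, 0)

    def test_nullisomy_rejected(self):
        with pytest.raises(ValueError):
            KaryotypeSpec("62,?", 0, 0)


class TestMarkerMap:
    def test_default_counts_match_pruned_array(self, marker_map):
        counts = marker_map.groupby("chrom").size().to_dict()
        assert counts == {"5": 2891, "15": 2692, "25": 1107, "X": 3431, "Y": 172}

    def test_par_partition_and_minimum(self, marker_map):
        par = marker_map[marker_map.region == "PAR"]
        assert len(par) >= 50
        assert (par.position <= 1_860_000).all()
        nonpar = marker_map[marker_map.region == "NONPAR"]
        assert (nonpar.position > 1_860_000).all()
        assert len(par) + len(nonpar) == 3431

    def test_positions_sorted_unique_within_chromosome(self, marker_map):
        for _, sub in marker_map.groupby("chrom"):
            pos = sub.position.to_numpy()
            assert np.all(np.diff(pos) > 0)

    def test_custom_counts(self):
        cfg = SimConfig(marker_counts={"5": 10})
        mm = make_marker_map(cfg)
        assert len(mm) == 10
        assert np.all(np.diff(mm.position) > 0)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(marker_counts={"5": 0})

    def test_invalid_noise_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(baf_noise_sd=0.0)
        with pytest.raises(ValueError):
            SimConfig(lrr_mean_by_cn={0: 0.0, 1: -0.5, 2: 0.0, 3: 0.13})


class TestSignalModel:
    def test_baf_in_unit_interval_lrr_finite(self, small_config, small_marker_map):
        sim = simulate_individual(
            KARYOTYPES["65,XXY"], small_config, tissues=("blood",),
            individual_id="b1", marker_map=small_marker_map,
        )
        rec = sim.tissues["blood"].records
        baf = rec.baf.dropna()
        assert ((baf >= 0) & (baf <= 1)).all()
        assert np.isfinite(rec.lrr.dropna()).all()

    def test_xxy_baf_modes(self, sim_config, marker_map):
        """Trisomic PAR shows modes near 1/3 and 2/3; disomic NONPAR near
        0, 1/2 and 1."""
        sim = simulate_individual(
            KARYOTYPES["65,XXY"], sim_config, tissues=("blood",),
            individual_id="modes", marker_map=marker_map,
        )
        rec = sim.tissues["blood"].records
        regions = partition_regions(rec)
        par = regions["PAR"].baf.dropna().to_numpy()
        win = par[(par > 0.25) & (par < 0.75)]
        lo, hi = win[win < 0.5], win[win > 0.5]
        assert abs(np.median(lo) - 1 / 3) < 0.03
        assert abs(np.median(hi) - 2 / 3) < 0.03
        nonpar = regions["NONPAR"].baf.dropna().to_numpy()
        mid = nonpar[(nonpar > 0.25) & (nonpar < 0.75)]
        assert abs(np.median(mid) - 0.5) < 0.03
        assert (nonpar < 0.1).sum() > 0.2 * len(nonpar)
        assert (nonpar > 0.9).sum() > 0.2 * len(nonpar)

    def test_cn2_window_fraction_matches_model_heterozygosity(self, sim_config, marker_map):
        """At 3000+ markers, the fraction of BAF in (0.25, 0.75) converges
        to the allele-frequency model's mean heterozygosity (+-3 points)."""
        sim = simulate_individual(
            KARYOTYPES["64,XX"], sim_config, tissues=("blood",),
            individual_id="h2frac", marker_map=marker_map,
        )
        rec = sim.tissues["blood"].records
        auto = rec[rec.chrom.isin(["5", "15"])]
        frac = ((auto.baf > 0.25) & (auto.baf < 0.75)).mean()
        assert frac == pytest.approx(sim_config.mean_heterozygosity(), abs=0.03)

    def test_cn1_window_fraction_below_5pct(self, sim_config, marker_map):
        sim = simulate_individual(
            KARYOTYPES["64,XY"], sim_config, tissues=("blood",),
            individual_id="h1frac", marker_map=marker_map,
        )
        rec = sim.tissues["blood"].records
        nonpar = partition_regions(rec)["NONPAR"].baf.dropna()
        assert ((nonpar > 0.25) & (nonpar < 0.75)).mean() < 0.05

    def test_monosomy_x_het_low_and_y_absent_over_seeds(self, marker_map):
        """63,X: ECAX heterozygosity below 5% and Y mostly failed calls,
        across seeds."""
        for seed in range(100):
            cfg = SimConfig(seed=seed, marker_counts={"X": 300, "Y": 60})
            mm = make_marker_map(cfg)
            sim = simulate_individual(
                KARYOTYPES["63,X"], cfg, tissues=("blood",),
                individual_id=f"mono{seed}", marker_map=mm,
            )
            rec = sim.tissues["blood"].records
            x = rec[rec.chrom == "X"].baf.dropna()
            assert ((x > 0.25) & (x < 0.75)).mean() < 0.05
            y = rec[rec.chrom == "Y"]
            assert y.baf.isna().mean() > 0.6

    def test_cn3_windowed_baf_bimodal(self):
        """Windowed BAF of a trisomic region rejects unimodality in >=95%
        of seeded replicates at ~300 windowed values."""
        hits = 0
        reps = 200
        for seed in range(reps):
            cfg = SimConfig(seed=seed, marker_counts={"X": 560}, min_par_markers=520)
            mm = make_marker_map(cfg)
            sim = simulate_individual(
                KARYOTYPES["65,XXY"], cfg, tissues=("blood",),
                individual_id=f"tri{seed}", marker_map=mm,
            )
            par = partition_regions(sim.tissues["blood"].records)["PAR"]
            s = region_stats(par, "PAR", dip_n_null=1000, dip_seed=5)
            hits += s.dip_p < 0.05
        assert hits >= 0.95 * reps

    def test_str_hemizygous_x_single_allele(self, small_config, small_marker_map):
        sim = simulate_individual(
            KARYOTYPES["64,XY"], small_config, tissues=("blood",),
            individual_id="xy_str", marker_map=small_marker_map,
        )
        panel = sim.tissues["blood"].sex_panel
        assert all(len(set(g)) == 1 for g in panel.x_genotypes.values())
        assert panel.all_y

    def test_lex003_model_heterozygosity(self):
        assert default_sex_panel_loci()["LEX003"].heterozygosity == pytest.approx(0.75)


class TestTissues:
    def test_non_chimeric_tissues_share_genotypes(self, small_config, small_marker_map):
        sim = simulate_individual(
            KARYOTYPES["64,XX"], small_config, tissues=("blood", "hair"),
            individual_id="t2", marker_map=small_marker_map,
        )
        b, h = sim.tissues["blood"], sim.tissues["hair"]
        assert b.sex_panel.x_genotypes == h.sex_panel.x_genotypes
        assert b.parentage_panel.genotypes == h.parentage_panel.genotypes
        # technical noise is independent
        assert not np.allclose(
            b.records.baf.fillna(-1).to_numpy(), h.records.baf.fillna(-1).to_numpy()
        )

    def test_chimera_discordant_between_blood_and_hair(self, small_config, small_marker_map):
        sim = simulate_individual(
            KARYOTYPES["64,XX/64,XY chimera"], small_config,
            tissues=("blood", "hair"), individual_id="chi", marker_map=small_marker_map,
        )
        blood = sim.tissues["blood"].parentage_panel
        hair = sim.tissues["hair"].parentage_panel
        assert blood.multi_allelic_markers()  # two genomes mixed in blood
        assert not hair.multi_allelic_markers()
        assert blood.amey and not hair.amey

    def test_tissue_concordance_calls_over_seeds(self):
        """Chimeras yield discordant tissue karyotype calls; pure
        karyotypes never do."""
        from equicna.cna import classify_karyotype

        def call_tissues(label, seed):
            cfg = SimConfig(
                seed=seed,
                marker_counts={"5": 400, "15": 400, "25": 200, "X": 800, "Y": 80},
            )
            mm = make_marker_map(cfg)
            sim = simulate_individual(
                KARYOTYPES[label], cfg, tissues=("blood", "hair"),
                individual_id=f"c{seed}", marker_map=mm,
            )
            labels = []
            for t in ("blood", "hair"):
                regions = partition_regions(sim.tissues[t].records)
                stats = {
                    r: region_stats(df, r, dip_n_null=400, dip_seed=2)
                    for r, df in regions.items()
                }
                labels.append(
                    classify_karyotype(stats, sex_panel=sim.tissues[t].sex_panel).label
                )
            return labels

        for seed in range(12):
            b, h = call_tissues("64,XX/64,XY chimera", seed)
            assert b != h, f"chimera seed {seed} concordant: {b}"
        for seed in range(12):
            b, h = call_tissues("64,XY", seed)
            assert b == h == "64,XY", f"pure seed {seed}: {b}/{h}"


class TestCohort:
    def test_composition_is_exact(self, sim_config):
        members = simulate_cohort(200, {"65,XXY": 5}, sim_config)
        assert len(members) == 200
        assert sum(m.spec.label == "65,XXY" for m in members) == 5

    def test_fill_sex_ratio(self, sim_config):
        members = simulate_cohort(2000, {}, sim_config)
        male = np.mean([m.phenotypic_sex == "male" for m in members])
        assert male == pytest.approx(0.49, abs=0.03)

    def test_same_seed_reproduces_cohort(self, sim_config):
        a = simulate_cohort(50, {"65,XXY": 2}, sim_config)
        b = simulate_cohort(50, {"65,XXY": 2}, sim_config)
        for x, y in zip(a, b):
            assert x.individual_id == y.individual_id
            assert x.flag_panel.genotypes == y.flag_panel.genotypes
        ra = a[0].simulate_full(tissues=("blood",), include_snp=False)
        rb = b[0].simulate_full(tissues=("blood",), include_snp=False)
        assert ra.tissues["blood"].sex_panel == rb.tissues["blood"].sex_panel

    def test_oversized_composition_rejected(self, sim_config):
        with pytest.raises(ValueError):
            simulate_cohort(3, {"65,XXY": 5}, sim_config)
        with pytest.raises(ValueError):
            simulate_cohort(10, {"65,XXY": -1}, sim_config)


class TestPedigreeSim:
    def test_full_sib_scheme_produces_full_sib_offspring(self):
        ped = simulate_pedigree(2, 2, "full_sib", seed=1)
        last = [i for i in ped.order if i.startswith("G2")]
        assert last
        sires = {ped.parents[i][0] for i in last}
        dams = {ped.parents[i][1] for i in last}
        assert len(sires) == 1 and len(dams) == 1
        s, d = sires.pop(), dams.pop()
        assert ped.parents[s] == ped.parents[d]  # parents are full sibs

    def test_reproducible(self):
        a = simulate_pedigree(4, 3, "random", seed=9)
        b = simulate_pedigree(4, 3, "random", seed=9)
        assert a.parents == b.parents

    def test_founder_minimum(self):
        with pytest.raises(ValueError):
            simulate_pedigree(1, 2)
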