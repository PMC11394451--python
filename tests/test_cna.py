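"""SNP region statistics and karyotype classification."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from equicna.cna import (
    RegionPartition,
    RegionStats,
    classify_karyotype,
    compare_tissues,
    partition_regions,
    region_stats,
    screen_parents,
    stats_table,
)
from equicna.io import read_final_report, write_final_report


def frame(chrom, pos, baf=None, lrr=None):
    n = len(pos)
    return pd.DataFrame(
        {
            "sample_id": "s1",
            "snp_name": [f"m{i}" for i in range(n)],
            "chrom": chrom if isinstance(chrom, list) else [chrom] * n,
            "position": pos,
            "baf": baf if baf is not None else np.full(n, 0.5),
            "lrr": lrr if lrr is not None else np.zeros(n),
        }
    )


FINAL_REPORT = """Sample ID\tSNP Name\tChr\tPosition\tB Allele Freq\tLog R Ratio
s1\tm1\t5\t100\t0.5\t0.01
s1\tm2\t5\t200\t0.98\t-0.02
s1\tm3\tX\t1000000\t0.33\t0.12
s1\tm4\tX\t2000000\t0.5\t0.0
s1\tm5\tY\t100000\tNaN\tNaN
s1\tm6\t15\t5000\t0.47\t0.05
s1\tm7\t15\t6000\t0.02\t0.01
s1\tm8\t25\t7000\t1.0\t-0.11
s1\tm9\t5\t300\t0.51\tNaN
s1\tm10\t7\t400\t0.5\t0.0
"""


class TestFinalReport:
    def test_well_formed_file_parses_fully(self):
        df = read_final_report(io.StringIO(FINAL_REPORT))
        assert len(df) == 10
        assert df["position"].dtype == np.int64

    def test_nan_lrr_becomes_missing(self):
        df = read_final_report(io.StringIO(FINAL_REPORT))
        assert np.isnan(df.loc[df.snp_name == "m9", "lrr"]).all()
        assert np.isnan(df.loc[df.snp_name == "m5", "baf"]).all()

    def test_missing_column_raises(self):
        bad = FINAL_REPORT.replace("B Allele Freq", "BAF-ish")
        with pytest.raises(ValueError, match="missing required"):
            read_final_report(io.StringIO(bad))

    def test_column_order_is_free(self):
        df0 = read_final_report(io.StringIO(FINAL_REPORT))
        lines = FINAL_REPORT.strip().split("\n")
        reordered = "\n".join(
            "\t".join(row.split("\t")[i] for i in [3, 0, 5, 1, 4, 2]) for row in lines
        )
        df1 = read_final_report(io.StringIO(reordered))
        assert (df0["baf"].fillna(-1) == df1["baf"].fillna(-1)).all()

    def test_simulator_round_trip_at_4_decimals(self, small_config, small_marker_map):
        from equicna.karyotype import KARYOTYPES
        from equicna.simulate import simulate_individual

        sim = simulate_individual(
            KARYOTYPES["64,XY"], small_config, tissues=("blood",),
            individual_id="rt", marker_map=small_marker_map,
        )
        rec = sim.tissues["blood"].records
        buf = io.StringIO()
        write_final_report(rec, buf)
        buf.seek(0)
        back = read_final_report(buf)
        assert len(back) == len(rec)
        np.testing.assert_allclose(
            back["baf"].to_numpy(), np.round(rec["baf"].to_numpy(), 4), equal_nan=True
        )
        np.testing.assert_allclose(
            back["lrr"].to_numpy(), np.round(rec["lrr"].to_numpy(), 4), equal_nan=True
        )


class TestPartition:
    def test_par_boundary_is_inclusive(self):
        df = frame(["X", "X", "7"], [1_860_000, 1_860_001, 500])
        out = partition_regions(df)
        assert list(out["PAR"]["position"]) == [1_860_000]
        assert list(out["NONPAR"]["position"]) == [1_860_001]

    def test_off_panel_chromosome_dropped(self):
        df = frame(["7"], [500])
        out = partition_regions(df)
        assert all(len(v) == 0 for v in out.values())

    def test_x_records_conserved(self, marker_map, sim_config):
        from equicna.karyotype import KARYOTYPES
        from equicna.simulate import simulate_individual

        sim = simulate_individual(
            KARYOTYPES["64,XX"], sim_config, tissues=("blood",),
            individual_id="cons", marker_map=marker_map,
        )
        rec = sim.tissues["blood"].records
        out = partition_regions(rec)
        n_x = ((rec.chrom == "X") & (rec.position <= 128_210_000)).sum()
        assert len(out["PAR"]) + len(out["NONPAR"]) == n_x


class TestRegionStats:
    def test_het_window_counts_half_open(self):
        df = frame("5", [1, 2, 3, 4], baf=[0.0, 0.5, 1.0, 0.3], lrr=[0, 0, 0, 0])
        s = region_stats(df, "ECA5", min_markers=1)
        assert s.het_pct == pytest.approx(50.0)
        assert s.mean_lrr == pytest.approx(0.0)

    def test_window_bounds_are_strict(self):
        df = frame("5", [1, 2], baf=[0.25, 0.75], lrr=[0, 0])
        s = region_stats(df, "ECA5", min_markers=1)
        assert s.het_pct == 0.0

    def test_no_usable_markers(self):
        df = frame("Y", [1, 2], baf=[np.nan, np.nan], lrr=[np.nan, np.nan])
        s = region_stats(df, "Y")
        assert s.insufficient and s.het_pct is None

    def test_insufficient_flag_still_reports(self):
        df = frame("Y", list(range(10)), baf=np.linspace(0.3, 0.7, 10))
        s = region_stats(df, "Y", min_markers=50)
        assert s.insufficient and s.het_pct is not None

    @given(st.permutations(list(range(8))))
    def test_het_invariant_to_marker_order(self, perm):
        baf = np.array([0.1, 0.3, 0.5, 0.7, 0.9, 0.26, 0.74, 0.5])
        df = frame("5", list(range(8)), baf=baf[perm], lrr=np.zeros(8))
        s = region_stats(df, "ECA5", min_markers=1)
        assert s.het_pct == pytest.approx(100 * 6 / 8)

    @given(st.lists(st.floats(-2, 2), min_size=6, max_size=6))
    def test_het_ignores_lrr_and_lrr_ignores_baf(self, lrr):
        baf = np.array([0.1, 0.4, 0.5, 0.6, 0.9, 0.5])
        df = frame("5", list(range(6)), baf=baf, lrr=np.asarray(lrr))
        s = region_stats(df, "ECA5", min_markers=1)
        assert s.het_pct == pytest.approx(100 * 4 / 6)
        assert s.mean_lrr == pytest.approx(np.mean(lrr))


def synthetic_stats(het, lrr, dip, n=500):
    return {
        name: RegionStats(name, n, *vals, insufficient=False)
        for name, vals in {
            "ECA5": (het[0], lrr[0], dip[0]),
            "ECA15": (het[1], lrr[1], dip[1]),
            "ECA25": (het[2], lrr[2], dip[2]),
            "PAR": (het[3], lrr[3], dip[3]),
            "NONPAR": (het[4], lrr[4], dip[4]),
            "Y": (het[5], lrr[5], dip[5]),
        }.items()
    }


class TestClassifier:
    def test_published_grid_horse4(self, fixture_tables):
        call = classify_karyotype(fixture_tables["region_stats"]["Horse 4"])
        assert call.label == "65,XXY"
        assert call.par_copies == 3 and call.x_nonpar_copies == 2 and call.y_present

    def test_published_grid_horse1_carries_y_warning(self, fixture_tables):
        call = classify_karyotype(fixture_tables["region_stats"]["Horse 1"])
        assert call.label == "65,XXY" and call.y_copy_warning

    def test_x_monosomy_pattern(self):
        stats = synthetic_stats(
            het=[33, 32, 31, 2.0, 2.0, 50.0],
            lrr=[0.0, 0.01, -0.01, -0.45, -0.45, -1.9],
            dip=[0.9, 0.95, 1.0, 1.0, 1.0, 0.5],
        )
        call = classify_karyotype(stats)
        assert call.label == "63,X" and not call.y_present

    def test_normal_male_pattern(self):
        stats = synthetic_stats(
            het=[33, 32, 31, 30.0, 0.5, 0.5],
            lrr=[0.0, 0.01, -0.01, 0.0, -0.46, -0.44],
            dip=[0.9, 0.95, 1.0, 0.8, 1.0, 1.0],
        )
        call = classify_karyotype(stats)
        assert call.label == "64,XY" and call.y_present and not call.y_copy_warning

    def test_unresolved_pattern_is_ambiguous_with_reasons(self):
        stats = synthetic_stats(
            het=[33, 32, 31, 45.0, 15.0, 0.5],
            lrr=[0.0, 0.01, -0.01, -0.3, -0.3, -0.45],
            dip=[0.9, 0.95, 1.0, 0.5, 0.9, 1.0],
        )
        call = classify_karyotype(stats)
        assert call.label == "ambiguous" and call.warnings

    def test_requires_autosomal_control(self):
        stats = synthetic_stats(
            het=[33, 32, 31, 50, 30, 1],
            lrr=[0, 0, 0, 0.12, 0, -0.4],
            dip=[1, 1, 1, 0.05, 1, 1],
        )
        for r in ("ECA5", "ECA15", "ECA25"):
            s = stats[r]
            stats[r] = RegionStats(r, 0, None, None, None, True)
        with pytest.raises(ValueError):
            classify_karyotype(stats)


class TestTissueAndParents:
    def c(self, label, tissue="blood", sample="s1"):
        from equicna.cna import KaryotypeCall

        return KaryotypeCall(sample, tissue, 2, 2, True, False, label, (), {})

    def test_concordant_confirms_constitutional(self):
        out = compare_tissues(self.c("65,XXY"), self.c("65,XXY", "hair"))
        assert out["concordant"] and out["final_label"] == "65,XXY"

    def test_discordant_defers_to_hair(self):
        out = compare_tissues(self.c("ambiguous"), self.c("64,XX", "hair"))
        assert not out["concordant"]
        assert "chimerism" in out["verdict"]
        assert out["final_label"] == "64,XX"

    def test_same_tissue_rejected(self):
        with pytest.raises(ValueError):
            compare_tissues(self.c("64,XY"), self.c("64,XY"))

    def test_parents_normal_means_de_novo(self):
        out = screen_parents(self.c("64,XY"), self.c("64,XX"))
        assert out["verdict"] == "de novo"

    def test_abnormal_parent_detected(self):
        out = screen_parents(self.c("65,XXY"), self.c("64,XX"))
        assert "parental" in out["verdict"]

    def test_ambiguous_parent_unresolved(self):
        out = screen_parents(self.c("ambiguous"), self.c("64,XX"))
        assert out["verdict"] == "unresolved"


def test_stats_table_renders_two_decimals(fixture_tables):
    table = stats_table(fixture_tables["region_stats"])
    row = table[(table["sample"] == "Horse 3") & (table["statistic"] == "HET (%)")]
    assert row["PAR"].iloc[0] == 50.00
    assert len(table) == 15  # 5 samples x 3 statistics
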