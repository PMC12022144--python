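import numpy as np
import pytest

from admixscan.core import build_site_table
from admixscan.genomics_io import (
    GeneticMap,
    read_ancestry_table,
    read_bed,
    read_phased_vcf,
    select_test_snps,
)
from admixscan.simdata import SweepSimConfig, TractSimConfig, simulate_panel, simulate_tracts, write_msp, write_vcf


VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=1,length=100000>
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tind0\tind1
"""


def write_lines(path, rows):
    path.write_text(VCF_HEADER + "".join(r + "\n" for r in rows))


class TestReadPhasedVcf:
    def test_ref_ancestral_keeps_alt_as_derived(self, tmp_path):
        f = tmp_path / "a.vcf"
        write_lines(f, ["1\t100\t.\tA\tG\t.\tPASS\tAA=A\tGT\t0|1\t1|1"])
        panel, sites = read_phased_vcf(f)
        assert panel.haplotypes.tolist() == [[0], [1], [1], [1]]
        assert sites["ancestral"].iloc[0] == "A" and sites["derived"].iloc[0] == "G"

    def test_alt_ancestral_flips_codes(self, tmp_path):
        f = tmp_path / "a.vcf"
        write_lines(f, ["1\t100\t.\tA\tG\t.\tPASS\tAA=G\tGT\t0|1\t1|1"])
        panel, sites = read_phased_vcf(f)
        assert panel.haplotypes.tolist() == [[1], [0], [0], [0]]
        assert sites["derived_freq"].iloc[0] == 0.25

    def test_polarization_flip_is_involution(self, tmp_path):
        """Flipping AA between REF and ALT inverts codes and maps f -> 1-f."""
        fa, fb = tmp_path / "a.vcf", tmp_path / "b.vcf"
        write_lines(fa, ["1\t100\t.\tA\tG\t.\tPASS\tAA=A\tGT\t0|1\t0|0"])
        write_lines(fb, ["1\t100\t.\tA\tG\t.\tPASS\tAA=G\tGT\t0|1\t0|0"])
        pa, sa = read_phased_vcf(fa)
        pb, sb = read_phased_vcf(fb)
        assert np.array_equal(pa.haplotypes, 1 - pb.haplotypes)
        assert sa["derived_freq"].iloc[0] == 1 - sb["derived_freq"].iloc[0]

    def test_unknown_ancestral_site_dropped(self, tmp_path):
        f = tmp_path / "a.vcf"
        write_lines(
            f,
            [
                "1\t100\t.\tA\tG\t.\tPASS\tAA=C\tGT\t0|1\t1|1",
                "1\t200\t.\tT\tC\t.\tPASS\tAA=T\tGT\t0|1\t0|0",
            ],
        )
        panel, _ = read_phased_vcf(f)
        assert panel.positions_bp.tolist() == [199]  # 0-based

    def test_unphased_genotype_raises_with_context(self, tmp_path):
        f = tmp_path / "a.vcf"
        write_lines(f, ["1\t100\t.\tA\tG\t.\tPASS\tAA=A\tGT\t0|1\t0/1"])
        with pytest.raises(ValueError, match="1:100.*ind1"):
            read_phased_vcf(f)

    def test_singleton_owner_identified(self, tmp_path):
        """10-site VCF with one ALT observed exactly once flags 1 singleton
        with the carrying diploid as owner."""
        rows = [
            f"1\t{100 + 10 * j}\t.\tA\tG\t.\tPASS\tAA=A\tGT\t0|0\t1|1"
            for j in range(9)
        ]
        rows.append("1\t300\t.\tA\tG\t.\tPASS\tAA=A\tGT\t0|1\t0|0")
        f = tmp_path / "a.vcf"
        write_lines(f, rows)
        _, sites = read_phased_vcf(f)
        assert sites["is_singleton"].sum() == 1
        row = sites[sites["is_singleton"]].iloc[0]
        assert row["position_bp"] == 299 and row["singleton_owner"] == 0

    def test_round_trip_through_writer(self, tmp_path):
        panel, sites, _ = simulate_panel(
            SweepSimConfig(Ne=50, n_diploids=5, seq_len_bp=100_000, mu=1e-7, seed=2)
        )
        write_vcf(panel, sites, tmp_path / "p.vcf")
        panel2, sites2 = read_phased_vcf(tmp_path / "p.vcf")
        assert np.array_equal(panel.haplotypes, panel2.haplotypes)
        assert np.array_equal(panel.positions_bp, panel2.positions_bp)


class TestSelectTestSnps:
    def test_midfrequency_three_class_site_selected(self, small_sites):
        idx = select_test_snps(small_sites)
        f = small_sites["derived_freq"].to_numpy()
        assert all(0.05 <= min(x, 1 - x) for x in f[idx])

    def test_maf_bounds_exclude_rare_and_near_fixed(self):
        import pandas as pd

        tab = pd.DataFrame(
            {
                "position_bp": [10, 20, 30],
                "derived_freq": [0.5, 0.96, 0.30],
                "n_hom_anc": [2, 1, 5],
                "n_het": [4, 1, 4],
                "n_hom_der": [2, 8, 0],
                "in_excluded_region": [False] * 3,
            }
        )
        idx = select_test_snps(tab)
        # 0.96 fails the MAF bound; f=0.30 with no derived homozygote fails
        # the three-genotype rule
        assert idx.tolist() == [0]

    def test_excluded_intervals_removed(self, small_sites):
        idx_all = select_test_snps(small_sites)
        idx = select_test_snps(small_sites, excluded=[(0, 600)])
        pos = small_sites["position_bp"].to_numpy()
        assert set(pos[idx]) == {p for p in pos[idx_all] if p >= 600}

    def test_idempotent_and_order_independent(self, small_sites):
        idx1 = select_test_snps(small_sites)
        shuffled = small_sites.sample(frac=1, random_state=0).reset_index(drop=True)
        idx2 = select_test_snps(shuffled)
        assert set(small_sites["position_bp"].to_numpy()[idx1]) == set(
            shuffled["position_bp"].to_numpy()[idx2]
        )

    def test_singletons_never_selected(self, small_panel, small_sites):
        idx = select_test_snps(small_sites, maf_min=0.0)
        assert not small_sites["is_singleton"].to_numpy()[idx].any()


class TestGeneticMap:
    def test_linear_midpoint(self):
        gm = GeneticMap([0, 1_000_000], [0.0, 1.0])
        assert gm(500_000) == pytest.approx(0.5)

    def test_exact_map_point(self):
        gm = GeneticMap([0, 1_000_000, 3_000_000], [0.0, 1.0, 1.5])
        assert gm(1_000_000) == pytest.approx(1.0)

    def test_terminal_slope_extrapolation(self):
        gm = GeneticMap([0, 1_000_000], [0.0, 1.0])
        assert gm(2_000_000) == pytest.approx(2.0)
        assert gm(-500_000) == pytest.approx(-0.5)

    def test_non_monotone_map_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            GeneticMap([0, 100, 50], [0, 1, 2])

    def test_queries_non_decreasing(self, rng):
        gm = GeneticMap([0, 1e6, 2e6, 5e6], [0, 0.5, 0.5, 4.0])
        q = np.sort(rng.uniform(-1e6, 7e6, 100))
        assert (np.diff(gm(q)) >= 0).all()


class TestAncestryTable:
    def test_single_window_constant_matrix(self, tmp_path):
        f = tmp_path / "a.msp.tsv"
        f.write_text(
            "#Subpopulation order/codes: AFR=0\tEUR=1\n"
            "#chm\tspos\tepos\tsgpos\tegpos\tn snps\ts0.0\ts0.1\n"
            "1\t0\t1000\t0.0\t1.0\t10\t0\t0\n"
        )
        am = read_ancestry_table(f, positions_bp=np.array([5, 500, 999]))
        assert (am.codes == 0).all() and am.labels == ["AFR", "EUR"]

    def test_switch_exactly_at_window_boundary(self, tmp_path):
        f = tmp_path / "a.msp.tsv"
        f.write_text(
            "#Subpopulation order/codes: AFR=0\tEUR=1\n"
            "#chm\tspos\tepos\tsgpos\tegpos\tn snps\ts0.0\ts0.1\n"
            "1\t0\t500\t0.0\t0.5\t5\t0\t1\n"
            "1\t500\t1000\t0.5\t1.0\t5\t1\t1\n"
        )
        am = read_ancestry_table(f, positions_bp=np.array([499, 500]))
        assert am.codes[0].tolist() == [0, 1]  # hap 0 switches at 500
        assert am.codes[1].tolist() == [1, 1]

    def test_gap_between_windows_rejected(self, tmp_path):
        f = tmp_path / "a.msp.tsv"
        f.write_text(
            "#Subpopulation order/codes: AFR=0\n"
            "#chm\tspos\tepos\tsgpos\tegpos\tn snps\ts0.0\ts0.1\n"
            "1\t0\t400\t0\t0.4\t4\t0\t0\n"
            "1\t500\t1000\t0.5\t1.0\t5\t0\t0\n"
        )
        with pytest.raises(ValueError, match="gaps/overlaps"):
            read_ancestry_table(f)

    def test_unknown_code_rejected(self, tmp_path):
        f = tmp_path / "a.msp.tsv"
        f.write_text(
            "#Subpopulation order/codes: AFR=0\tEUR=1\n"
            "#chm\tspos\tepos\tsgpos\tegpos\tn snps\ts0.0\ts0.1\n"
            "1\t0\t1000\t0\t1\t5\t0\t7\n"
        )
        with pytest.raises(ValueError, match="unknown ancestry code"):
            read_ancestry_table(f)

    def test_write_read_round_trip(self, tmp_path):
        cfg = TractSimConfig(n_haplotypes=6, K=3, m=(0.5, 0.3, 0.2), g=20, seed=6)
        grid = np.linspace(0, 100, 40)
        am = simulate_tracts(cfg, grid)
        write_msp(am, tmp_path / "t.msp.tsv")
        am2 = read_ancestry_table(tmp_path / "t.msp.tsv", positions_bp=am.positions_bp)
        assert np.array_equal(am.codes, am2.codes)
        assert am2.labels == am.labels


def test_read_bed_skips_headers(tmp_path):
    f = tmp_path / "x.bed"
    f.write_text("track name=x\n1\t100\t200\n#c\n2\t0\t50\n")
    assert read_bed(f) == [("1", 100, 200), ("2", 0, 50)]
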