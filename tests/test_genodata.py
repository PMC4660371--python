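"""EIGENSTRAT I/O, pseudo-haploid calling, merging, pruning, blocks, sexing."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fourstrand import genodata, syndata
from fourstrand.genodata import (
    DIPLOID,
    MISSING,
    PSEUDO_HAPLOID,
    EigenstratParseError,
    GenotypePanel,
    assign_blocks,
    determine_sex,
    ld_prune,
    merge_panels,
    pseudo_haploid_call,
    read_eigenstrat,
    write_eigenstrat,
)


def panel_of(dosages, pops=None, ploidy=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    n = dosages.shape[0]
    pops = pops or [f"pop{i}" for i in range(n)]
    ploidy = ploidy or [DIPLOID] * n
    samples = pd.DataFrame(
        {"id": [f"s{i}" for i in range(n)], "population": pops,
         "ploidy_mode": ploidy, "sex": ["U"] * n}
    )
    return GenotypePanel(dosages, samples)


def snp_table(n, chrom="1", start_cm=0.0, step_cm=1.0):
    return pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(n)],
            "chrom": [chrom] * n,
            "position": [(i + 1) * 100_000 for i in range(n)],
            "genetic_pos": [start_cm + i * step_cm for i in range(n)],
            "allele1": ["A"] * n,
            "allele2": ["G"] * n,
        }
    )


class TestEigenstrat:
    def test_round_trip_lossless(self, small_sim, tmp_path):
        prefix = str(tmp_path / "rt")
        write_eigenstrat(small_sim["panel"], small_sim["snps"], prefix)
        panel, snps = read_eigenstrat(prefix)
        assert np.array_equal(panel.dosages, small_sim["panel"].dosages)
        assert panel.samples["ploidy_mode"].tolist() == (
            small_sim["panel"].samples["ploidy_mode"].tolist()
        )
        pd.testing.assert_frame_equal(
            snps, small_sim["snps"], check_dtype=False, atol=1e-9
        )

    def test_handcrafted_triplet(self, tmp_path):
        # 3 SNPs x 2 samples; '9' is missing
        (tmp_path / "h.geno").write_text("02\n19\n20\n")
        (tmp_path / "h.snp").write_text(
            "rs1 1 0.0001 10000 A G\nrs2 1 0.0002 20000 C T\nrs3 2 0.0001 5000 A C\n"
        )
        (tmp_path / "h.ind").write_text("Ind1 M Pop1\nInd2 F Pop2\n")
        panel, snps = read_eigenstrat(str(tmp_path / "h"))
        expected = np.array([[0, 1, 2], [2, MISSING, 0]], dtype=np.int8)
        assert np.array_equal(panel.dosages, expected)
        assert snps["genetic_pos"].tolist() == [0.01, 0.02, 0.01]  # Morgans -> cM
        assert panel.samples["population"].tolist() == ["Pop1", "Pop2"]
        assert (panel.samples["ploidy_mode"] == DIPLOID).all()

    def test_ragged_geno_line_reports_line_number(self, tmp_path):
        (tmp_path / "b.geno").write_text("02\n1\n")
        (tmp_path / "b.snp").write_text("rs1 1 0.0 1 A G\nrs2 1 0.0 2 A G\n")
        (tmp_path / "b.ind").write_text("I1 M P\nI2 M P\n")
        with pytest.raises(EigenstratParseError, match="line 2"):
            read_eigenstrat(str(tmp_path / "b"))

    def test_invalid_character_rejected(self, tmp_path):
        (tmp_path / "c.geno").write_text("03\n")
        (tmp_path / "c.snp").write_text("rs1 1 0.0 1 A G\n")
        (tmp_path / "c.ind").write_text("I1 M P\nI2 M P\n")
        with pytest.raises(EigenstratParseError):
            read_eigenstrat(str(tmp_path / "c"))


class TestPseudoHaploidCall:
    def test_single_observed_base_is_certain(self):
        snps = snp_table(1)
        pileup = pd.DataFrame(
            {"snp_id": ["rs0"], "countA": [0], "countC": [0], "countG": [5],
             "countT": [0]}
        )
        panel = pseudo_haploid_call(pileup, snps, seed=1)
        assert panel.dosages[0, 0] == 0  # allele1 (A) absent
        assert panel.samples["ploidy_mode"].iloc[0] == PSEUDO_HAPLOID

    def test_triallelic_site_discarded(self):
        snps = snp_table(1)
        pileup = pd.DataFrame(
            {"snp_id": ["rs0"], "countA": [2], "countC": [0], "countG": [1],
             "countT": [1]}
        )
        panel = pseudo_haploid_call(pileup, snps, seed=1)
        assert panel.dosages[0, 0] == MISSING

    def test_zero_depth_site_missing(self):
        snps = snp_table(2)
        pileup = pd.DataFrame(
            {"snp_id": ["rs0"], "countA": [3], "countC": [0], "countG": [1],
             "countT": [0]}
        )
        panel = pseudo_haploid_call(pileup, snps, seed=1)
        assert panel.dosages[0, 1] == MISSING

    def test_allele_chosen_with_base_frequency(self):
        # 10,000 A/G sites with counts {A:3, G:1}: P(call A) = 0.75
        n = 10_000
        snps = snp_table(n)
        pileup = pd.DataFrame(
            {"snp_id": [f"rs{i}" for i in range(n)], "countA": 3, "countC": 0,
             "countG": 1, "countT": 0}
        )
        panel = pseudo_haploid_call(pileup, snps, seed=2)
        n_a = int((panel.dosages[0] == 2).sum())
        _, p = stats.chisquare([n_a, n - n_a], [0.75 * n, 0.25 * n])
        assert p > 0.01


class TestMerge:
    def _modern(self):
        rng = np.random.default_rng(0)
        snps = snp_table(6)
        snps.loc[5, "chrom"] = "X"  # non-autosomal
        dosages = rng.integers(0, 3, size=(7, 6)).astype(np.int8)
        dosages[:, 4] = 0  # monomorphic -> MAF 0
        pops = ["P1"] * 4 + ["P2"] * 3  # P2 too small
        return panel_of(dosages, pops=pops), snps

    def _ancient(self):
        snps = snp_table(6)
        snps.loc[2, ["allele1", "allele2"]] = ["G", "A"]  # swapped coding
        snps.loc[3, ["allele1", "allele2"]] = ["C", "T"]  # incompatible
        dosages = np.array([[2, 0, 2, 2, 0, 2]], dtype=np.int8)
        return (
            panel_of(dosages, pops=["Ancient"], ploidy=[PSEUDO_HAPLOID]),
            snps,
        )

    def test_filters_and_report(self):
        modern, msnps = self._modern()
        ancient, asnps = self._ancient()
        merged, snps, report = merge_panels(ancient, asnps, modern, msnps)
        assert report["non_autosomal_removed"] == 1
        assert report["small_modern_pops_removed"] == ["P2"]
        assert report["maf_zero_removed"] >= 1
        assert report["allele_mismatch_removed"] == 1
        assert "rs3" not in set(snps["snp_id"])  # incompatible alleles
        assert "rs4" not in set(snps["snp_id"])  # MAF 0
        assert "rs5" not in set(snps["snp_id"])  # chrX
        assert set(merged.samples["population"]) == {"Ancient", "P1"}

    def test_swapped_alleles_flip_dosage(self):
        modern, msnps = self._modern()
        ancient, asnps = self._ancient()
        merged, snps, _ = merge_panels(ancient, asnps, modern, msnps)
        j = snps.index[snps["snp_id"] == "rs2"][0]
        # ancient dosage was 2 on G/A coding -> 0 on the modern A/G coding
        assert merged.dosages[0, j] == 0

    def test_no_overlap_is_error(self):
        modern, msnps = self._modern()
        ancient, asnps = self._ancient()
        asnps = asnps.assign(snp_id=[f"other{i}" for i in range(len(asnps))])
        with pytest.raises(ValueError, match="overlap"):
            merge_panels(ancient, asnps, modern, msnps)


class TestLdPrune:
    def test_duplicated_snp_removes_exactly_one(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 3, size=50).astype(np.int8)
        other = rng.integers(0, 3, size=(50, 4)).astype(np.int8)
        dosages = np.column_stack([col, col, other]).astype(np.int8)
        snps = snp_table(6)
        panel = panel_of(dosages)
        kept = ld_prune(panel, snps, window=5, step=2, r2_threshold=0.5)
        assert ("rs0" in kept) != ("rs1" in kept)  # exactly one survivor

    def test_independent_snps_survive_low_threshold(self):
        rng = np.random.default_rng(2)
        p = 0.4
        dosages = rng.binomial(2, p, size=(500, 2)).astype(np.int8)
        panel = panel_of(dosages)
        kept = ld_prune(panel, snp_table(2), window=2, step=1, r2_threshold=0.2)
        assert len(kept) == 2

    def test_matches_naive_greedy_pruning(self):
        rng = np.random.default_rng(3)
        n_snps, n_samp = 8, 60
        base = rng.binomial(2, 0.5, size=(n_samp, n_snps)).astype(np.int8)
        base[:, 1] = base[:, 0]  # perfect LD pair
        base[:, 4] = np.clip(base[:, 3] + rng.binomial(1, 0.1, n_samp), 0, 2)
        panel = panel_of(base)
        snps = snp_table(n_snps)
        kept = ld_prune(panel, snps, window=n_snps, step=1, r2_threshold=0.5)

        # independent naive pass over the full matrix with the same tie-break
        X = base.astype(float)
        maf = np.minimum(X.mean(0) / 2, 1 - X.mean(0) / 2)
        alive = list(range(n_snps))
        while True:
            r = np.corrcoef(X[:, alive].T) ** 2
            np.fill_diagonal(r, 0)
            if np.nanmax(r) <= 0.5:
                break
            i, j = np.unravel_index(np.nanargmax(r), r.shape)
            gi, gj = alive[i], alive[j]
            drop = gi if maf[gi] < maf[gj] else gj if maf[gj] < maf[gi] else max(gi, gj)
            alive.remove(drop)
        assert kept == [f"rs{i}" for i in alive]

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(4)
        dosages = rng.integers(0, 3, size=(40, 10)).astype(np.int8)
        dosages[:, 7] = dosages[:, 2]
        snps = snp_table(10)
        kept1 = ld_prune(panel_of(dosages), snps, window=10, step=4,
                         r2_threshold=0.3)
        perm = rng.permutation(40)
        kept2 = ld_prune(panel_of(dosages[perm]), snps, window=10, step=4,
                         r2_threshold=0.3)
        assert kept1 == kept2

    def test_profiles(self, small_sim):
        with pytest.raises(ValueError, match="profile"):
            genodata.prune_profile(small_sim["panel"], small_sim["snps"], "bogus")


class TestAssignBlocks:
    def test_same_block_within_window(self):
        snps = snp_table(2)
        snps["genetic_pos"] = [0.1, 4.9]
        blocks = assign_blocks(snps, 5.0)
        assert blocks[0] == blocks[1]

    def test_half_open_boundary(self):
        snps = snp_table(2)
        snps["genetic_pos"] = [4.999, 5.0]
        blocks = assign_blocks(snps, 5.0)
        assert blocks[0] != blocks[1]

    def test_blocks_restart_per_chromosome(self):
        c1 = snp_table(12, chrom="1", step_cm=1.0)
        c2 = snp_table(12, chrom="2", step_cm=1.0)
        c2["snp_id"] = [f"c2_{i}" for i in range(12)]
        snps = pd.concat([c1, c2], ignore_index=True)
        blocks = assign_blocks(snps, 5.0)
        # positions 0..11 cM -> 3 windows per chromosome -> 6 total
        assert len(np.unique(blocks)) == 6

    def test_missing_genetic_positions_error(self):
        snps = snp_table(3)
        snps.loc[1, "genetic_pos"] = np.nan
        with pytest.raises(ValueError, match="genetic"):
            assign_blocks(snps)


class TestDetermineSex:
    def test_no_y_reads_is_female(self):
        call = determine_sex(0, 10_000)
        assert call.ry == 0.0 and call.call == "XX"

    def test_half_y_reads_is_male(self):
        call = determine_sex(5_000, 5_000)
        assert call.ry == 0.5 and call.call == "XY"

    def test_intermediate_ratio_indeterminate(self):
        call = determine_sex(45, 955)
        assert call.ry == pytest.approx(0.045)
        assert call.ci95[0] == pytest.approx(0.0322, abs=1e-3)
        assert call.ci95[1] == pytest.approx(0.0579, abs=1e-3)
        assert call.call == "indeterminate"

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError):
            determine_sex(0, 0)
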