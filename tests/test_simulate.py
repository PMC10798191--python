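"""Ground-truth generators: determinism, planted signal, closure."""

import numpy as np
import pandas as pd
import pytest

from recescan.io import read_bed, read_bedpe, read_maf, read_tss_table, write_maf
from recescan.phylo import BASE_INDEX
from recescan.simulate import (RegionSpec, apply_species_dropout, default_tree,
                               element_in_flanks_specs, simulate_alignment,
                               simulate_epigenome, simulate_expression)

CHROM_SIZES = {"chr1": 500_000, "chr2": 500_000}


def _element_grid(n, length=200, spacing=10_000):
    rows = []
    for i in range(n):
        c = "chr1" if i % 2 == 0 else "chr2"
        s = 5000 + (i // 2) * spacing
        rows.append(dict(chrom=c, start=s, end=s + length))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestSimulateAlignment:
    def test_zero_rate_freezes_sequence(self, primate_tree, hky):
        specs = [RegionSpec("chr1", 0, 100, "conserved", rho=0.0)]
        blocks, _ = simulate_alignment(primate_tree, hky, specs, seed=1)
        seqs = set(blocks[0].sequences.values())
        assert len(seqs) == 1  # every species identical to the root draw

    def test_neutral_base_frequencies_match_pi(self, primate_tree, hky):
        specs = [RegionSpec("chr1", 0, 50_000)]
        blocks, _ = simulate_alignment(primate_tree, hky, specs, seed=2)
        counts = np.zeros(4)
        for seq in blocks[0].sequences.values():
            for b, i in BASE_INDEX.items():
                counts[i] += seq.count(b)
        freqs = counts / counts.sum()
        assert np.all(np.abs(freqs - hky.pi) < 0.02)

    def test_same_seed_identical_maf(self, primate_tree, hky, tmp_path):
        specs = element_in_flanks_specs("chr1", 0)
        for name in ("a.maf", "b.maf"):
            blocks, _ = simulate_alignment(primate_tree, hky, specs, seed=7)
            write_maf(blocks, tmp_path / name, CHROM_SIZES)
        assert (tmp_path / "a.maf").read_bytes() == (tmp_path / "b.maf").read_bytes()

    def test_overlapping_specs_rejected(self, primate_tree, hky):
        specs = [RegionSpec("chr1", 0, 100), RegionSpec("chr1", 50, 150)]
        with pytest.raises(ValueError, match="overlapping"):
            simulate_alignment(primate_tree, hky, specs, seed=1)

    def test_truth_records_planted_regions(self, primate_tree, hky):
        specs = element_in_flanks_specs("chr1", 0, regime="accelerated",
                                        rho=0.3, lam=4.0)
        _, truth = simulate_alignment(primate_tree, hky, specs, seed=3)
        assert len(truth) == 1
        assert truth.iloc[0]["name"] == "accelerated"
        assert (truth.iloc[0]["start"], truth.iloc[0]["end"]) == (400, 600)

    def test_maf_round_trip(self, primate_tree, hky, tmp_path):
        specs = element_in_flanks_specs("chr1", 1000)
        blocks, _ = simulate_alignment(primate_tree, hky, specs, seed=4)
        write_maf(blocks, tmp_path / "x.maf", CHROM_SIZES)
        back = read_maf(tmp_path / "x.maf", ref="Homo")
        assert len(back) == len(blocks)
        assert back[0].start == blocks[0].start
        assert back[0].sequences == blocks[0].sequences


class TestDropout:
    def _blocks(self, tree, model, n=30):
        specs = [RegionSpec("chr1", i * 120, i * 120 + 100) for i in range(n)]
        # non-abutting specs: one block each
        blocks, _ = simulate_alignment(tree, model, specs, seed=5)
        return blocks

    def test_zero_dropout_is_identity(self, primate_tree, hky):
        blocks = self._blocks(primate_tree, hky, n=5)
        out, table = apply_species_dropout(blocks, 0.0, seed=1)
        assert all(a.sequences == b.sequences for a, b in zip(blocks, out))
        assert table["passes"].all()

    def test_heavy_dropout_fails_presence_filter(self, primate_tree, hky):
        # P[>=18 of 20 kept at p=0.5] = (1 + 20 + 190) / 2^20 < 3e-4
        blocks = self._blocks(primate_tree, hky, n=30)
        _, table = apply_species_dropout(blocks, 0.5, seed=2,
                                         total_species=primate_tree.n_leaves)
        assert (~table["passes"]).mean() > 0.9

    def test_deterministic_under_seed(self, primate_tree, hky):
        blocks = self._blocks(primate_tree, hky, n=5)
        a, _ = apply_species_dropout(blocks, 0.3, seed=9)
        b, _ = apply_species_dropout(blocks, 0.3, seed=9)
        assert all(x.sequences == y.sequences for x, y in zip(a, b))

    def test_kept_species_never_dropped(self, primate_tree, hky):
        blocks = self._blocks(primate_tree, hky, n=10)
        out, _ = apply_species_dropout(blocks, 0.9, seed=3, keep=("Homo",))
        assert all("Homo" in b.sequences for b in out)


class TestEpigenome:
    def test_null_factor_matches_uniform_rate(self):
        els = _element_grid(40)
        epi = simulate_epigenome(CHROM_SIZES, els, seed=11, n_peaks=2000,
                                 enrichment_factor=1.0, n_genes=30, n_loops=20)
        got = sum(
            ((els["chrom"] == p.chrom) & (els["start"] < p.end) & (els["end"] > p.start)).any()
            for p in epi["peaks"].itertuples(index=False))
        rate = got / len(epi["peaks"])
        p_u = epi["p_uniform"]
        sd = np.sqrt(p_u * (1 - p_u) / 2000)
        assert abs(rate - p_u) < 4 * sd

    def test_planted_enrichment_factor_four(self):
        els = _element_grid(40)
        epi = simulate_epigenome(CHROM_SIZES, els, seed=12, n_peaks=1000,
                                 enrichment_factor=4.0, n_genes=30, n_loops=20)
        got = sum(
            ((els["chrom"] == p.chrom) & (els["start"] < p.end) & (els["end"] > p.start)).any()
            for p in epi["peaks"].itertuples(index=False))
        expect = epi["target_overlap_rate"]
        sd = np.sqrt(expect * (1 - expect) / 1000)
        assert abs(got / 1000 - expect) < 4 * sd
        assert expect == pytest.approx(4 * epi["p_uniform"], rel=1e-9)

    def test_same_seed_identical_outputs(self):
        els = _element_grid(10)
        a = simulate_epigenome(CHROM_SIZES, els, seed=13, n_genes=30, n_loops=20)
        b = simulate_epigenome(CHROM_SIZES, els, seed=13, n_genes=30, n_loops=20)
        for key in ("peaks", "genes", "loops", "loop_truth"):
            pd.testing.assert_frame_equal(a[key], b[key])

    def test_infeasible_geometry_rejected(self):
        with pytest.raises(ValueError):
            simulate_epigenome({"chr1": 100}, _element_grid(0), seed=1,
                               n_peaks=10, peak_width=500, n_genes=1)

    def test_outputs_parse_with_own_readers(self, tmp_path):
        from recescan.io import write_bed, write_bedpe

        els = _element_grid(10)
        epi = simulate_epigenome(CHROM_SIZES, els, seed=14, n_genes=30, n_loops=20)
        write_bed(epi["peaks"], tmp_path / "p.bed")
        write_bedpe(epi["loops"], tmp_path / "l.bedpe")
        epi["genes"].to_csv(tmp_path / "g.tsv", sep="\t", index=False)
        assert len(read_bed(tmp_path / "p.bed")) == len(epi["peaks"])
        assert len(read_bedpe(tmp_path / "l.bedpe")) == len(epi["loops"])
        assert len(read_tss_table(tmp_path / "g.tsv")) == len(epi["genes"])


class TestExpression:
    def test_flat_when_beta_zero(self):
        genes = [f"G{i}" for i in range(50)]
        expr, meta = simulate_expression(genes, seed=20, trend_genes=genes[:10],
                                         beta=0.0)
        from recescan.trajectory import corrected_trajectory, trajectory_age_correlation

        traj = corrected_trajectory(expr, meta, genes[:10])
        rho, p = trajectory_age_correlation(traj)
        assert abs(rho) < 0.4

    def test_deterministic_under_seed(self):
        genes = [f"G{i}" for i in range(20)]
        a, _ = simulate_expression(genes, seed=21)
        b, _ = simulate_expression(genes, seed=21)
        pd.testing.assert_frame_equal(a, b)

    def test_needs_three_ages(self):
        with pytest.raises(ValueError, match="ages"):
            simulate_expression(["G1"], seed=1, n_samples=2)

    def test_unknown_trend_gene_rejected(self):
        with pytest.raises(ValueError, match="trend genes"):
            simulate_expression(["G1"], seed=1, trend_genes=["NOPE"])
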