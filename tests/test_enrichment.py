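"""Region classification, size-matched controls, Fisher/binomial enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from recescan.enrichment import (CATEGORIES, GenomeAnnotation,
                                 binomial_enrichment, classify_elements,
                                 classify_region, count_overlapping,
                                 fisher_enrichment, sample_matched_controls,
                                 _table_or)

SIZES = {"chr1": 100_000, "chr2": 100_000}


@pytest.fixture()
def annotation():
    genes = pd.DataFrame([
        # + strand gene: TSS 20000, TES 30000, 2 exons, CDS 21000-28500
        dict(gene_id="gA", chrom="chr1", strand="+", tss=20_000, tes=30_000,
             exons="20000-22000,28000-30000", cds_start=21_500, cds_end=28_500),
        # - strand gene on chr2
        dict(gene_id="gB", chrom="chr2", strand="-", tss=50_000, tes=40_000,
             exons="40000-42000,48000-50000", cds_start=41_000, cds_end=49_000),
    ])
    return GenomeAnnotation(SIZES, genes)


class TestClassifyRegion:
    def test_promoter_wins(self, annotation):
        assert classify_region("chr1", 18_500, 18_600, annotation) == "Promoter"

    def test_promoter_beats_other_features(self, annotation):
        # stretches from the promoter window into the first exon/UTR
        assert classify_region("chr1", 19_000, 22_000, annotation) == "Promoter"

    def test_five_prime_utr(self, annotation):
        # exonic, 5' of the CDS start, outside the promoter window
        assert classify_region("chr1", 21_100, 21_300, annotation) == "5'UTR"

    def test_three_prime_utr(self, annotation):
        assert classify_region("chr1", 28_600, 28_700, annotation) == "3'UTR"

    def test_exon_cds(self, annotation):
        assert classify_region("chr1", 21_500, 21_600, annotation) == "Exon"

    def test_intron(self, annotation):
        assert classify_region("chr1", 25_000, 25_100, annotation) == "Intron"

    def test_downstream_within_3kb(self, annotation):
        assert classify_region("chr1", 31_000, 31_100, annotation) == "Downstream"

    def test_distal_intergenic(self, annotation):
        assert classify_region("chr1", 80_000, 80_100, annotation) == "Distal Intergenic"

    def test_minus_strand_promoter(self, annotation):
        # gB promoter: [50000-1000, 50000+2000) = [49000, 52000)
        assert classify_region("chr2", 51_500, 51_600, annotation) == "Promoter"

    def test_unknown_chromosome(self, annotation):
        with pytest.raises(KeyError):
            classify_region("chrZ", 0, 10, annotation)

    def test_partition_property(self, annotation, rng):
        starts = rng.integers(0, 99_000, size=100)
        els = pd.DataFrame({"chrom": rng.choice(["chr1", "chr2"], 100),
                            "start": starts, "end": starts + 100})
        cats = classify_elements(els, annotation)
        assert len(cats) == 100
        assert set(cats) <= set(CATEGORIES)
        assert cats.value_counts().sum() == 100


class TestMatchedControls:
    def _elements(self):
        return pd.DataFrame({"chrom": ["chr1", "chr1", "chr2"],
                             "start": [10, 1000, 5000],
                             "end": [110, 1500, 5024]})

    def test_length_multiset_preserved(self):
        els = self._elements()
        sets = sample_matched_controls(els, SIZES, n_sets=20, seed=1)
        want = sorted(els["end"] - els["start"])
        for s in sets:
            assert sorted(s["end"] - s["start"]) == want

    def test_within_bounds_and_exclusions(self):
        els = self._elements()
        excl = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [90_000]})
        sets = sample_matched_controls(els, SIZES, n_sets=10, seed=2,
                                       exclusions=excl)
        for s in sets:
            for r in s.itertuples(index=False):
                assert 0 <= r.start < r.end <= SIZES[r.chrom]
                if r.chrom == "chr1":
                    assert r.start >= 90_000

    def test_seed_reproducibility(self):
        els = self._elements()
        a = sample_matched_controls(els, SIZES, n_sets=5, seed=3)
        b = sample_matched_controls(els, SIZES, n_sets=5, seed=3)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_impossible_length_reported(self):
        els = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [200_001]})
        with pytest.raises(ValueError, match="200001"):
            sample_matched_controls(els, SIZES, n_sets=2, seed=1)


class TestFisher:
    def test_single_table_or_and_p_match_hypergeom(self):
        # 2x2 table (10, 90 / 5, 95): OR and two-sided p from first principles
        assert _table_or(10, 90, 5, 95) == pytest.approx(950 / 450)
        from scipy.stats import fisher_exact

        _, p = fisher_exact([[10, 90], [5, 95]], alternative="two-sided")
        # oracle: sum of hypergeometric probabilities <= P(observed)
        M, n, N = 200, 15, 100  # total, successes (10+5), first-group size
        p0 = hypergeom.pmf(10, M, n, N)
        oracle = sum(hypergeom.pmf(k, M, n, N)
                     for k in range(max(0, n - (M - N)), min(n, N) + 1)
                     if hypergeom.pmf(k, M, n, N) <= p0 * (1 + 1e-12))
        assert p == pytest.approx(oracle, abs=1e-10)

    def test_identical_counts_give_unit_or(self):
        els = pd.DataFrame({"chrom": ["chr1"] * 10,
                            "start": np.arange(10) * 1000,
                            "end": np.arange(10) * 1000 + 100})
        feats = els.copy()  # query overlap = 10/10
        controls = [els.copy() for _ in range(5)]  # control overlap = 10/10
        res = fisher_enrichment(els, controls, feats)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_empty_feature_set_flagged(self):
        els = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        res = fisher_enrichment(els, [els.copy()],
                                pd.DataFrame(columns=["chrom", "start", "end"]))
        assert res.flagged and np.isnan(res.odds_ratio)


class TestBinomial:
    def test_upper_tail_matches_summation(self):
        els = pd.DataFrame({"chrom": ["chr1"] * 100,
                            "start": np.arange(100) * 500,
                            "end": np.arange(100) * 500 + 100})
        # feature overlapping exactly the first 50 elements
        feats = els.iloc[:50][["chrom", "start", "end"]]
        # control sets overlapping exactly 25 of their 100
        ctl = els.copy()
        ctl["start"] += 10_000_000  # move off all features
        ctl.loc[ctl.index[:25], "start"] = feats["start"].to_numpy()[:25]
        ctl.loc[ctl.index[:25], "end"] = ctl.loc[ctl.index[:25], "start"] + 100
        res = binomial_enrichment(els, [ctl], {"cat": feats})
        from math import comb

        oracle = sum(comb(100, k) * 0.25 ** k * 0.75 ** (100 - k)
                     for k in range(50, 101))
        assert res.iloc[0]["p_value"] == pytest.approx(oracle, abs=1e-12)
        assert res.iloc[0]["observed"] == 50

    def test_k_at_expectation_is_not_significant(self):
        from scipy.stats import binom

        p = float(binom.sf(25 - 1, 100, 0.25))
        assert 0.35 < p < 0.65

    def test_single_category_adjusted_equals_raw(self):
        els = pd.DataFrame({"chrom": ["chr1"] * 4, "start": [0, 10, 20, 30],
                            "end": [5, 15, 25, 35]})
        feats = els.iloc[:2][["chrom", "start", "end"]]
        ctl = els.copy()
        res = binomial_enrichment(els, [ctl], {"only": feats})
        assert res.iloc[0]["adjusted_p"] == pytest.approx(res.iloc[0]["p_value"])


class TestOverlapCounting:
    def test_matches_brute_force(self, rng):
        for _ in range(5):
            n, m = rng.integers(5, 200), rng.integers(5, 200)
            a_start = rng.integers(0, 10_000, n)
            b_start = rng.integers(0, 10_000, m)
            a = pd.DataFrame({"chrom": rng.choice(["c1", "c2"], n),
                              "start": a_start,
                              "end": a_start + rng.integers(1, 500, n)})
            b = pd.DataFrame({"chrom": rng.choice(["c1", "c2"], m),
                              "start": b_start,
                              "end": b_start + rng.integers(1, 500, m)})
            brute = sum(
                any(ra.chrom == rb.chrom and ra.start < rb.end and ra.end > rb.start
                    for rb in b.itertuples(index=False))
                for ra in a.itertuples(index=False))
            assert count_overlapping(a, b) == brute
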