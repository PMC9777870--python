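"""Interval arithmetic, overlap search, permutation nulls, annotation."""

import numpy as np
import pandas as pd
import pytest

from dasekit.integration import (
    annotate_dase,
    find_overlaps,
    permutation_overlap_test,
    snp_to_interval,
    window_around,
)

GENOME = {"1": 10_000_000, "2": 5_000_000}


def track(rows):
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


class TestWindowAround:
    def test_interior_window_arithmetic(self):
        w = window_around("1", 300_001, GENOME, width=200_000)
        assert (w.start, w.end) == (100_000, 500_001)

    def test_clamped_near_start(self):
        w = window_around("1", 50_000, GENOME, width=200_000)
        assert (w.start, w.end) == (0, 250_000)

    def test_width_zero_is_single_base(self):
        w = window_around("1", 1234, GENOME, width=0)
        assert (w.start, w.end) == (1233, 1234)
        s = snp_to_interval("1", 1234)
        assert (s.start, s.end) == (w.start, w.end)

    def test_monotone_in_width(self):
        widths = [0, 10, 1000, 10**6]
        wins = [window_around("1", 5_000_000, GENOME, width=w) for w in widths]
        for a, b in zip(wins, wins[1:]):
            assert b.start <= a.start and b.end >= a.end

    def test_unknown_chromosome_is_hard_error(self):
        with pytest.raises(KeyError, match="chrX"):
            window_around("chrX", 100, GENOME)


class TestFindOverlaps:
    def test_half_open_boundary_semantics(self):
        q = track([("1", 0, 10)])
        assert find_overlaps(q, track([("1", 10, 20)])).empty
        assert len(find_overlaps(q, track([("1", 9, 20)]))) == 1

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)

        def random_track(n):
            contig = rng.choice(["1", "2"], size=n)
            start = rng.integers(0, 10_000, size=n)
            length = rng.integers(1, 500, size=n)
            return pd.DataFrame({"contig": contig, "start": start, "end": start + length})

        for n in (50, 300, 1000):
            q, r = random_track(n), random_track(n)
            got = find_overlaps(q, r)
            got_pairs = set(zip(got["query_index"], got["ref_index"]))
            brute = {
                (qi, ri)
                for qi, qrow in q.iterrows()
                for ri, rrow in r.iterrows()
                if qrow["contig"] == rrow["contig"]
                and qrow["start"] < rrow["end"]
                and rrow["start"] < qrow["end"]
            }
            assert got_pairs == brute


class TestPermutationOverlapTest:
    def test_self_overlap_is_maximally_enriched(self):
        q = track([("1", i * 1_000_000, i * 1_000_000 + 100) for i in range(1, 9)])
        r = permutation_overlap_test(q, q, GENOME, n_perm=200, seed=0)
        assert r.observed == len(q)
        assert r.p_value == pytest.approx(1 / 201)

    def test_reference_covering_genome_gives_p_one(self):
        q = track([("1", 100, 200), ("2", 300, 350)])
        ref = track([("1", 0, GENOME["1"]), ("2", 0, GENOME["2"])])
        r = permutation_overlap_test(q, ref, GENOME, n_perm=100, seed=0)
        assert r.observed == 2
        assert r.p_value == 1.0

    def test_permutation_mean_matches_analytic_coverage(self):
        # 50 single-base queries vs a reference covering 20% of one chromosome:
        # each permuted placement hits with probability ~0.2
        genome = {"1": 1_000_000}
        q = track([("1", i * 100, i * 100 + 1) for i in range(50)])
        ref = track([("1", 0, 200_000)])
        r = permutation_overlap_test(q, ref, genome, n_perm=1000, seed=3)
        se = np.sqrt(0.2 * 0.8 / 50) / np.sqrt(1000) * 50
        assert abs(r.perm_mean / 50 - 0.2) < 0.02

    def test_seed_reproducibility(self):
        q = track([("1", i * 10_000, i * 10_000 + 100) for i in range(30)])
        ref = track([("1", 0, 2_000_000)])
        a = permutation_overlap_test(q, ref, GENOME, n_perm=300, seed=11)
        b = permutation_overlap_test(q, ref, GENOME, n_perm=300, seed=11)
        assert a == b
        assert a.perm_sd > 0 and np.isfinite(a.z)

    def test_query_longer_than_chromosome_rejected(self):
        q = track([("2", 0, GENOME["2"] + 1)])
        with pytest.raises(ValueError, match="longer than"):
            permutation_overlap_test(q, track([("2", 0, 10)]), GENOME, n_perm=10, seed=0)


class TestAnnotateDase:
    def results(self):
        return pd.DataFrame(
            {
                "snp_id": ["s1", "s2", "s3"],
                "trait": "T",
                "contig": "1",
                "position": [150, 500, 5000],  # 1-based
                "fdr": [0.01, 0.01, 0.5],
                "log2fc": [1.0, -1.0, 0.2],
            }
        )

    def test_snp_in_feature_uses_coordinate_conversion(self):
        # 1-based position p inside 0-based feature [p-1, p)
        tracks = {"mark": track([("1", 149, 150)])}
        out, _ = annotate_dase(self.results(), tracks=tracks, genome_sizes=GENOME, width=100)
        assert out.loc[out["snp_id"] == "s1", "mark_snp_in_feature"].item()
        assert not out.loc[out["snp_id"] == "s2", "mark_snp_in_feature"].item()

    def test_window_flags_match_hand_enumeration(self):
        # width 100: s1 window [49,250), s2 [399,600), s3 [4899,5100)
        tracks = {"mark": track([("1", 240, 260), ("1", 4000, 4500)])}
        out, _ = annotate_dase(self.results(), tracks=tracks, genome_sizes=GENOME, width=100)
        flags = out.set_index("snp_id")["mark_feature_in_window"]
        assert flags["s1"] and not flags["s2"] and not flags["s3"]

    def test_empty_track_completes_with_false_flags(self):
        tracks = {"empty": track([])}
        out, per_gene = annotate_dase(self.results(), tracks=tracks, genome_sizes=GENOME)
        assert not out["empty_snp_in_feature"].any()

    def test_gene_assignment_and_per_gene_counts(self):
        genes = pd.DataFrame(
            {"contig": ["1", "1"], "start": [0, 400], "end": [300, 600],
             "gene_id": ["GENE_A", "GENE_B"]}
        )
        out, per_gene = annotate_dase(self.results(), gene_map=genes, genome_sizes=GENOME)
        assert out.set_index("snp_id")["gene_id"]["s1"] == "GENE_A"
        assert out.set_index("snp_id")["gene_id"]["s2"] == "GENE_B"
        # significant SNPs only (fdr <= 0.05): one per gene
        assert dict(zip(per_gene["gene_id"], per_gene["n_dase_snps"])) == {
            "GENE_A": 1, "GENE_B": 1,
        }

    def test_contig_mismatch_is_hard_error_listing_names(self):
        tracks = {"mark": track([("chr1", 0, 100)])}
        with pytest.raises(ValueError, match="chr1"):
            annotate_dase(self.results(), tracks=tracks, genome_sizes=GENOME)


def test_null_permutation_pvalues_super_uniform():
    """Independent uniform tracks: p < 0.05 in at most ~5% of replicate tests."""
    rng = np.random.default_rng(21)
    genome = {"1": 2_000_000}
    n_sig = 0
    reps = 100
    for _ in range(reps):
        qs = rng.integers(0, genome["1"] - 200, size=30)
        rs = rng.integers(0, genome["1"] - 2000, size=40)
        q = pd.DataFrame({"contig": "1", "start": qs, "end": qs + 200})
        ref = pd.DataFrame({"contig": "1", "start": rs, "end": rs + 2000})
        r = permutation_overlap_test(q, ref, genome, n_perm=200, seed=int(rng.integers(2**31)))
        if r.p_value < 0.05:
            n_sig += 1
    assert n_sig / reps <= 0.08
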