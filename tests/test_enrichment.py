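"""Interval overlap counting, permutation reshuffle, SD/repeat/gene summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from clonecnv import (
    GenomeDef,
    Interval,
    IntervalSet,
    annotate_genes,
    count_overlaps,
    permutation_overlap_test,
    permute_intervals,
    repeat_fraction_profile,
    sd_overlap_summary,
)
from clonecnv.simulate import simulate_repeat_coverage

GENOME = GenomeDef([("chr1", 1_000_000), ("chr2", 1_000_000)])


def iset(triples, genome=GENOME):
    return IntervalSet(
        [Interval(c, s, e, name=f"i{k}") for k, (c, s, e) in enumerate(triples)], genome
    )


class TestCountOverlaps:
    def test_positive_intersection_counts(self):
        n, _ = count_overlaps(iset([("chr1", 100, 200)]), iset([("chr1", 150, 300)]))
        assert n == 1

    def test_half_open_abutment_does_not_count(self):
        n, _ = count_overlaps(iset([("chr1", 100, 200)]), iset([("chr1", 200, 300)]))
        assert n == 0

    def test_query_interval_counts_once_despite_multiple_hits(self):
        q = iset([("chr1", 0, 500_000)])
        db = iset([("chr1", 10, 20), ("chr1", 100, 200), ("chr1", 1000, 2000)])
        n, ann = count_overlaps(q, db)
        assert n == 1
        assert ann.loc[0, "overlap_bp"] == 10 + 100 + 1000

    def test_count_is_per_query_not_symmetric(self):
        a = iset([("chr1", 0, 100), ("chr1", 200, 300)])
        b = iset([("chr1", 0, 300)])
        assert count_overlaps(a, b)[0] == 2
        assert count_overlaps(b, a)[0] == 1

    def test_min_bp_threshold(self):
        q = iset([("chr1", 100, 200)])
        db = iset([("chr1", 195, 400)])
        assert count_overlaps(q, db, min_bp=5)[0] == 1
        assert count_overlaps(q, db, min_bp=6)[0] == 0

    def test_mismatched_genomes_rejected(self):
        other = GenomeDef([("chr1", 2_000_000)])
        with pytest.raises(ValueError, match="different genome"):
            count_overlaps(iset([("chr1", 0, 10)]), iset([("chr1", 0, 10)], other))


class TestPermuteIntervals:
    def test_lengths_and_counts_preserved(self):
        q = iset([("chr1", 0, 1000), ("chr1", 5000, 9000), ("chr2", 100, 200)])
        p = permute_intervals(q, seed=1)
        assert sorted((iv.chromosome, iv.length) for iv in p) == sorted(
            (iv.chromosome, iv.length) for iv in q
        )

    def test_interval_never_changes_chromosome(self):
        q = iset([("chr1", 0, 50_000)])
        for seed in range(50):
            assert all(iv.chromosome == "chr1" for iv in permute_intervals(q, seed))

    def test_chromosome_sized_interval_forced_in_place(self):
        q = iset([("chr1", 0, 1_000_000)])
        p = permute_intervals(q, seed=3)
        assert p.intervals[0].start == 0 and p.intervals[0].end == 1_000_000

    def test_start_distribution_uniform(self):
        # 1 kb interval on a 1 Mb chromosome: start ~ Uniform{0..999000}
        q = iset([("chr1", 0, 1000)])
        starts = [permute_intervals(q, seed).intervals[0].start for seed in range(10_000)]
        ks = stats.kstest(np.array(starts) / 999_000, "uniform")
        assert ks.pvalue > 0.01


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 2))
def test_permutation_preserves_every_length_exactly(seed):
    rng = np.random.default_rng(seed)
    triples = []
    for _ in range(rng.integers(1, 10)):
        chrom = ("chr1", "chr2")[rng.integers(0, 2)]
        size = int(rng.integers(1, 500_000))
        s = int(rng.integers(0, 1_000_000 - size))
        triples.append((chrom, s, s + size))
    q = iset(triples)
    p = permute_intervals(q, seed)
    per_chrom = lambda x: sorted((iv.chromosome, iv.length) for iv in x)
    assert per_chrom(p) == per_chrom(q)
    for iv in p:
        assert 0 <= iv.start < iv.end <= 1_000_000


class TestPermutationTest:
    def test_full_coverage_db_gives_all_ties_p_zero(self):
        q = iset([("chr1", 100, 200), ("chr2", 100, 200)])
        db = iset([("chr1", 0, 1_000_000), ("chr2", 0, 1_000_000)])
        res = permutation_overlap_test(q, db, n_iter=1000, seed=0)
        # permuted counts always tie with the observed; ties are not "greater"
        assert res.n_greater == 0 and res.p_value == 0.0
        assert res.reported_string == "< 0.001"

    def test_engineered_enrichment_reports_floor(self, perm_genome, known_cnv_db):
        ivs = [
            Interval(iv.chromosome, iv.start, min(iv.start + 10_000, iv.end), name=f"e{k}")
            for k, iv in enumerate(list(known_cnv_db)[:30])
        ]
        q = IntervalSet(ivs, perm_genome)
        res = permutation_overlap_test(q, known_cnv_db, n_iter=1000, seed=5)
        assert res.observed_overlap_count == 30
        assert res.reported_string == "< 0.001"

    def test_empty_query_is_an_error(self):
        db = iset([("chr1", 0, 100)])
        with pytest.raises(ValueError, match="empty query"):
            permutation_overlap_test(iset([]), db, n_iter=10, seed=0)

    def test_deterministic_given_seed(self):
        q = iset([("chr1", 0, 100_000), ("chr2", 50_000, 90_000)])
        db = iset([("chr1", 200_000, 400_000), ("chr2", 0, 60_000)])
        a = permutation_overlap_test(q, db, n_iter=200, seed=7)
        b = permutation_overlap_test(q, db, n_iter=200, seed=7)
        assert (a.observed_overlap_count, a.n_greater) == (b.observed_overlap_count, b.n_greater)


class TestSdSummary:
    def test_disjoint_sets_zero(self):
        cnvs = iset([("chr1", 0, 1000)])
        sds = iset([("chr2", 0, 1000)])
        assert sd_overlap_summary(cnvs, sds) == (0, 0, 0.0)

    def test_superset_sds_full_fraction(self):
        cnvs = iset([("chr1", 100, 200), ("chr2", 100, 300)])
        sds = iset([("chr1", 0, 1_000_000), ("chr2", 0, 1_000_000)])
        n, length, frac = sd_overlap_summary(cnvs, sds)
        assert (n, length, frac) == (2, 300, 1.0)

    def test_partial_overlap_counts_full_cnv_lengths(self):
        # 48-of-72 structure: overlapped length sums whole CNVs that touch an SD
        cnvs = iset([("chr1", i * 10_000, i * 10_000 + 1000) for i in range(72)])
        sds = iset([("chr1", i * 10_000, i * 10_000 + 10) for i in range(48)])
        n, length, frac = sd_overlap_summary(cnvs, sds)
        assert n == 48
        assert length == 48 * 1000
        assert frac == pytest.approx(48 / 72)


class TestRepeatProfile:
    def test_full_coverage_gives_unit_fraction(self):
        cnvs = iset([("chr1", 100_000, 200_000)])
        reps = IntervalSet([Interval("chr1", 0, 1_000_000, cls="LINE")], GENOME)
        prof = repeat_fraction_profile(cnvs, reps)
        row = prof[(prof.region == "intraCNV") & (prof["class"] == "LINE")]
        assert row.fraction.iloc[0] == 1.0

    def test_no_repeats_zero_everywhere(self):
        cnvs = iset([("chr1", 100_000, 200_000)])
        prof = repeat_fraction_profile(cnvs, iset([]))
        assert (prof.fraction == 0).all()

    def test_flank_bands_are_disjoint_and_clipped(self):
        cnvs = iset([("chr1", 400_000, 500_000), ("chr1", 520_000, 600_000)])
        prof = repeat_fraction_profile(cnvs, iset([]), flank_offsets=(10_000, 100_000))
        regions = dict(zip(prof.region, prof.region_bp))
        # the 20 kb gap between the CNVs contributes 10 kb to each CNV's near band
        assert regions["flank@0-10000bp"] == 10_000 + 10_000 + 10_000 + 10_000
        # band totals never exceed the non-CNV genome on that chromosome
        assert sum(set(regions.values())) <= 1_000_000

    def test_recovers_engineered_density_ratio(self):
        # LINE coverage built 2x higher in the near flank than inside the CNV
        genome = GenomeDef([("chr1", 10_000_000)])
        cnvs = IntervalSet([Interval("chr1", 4_000_000, 5_000_000)], genome)
        intra = [Interval("chr1", 4_000_000, 5_000_000)]
        flank = [Interval("chr1", 3_990_000, 4_000_000), Interval("chr1", 5_000_000, 5_010_000)]
        ratios = []
        for seed in range(10):
            reps = IntervalSet(
                simulate_repeat_coverage(genome, intra, 0.2, 500, "LINE", seed=seed)
                + simulate_repeat_coverage(genome, flank, 0.4, 500, "LINE", seed=seed + 100),
                genome,
            )
            prof = repeat_fraction_profile(cnvs, reps, flank_offsets=(10_000,))
            by_region = prof[prof["class"] == "LINE"].set_index("region")["fraction"]
            ratios.append(by_region["flank@0-10000bp"] / by_region["intraCNV"])
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.1)


class TestAnnotateGenes:
    GENES = IntervalSet(
        [
            Interval("chr1", 100, 200, name="GENE_B"),
            Interval("chr1", 50, 120, name="GENE_A"),
            Interval("chr2", 0, 1000, name="GENE_C"),
        ],
        GENOME,
    )

    def test_no_overlap_gives_empty_list(self):
        assert annotate_genes(iset([("chr1", 300, 400)]), self.GENES) == [[]]

    def test_contained_gene_listed_once_sorted_by_start(self):
        out = annotate_genes(iset([("chr1", 40, 250)]), self.GENES)
        assert out == [["GENE_A", "GENE_B"]]

    def test_boundary_spanning_gene_listed(self):
        out = annotate_genes(iset([("chr1", 110, 115)]), self.GENES)
        assert out == [["GENE_A", "GENE_B"]]
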