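import pytest

from clonecnv import GenomeDef, Interval, IntervalSet
from clonecnv.simulate import simulate_annotation_tracks


@pytest.fixture
def small_genome():
    return GenomeDef([("chr1", 8_000_000), ("chr2", 8_000_000)])


@pytest.fixture
def xy_genome():
    """Diploid autosomes plus a single-copy X, as in a male donor."""
    return GenomeDef(
        [("chr1", 8_000_000), ("chrX", 8_000_000)], ploidy_baseline={"chrX": 1}
    )


def make_uniform_query(genome, n, size_lo, size_hi, rng):
    """Query intervals placed uniformly at random: the permutation null."""
    names = genome.names
    ivs = []
    for i in range(n):
        chrom = names[rng.integers(0, len(names))]
        L = genome.length(chrom)
        size = int(rng.integers(size_lo, size_hi))
        s = int(rng.integers(0, L - size + 1))
        ivs.append(Interval(chrom, s, s + size, name=f"q{i}"))
    return IntervalSet(ivs, genome)


@pytest.fixture
def perm_genome():
    return GenomeDef([(f"chr{i + 1}", 10_000_000) for i in range(8)])


@pytest.fixture
def known_cnv_db(perm_genome):
    tracks = simulate_annotation_tracks(
        perm_genome,
        n_intervals={"known_cnv": 240, "sd": 0, "repeat": 0, "gene": 0},
        size_range=(10_000, 100_000),
        seed=42,
    )
    return tracks["known_cnv"]
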