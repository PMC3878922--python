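"""Interval-set overlap statistics for CNV catalogs.

Covers: counting query intervals that share sequence with a database
(any-overlap, >= 1 bp in half-open coordinates), the within-chromosome
reshuffle permutation test for overlap enrichment, segmental-duplication
overlap summaries, repeat-class genomic fractions inside CNVs and in
distance-banded flanking windows, and gene annotation of calls.

The permutation null reshuffles each interval independently to a uniform
start on its own chromosome, preserving every interval's length and each
chromosome's interval count.  Permuted intervals may overlap each other
and their original positions; the empirical p-value counts permutations
whose overlap count is strictly greater than the observed one, and a
zero count is reported as "< 1/n_iter".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import Interval, IntervalSet

__all__ = [
    "PermutationResult",
    "count_overlaps",
    "permute_intervals",
    "permutation_overlap_test",
    "sd_overlap_summary",
    "repeat_fraction_profile",
    "annotate_genes",
]

DEFAULT_FLANK_OFFSETS = (10_000, 100_000, 1_000_000, 10_000_000)


@dataclass(frozen=True)
class PermutationResult:
    observed_overlap_count: int
    n_iter: int
    n_greater: int

    @property
    def p_value(self) -> float:
        return self.n_greater / self.n_iter

    @property
    def reported_string(self) -> str:
        if self.n_greater == 0:
            return f"< {1.0 / self.n_iter:g}"
        return f"{self.p_value:g}"


class _MergedTrack:
    """Merged, sorted intervals per chromosome with coverage prefix sums."""

    def __init__(self, ivs: IntervalSet):
        self.per_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, lst in ivs.by_chromosome().items():
            arr = sorted((iv.start, iv.end) for iv in lst)
            starts, ends = [], []
            for s, e in arr:
                if ends and s <= ends[-1]:
                    ends[-1] = max(ends[-1], e)
                else:
                    starts.append(s)
                    ends.append(e)
            st = np.asarray(starts, dtype=np.int64)
            en = np.asarray(ends, dtype=np.int64)
            cum = np.concatenate([[0], np.cumsum(en - st)])
            self.per_chrom[chrom] = (st, en, cum)

    def coverage_before(self, chrom: str, x: np.ndarray) -> np.ndarray:
        """Total covered bp in [0, x) for each x."""
        if chrom not in self.per_chrom:
            return np.zeros(len(x), dtype=np.int64)
        st, en, cum = self.per_chrom[chrom]
        i = np.searchsorted(st, x, side="right")
        out = np.zeros(len(x), dtype=np.int64)
        nz = i > 0
        ii = i[nz] - 1
        partial = np.minimum(x[nz] - st[ii], en[ii] - st[ii])
        out[nz] = cum[ii] + partial
        return out

    def overlap_bp(self, chrom: str, qs: np.ndarray, qe: np.ndarray) -> np.ndarray:
        return self.coverage_before(chrom, qe) - self.coverage_before(chrom, qs)

    def merged_intervals(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        if chrom not in self.per_chrom:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        st, en, _ = self.per_chrom[chrom]
        return st, en


def _check_same_genome(a: IntervalSet, b: IntervalSet) -> None:
    if not a.same_genome(b):
        raise ValueError("interval sets live on different genome definitions")


def count_overlaps(
    query: IntervalSet, db: IntervalSet, min_bp: int = 1
) -> tuple[int, pd.DataFrame]:
    """Count query intervals sharing >= min_bp of sequence with the database.

    Each query interval counts at most once no matter how many database
    intervals it hits.  Returns the count and a per-interval annotation
    table (interval, overlap bp, hit flag).  Asymmetric by design: the
    count is over *query* intervals.
    """
    _check_same_genome(query, db)
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    track = _MergedTrack(db)
    rows = []
    for iv in query:
        ov = int(
            track.overlap_bp(
                iv.chromosome, np.asarray([iv.start]), np.asarray([iv.end])
            )[0]
        )
        rows.append((iv.chromosome, iv.start, iv.end, iv.name, ov, ov >= min_bp))
    ann = pd.DataFrame(
        rows, columns=["chromosome", "start", "end", "name", "overlap_bp", "hit"]
    )
    return int(ann["hit"].sum()), ann


def permute_intervals(query: IntervalSet, seed: int = 0) -> IntervalSet:
    """Reshuffle each interval to a uniform start on its own chromosome.

    Sizes and per-chromosome interval counts are preserved exactly; an
    interval as long as its chromosome has only one possible placement.
    """
    rng = np.random.default_rng(seed)
    out: list[Interval] = []
    for iv in query:
        L = query.genome.length(iv.chromosome)
        span = iv.length
        if span > L:
            raise ValueError(
                f"interval {iv.name or iv.chromosome} longer than its chromosome"
            )
        start = int(rng.integers(0, L - span + 1))
        out.append(Interval(iv.chromosome, start, start + span, name=iv.name, cls=iv.cls))
    return IntervalSet(out, query.genome, name=query.name)


def permutation_overlap_test(
    query: IntervalSet,
    db: IntervalSet,
    n_iter: int = 1000,
    seed: int = 0,
    min_bp: int = 1,
) -> PermutationResult:
    """Within-chromosome reshuffle test for overlap enrichment.

    The observed statistic is the number of query intervals overlapping
    the database; each iteration reshuffles the query within chromosomes
    and recomputes it.  p = fraction of iterations strictly greater than
    the observed count.
    """
    _check_same_genome(query, db)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if len(query) == 0:
        raise ValueError("empty query: overlap enrichment p-value is undefined")
    track = _MergedTrack(db)
    rng = np.random.default_rng(seed)

    by_chrom = query.by_chromosome()
    chrom_data = []
    for chrom, lst in by_chrom.items():
        L = query.genome.length(chrom)
        spans = np.asarray([iv.length for iv in lst], dtype=np.int64)
        if (spans > L).any():
            raise ValueError(f"interval longer than chromosome {chrom}")
        chrom_data.append((chrom, L, spans))

    observed = 0
    for chrom, _, spans in chrom_data:
        qs = np.asarray([iv.start for iv in by_chrom[chrom]], dtype=np.int64)
        observed += int((track.overlap_bp(chrom, qs, qs + spans) >= min_bp).sum())

    n_greater = 0
    for _ in range(n_iter):
        count = 0
        for chrom, L, spans in chrom_data:
            starts = rng.integers(0, L - spans + 1)
            count += int((track.overlap_bp(chrom, starts, starts + spans) >= min_bp).sum())
        if count > observed:
            n_greater += 1
    return PermutationResult(observed, n_iter, n_greater)


def sd_overlap_summary(
    cnvs: IntervalSet, sds: IntervalSet, min_bp: int = 1
) -> tuple[int, int, float]:
    """Summarize CNV overlap with segmental duplications.

    Returns ``(n_overlapping, total_overlapped_length,
    fraction_of_total_cnv_length)`` where the overlapped length is the
    summed *full* length of every CNV that touches an SD and the fraction
    normalizes it by the total length of all CNVs.
    """
    n_hit, ann = count_overlaps(cnvs, sds, min_bp=min_bp)
    hit_len = int((ann.loc[ann["hit"], "end"] - ann.loc[ann["hit"], "start"]).sum())
    total = cnvs.total_length()
    return n_hit, hit_len, (hit_len / total if total else 0.0)


def _flank_regions(
    cnvs: IntervalSet, flank_offsets: tuple[int, ...]
) -> dict[str, list[tuple[str, int, int]]]:
    """Distance-banded flanking regions around the merged CNV set.

    Band k holds the bases whose distance to the nearest CNV base lies in
    ``[offsets[k-1], offsets[k])`` (offset 0 prepended).  Bases in gaps
    between two CNVs are assigned to the nearer one (ties to the left), so
    the bands are disjoint by construction.  Chromosomes without any CNV
    carry no flank (distance undefined).
    """
    offs = (0,) + tuple(sorted(flank_offsets))
    track = _MergedTrack(cnvs)
    regions: dict[str, list[tuple[str, int, int]]] = {
        f"flank@{offs[k]}-{offs[k + 1]}bp": [] for k in range(len(offs) - 1)
    }
    labels = list(regions)
    genome = cnvs.genome
    for chrom in genome.names:
        st, en = track.merged_intervals(chrom)
        if len(st) == 0:
            continue
        L = genome.length(chrom)
        # gaps: (g0, g1, has_left_cnv, has_right_cnv)
        gaps = []
        if st[0] > 0:
            gaps.append((0, int(st[0]), False, True))
        for k in range(len(st) - 1):
            gaps.append((int(en[k]), int(st[k + 1]), True, True))
        if en[-1] < L:
            gaps.append((int(en[-1]), L, True, False))
        for g0, g1, has_l, has_r in gaps:
            if has_l and has_r:
                mid = (g0 + g1 + 1) // 2  # x < mid is nearer the left CNV
            elif has_l:
                mid = g1
            else:
                mid = g0
            for k in range(len(offs) - 1):
                lo, hi = offs[k], offs[k + 1]
                if has_l:
                    a, b = max(g0 + lo, g0), min(g0 + hi, mid)
                    if b > a:
                        regions[labels[k]].append((chrom, a, b))
                if has_r:
                    a, b = max(g1 - hi, mid), min(g1 - lo, g1)
                    if b > a:
                        regions[labels[k]].append((chrom, a, b))
    return regions


def repeat_fraction_profile(
    cnvs: IntervalSet,
    repeats: IntervalSet,
    flank_offsets: tuple[int, ...] = DEFAULT_FLANK_OFFSETS,
    classes: tuple[str, ...] = ("LINE", "SINE", "LTR"),
) -> pd.DataFrame:
    """Genomic fraction of each repeat class inside CNVs and in flank bands.

    The fraction for a region set and class is (bp of that class inside
    the region set) / (bp of the region set); the per-kb density is the
    same ratio scaled to one kilobase.  Flank bands are distance annuli
    clipped at chromosome ends and at neighboring CNVs; empty regions are
    omitted.
    """
    _check_same_genome(cnvs, repeats)
    region_sets: dict[str, list[tuple[str, int, int]]] = {
        "intraCNV": [(iv.chromosome, iv.start, iv.end) for iv in cnvs]
    }
    region_sets.update(_flank_regions(cnvs, flank_offsets))
    class_tracks = {
        cls: _MergedTrack(
            IntervalSet([iv for iv in repeats if iv.cls == cls], repeats.genome)
        )
        for cls in classes
    }
    rows = []
    for label, regs in region_sets.items():
        region_bp = sum(b - a for _, a, b in regs)
        if region_bp == 0:
            continue
        for cls, track in class_tracks.items():
            cls_bp = 0
            for chrom, a, b in regs:
                cls_bp += int(
                    track.overlap_bp(chrom, np.asarray([a]), np.asarray([b]))[0]
                )
            frac = cls_bp / region_bp
            rows.append((label, cls, region_bp, cls_bp, frac, frac * 1000.0))
    return pd.DataFrame(
        rows,
        columns=["region", "class", "region_bp", "class_bp", "fraction", "per_kb"],
    )


def annotate_genes(cnvs: IntervalSet, genes: IntervalSet, min_bp: int = 1) -> list[list[str]]:
    """Per-CNV lists of overlapping gene names, sorted by gene start.

    A gene is listed when it shares >= min_bp with the CNV (a gene
    spanning the boundary counts); a CNV hitting no gene gets an empty
    list.
    """
    _check_same_genome(cnvs, genes)
    by_chrom = genes.by_chromosome()
    out: list[list[str]] = []
    for iv in cnvs:
        hits = [
            g
            for g in by_chrom.get(iv.chromosome, [])
            if min(g.end, iv.end) - max(g.start, iv.start) >= min_bp
        ]
        hits.sort(key=lambda g: (g.start, g.end, g.name))
        out.append([g.name for g in hits])
    return out
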