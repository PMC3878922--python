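"""Synthetic clone-genome data generators.

Every generator emulates the statistical structure that the downstream
analysis assumes rather than raw platform output:

* two-channel aCGH probe ``log2(test/reference)`` ratios as Gaussian noise
  around segment means ``log2(c_clone / c_baseline)``, with the nuclear
  donor (the reference channel) at baseline ploidy;
* dye-swap replicates with the *negated* event signal and an independent
  noise realization;
* SNP-array LRR/BAF tracks where heterozygous BAF bands sit at the allele
  dosage ratios ``b / c`` (0.5 diploid, 1/3 and 2/3 at three copies) and
  copy-neutral LOH removes the het band while leaving LRR at zero;
* triplicate qPCR threshold cycles under ideal doubling per cycle;
* annotation tracks (known-CNV database, segmental duplications, repeat
  classes, genes) and HWE microsatellite genotype panels.

All generators take an integer seed and are bit-reproducible for a fixed
seed.  Truth events accompany every dataset so recall / precision of the
callers is computable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GenomeDef, Interval, IntervalSet, TruthEvent, validate_events

PROBE_COLUMNS = ["probe_id", "chromosome", "position", "log2_ratio"]
SNP_COLUMNS = ["snp_id", "chromosome", "position", "lrr", "baf"]

#: default platform parameters: ~3.3 kb aCGH probe spacing, ~13 kb SNP spacing
DEFAULT_PROBE_SPACING = 3300
DEFAULT_SNP_SPACING = 13_000
#: noise defaults are implementer choices calibrated so that a single-copy
#: change (|log2| = 0.585) is ~4 noise SDs and the 3-copy BAF mode shift
#: (0.167) is ~5.5 noise SDs
DEFAULT_ACGH_NOISE_SD = 0.15
DEFAULT_LRR_NOISE_SD = 0.15
DEFAULT_BAF_NOISE_SD = 0.03
DEFAULT_HET_RATE = 0.3


def _jittered_positions(length: int, spacing: float, rng: np.random.Generator) -> np.ndarray:
    """Probe positions at jittered regular spacing, strictly increasing."""
    n = int(length // spacing)
    if n == 0:
        return np.array([], dtype=np.int64)
    grid = (np.arange(n) + 0.5) * spacing
    jitter = rng.uniform(-0.3, 0.3, size=n) * spacing
    pos = np.clip(np.round(grid + jitter).astype(np.int64), 0, length - 1)
    # enforce strict monotonicity after rounding
    pos = np.maximum.accumulate(pos + np.arange(n)) - np.arange(n)
    return np.clip(pos, 0, length - 1)


def local_copy_number(
    genome: GenomeDef, events: Sequence[TruthEvent], chrom: str, positions: np.ndarray
) -> np.ndarray:
    """Total copy number of the clone at each position (baseline outside events)."""
    cn = np.full(len(positions), genome.baseline(chrom), dtype=np.int64)
    for ev in events:
        if ev.chromosome != chrom or ev.kind == "cn_loh":
            continue
        mask = (positions >= ev.start) & (positions < ev.end)
        cn[mask] = ev.copy_number
    return cn


def in_loh(events: Sequence[TruthEvent], chrom: str, positions: np.ndarray) -> np.ndarray:
    mask = np.zeros(len(positions), dtype=bool)
    for ev in events:
        if ev.chromosome == chrom and ev.kind == "cn_loh":
            mask |= (positions >= ev.start) & (positions < ev.end)
    return mask


def simulate_acgh(
    genome: GenomeDef,
    events: Sequence[TruthEvent],
    probe_spacing: float = DEFAULT_PROBE_SPACING,
    noise_sd: float = DEFAULT_ACGH_NOISE_SD,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate an aCGH probe table for a clone hybridized against its donor.

    Returns a DataFrame with columns ``probe_id, chromosome, position,
    log2_ratio`` sorted by (chromosome, position); ``log2_ratio`` is
    ``Normal(log2(c_clone / c_baseline), noise_sd)``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if probe_spacing <= 0:
        raise ValueError("probe_spacing must be > 0")
    validate_events(genome, events)
    rng = np.random.default_rng(seed)
    frames = []
    counter = 0
    for chrom, length in genome.chromosomes:
        pos = _jittered_positions(length, probe_spacing, rng)
        cn = local_copy_number(genome, events, chrom, pos)
        mean = np.log2(cn / genome.baseline(chrom))
        log2 = mean + rng.normal(0.0, noise_sd, size=len(pos)) if noise_sd > 0 else mean
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": [f"P{counter + i:07d}" for i in range(len(pos))],
                    "chromosome": chrom,
                    "position": pos,
                    "log2_ratio": log2.astype(float),
                }
            )
        )
        counter += len(pos)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=PROBE_COLUMNS)


def simulate_dye_swap(
    forward: pd.DataFrame,
    truth: Sequence[TruthEvent],
    noise_sd: float = DEFAULT_ACGH_NOISE_SD,
    seed: int = 0,
    genome: GenomeDef | None = None,
) -> pd.DataFrame:
    """Simulate the dye-swap replicate of a forward hybridization.

    The swap uses the same probe set but its expected signal is the
    *negated* event signal plus an independent noise realization — it is
    not the arithmetic negation of the forward noise.  ``genome`` supplies
    per-chromosome baseline ploidy; a diploid baseline is assumed when
    omitted.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    out = forward.copy()
    log2 = np.zeros(len(out))
    for chrom, sub in out.groupby("chromosome", sort=False):
        pos = sub["position"].to_numpy()
        base = genome.baseline(chrom) if genome is not None else 2
        cn = np.full(len(pos), base, dtype=np.int64)
        for ev in truth:
            if ev.chromosome != chrom or ev.kind == "cn_loh":
                continue
            m = (pos >= ev.start) & (pos < ev.end)
            cn[m] = ev.copy_number
        mean = -np.log2(cn / base)
        noise = rng.normal(0.0, noise_sd, size=len(pos)) if noise_sd > 0 else 0.0
        log2[sub.index.to_numpy()] = mean + noise
    out["log2_ratio"] = log2
    return out


def simulate_snp_array(
    genome: GenomeDef,
    events: Sequence[TruthEvent],
    snp_spacing: float = DEFAULT_SNP_SPACING,
    het_rate: float = DEFAULT_HET_RATE,
    lrr_noise_sd: float = DEFAULT_LRR_NOISE_SD,
    baf_noise_sd: float = DEFAULT_BAF_NOISE_SD,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a SNP-array LRR/BAF table for a clone.

    Each SNP is heterozygous with probability ``het_rate`` outside
    copy-neutral LOH events and never inside them.  Het BAF is centred at
    ``b / c`` for ``b`` B-allele copies out of ``c`` total (``b`` uniform
    over ``1..c-1``); homozygotes sit at 0 or 1.  LRR is centred at
    ``log2(c / baseline)`` for gains and losses and at 0 inside cn-LOH.
    BAF noise is Gaussian truncated to [0, 1].
    """
    if not 0 <= het_rate <= 1:
        raise ValueError("het_rate must be in [0, 1]")
    validate_events(genome, events)
    rng = np.random.default_rng(seed)
    frames = []
    counter = 0
    for chrom, length in genome.chromosomes:
        pos = _jittered_positions(length, snp_spacing, rng)
        n = len(pos)
        cn = local_copy_number(genome, events, chrom, pos)
        loh = in_loh(events, chrom, pos)
        het = (rng.random(n) < het_rate) & ~loh & (cn >= 2)
        b_copies = np.where(het, 1 + rng.integers(0, np.maximum(cn - 1, 1)), 0)
        baf_mean = np.where(het, b_copies / cn, rng.integers(0, 2, size=n).astype(float))
        baf = baf_mean + (rng.normal(0.0, baf_noise_sd, size=n) if baf_noise_sd > 0 else 0.0)
        baf = np.clip(baf, 0.0, 1.0)
        base = genome.baseline(chrom)
        lrr_mean = np.where(loh, 0.0, np.log2(cn / base))
        lrr = lrr_mean + (rng.normal(0.0, lrr_noise_sd, size=n) if lrr_noise_sd > 0 else 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "snp_id": [f"S{counter + i:07d}" for i in range(n)],
                    "chromosome": chrom,
                    "position": pos,
                    "lrr": lrr.astype(float),
                    "baf": baf.astype(float),
                }
            )
        )
        counter += n
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=SNP_COLUMNS)


@dataclass
class QpcrAssay:
    """Replicate threshold cycles for the four well groups of one target.

    ``inside_expected_cnv`` marks whether the primer pair sits inside the
    array-called interval being validated; replicate Cts are stored per
    group (sample/calibrator x target/control locus).
    """

    target_id: str
    chromosome: str = ""
    position: int = 0
    inside_expected_cnv: bool = True
    sample_target: list[float] = field(default_factory=list)
    sample_control: list[float] = field(default_factory=list)
    calibrator_target: list[float] = field(default_factory=list)
    calibrator_control: list[float] = field(default_factory=list)


def simulate_qpcr(
    copy_number: float,
    baseline_copy: int = 2,
    ct_reference: float = 25.0,
    replicates: int = 3,
    ct_noise_sd: float = 0.05,
    seed: int = 0,
    efficiency: float = 2.0,
    target_id: str = "target",
) -> QpcrAssay:
    """Simulate triplicate Cts for a sample/calibrator pair at one locus.

    The sample's target Ct is shifted by ``-log_E(copy_number /
    baseline_copy)`` relative to the calibrator (the donor), where ``E`` is
    the amplification efficiency (ideal doubling, 2.0, by default); the
    control locus is diploid in both, so its Cts agree in expectation.
    """
    if copy_number <= 0:
        raise ValueError("copy_number must be > 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    shift = -np.log(copy_number / baseline_copy) / np.log(efficiency)

    def cts(mean: float) -> list[float]:
        noise = rng.normal(0.0, ct_noise_sd, size=replicates) if ct_noise_sd > 0 else np.zeros(replicates)
        return list(np.asarray(mean + noise, dtype=float))

    return QpcrAssay(
        target_id=target_id,
        sample_target=cts(ct_reference + shift),
        sample_control=cts(ct_reference),
        calibrator_target=cts(ct_reference),
        calibrator_control=cts(ct_reference),
    )


def simulate_annotation_tracks(
    genome: GenomeDef,
    n_intervals: dict[str, int] | int = 50,
    size_range: tuple[int, int] = (10_000, 300_000),
    seed: int = 0,
    density_cap: float = 0.5,
    repeat_classes: tuple[str, ...] = ("LINE", "SINE", "LTR"),
) -> dict[str, IntervalSet]:
    """Simulate known-CNV, segmental-duplication, repeat and gene tracks.

    ``n_intervals`` is either one count applied to every track or a mapping
    with keys ``known_cnv, sd, repeat, gene``.  Interval sizes are uniform
    over ``size_range``; placements are uniform over chromosomes weighted
    by length.  Placement is rejected when the requested total length on a
    chromosome would exceed ``density_cap`` of it.
    """
    tracks = ("known_cnv", "sd", "repeat", "gene")
    if isinstance(n_intervals, int):
        counts = {t: n_intervals for t in tracks}
    else:
        counts = {t: int(n_intervals.get(t, 0)) for t in tracks}
    lo, hi = size_range
    if lo <= 0 or hi < lo:
        raise ValueError("size_range must be positive with lo <= hi")
    rng = np.random.default_rng(seed)
    lengths = np.array([L for _, L in genome.chromosomes], dtype=float)
    names = genome.names
    out: dict[str, IntervalSet] = {}
    for track in tracks:
        n = counts[track]
        ivs: list[Interval] = []
        placed: dict[str, int] = {c: 0 for c in names}
        probs = lengths / lengths.sum()
        for i in range(n):
            chrom = names[rng.choice(len(names), p=probs)]
            L = genome.length(chrom)
            size = int(rng.integers(lo, min(hi, L - 1) + 1))
            if placed[chrom] + size > density_cap * L:
                raise ValueError(
                    f"cannot place interval {i} of track {track!r} on {chrom} "
                    f"without exceeding density cap {density_cap}"
                )
            start = int(rng.integers(0, L - size + 1))
            cls = repeat_classes[rng.integers(0, len(repeat_classes))] if track == "repeat" else ""
            name = f"{track}_{i:04d}" if track != "gene" else f"GENE{i:04d}"
            ivs.append(Interval(chrom, start, start + size, name=name, cls=cls))
            placed[chrom] += size
        out[track] = IntervalSet(ivs, genome, name=track)
    return out


def simulate_repeat_coverage(
    genome: GenomeDef,
    regions: Sequence[Interval],
    coverage: float,
    repeat_length: int,
    cls: str,
    seed: int = 0,
    name_prefix: str = "rep",
) -> list[Interval]:
    """Place non-overlapping repeats of one class achieving a target coverage.

    Each region is partitioned into blocks of ``repeat_length / coverage``
    and one repeat is placed at a random offset inside each block, so the
    realized coverage fraction equals ``coverage`` up to edge effects.
    Used to build tracks with controlled per-region repeat density.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    rng = np.random.default_rng(seed)
    block = int(round(repeat_length / coverage))
    ivs: list[Interval] = []
    k = 0
    for reg in regions:
        x = reg.start
        while x + repeat_length <= reg.end:
            hi = min(x + block, reg.end) - repeat_length
            s = int(rng.integers(x, hi + 1)) if hi > x else x
            ivs.append(Interval(reg.chromosome, s, s + repeat_length, name=f"{name_prefix}{k:05d}", cls=cls))
            k += 1
            x += block
    return ivs


def simulate_microsat_panel(
    allele_freqs: dict[str, Sequence[float]],
    n_individuals: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw HWE genotypes at each microsatellite locus independently.

    Returns a long-format DataFrame ``individual, locus, allele1, allele2``
    with alleles stored in sorted order (genotypes are unordered pairs).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for locus, freqs in allele_freqs.items():
        p = np.asarray(freqs, dtype=float)
        if (p < 0).any():
            raise ValueError(f"negative allele frequency at locus {locus!r}")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"allele frequencies at {locus!r} sum to {p.sum()}, not 1")
        a1 = rng.choice(len(p), size=n_individuals, p=p)
        a2 = rng.choice(len(p), size=n_individuals, p=p)
        lo, hi = np.minimum(a1, a2), np.maximum(a1, a2)
        for i in range(n_individuals):
            rows.append((f"ind{i:05d}", locus, int(lo[i]), int(hi[i])))
    return pd.DataFrame(rows, columns=["individual", "locus", "allele1", "allele2"])
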