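"""Readers and writers for the package's tabular formats.

Probe/SNP/Ct/frequency/genotype tables are TSV with headers; interval
tracks are BED (0-based half-open, per the BED standard).  Human-facing
report coordinates are 1-based inclusive starts with length reported as
``end - start`` of the underlying half-open interval.  All writers order
rows by (chromosome, position) and are deterministic.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .genome import GenomeDef, Interval, IntervalSet, TruthEvent
from .simulate import PROBE_COLUMNS, SNP_COLUMNS, QpcrAssay

__all__ = [
    "read_probe_table",
    "write_probe_table",
    "read_snp_table",
    "write_snp_table",
    "read_bed",
    "write_bed",
    "read_truth_events",
    "write_truth_events",
    "read_ct_table",
    "write_ct_table",
    "read_freq_table",
    "write_freq_table",
    "read_genotypes",
    "write_genotypes",
    "read_genome",
    "write_genome",
    "read_config",
    "write_config",
    "to_report_coords",
    "from_report_coords",
]


def to_report_coords(start: int, end: int) -> tuple[int, int, int]:
    """Internal half-open (start, end) -> printed (start_1based, end, length)."""
    return start + 1, end, end - start


def from_report_coords(start_1based: int, end: int) -> tuple[int, int]:
    """Printed 1-based inclusive coordinates -> internal half-open."""
    return start_1based - 1, end


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing} (found {list(df.columns)})")


def _check_sorted_positions(df: pd.DataFrame, path) -> None:
    for chrom, sub in df.groupby("chromosome", sort=False):
        pos = sub["position"].to_numpy()
        if len(pos) > 1 and not np.all(np.diff(pos) > 0):
            bad = int(np.nonzero(np.diff(pos) <= 0)[0][0])
            row = sub.index[bad + 1] + 2  # +1 header, +1 1-based
            raise ValueError(f"{path}: positions not strictly increasing on {chrom} at line {row}")


def read_probe_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, PROBE_COLUMNS, path)
    if not np.isfinite(df["log2_ratio"].to_numpy(dtype=float)).all():
        raise ValueError(f"{path}: non-finite log2_ratio values")
    _check_sorted_positions(df, path)
    return df[PROBE_COLUMNS]


def write_probe_table(df: pd.DataFrame, path) -> None:
    df[PROBE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_snp_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, SNP_COLUMNS, path)
    baf = df["baf"].to_numpy(dtype=float)
    if ((baf < 0) | (baf > 1)).any():
        bad = int(np.nonzero((baf < 0) | (baf > 1))[0][0]) + 2
        raise ValueError(f"{path}: BAF outside [0, 1] at line {bad}")
    _check_sorted_positions(df, path)
    return df[SNP_COLUMNS]


def write_snp_table(df: pd.DataFrame, path) -> None:
    df[SNP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_bed(path, genome: GenomeDef | None = None) -> list[Interval] | IntervalSet:
    """Read a BED(+) file: chrom, start, end[, name[, class]].

    Returns an :class:`IntervalSet` when a genome is supplied (validating
    bounds and chromosome names), else a plain interval list.
    """
    ivs: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            name = parts[3] if len(parts) > 3 else ""
            cls = parts[4] if len(parts) > 4 else ""
            if genome is not None and parts[0] not in genome:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {parts[0]!r}")
            ivs.append(Interval(parts[0], start, end, name=name, cls=cls))
    return IntervalSet(ivs, genome) if genome is not None else ivs


def write_bed(intervals: IntervalSet | Sequence[Interval], path) -> None:
    ivs = list(intervals)
    with open(path, "w") as fh:
        for iv in ivs:
            cols = [iv.chromosome, str(iv.start), str(iv.end)]
            if iv.name or iv.cls:
                cols.append(iv.name)
            if iv.cls:
                cols.append(iv.cls)
            fh.write("\t".join(cols) + "\n")


def read_truth_events(path, genome: GenomeDef | None = None) -> list[TruthEvent]:
    """Truth events as BED+2: chrom, start, end, kind, copy_number."""
    events = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}:{lineno}: expected chrom/start/end/kind/copy_number")
            ev = TruthEvent(parts[0], int(parts[1]), int(parts[2]), parts[3], int(parts[4]))
            if genome is not None:
                ev.validate_against(genome)
            events.append(ev)
    return events


def write_truth_events(events: Sequence[TruthEvent], path) -> None:
    with open(path, "w") as fh:
        for ev in sorted(events, key=lambda e: (e.chromosome, e.start)):
            fh.write(
                f"{ev.chromosome}\t{ev.start}\t{ev.end}\t{ev.kind}\t{ev.copy_number}\n"
            )


CT_COLUMNS = ["assay_id", "group", "replicate", "ct"]
_CT_GROUPS = ("sample_target", "sample_control", "calibrator_target", "calibrator_control")


def read_ct_table(path, meta: pd.DataFrame | None = None) -> dict[str, QpcrAssay]:
    """Read replicate Cts into assays, keyed by assay id.

    ``meta`` optionally supplies primer metadata (columns ``assay_id,
    chromosome, position, inside``) mirroring a primer table with
    target locus coordinates and an inside/outside-CNV flag.
    """
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, CT_COLUMNS, path)
    bad = ~df["group"].isin(_CT_GROUPS)
    if bad.any():
        lineno = int(np.nonzero(bad.to_numpy())[0][0]) + 2
        raise ValueError(f"{path}: unknown well group at line {lineno}")
    meta_idx = meta.set_index("assay_id") if meta is not None else None
    assays: dict[str, QpcrAssay] = {}
    for aid, sub in df.groupby("assay_id", sort=False):
        assay = QpcrAssay(target_id=str(aid))
        for group, grp in sub.groupby("group", sort=False):
            getattr(assay, group).extend(grp["ct"].astype(float).tolist())
        if meta_idx is not None and aid in meta_idx.index:
            row = meta_idx.loc[aid]
            assay.chromosome = str(row["chromosome"])
            assay.position = int(row["position"])
            assay.inside_expected_cnv = bool(row["inside"])
        assays[str(aid)] = assay
    return assays


def write_ct_table(assays: Sequence[QpcrAssay], path) -> None:
    rows = []
    for a in assays:
        for group in _CT_GROUPS:
            for rep, ct in enumerate(getattr(a, group), 1):
                rows.append((a.target_id, group, rep, ct))
    pd.DataFrame(rows, columns=CT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_freq_table(path) -> dict[str, list[float]]:
    """Allele-frequency TSV: locus, allele, freq -> {locus: [freqs]}."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["locus", "allele", "freq"], path)
    out: dict[str, list[float]] = {}
    for locus, sub in df.groupby("locus", sort=False):
        out[str(locus)] = sub.sort_values("allele")["freq"].astype(float).tolist()
    return out


def write_freq_table(freqs: dict[str, Sequence[float]], path) -> None:
    rows = [(locus, i, f) for locus, fs in freqs.items() for i, f in enumerate(fs)]
    pd.DataFrame(rows, columns=["locus", "allele", "freq"]).to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["locus", "allele1", "allele2"], path)
    return df


def write_genotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_genome(path) -> GenomeDef:
    """Genome definition TSV: chromosome, length[, ploidy]."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["chromosome", "length"], path)
    ploidy = {}
    if "ploidy" in df.columns:
        ploidy = {str(r.chromosome): int(r.ploidy) for r in df.itertuples()}
    return GenomeDef(
        [(str(r.chromosome), int(r.length)) for r in df.itertuples()], ploidy
    )


def write_genome(genome: GenomeDef, path) -> None:
    rows = [(c, L, genome.baseline(c)) for c, L in genome.chromosomes]
    pd.DataFrame(rows, columns=["chromosome", "length", "ploidy"]).to_csv(
        path, sep="\t", index=False
    )


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
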