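"""End-to-end clone analysis: simulate or load data, call, validate, report.

Stage order per clone: sample QC -> aCGH segmentation and CNV calling ->
dye-swap concordance -> BAF allelic imbalance / copy-neutral LOH -> multi-
point qPCR validation -> known-CNV overlap and permutation enrichment ->
gene annotation -> microsatellite identity -> consolidated report.  A
clone failing SNP-array QC skips its downstream SNP-based stages with the
failure recorded.  One global seed fans out to per-stage child seeds by
fixed offsets so stages are individually reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import baf as baf_mod
from . import enrichment, identity, io, qpcr, simulate
from .genome import GenomeDef, Interval, IntervalSet, TruthEvent, child_seed
from .segmentation import CnvCall, CnvCallingParams, call_cnvs, dye_swap_concordance, rank_segment

log = logging.getLogger("clonecnv")

# per-stage seed offsets (clone index is folded in separately)
_OFF_ACGH, _OFF_SWAP, _OFF_SNP, _OFF_QPCR, _OFF_TRACKS, _OFF_PERM, _OFF_MSAT = range(1, 8)

DEFAULT_PANEL_FREQS = {
    # nine-marker synthetic panel; frequencies are synthetic stand-ins for
    # unpublished breed allele frequencies
    f"M{i:02d}": [0.4, 0.3, 0.2, 0.1]
    for i in range(1, 10)
}

DEFAULTS: dict[str, Any] = {
    "probe_spacing": simulate.DEFAULT_PROBE_SPACING,
    "acgh_noise_sd": simulate.DEFAULT_ACGH_NOISE_SD,
    "snp_spacing": simulate.DEFAULT_SNP_SPACING,
    "het_rate": simulate.DEFAULT_HET_RATE,
    "lrr_noise_sd": simulate.DEFAULT_LRR_NOISE_SD,
    "baf_noise_sd": simulate.DEFAULT_BAF_NOISE_SD,
    "alpha": 1.0e-6,
    "max_gap": 1_000_000,
    "min_probes": 5,
    "gain_thr": 0.2,
    "loss_thr": -0.2,
    "min_reciprocal": 0.5,
    "lrr_sd_threshold": 0.24,
    "min_window": 360_000,
    "mode_delta": 0.08,
    "lrr_neutral": 0.1,
    "qpcr_points_inside": 3,
    "qpcr_points_outside": 2,
    "qpcr_ct_noise_sd": 0.05,
    "qpcr_gain_thr": 1.4,
    "qpcr_loss_thr": 0.7,
    "perm_iterations": 1000,
    "annotation_intervals": 40,
}


@dataclass
class RunConfig:
    """Resolved pipeline configuration (unset keys fall back to defaults)."""

    genome: GenomeDef
    clones: list[dict]  # each: {"id": str, "events": list[TruthEvent]}
    seed: int = 0
    out_dir: str | None = None
    stages: dict[str, bool] = field(default_factory=dict)
    params: dict[str, Any] = field(default_factory=dict)

    def param(self, key: str):
        return self.params.get(key, DEFAULTS[key])

    def stage_on(self, name: str) -> bool:
        return self.stages.get(name, True)

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        genome = GenomeDef(
            [(c, int(L)) for c, L in cfg["genome"]["chromosomes"]],
            {k: int(v) for k, v in cfg["genome"].get("ploidy", {}).items()},
        )
        clones = []
        for cl in cfg.get("clones", []):
            events = [
                TruthEvent(e[0], int(e[1]), int(e[2]), e[3], int(e[4]))
                for e in cl.get("events", [])
            ]
            clones.append({"id": cl["id"], "events": events})
        return cls(
            genome=genome,
            clones=clones,
            seed=int(cfg.get("seed", 0)),
            out_dir=cfg.get("out_dir"),
            stages={k: bool(v) for k, v in cfg.get("stages", {}).items()},
            params=dict(cfg.get("params", {})),
        )

    def to_dict(self) -> dict:
        return {
            "genome": {
                "chromosomes": [[c, L] for c, L in self.genome.chromosomes],
                "ploidy": dict(self.genome.ploidy_baseline),
            },
            "clones": [
                {
                    "id": cl["id"],
                    "events": [
                        [e.chromosome, e.start, e.end, e.kind, e.copy_number]
                        for e in cl["events"]
                    ],
                }
                for cl in self.clones
            ],
            "seed": self.seed,
            "out_dir": self.out_dir,
            "stages": dict(self.stages),
            "params": dict(self.params),
        }


@dataclass
class CloneReport:
    clone_id: str
    qc: baf_mod.QcResult | None = None
    cnv_calls: list[CnvCall] = field(default_factory=list)
    loh_calls: list[baf_mod.LohCall] = field(default_factory=list)
    gene_lists: list[list[str]] = field(default_factory=list)
    known_overlap: enrichment.PermutationResult | None = None
    known_hits: list[bool] = field(default_factory=list)
    identity_all_match: bool | None = None
    pi: identity.PiResult | None = None
    notes: list[str] = field(default_factory=list)


def _truth_copy_number(genome: GenomeDef, events: list[TruthEvent], chrom: str, pos: int) -> int:
    cn = genome.baseline(chrom)
    for ev in events:
        if ev.chromosome == chrom and ev.kind != "cn_loh" and ev.start <= pos < ev.end:
            cn = ev.copy_number
    return cn


def _simulate_call_assays(
    genome: GenomeDef,
    events: list[TruthEvent],
    call: CnvCall,
    n_inside: int,
    n_outside: int,
    ct_noise_sd: float,
    seed: int,
) -> list[simulate.QpcrAssay]:
    """Primer points spread through the call and in its flanks, with Cts
    generated from the clone's *true* local copy number at each point."""
    assays = []
    span = call.length
    positions: list[tuple[int, bool]] = []
    for k in range(n_inside):
        frac = (k + 1) / (n_inside + 1)
        positions.append((call.start + int(frac * span), True))
    flank = max(span // 2, 50_000)
    L = genome.length(call.chromosome)
    for k in range(n_outside):
        off = (k // 2 + 1) * flank
        pos = call.start - off if k % 2 == 0 else call.end + off
        if 0 <= pos < L:
            positions.append((int(pos), False))
    base = genome.baseline(call.chromosome)
    for idx, (pos, inside) in enumerate(positions):
        cn = _truth_copy_number(genome, events, call.chromosome, pos)
        a = simulate.simulate_qpcr(
            copy_number=cn,
            baseline_copy=base,
            ct_noise_sd=ct_noise_sd,
            seed=child_seed(seed, idx),
            target_id=f"{call.chromosome}:{pos}",
        )
        a.chromosome = call.chromosome
        a.position = pos
        a.inside_expected_cnv = inside
        assays.append(a)
    return assays


def run_pipeline(config: RunConfig) -> list[CloneReport]:
    """Run the full discovery-and-validation workflow for every clone."""
    genome = config.genome
    p = config.param
    params = CnvCallingParams(
        alpha=p("alpha"),
        max_gap=int(p("max_gap")),
        min_probes=int(p("min_probes")),
        gain_thr=p("gain_thr"),
        loss_thr=p("loss_thr"),
    )
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    tracks = None
    if config.stage_on("overlap") or config.stage_on("annotate"):
        tracks = simulate.simulate_annotation_tracks(
            genome,
            n_intervals=int(p("annotation_intervals")),
            size_range=(10_000, 100_000),
            seed=child_seed(config.seed, _OFF_TRACKS),
        )

    reports: list[CloneReport] = []
    for ci, clone in enumerate(config.clones):
        cid, events = clone["id"], clone["events"]
        rep = CloneReport(clone_id=cid)
        base_seed = child_seed(config.seed, 1000 * (ci + 1))
        log.info("clone %s: %d truth events", cid, len(events))

        # --- SNP array + QC -------------------------------------------------
        snps = None
        if config.stage_on("qc") or config.stage_on("baf"):
            snps = simulate.simulate_snp_array(
                genome,
                events,
                snp_spacing=p("snp_spacing"),
                het_rate=p("het_rate"),
                lrr_noise_sd=p("lrr_noise_sd"),
                baf_noise_sd=p("baf_noise_sd"),
                seed=child_seed(base_seed, _OFF_SNP),
            )
            rep.qc = baf_mod.qc_lrr(snps, p("lrr_sd_threshold"), sample_id=cid)
            if not rep.qc.passed:
                rep.notes.append(f"QC failed: {rep.qc.reason}; SNP-based stages skipped")
                log.warning("clone %s failed QC: %s", cid, rep.qc.reason)

        # --- aCGH segmentation and calling ---------------------------------
        probes = None
        if config.stage_on("cnv"):
            probes = simulate.simulate_acgh(
                genome,
                events,
                probe_spacing=p("probe_spacing"),
                noise_sd=p("acgh_noise_sd"),
                seed=child_seed(base_seed, _OFF_ACGH),
            )
            segments = rank_segment(probes, params)
            rep.cnv_calls = call_cnvs(segments, params)
            log.info("clone %s: %d segments -> %d CNV calls", cid, len(segments), len(rep.cnv_calls))

        # --- dye swap -------------------------------------------------------
        if config.stage_on("dye_swap") and probes is not None:
            swap = simulate.simulate_dye_swap(
                probes, events, p("acgh_noise_sd"), seed=child_seed(base_seed, _OFF_SWAP), genome=genome
            )
            swap_calls = call_cnvs(rank_segment(swap, params), params)
            dye_swap_concordance(rep.cnv_calls, swap_calls, p("min_reciprocal"))

        # --- BAF imbalance and cn-LOH --------------------------------------
        if config.stage_on("baf") and snps is not None and rep.qc and rep.qc.passed:
            imb = baf_mod.detect_allelic_imbalance(
                snps,
                min_window=int(p("min_window")),
                mode_delta=p("mode_delta"),
            )
            het_rate_obs = float(
                ((snps["baf"] > 0.2) & (snps["baf"] < 0.8)).mean()
            )
            if het_rate_obs > 0:
                rep.loh_calls = baf_mod.detect_cn_loh(
                    snps,
                    min_window=int(p("min_window")),
                    expected_het_rate=het_rate_obs,
                    lrr_neutral=p("lrr_neutral"),
                )
            for call in rep.cnv_calls:
                span = snps[
                    (snps["chromosome"] == call.chromosome)
                    & (snps["position"] >= call.start)
                    & (snps["position"] < call.end)
                ]
                if len(span) < 10:
                    call.validations["baf"] = "NA"  # too small for B-allele interpretation
                    continue
                if call.event == "gain":
                    ok = any(
                        s.state == "imbalanced"
                        and s.chromosome == call.chromosome
                        and min(s.end, call.end) - max(s.start, call.start) > 0
                        for s in imb
                    )
                else:  # loss: het band vanishes and LRR drops
                    het_frac = float(((span["baf"] > 0.2) & (span["baf"] < 0.8)).mean())
                    ok = span["lrr"].mean() < -p("lrr_neutral") and het_frac < 0.05
                call.validations["baf"] = "pass" if ok else "fail"

        # --- multi-point qPCR ----------------------------------------------
        if config.stage_on("qpcr"):
            for k, call in enumerate(rep.cnv_calls):
                assays = _simulate_call_assays(
                    genome,
                    events,
                    call,
                    int(p("qpcr_points_inside")),
                    int(p("qpcr_points_outside")),
                    p("qpcr_ct_noise_sd"),
                    child_seed(base_seed, _OFF_QPCR + 10 * k),
                )
                verdict = qpcr.validate_boundaries(
                    call, assays, p("qpcr_gain_thr"), p("qpcr_loss_thr")
                )
                call.validations["qpcr"] = {
                    "validated": "pass",
                    "not_validated": "fail",
                    "indeterminate": "NA",
                }[verdict.verdict]

        # --- overlap with known-CNV track, permutation, genes ---------------
        if tracks is not None and rep.cnv_calls:
            call_set = IntervalSet(
                [
                    Interval(c.chromosome, c.start, c.end, name=f"{cid}_cnv{k}")
                    for k, c in enumerate(rep.cnv_calls)
                ],
                genome,
            )
            if config.stage_on("overlap"):
                _, ann = enrichment.count_overlaps(call_set, tracks["known_cnv"])
                rep.known_hits = ann["hit"].tolist()
                rep.known_overlap = enrichment.permutation_overlap_test(
                    call_set,
                    tracks["known_cnv"],
                    n_iter=int(p("perm_iterations")),
                    seed=child_seed(base_seed, _OFF_PERM),
                )
            if config.stage_on("annotate"):
                rep.gene_lists = enrichment.annotate_genes(call_set, tracks["gene"])

        # --- microsatellite identity ----------------------------------------
        if config.stage_on("identity"):
            freqs = config.params.get("panel_freqs", DEFAULT_PANEL_FREQS)
            loci = [identity.MicrosatLocus(n, tuple(f)) for n, f in freqs.items()]
            rep.pi = identity.panel_pi(loci)
            donor = simulate.simulate_microsat_panel(
                freqs, 1, seed=child_seed(config.seed, _OFF_MSAT)
            )
            clone_gt = donor.copy()  # SCNT clone carries the donor genotype
            _, rep.identity_all_match = identity.genotype_match(donor, clone_gt)

        reports.append(rep)

    if out_dir:
        write_report(reports, out_dir)
    return reports


_VAL_LETTER = {"qpcr": "Q", "dye_swap": "S", "baf": "B"}


def report_table(reports: list[CloneReport]) -> pd.DataFrame:
    """Consolidated call table, one row per CNV call, printed 1-based."""
    rows = []
    for rep in reports:
        for k, call in enumerate(rep.cnv_calls):
            s1, e1, length = io.to_report_coords(call.start, call.end)
            letters = [
                _VAL_LETTER[key]
                for key in ("qpcr", "dye_swap", "baf")
                if call.validations.get(key) == "pass"
            ]
            genes = rep.gene_lists[k] if k < len(rep.gene_lists) else []
            known = (
                "Yes" if (k < len(rep.known_hits) and rep.known_hits[k]) else "No"
            )
            rows.append(
                (
                    rep.clone_id,
                    call.chromosome,
                    s1,
                    e1,
                    length,
                    "CN Gain" if call.event == "gain" else "CN Loss",
                    ", ".join(genes) if genes else "-",
                    ", ".join(letters) if letters else "-",
                    known,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "clone",
            "chromosome",
            "start",
            "end",
            "length",
            "event",
            "genes",
            "validated_by",
            "known_cnv",
        ],
    )


def write_report(reports: list[CloneReport], out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = report_table(reports)
    table.to_csv(out_dir / "cnv_report.tsv", sep="\t", index=False)
    lines = []
    for rep in reports:
        lines.append(f"== {rep.clone_id} ==")
        if rep.qc is not None:
            status = "pass" if rep.qc.passed else f"FAIL ({rep.qc.reason})"
            lines.append(f"QC SD(LRR): {rep.qc.lrr_sd:.4f} -> {status}")
        lines.append(f"CNV calls: {len(rep.cnv_calls)}")
        for call in rep.cnv_calls:
            s1, e1, length = io.to_report_coords(call.start, call.end)
            lines.append(
                f"  {call.chromosome}:{s1}-{e1} ({length} bp) {call.event} "
                f"n_probes={call.n_probes} mean_log2={call.mean_log2:.3f} "
                f"validations={call.validations}"
            )
        lines.append(f"cn-LOH calls: {len(rep.loh_calls)}")
        for loh in rep.loh_calls:
            s1, e1, length = io.to_report_coords(loh.start, loh.end)
            lines.append(
                f"  {loh.chromosome}:{s1}-{e1} ({length} bp) n_snps={loh.n_snps} "
                f"mean_lrr={loh.mean_lrr:.3f}"
            )
        if rep.known_overlap is not None:
            res = rep.known_overlap
            lines.append(
                f"known-CNV overlap: {res.observed_overlap_count}/{len(rep.cnv_calls)} "
                f"calls, permutation P {res.reported_string} ({res.n_iter} iterations)"
            )
        if rep.pi is not None:
            lines.append(
                f"identity: all loci match = {rep.identity_all_match}; "
                f"PI(HWE) = {rep.pi.multilocus_hwe:.3g}, "
                f"PI(sibs) = {rep.pi.multilocus_sibs:.3g}"
            )
        for note in rep.notes:
            lines.append(f"note: {note}")
        lines.append("")
    (out_dir / "summary.txt").write_text("\n".join(lines))
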