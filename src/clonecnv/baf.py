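"""SNP-array QC, allelic-imbalance and copy-neutral LOH detection.

Works on LRR/BAF tables.  Sample QC follows the SD(LRR) < 0.24 rule.
Allelic imbalance is detected by segmenting the mirrored BAF statistic
``|BAF - 0.5|`` of heterozygous SNPs with the same rank segmentation
engine used for aCGH log2 ratios, then testing each sufficiently large
segment for two heterozygous BAF modes symmetric about 0.5 (the allele
dosage signature of a gain: 1/3 and 2/3 at three copies).  Copy-neutral
LOH is a maximal run of SNPs with no heterozygous call that is long
enough, binomially improbable under the genome-wide heterozygosity rate,
and copy neutral (|mean LRR| small) — the uniparental-disomy signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import CnvCallingParams, rank_segment

__all__ = [
    "QcResult",
    "BafSegment",
    "LohCall",
    "qc_lrr",
    "detect_allelic_imbalance",
    "detect_cn_loh",
]

HET_BAND = (0.2, 0.8)
SEX_CHROMOSOMES = frozenset({"X", "Y", "chrX", "chrY"})


@dataclass(frozen=True)
class QcResult:
    sample_id: str
    lrr_sd: float
    passed: bool
    reason: str = ""


@dataclass
class BafSegment:
    chromosome: str
    start: int
    end: int
    n_het_snps: int
    het_baf_modes: list[float]
    mean_lrr: float
    state: str  # "balanced" | "imbalanced" | "indeterminate"


@dataclass
class LohCall:
    chromosome: str
    start: int
    end: int
    n_snps: int
    p_run: float
    mean_lrr: float

    @property
    def length(self) -> int:
        return self.end - self.start


def qc_lrr(
    snps: pd.DataFrame,
    sd_threshold: float = 0.24,
    sample_id: str = "sample",
    min_snps: int = 100,
) -> QcResult:
    """Sample-level QC: pass iff the SD of autosomal LRR is below threshold."""
    auto = snps[~snps["chromosome"].isin(SEX_CHROMOSOMES)]
    if len(auto) < min_snps:
        return QcResult(
            sample_id,
            float("nan"),
            False,
            f"only {len(auto)} autosomal SNPs (< {min_snps}); SD unreliable",
        )
    sd = float(auto["lrr"].std(ddof=1))
    passed = sd < sd_threshold
    return QcResult(sample_id, sd, passed, "" if passed else f"SD(LRR) {sd:.3f} >= {sd_threshold}")


def _is_het(baf: np.ndarray, het_band: tuple[float, float]) -> np.ndarray:
    return (baf > het_band[0]) & (baf < het_band[1])


def detect_allelic_imbalance(
    snps: pd.DataFrame,
    min_window: int = 360_000,
    het_band: tuple[float, float] = HET_BAND,
    mode_delta: float = 0.08,
    min_het_snps: int = 10,
    params: CnvCallingParams | None = None,
) -> list[BafSegment]:
    """Find segments whose het BAFs split into two bands off 0.5.

    Heterozygous SNPs (BAF inside ``het_band``) are segmented on the
    mirrored statistic |BAF - 0.5|.  A segment spanning at least
    ``min_window`` whose het BAFs form an upper and a lower cluster with
    half-separation ``d >= mode_delta`` is reported ``imbalanced`` with
    the two cluster means as band centers; segments with fewer than
    ``min_het_snps`` hets are ``indeterminate`` (too small to interpret);
    everything else is ``balanced``.
    """
    params = params or CnvCallingParams()
    out: list[BafSegment] = []
    for chrom, sub in snps.groupby("chromosome", sort=False):
        baf = sub["baf"].to_numpy(dtype=float)
        het = _is_het(baf, het_band)
        hsub = sub[het]
        if len(hsub) == 0:
            continue
        mirrored = pd.DataFrame(
            {
                "chromosome": chrom,
                "position": hsub["position"].to_numpy(),
                "log2_ratio": np.abs(hsub["baf"].to_numpy() - 0.5),
            }
        )
        segs = rank_segment(mirrored, params)
        for seg in segs:
            in_seg = hsub[(hsub["position"] >= seg.start) & (hsub["position"] < seg.end)]
            hb = in_seg["baf"].to_numpy(dtype=float)
            span_snps = sub[(sub["position"] >= seg.start) & (sub["position"] < seg.end)]
            mean_lrr = float(span_snps["lrr"].mean()) if len(span_snps) else float("nan")
            if len(hb) < min_het_snps:
                state, modes = "indeterminate", []
            else:
                upper, lower = hb[hb > 0.5], hb[hb <= 0.5]
                if len(upper) and len(lower):
                    mode_hi, mode_lo = float(upper.mean()), float(lower.mean())
                    d = (mode_hi - mode_lo) / 2.0
                    two_banded = d >= mode_delta
                else:
                    mode_hi = mode_lo = float(hb.mean())
                    two_banded = False
                if two_banded and seg.end - seg.start >= min_window:
                    state, modes = "imbalanced", [mode_lo, mode_hi]
                else:
                    state, modes = "balanced", [float(hb.mean())]
            out.append(
                BafSegment(chrom, seg.start, seg.end, len(hb), modes, mean_lrr, state)
            )
    return out


def detect_cn_loh(
    snps: pd.DataFrame,
    min_window: int = 360_000,
    expected_het_rate: float | None = None,
    lrr_neutral: float = 0.1,
    p_threshold: float = 1e-6,
    het_band: tuple[float, float] = HET_BAND,
) -> list[LohCall]:
    """Detect copy-neutral LOH runs.

    A call is a maximal run of consecutive SNPs with no heterozygous BAF
    that (a) spans at least ``min_window`` bp, (b) has binomial
    probability ``(1 - het_rate)^n_snps`` below ``p_threshold`` of arising
    by chance, and (c) is copy neutral: |mean LRR| <= ``lrr_neutral``
    (this gate is what distinguishes LOH/UPD from a deletion, which also
    loses the het band but shifts LRR).  ``expected_het_rate`` defaults to
    the genome-wide het fraction of the sample; a rate of zero makes LOH
    undefinable and is refused.
    """
    het_all = _is_het(snps["baf"].to_numpy(dtype=float), het_band)
    if expected_het_rate is None:
        expected_het_rate = float(het_all.mean())
    if expected_het_rate <= 0:
        raise ValueError("expected het rate is 0: LOH is undefinable on this sample")
    out: list[LohCall] = []
    for chrom, sub in snps.groupby("chromosome", sort=False):
        baf = sub["baf"].to_numpy(dtype=float)
        lrr = sub["lrr"].to_numpy(dtype=float)
        pos = sub["position"].to_numpy()
        het = _is_het(baf, het_band)
        n = len(sub)
        i = 0
        while i < n:
            if het[i]:
                i += 1
                continue
            j = i
            while j < n and not het[j]:
                j += 1
            span = int(pos[j - 1]) + 1 - int(pos[i])
            n_run = j - i
            p_run = float((1.0 - expected_het_rate) ** n_run)
            mean_lrr = float(lrr[i:j].mean())
            if span >= min_window and p_run < p_threshold and abs(mean_lrr) <= lrr_neutral:
                out.append(LohCall(chrom, int(pos[i]), int(pos[j - 1]) + 1, n_run, p_run, mean_lrr))
            i = j
    return out
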