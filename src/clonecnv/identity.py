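"""Microsatellite identity verification and probability of identity (PI).

PI is the probability that two individuals share a multilocus genotype.
Two closed forms are used, both functions of the allele-frequency power
sums ``S2 = sum p_i^2`` and ``S4 = sum p_i^4``:

* unrelated individuals under Hardy-Weinberg equilibrium:
  ``PI = 2 * S2^2 - S4``
* full siblings (Mendelian sharing with HWE parents):
  ``PI_sibs = 0.25 + 0.5 * S2 + 0.5 * S2^2 - 0.25 * S4``

Multilocus PI multiplies per-locus values under locus independence.
Genotypes are unordered allele pairs; donor-clone identity checking
compares them locus by locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MicrosatLocus",
    "PiResult",
    "pi_hwe_locus",
    "pi_sibs_locus",
    "multilocus_pi",
    "panel_pi",
    "genotype_match",
]


@dataclass(frozen=True)
class MicrosatLocus:
    name: str
    freqs: tuple[float, ...]

    def __post_init__(self):
        p = np.asarray(self.freqs, dtype=float)
        if len(p) < 1:
            raise ValueError(f"locus {self.name!r}: need at least one allele")
        if (p < 0).any():
            raise ValueError(f"locus {self.name!r}: negative allele frequency")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"locus {self.name!r}: frequencies sum to {p.sum()}, not 1")


@dataclass(frozen=True)
class PiResult:
    per_locus_hwe: dict[str, float]
    per_locus_sibs: dict[str, float]
    multilocus_hwe: float
    multilocus_sibs: float


def _power_sums(locus: MicrosatLocus) -> tuple[float, float]:
    p = np.asarray(locus.freqs, dtype=float)
    return float(np.sum(p**2)), float(np.sum(p**4))


def pi_hwe_locus(locus: MicrosatLocus) -> float:
    """Probability two unrelated HWE individuals share a genotype at this locus."""
    s2, s4 = _power_sums(locus)
    return 2.0 * s2**2 - s4


def pi_sibs_locus(locus: MicrosatLocus) -> float:
    """Probability two full siblings share a genotype at this locus."""
    s2, s4 = _power_sums(locus)
    return 0.25 + 0.5 * s2 + 0.5 * s2**2 - 0.25 * s4


def multilocus_pi(loci: Sequence[MicrosatLocus], model: str = "hwe") -> float:
    """Product of per-locus PIs (loci assumed independent)."""
    if not loci:
        raise ValueError("empty locus panel")
    if model == "hwe":
        per = [pi_hwe_locus(l) for l in loci]
    elif model == "sibs":
        per = [pi_sibs_locus(l) for l in loci]
    else:
        raise ValueError(f"unknown model {model!r} (expected 'hwe' or 'sibs')")
    return float(np.prod(per))


def panel_pi(loci: Sequence[MicrosatLocus]) -> PiResult:
    """Per-locus and multilocus PI under both relatedness models."""
    if not loci:
        raise ValueError("empty locus panel")
    hwe = {l.name: pi_hwe_locus(l) for l in loci}
    sibs = {l.name: pi_sibs_locus(l) for l in loci}
    return PiResult(
        hwe,
        sibs,
        float(np.prod(list(hwe.values()))),
        float(np.prod(list(sibs.values()))),
    )


def genotype_match(
    donor: pd.DataFrame, clone: pd.DataFrame, panel: Sequence[str] | None = None
) -> tuple[dict[str, bool | None], bool]:
    """Compare donor and clone genotypes locus by locus.

    Inputs are genotype tables with columns ``locus, allele1, allele2``
    (one row per locus per individual).  Alleles are compared as unordered
    pairs.  Returns per-locus booleans (``None`` for a locus missing in
    either table, which is excluded from — and does not break — the
    all-match flag over the loci actually compared) plus the all-match
    flag.
    """

    def table(df: pd.DataFrame) -> dict[str, frozenset | tuple]:
        out = {}
        for _, row in df.iterrows():
            a, b = row["allele1"], row["allele2"]
            out[str(row["locus"])] = tuple(sorted((a, b)))
        return out

    d, c = table(donor), table(clone)
    loci = list(panel) if panel is not None else sorted(set(d) | set(c))
    per: dict[str, bool | None] = {}
    for locus in loci:
        if locus not in d or locus not in c:
            per[locus] = None
        else:
            per[locus] = d[locus] == c[locus]
    compared = [v for v in per.values() if v is not None]
    all_match = bool(compared) and all(compared)
    return per, all_match
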