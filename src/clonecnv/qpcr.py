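"""Relative copy number by the 2^-ddCt method and multi-point CNV validation.

The fold change of a target locus is ``2^-(dCt_sample - dCt_calibrator)``
where each dCt normalizes the target Ct against a diploid internal
control locus and the calibrator is the nuclear donor DNA.  Multi-point
validation runs assays inside and outside an array-called interval: the
call is validated when every inside point changes copy number in the
called direction and every outside point stays diploid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import CnvCall
from .simulate import QpcrAssay

__all__ = [
    "FoldChange",
    "BoundaryVerdict",
    "ddct_fold_change",
    "classify_fold",
    "validate_boundaries",
]

WELL_GROUPS = ("sample_target", "sample_control", "calibrator_target", "calibrator_control")


@dataclass(frozen=True)
class FoldChange:
    value: float
    classification: str  # "gain" | "loss" | "neutral"


@dataclass
class BoundaryVerdict:
    verdict: str  # "validated" | "not_validated" | "indeterminate"
    reason: str = ""
    refined_start: int | None = None
    refined_end: int | None = None


def _group_mean(assay: QpcrAssay, group: str) -> float:
    cts = getattr(assay, group)
    if not cts:
        raise ValueError(f"assay {assay.target_id!r}: missing well group {group!r}")
    arr = np.asarray(cts, dtype=float)
    if (arr <= 0).any():
        raise ValueError(f"assay {assay.target_id!r}: non-positive Ct in {group!r}")
    return float(arr.mean())


def ddct_fold_change(assay: QpcrAssay) -> float:
    """2^-ddCt relative copy number of the sample versus the calibrator.

    dCt_sample = mean Ct(sample target) - mean Ct(sample control);
    dCt_cal likewise on calibrator wells; returns 2^-(dCt_sample - dCt_cal).
    A diploid sample at a diploid locus yields 1.0; a 3-copy target 1.5.
    """
    d_sample = _group_mean(assay, "sample_target") - _group_mean(assay, "sample_control")
    d_cal = _group_mean(assay, "calibrator_target") - _group_mean(assay, "calibrator_control")
    return float(2.0 ** -(d_sample - d_cal))


def classify_fold(value: float, gain_thr: float = 1.4, loss_thr: float = 0.7) -> str:
    """Classify a fold change as gain / loss / neutral.

    Default thresholds sit midway between the neutral expectation (1.0)
    and the single-copy change expectations (1.5 gain, 0.5 loss).
    """
    if not loss_thr < 1.0 < gain_thr:
        raise ValueError("thresholds must satisfy loss_thr < 1 < gain_thr")
    if value <= 0:
        raise ValueError("fold change must be > 0")
    if value >= gain_thr:
        return "gain"
    if value <= loss_thr:
        return "loss"
    return "neutral"


def fold_change_result(assay: QpcrAssay, gain_thr: float = 1.4, loss_thr: float = 0.7) -> FoldChange:
    v = ddct_fold_change(assay)
    return FoldChange(v, classify_fold(v, gain_thr, loss_thr))


def validate_boundaries(
    cnv: CnvCall,
    assays: list[QpcrAssay],
    gain_thr: float = 1.4,
    loss_thr: float = 0.7,
) -> BoundaryVerdict:
    """Multi-point qPCR verdict for one CNV call.

    ``validated``: every inside assay classifies concordant with the call
    direction and every outside assay classifies neutral.
    ``not_validated``: no inside assay is concordant.  Anything in
    between (mixed inside results, or non-neutral outside points) is
    ``indeterminate``.  The refined boundary interval spans from the
    outermost concordant inside points out to the innermost neutral
    outside points on each side, when such points exist.
    """
    if not assays:
        return BoundaryVerdict("indeterminate", reason="no assays supplied")
    inside = [a for a in assays if a.inside_expected_cnv]
    outside = [a for a in assays if not a.inside_expected_cnv]
    if not inside:
        return BoundaryVerdict("indeterminate", reason="no assay inside the call")

    def cls(a: QpcrAssay) -> str:
        return classify_fold(ddct_fold_change(a), gain_thr, loss_thr)

    inside_cls = {a.target_id: cls(a) for a in inside}
    outside_cls = {a.target_id: cls(a) for a in outside}
    concordant = [a for a in inside if inside_cls[a.target_id] == cnv.event]
    outside_neutral = [a for a in outside if outside_cls[a.target_id] == "neutral"]

    if not concordant:
        verdict = BoundaryVerdict("not_validated", reason="no inside point shows the called change")
    elif len(concordant) == len(inside) and len(outside_neutral) == len(outside):
        verdict = BoundaryVerdict("validated")
    else:
        verdict = BoundaryVerdict(
            "indeterminate",
            reason=(
                f"{len(concordant)}/{len(inside)} inside points concordant, "
                f"{len(outside_neutral)}/{len(outside)} outside points neutral"
            ),
        )

    if concordant:
        in_lo = min(a.position for a in concordant)
        in_hi = max(a.position for a in concordant)
        left_flank = [a.position for a in outside_neutral if a.position < in_lo]
        right_flank = [a.position for a in outside_neutral if a.position > in_hi]
        verdict.refined_start = max(left_flank) if left_flank else in_lo
        verdict.refined_end = min(right_flank) if right_flank else in_hi
    return verdict
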