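"""Benchmarking helpers: compare calls against simulated ground truth.

These are used to measure recall, false-call counts and probe-level
boundary error of the CNV caller on synthetic genomes where the true
event list is known.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .genome import TruthEvent
from .segmentation import CnvCall


def reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    ov = min(a_end, b_end) - max(a_start, b_start)
    if ov <= 0:
        return 0.0
    return min(ov / (a_end - a_start), ov / (b_end - b_start))


def match_calls_to_truth(
    calls: Sequence[CnvCall],
    truth: Sequence[TruthEvent],
    min_reciprocal: float = 0.5,
) -> tuple[dict[int, int], list[int]]:
    """Greedy 1:1 matching of calls to truth gain/loss events.

    Returns (truth_index -> call_index) for matched pairs with reciprocal
    overlap >= ``min_reciprocal`` and the same direction, plus the indices
    of unmatched (false) calls.
    """
    cn_truth = [(i, ev) for i, ev in enumerate(truth) if ev.kind in ("gain", "loss")]
    matched: dict[int, int] = {}
    used: set[int] = set()
    for ti, ev in cn_truth:
        best, best_ro = None, min_reciprocal
        for ci, call in enumerate(calls):
            if ci in used or call.chromosome != ev.chromosome or call.event != ev.kind:
                continue
            ro = reciprocal_overlap(call.start, call.end, ev.start, ev.end)
            if ro >= best_ro:
                best, best_ro = ci, ro
        if best is not None:
            matched[ti] = best
            used.add(best)
    false_calls = [ci for ci in range(len(calls)) if ci not in used]
    return matched, false_calls


def recall(calls: Sequence[CnvCall], truth: Sequence[TruthEvent], min_reciprocal: float = 0.5) -> float:
    cn_truth = [ev for ev in truth if ev.kind in ("gain", "loss")]
    if not cn_truth:
        return float("nan")
    matched, _ = match_calls_to_truth(calls, truth, min_reciprocal)
    return len(matched) / len(cn_truth)


def boundary_errors_probes(
    calls: Sequence[CnvCall],
    truth: Sequence[TruthEvent],
    probes: pd.DataFrame,
    min_reciprocal: float = 0.5,
) -> list[int]:
    """Per-boundary errors in probe counts for matched truth events.

    For each matched event the error at each end is the number of probes
    between the called boundary and the nearest probe inside the true
    event (0 = the call starts/ends exactly at the event's edge probes).
    """
    matched, _ = match_calls_to_truth(calls, truth, min_reciprocal)
    errors: list[int] = []
    truth_list = list(truth)
    for ti, ci in matched.items():
        ev, call = truth_list[ti], list(calls)[ci]
        pos = probes.loc[probes["chromosome"] == ev.chromosome, "position"].to_numpy()
        true_i0 = int(np.searchsorted(pos, ev.start, side="left"))
        true_i1 = int(np.searchsorted(pos, ev.end, side="left"))  # exclusive
        call_i0 = int(np.searchsorted(pos, call.start, side="left"))
        call_i1 = int(np.searchsorted(pos, call.end - 1, side="right"))
        errors.append(abs(call_i0 - true_i0))
        errors.append(abs(call_i1 - true_i1))
    return errors
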