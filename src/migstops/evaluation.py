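"""Recovery scoring of detected stopovers against simulated ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class RecoveryScore:
    precision: float
    recall: float
    median_boundary_error_h: float
    n_true: int
    n_detected: int
    n_matched: int


def _overlap_h(a_start, a_end, b_start, b_end) -> float:
    lo = max(pd.Timestamp(a_start), pd.Timestamp(b_start))
    hi = min(pd.Timestamp(a_end), pd.Timestamp(b_end))
    return max(0.0, (hi - lo).total_seconds() / 3600.0)


def score_recovery(detected, truth_stopovers, min_true_duration_h: float = 3.0,
                   min_overlap_h: float = 0.5) -> RecoveryScore:
    """Precision / recall / boundary error of detected vs true stopovers.

    A true stopover counts as recovered when some detected interval of the
    same individual overlaps it by more than ``min_overlap_h``; a detected
    interval is a true positive when it overlaps any true stopover (of any
    duration).  Boundary error pools |start error| and |end error| over
    matched (true >= threshold, best-overlap) pairs.
    """
    truths = [t for t in truth_stopovers
              if t.duration_h >= min_true_duration_h]
    errors = []
    n_matched = 0
    for t in truths:
        best, best_ov = None, 0.0
        for d in detected:
            if d.individual_id != t.individual_id:
                continue
            ov = _overlap_h(d.start, d.end, t.start, t.end)
            if ov > best_ov:
                best, best_ov = d, ov
        if best is not None and best_ov > min_overlap_h:
            n_matched += 1
            errors.append(abs((best.start - t.start).total_seconds()) / 3600.0)
            errors.append(abs((best.end - t.end).total_seconds()) / 3600.0)

    n_tp_detected = 0
    for d in detected:
        for t in truth_stopovers:
            if (d.individual_id == t.individual_id
                    and _overlap_h(d.start, d.end, t.start, t.end)
                    > min_overlap_h):
                n_tp_detected += 1
                break

    precision = n_tp_detected / len(detected) if detected else float("nan")
    recall = n_matched / len(truths) if truths else float("nan")
    med = float(np.median(errors)) if errors else float("nan")
    return RecoveryScore(precision=precision, recall=recall,
                         median_boundary_error_h=med, n_true=len(truths),
                         n_detected=len(detected), n_matched=n_matched)
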