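"""Event-level validation: matching detections against a reference,
sensitivity and false detection rate, and threshold sweeps.

Sensitivity = TP / (TP + FN): the fraction of reference events the
detector found.  False detection rate (FDR) = FP / (FP + TP): the
fraction of detections that are spurious.  A detected event counts as a
true positive when it overlaps in time with exactly one reference event
(greedy one-to-one matching in time order).

:func:`threshold_sweep` reruns a detector over a grid of SD thresholds
and picks the threshold that maximizes sensitivity minus FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Callable, Optional, Sequence

import numpy as np

from .core import EventTable
from . import detection as det

__all__ = [
    "ConfusionCounts",
    "SweepResult",
    "match_events",
    "performance_metrics",
    "threshold_grid",
    "threshold_sweep",
    "evaluate_detection",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")


@dataclass(frozen=True)
class SweepResult:
    thresholds: tuple[float, ...]
    sensitivity_curve: tuple[Optional[float], ...]
    fdr_curve: tuple[Optional[float], ...]
    optimal_threshold: float

    def objective_curve(self) -> list[float]:
        """sensitivity - FDR per threshold, with the absent-value
        substitutions used for the optimization."""
        return [
            (s if s is not None else 0.0) - (f if f is not None else 1.0)
            for s, f in zip(self.sensitivity_curve, self.fdr_curve)
        ]


def match_events(detected: EventTable, reference: EventTable) -> ConfusionCounts:
    """Greedy one-to-one temporal-overlap matching.

    Both tables must be internally disjoint.  Walking detections in time
    order, each is matched to the earliest not-yet-matched reference
    event it overlaps.  TP = matched pairs, FP = unmatched detections,
    FN = unmatched reference events.
    """
    detected.assert_disjoint("detected table")
    reference.assert_disjoint("reference table")
    ref = reference.events
    used = [False] * len(ref)
    tp = 0
    for d in detected:
        for j, r in enumerate(ref):
            if used[j]:
                continue
            if r.start_s >= d.end_s:
                break  # reference sorted; no later event can overlap
            if d.overlaps(r):
                used[j] = True
                tp += 1
                break
    return ConfusionCounts(tp=tp, fp=len(detected) - tp, fn=len(ref) - tp)


def performance_metrics(counts: ConfusionCounts) -> dict:
    """Sensitivity and FDR from confusion counts.

    A zero denominator yields ``None`` (explicitly absent), never a
    silent zero.
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    sensitivity = tp / (tp + fn) if tp + fn > 0 else None
    fdr = fp / (fp + tp) if fp + tp > 0 else None
    return {"sensitivity": sensitivity, "fdr": fdr}


def threshold_grid(start: float, stop: float, step: float) -> list[float]:
    """Half-open arithmetic grid ``{start, start+step, ...}`` strictly
    below ``stop`` — e.g. (0, 5, 0.2) gives the 25 thresholds 0..4.8."""
    if step <= 0:
        raise ValueError("step must be positive")
    if not start < stop:
        raise ValueError("need start < stop")
    n = int(np.floor((stop - start) / step - 1e-9)) + 1
    return [start + k * step for k in range(n)]


def _spindle_runner(series, rate, thr, channel):
    return det.detect_spindles(
        series, rate, det.SpindleParams(threshold_sd=thr), channel=channel
    )


def _kcomplex_runner(series, rate, thr, channel):
    return det.detect_kcomplexes(
        series, rate, det.KComplexParams(threshold_sd=thr), channel=channel
    )


def _rem_runner(series, rate, thr, channel):
    return det.detect_rems(series, rate, threshold_sd=thr, channel=channel)


def _twitch_runner(series, rate, thr, channel):
    return det.detect_muscle_twitches(series, rate, threshold_sd=thr, channel=channel)


_DETECTOR_RUNNERS: dict[str, Callable] = {
    "spindle": _spindle_runner,
    "kcomplex": _kcomplex_runner,
    "rem": _rem_runner,
    "twitch": _twitch_runner,
}


def threshold_sweep(
    series,
    rate: float,
    reference: EventTable,
    detector: str,
    grid: Sequence[float],
    channel: str = "",
) -> SweepResult:
    """Run a detector once per grid threshold against a reference table.

    The optimal threshold maximizes sensitivity minus FDR; an absent FDR
    (no detections) counts as 1 inside the objective only; ties go to the
    earliest grid value.
    """
    if detector not in _DETECTOR_RUNNERS:
        raise ValueError(
            f"unknown detector {detector!r}; choose from {sorted(_DETECTOR_RUNNERS)}"
        )
    if len(grid) == 0:
        raise ValueError("threshold grid is empty")
    runner = _DETECTOR_RUNNERS[detector]
    sens_curve: list[Optional[float]] = []
    fdr_curve: list[Optional[float]] = []
    for thr in grid:
        metrics = performance_metrics(
            match_events(runner(series, rate, thr, channel), reference)
        )
        sens_curve.append(metrics["sensitivity"])
        fdr_curve.append(metrics["fdr"])
    objective = [
        (s if s is not None else 0.0) - (f if f is not None else 1.0)
        for s, f in zip(sens_curve, fdr_curve)
    ]
    best = int(np.argmax(objective))  # argmax takes the first maximum
    return SweepResult(
        thresholds=tuple(float(t) for t in grid),
        sensitivity_curve=tuple(sens_curve),
        fdr_curve=tuple(fdr_curve),
        optimal_threshold=float(grid[best]),
    )


def evaluate_detection(detected: EventTable, reference: EventTable) -> dict:
    """Convenience: counts plus metrics in one dictionary."""
    counts = match_events(detected, reference)
    out = performance_metrics(counts)
    out.update(tp=counts.tp, fp=counts.fp, fn=counts.fn)
    return out
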