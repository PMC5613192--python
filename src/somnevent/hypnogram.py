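"""Hypnogram editing, sleep statistics, and staging of detected events.

The native hypnogram is one integer stage code per second (see
:class:`somnevent.core.Hypnogram`).  Statistics follow the standard
definitions: time in bed (TIB) is the whole recording, total sleep time
(TST) the seconds spent in N1+N2+N3+REM, sleep efficiency 100*TST/TIB,
stage latency the time from recording start to the first second of the
stage, and WASO the Wake time after the first sleep second.  Artefact
seconds count toward TIB but are excluded from TST and WASO.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import EventTable, Hypnogram, StageDescription, normalize_stage_name

__all__ = ["SleepStats", "edit_stage", "sleep_statistics", "stage_of_events", "plot_hypnogram"]

_SLEEP_STAGES = ("N1", "N2", "N3", "REM")


@dataclass(frozen=True)
class SleepStats:
    """Summary sleep statistics of one hypnogram.  Durations in minutes,
    percentages of total sleep time; latencies are ``None`` for stages
    never reached."""

    time_in_bed_min: float
    total_sleep_time_min: float
    sleep_efficiency_pct: float
    waso_min: float
    stage_duration_min: dict
    stage_pct_tst: dict
    stage_latency_min: dict

    def to_dict(self) -> dict:
        out = {
            "time_in_bed_min": self.time_in_bed_min,
            "total_sleep_time_min": self.total_sleep_time_min,
            "sleep_efficiency_pct": self.sleep_efficiency_pct,
            "waso_min": self.waso_min,
        }
        for name, v in self.stage_duration_min.items():
            out[f"{name}_duration_min"] = v
        for name, v in self.stage_pct_tst.items():
            out[f"{name}_pct_tst"] = v
        for name, v in self.stage_latency_min.items():
            out[f"{name}_latency_min"] = v
        return out


def edit_stage(hyp: Hypnogram, start_s: float, end_s: float, stage) -> Hypnogram:
    """Return a new hypnogram with seconds ``[start_s, end_s)`` set to
    ``stage`` (a stage name or an integer code from the vocabulary)."""
    if not 0 <= start_s < end_s <= hyp.duration_s:
        raise ValueError(
            f"interval [{start_s}, {end_s}) outside hypnogram [0, {hyp.duration_s}]"
        )
    if isinstance(stage, str):
        code = hyp.description.code(stage)
    else:
        code = int(stage)
        if code not in hyp.description.codes:
            raise ValueError(
                f"stage code {code} absent from vocabulary {hyp.description.mapping}"
            )
    stages = hyp.stages.copy()
    stages[int(start_s) : int(end_s)] = code
    return Hypnogram(stages, hyp.description)


def sleep_statistics(hyp: Hypnogram) -> SleepStats:
    """Compute standard sleep statistics from a per-second hypnogram."""
    mapping = hyp.description.mapping
    stages = hyp.stages
    tib_min = stages.size / 60.0

    sleep_codes = [mapping[s] for s in _SLEEP_STAGES if s in mapping]
    is_sleep = np.isin(stages, sleep_codes)
    tst_min = float(is_sleep.sum()) / 60.0
    efficiency = 100.0 * tst_min / tib_min if tib_min > 0 else 0.0

    wake_code = mapping.get("Wake")
    waso_min = 0.0
    if is_sleep.any() and wake_code is not None:
        first_sleep = int(np.argmax(is_sleep))
        waso_min = float(np.sum(stages[first_sleep:] == wake_code)) / 60.0

    durations, pct_tst, latencies = {}, {}, {}
    for name, code in mapping.items():
        where = stages == code
        durations[name] = float(where.sum()) / 60.0
        if name in _SLEEP_STAGES:
            pct_tst[name] = 100.0 * durations[name] / tst_min if tst_min > 0 else None
        latencies[name] = float(np.argmax(where)) / 60.0 if where.any() else None

    return SleepStats(
        time_in_bed_min=tib_min,
        total_sleep_time_min=tst_min,
        sleep_efficiency_pct=efficiency,
        waso_min=waso_min,
        stage_duration_min=durations,
        stage_pct_tst=pct_tst,
        stage_latency_min=latencies,
    )


def stage_of_events(hyp: Hypnogram, events: EventTable) -> EventTable:
    """Stamp each event with the hypnogram stage code at its onset second.

    Events that span a stage boundary are staged by their onset.
    """
    stages = []
    for ev in events:
        if not 0 <= ev.start_s < hyp.duration_s:
            raise ValueError(
                f"{ev.kind} event at {ev.start_s} s lies outside the "
                f"hypnogram [0, {hyp.duration_s}) s"
            )
        stages.append(hyp.stage_at(ev.start_s))
    return events.with_stage(stages)


def plot_hypnogram(hyp: Hypnogram, ax=None, order: Optional[list[str]] = None):
    """Stage-vs-time step plot of the hypnogram (convenience extra).

    ``order`` controls the top-to-bottom display order of stages; it does
    not affect any computation.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 2.5))
    if order is None:
        order = ["Art", "Wake", "REM", "N1", "N2", "N3"]
    order = [normalize_stage_name(s) for s in order if normalize_stage_name(s) in hyp.description.mapping]
    ypos = {hyp.description.mapping[name]: -i for i, name in enumerate(order)}
    y = np.array([ypos[c] for c in hyp.stages])
    t = np.arange(hyp.duration_s) / 60.0
    ax.step(t, y, where="post", lw=1.0, color="k")
    ax.set_yticks([-i for i in range(len(order))], order)
    ax.set_xlabel("time (min)")
    return ax
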