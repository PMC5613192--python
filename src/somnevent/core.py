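"""Core containers shared across the package.

The objects here are deliberately thin: a :class:`Recording` wraps a
channels x samples matrix in microvolts, a :class:`Hypnogram` is a
per-second series of integer stage codes, and detected or injected sleep
events live in an :class:`EventTable`.  All processing functions treat
these as immutable inputs and return new objects (the non-destructive
contract: the original signal can always be retrieved).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "StageDescription",
    "DEFAULT_STAGES",
    "Annotation",
    "Event",
    "EventTable",
    "Hypnogram",
    "EVENT_KINDS",
]

#: Event kinds understood by the detectors and the synthetic generator.
EVENT_KINDS = ("spindle", "kcomplex", "slowwave", "rem", "twitch", "peak")

#: Canonical stage vocabulary: artefact, wake, the three NREM depths and REM.
DEFAULT_STAGES = {"Art": -1, "Wake": 0, "N1": 1, "N2": 2, "N3": 3, "REM": 4}

_STAGE_ALIASES = {
    "art": "Art",
    "artefact": "Art",
    "artifact": "Art",
    "wake": "Wake",
    "w": "Wake",
    "n1": "N1",
    "s1": "N1",
    "n2": "N2",
    "s2": "N2",
    "n3": "N3",
    "s3": "N3",
    "rem": "REM",
    "r": "REM",
}


def normalize_stage_name(name: str) -> str:
    """Map a free-form stage label onto the canonical six-stage vocabulary."""
    key = name.strip().lower()
    if key in _STAGE_ALIASES:
        return _STAGE_ALIASES[key]
    raise ValueError(
        f"unknown sleep stage name {name!r}; expected one of "
        "Art, Wake, N1, N2, N3, REM (or a common alias)"
    )


@dataclass(frozen=True)
class Recording:
    """Multichannel polysomnographic recording.

    Parameters
    ----------
    data
        2-D array, channels x samples, in microvolts.
    rate
        Sampling frequency in Hz.
    channels
        Channel labels, one per row of ``data``.
    start_time
        Optional absolute clock time of the first sample, seconds after
        midnight.
    """

    data: np.ndarray
    rate: float
    channels: tuple[str, ...]
    start_time: Optional[float] = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim == 1:
            data = data[np.newaxis, :]
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channels", tuple(self.channels))
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if data.ndim != 2:
            raise ValueError("data must be a channels x samples matrix")
        if len(self.channels) != data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel labels for {data.shape[0]} rows"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def channel(self, label: str) -> np.ndarray:
        """Return one channel's samples (a copy) by label."""
        try:
            idx = self.channels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in recording {list(self.channels)}"
            ) from None
        return self.data[idx].copy()


@dataclass(frozen=True)
class StageDescription:
    """Vocabulary of a hypnogram file: stage name -> integer code, plus the
    number of stage values per second stored in the file."""

    mapping: dict = field(default_factory=lambda: dict(DEFAULT_STAGES))
    values_per_second: Fraction = Fraction(1)

    def __post_init__(self) -> None:
        vps = self.values_per_second
        if not isinstance(vps, Fraction):
            vps = Fraction(vps).limit_denominator(10_000)
            object.__setattr__(self, "values_per_second", vps)
        if vps <= 0:
            raise ValueError("values_per_second must be positive")
        mapping = {normalize_stage_name(k): int(v) for k, v in self.mapping.items()}
        if len(set(mapping.values())) != len(mapping):
            raise ValueError("stage codes must be unique")
        object.__setattr__(self, "mapping", mapping)

    @property
    def codes(self) -> dict:
        """Inverse mapping: integer code -> stage name."""
        return {v: k for k, v in self.mapping.items()}

    def code(self, stage: str) -> int:
        return self.mapping[normalize_stage_name(stage)]


@dataclass(frozen=True)
class Annotation:
    """Free-text note anchored to a time interval of the recording."""

    onset: float
    duration: float
    text: str = ""

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"annotation onset must be >= 0, got {self.onset}")
        if self.duration < 0:
            raise ValueError(f"annotation duration must be >= 0, got {self.duration}")


@dataclass(frozen=True)
class Event:
    """One detected or injected event.

    Intervals are half-open ``[start_s, end_s)`` in seconds from the start
    of the recording.  Peaks are instantaneous (``start_s == end_s``).
    """

    kind: str
    channel: str
    start_s: float
    end_s: float
    stage: Optional[int] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "peak":
            if self.end_s < self.start_s:
                raise ValueError("peak end_s must equal start_s")
        elif not self.start_s < self.end_s:
            raise ValueError(
                f"event must have start_s < end_s, got [{self.start_s}, {self.end_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def overlaps(self, other: "Event") -> bool:
        return self.start_s < other.end_s and other.start_s < self.end_s


class EventTable:
    """Ordered collection of events, sorted by start time then channel."""

    def __init__(self, events: Iterable[Event] = ()):
        self._events = sorted(events, key=lambda e: (e.start_s, e.channel, e.end_s))

    def __len__(self) -> int:
        return len(self._events)

    def __iter__(self) -> Iterator[Event]:
        return iter(self._events)

    def __getitem__(self, i):
        return self._events[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, EventTable) and self._events == other._events

    def __repr__(self) -> str:
        return f"EventTable({len(self._events)} events)"

    @property
    def events(self) -> list[Event]:
        return list(self._events)

    def with_stage(self, stages: Iterable[Optional[int]]) -> "EventTable":
        return EventTable(
            replace(e, stage=s) for e, s in zip(self._events, stages, strict=True)
        )

    def filter(self, predicate) -> "EventTable":
        return EventTable(e for e in self._events if predicate(e))

    def assert_disjoint(self, name: str = "table") -> None:
        """Raise if any two events in the table overlap in time."""
        for a, b in zip(self._events, self._events[1:]):
            if a.overlaps(b):
                raise ValueError(
                    f"{name} contains overlapping events at "
                    f"[{a.start_s}, {a.end_s}) and [{b.start_s}, {b.end_s})"
                )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kind": [e.kind for e in self._events],
                "channel": [e.channel for e in self._events],
                "start_s": [e.start_s for e in self._events],
                "end_s": [e.end_s for e in self._events],
                "duration_s": [e.duration_s for e in self._events],
                "stage": [e.stage for e in self._events],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "EventTable":
        events = []
        for row in df.itertuples(index=False):
            stage = getattr(row, "stage", None)
            if stage is None or (isinstance(stage, float) and np.isnan(stage)):
                stage = None
            else:
                stage = int(stage)
            events.append(
                Event(
                    kind=str(row.kind),
                    channel=str(row.channel),
                    start_s=float(row.start_s),
                    end_s=float(row.end_s),
                    stage=stage,
                )
            )
        return cls(events)


class Hypnogram:
    """Per-second sleep-stage series with a fixed stage vocabulary."""

    def __init__(self, stages, description: Optional[StageDescription] = None):
        self.description = description if description is not None else StageDescription()
        stages = np.asarray(stages, dtype=np.int64)
        if stages.ndim != 1:
            raise ValueError("hypnogram stages must be a 1-D sequence")
        if stages.size == 0:
            raise ValueError("hypnogram is empty")
        known = set(self.description.mapping.values())
        bad = set(np.unique(stages).tolist()) - known
        if bad:
            raise ValueError(
                f"hypnogram contains codes {sorted(bad)} absent from the "
                f"stage description {self.description.mapping}"
            )
        self.stages = stages
        self.stages.setflags(write=False)

    @property
    def duration_s(self) -> int:
        return int(self.stages.size)

    def stage_at(self, t_s: float) -> int:
        """Stage code at time ``t_s`` (seconds from recording start)."""
        idx = int(t_s)
        if not 0 <= idx < self.duration_s:
            raise ValueError(f"time {t_s} s outside hypnogram [0, {self.duration_s})")
        return int(self.stages[idx])

    def seconds_in(self, stage: str) -> int:
        code = self.description.code(stage)
        return int(np.sum(self.stages == code))

    def copy(self) -> "Hypnogram":
        return Hypnogram(self.stages.copy(), self.description)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Hypnogram)
            and np.array_equal(self.stages, other.stages)
            and self.description.mapping == other.description.mapping
        )

    def __repr__(self) -> str:
        return f"Hypnogram({self.duration_s} s)"
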