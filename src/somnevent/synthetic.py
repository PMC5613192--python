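"""Synthetic polysomnography with a ground-truth event ledger.

Generates stage-structured EEG/EOG/EMG nights — 1/f ("pink") Gaussian
background plus additive waveform templates for the five transient event
kinds — together with the hypnogram and an :class:`EventTable` of every
injected event, so each detector and the whole evaluation loop can be
exercised without any external data.

The templates are archetypes, not physiological simulations: a spindle is
a Hann-windowed 13 Hz burst (1 s, 25 uV peak), a K-complex a smoothed
biphasic negative-then-positive transient (0.8 s, 120 uV peak-to-peak), a
slow wave a 1 Hz high-amplitude oscillation epoch, a rapid eye movement a
sharp 0.1 s-rise deflection, a muscle twitch a brief 25 Hz burst.
Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import Event, EventTable, Hypnogram, Recording, StageDescription

__all__ = [
    "DEFAULT_MORPHOLOGY",
    "GroundTruth",
    "PsgConfig",
    "background_eeg",
    "event_template",
    "inject_events",
    "benchmark_signal",
    "make_psg",
]

#: Default waveform parameters per event kind (durations s, amplitudes uV).
DEFAULT_MORPHOLOGY = {
    "spindle": {"freq": 13.0, "duration": 1.0, "amp": 25.0},
    "kcomplex": {"duration": 0.8, "p2p": 120.0},
    "slowwave": {"freq": 1.0, "duration": 4.0, "p2p": 100.0},
    "rem": {"duration": 0.5, "amp": 150.0, "rise": 0.1},
    "twitch": {"freq": 25.0, "duration": 0.3, "amp": 60.0},
}

#: Stage in which each event kind is injected when stage consistency is on.
STAGE_OF_KIND = {
    "spindle": "N2",
    "kcomplex": "N2",
    "slowwave": "N3",
    "rem": "REM",
    "twitch": "REM",
}


@dataclass(frozen=True)
class GroundTruth:
    """Ledger tying a synthetic night to its injected events."""

    events: EventTable
    hypnogram: Hypnogram
    seed: int
    params: dict


def background_eeg(
    duration_s: float, rate: float, seed: int, slope: float = -1.0
) -> np.ndarray:
    """Gaussian noise with power spectrum proportional to ``f**slope``
    (slope -1 is the classic 1/f EEG background), unit standard
    deviation, reproducible by seed."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration_s * rate))
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (slope / 2.0)
    x = np.fft.irfft(spectrum * shaping, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def event_template(kind: str, rate: float, **morphology) -> np.ndarray:
    """Additive waveform template for one event kind (in microvolts)."""
    morph = dict(DEFAULT_MORPHOLOGY[kind])
    morph.update(morphology)
    d = float(morph["duration"])
    n = max(2, int(round(d * rate)))
    t = np.arange(n) / rate
    hann = np.sin(np.pi * t / d) ** 2
    if kind in ("spindle", "twitch"):
        return morph["amp"] * hann * np.sin(2.0 * np.pi * morph["freq"] * t)
    if kind == "kcomplex":
        # sharp negative lobe then positive rebound, one smoothed cycle
        wave = -np.sin(2.0 * np.pi * t / d) * hann
        return morph["p2p"] * wave / (wave.max() - wave.min())
    if kind == "slowwave":
        wave = np.sin(2.0 * np.pi * morph["freq"] * t) * hann
        return morph["p2p"] * wave / (wave.max() - wave.min())
    if kind == "rem":
        rise = float(morph["rise"])
        wave = np.where(t < rise, t / rise, np.maximum(0.0, (d - t) / (d - rise)))
        return morph["amp"] * wave
    raise ValueError(f"no template for event kind {kind!r}")


def inject_events(
    series,
    rate: float,
    kind: str,
    onsets: Sequence[float],
    morphology: Optional[dict] = None,
    channel: str = "",
) -> tuple[np.ndarray, EventTable]:
    """Add one template per onset to a copy of ``series``.

    Returns the new signal and the ledger of injected events (one per
    onset).  Requested events must fit inside the series and must not
    overlap one another.
    """
    x = np.asarray(series, dtype=float).copy()
    morph = dict(DEFAULT_MORPHOLOGY[kind])
    if morphology:
        morph.update(morphology)
    duration = float(morph["duration"])
    onsets = sorted(float(o) for o in onsets)
    for a, b in zip(onsets, onsets[1:]):
        if b < a + duration:
            raise ValueError(
                f"requested {kind} events at {a} s and {b} s overlap "
                f"(duration {duration} s)"
            )
    template = event_template(kind, rate, **morph)
    events = []
    for onset in onsets:
        start = int(round(onset * rate))
        if start < 0 or start + template.size > x.size:
            raise ValueError(f"{kind} event at {onset} s does not fit in the series")
        x[start : start + template.size] += template
        events.append(
            Event(kind=kind, channel=channel, start_s=onset, end_s=onset + duration)
        )
    return x, EventTable(events)


def _slot_onsets(
    start_s: float,
    length_s: float,
    n_events: int,
    duration: float,
    rng: np.random.Generator,
    margin: float = 2.0,
) -> list[float]:
    """Place ``n_events`` non-overlapping onsets inside a block by slotting:
    one event per equal slot, jittered within the slot."""
    usable = length_s - 2.0 * margin
    if n_events <= 0 or usable <= duration:
        return []
    n_events = min(n_events, int(usable // (duration + 1.0)))
    if n_events <= 0:
        return []
    slot = usable / n_events
    onsets = []
    for k in range(n_events):
        jitter = rng.uniform(0.0, max(slot - duration - 0.5, 0.0))
        onsets.append(start_s + margin + k * slot + jitter)
    return onsets


def benchmark_signal(
    kind: str,
    seed: int,
    duration_s: float = 600.0,
    rate: float = 100.0,
    n_events: int = 20,
    background_sd: Optional[float] = None,
    morphology: Optional[dict] = None,
    channel: str = "C3",
) -> tuple[np.ndarray, EventTable]:
    """Single-channel benchmark night for one detector.

    Ten minutes of background with ``n_events`` injected events of one
    kind at the default morphology: pink 10 uV background for the EEG
    kinds (spindle, kcomplex, slowwave), pink 10 uV for the EOG (rem),
    white 3 uV for the EMG (twitch).
    """
    if background_sd is None:
        background_sd = 3.0 if kind == "twitch" else 10.0
    slope = 0.0 if kind == "twitch" else -1.0
    bg = background_sd * background_eeg(duration_s, rate, seed, slope=slope)
    morph = dict(DEFAULT_MORPHOLOGY[kind])
    if morphology:
        morph.update(morphology)
    rng = np.random.default_rng(seed + 1_000_003)
    onsets = _slot_onsets(0.0, duration_s, n_events, morph["duration"], rng)
    return inject_events(bg, rate, kind, onsets, morph, channel=channel)


@dataclass(frozen=True)
class PsgConfig:
    """Generation config for a full synthetic night.

    ``stage_blocks`` tile the night cyclically; densities are events per
    minute of the kind's home stage.  Background SDs are in microvolts.
    """

    duration_s: float = 1800.0
    rate: float = 100.0
    eeg_channels: tuple[str, ...] = ("C3", "Cz")
    eog_channel: str = "EOG1"
    emg_channel: str = "EMG1"
    eeg_background_sd: float = 10.0
    eog_background_sd: float = 10.0
    emg_background_sd: float = 3.0
    stage_blocks: tuple[tuple[str, float], ...] = (
        ("Wake", 60.0),
        ("N1", 60.0),
        ("N2", 300.0),
        ("N3", 180.0),
        ("REM", 120.0),
    )
    events_per_min: dict = field(
        default_factory=lambda: {
            "spindle": 2.0,
            "kcomplex": 1.0,
            "slowwave": 3.0,
            "rem": 4.0,
            "twitch": 1.0,
        }
    )
    morphology: dict = field(default_factory=dict)
    stage_consistent: bool = True

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.rate <= 0:
            raise ValueError("duration and rate must be positive")
        if not self.stage_blocks:
            raise ValueError("stage_blocks must tile the night")

    @classmethod
    def from_dict(cls, d: dict) -> "PsgConfig":
        d = dict(d)
        if "stage_blocks" in d:
            d["stage_blocks"] = tuple((str(s), float(v)) for s, v in d["stage_blocks"])
        if "eeg_channels" in d:
            d["eeg_channels"] = tuple(d["eeg_channels"])
        return cls(**d)


def _build_hypnogram(config: PsgConfig) -> Hypnogram:
    desc = StageDescription()
    duration = int(round(config.duration_s))
    stages = np.empty(duration, dtype=np.int64)
    pos = 0
    while pos < duration:
        for name, secs in config.stage_blocks:
            n = min(int(round(secs)), duration - pos)
            stages[pos : pos + n] = desc.code(name)
            pos += n
            if pos >= duration:
                break
    return Hypnogram(stages, desc)


def _stage_runs(hyp: Hypnogram) -> list[tuple[int, int, int]]:
    """(code, start_s, length_s) for each maximal constant-stage run."""
    stages = hyp.stages
    edges = np.flatnonzero(np.diff(stages)) + 1
    starts = np.concatenate(([0], edges))
    stops = np.concatenate((edges, [stages.size]))
    return [(int(stages[a]), int(a), int(b - a)) for a, b in zip(starts, stops)]


def make_psg(config: Optional[PsgConfig] = None, seed: int = 0) -> tuple[Recording, GroundTruth]:
    """Generate a full multichannel synthetic night.

    Events are injected into the first EEG channel (spindles and
    K-complexes in N2 blocks, slow waves in N3), the EOG channel (REMs)
    and the EMG channel (twitches), at the configured per-minute
    densities.  Deterministic per (config, seed).
    """
    if config is None:
        config = PsgConfig()
    rng = np.random.default_rng(seed)
    hyp = _build_hypnogram(config)
    n = int(round(config.duration_s * config.rate))

    def bg(sd: float, slope: float = -1.0) -> np.ndarray:
        sub = int(rng.integers(0, 2**31 - 1))
        return sd * background_eeg(config.duration_s, config.rate, sub, slope=slope)

    channels: dict[str, np.ndarray] = {}
    for label in config.eeg_channels:
        channels[label] = bg(config.eeg_background_sd)
    channels[config.eog_channel] = bg(config.eog_background_sd)
    channels[config.emg_channel] = bg(config.emg_background_sd, slope=0.0)

    home_channel = {
        "spindle": config.eeg_channels[0],
        "kcomplex": config.eeg_channels[0],
        "slowwave": config.eeg_channels[0],
        "rem": config.eog_channel,
        "twitch": config.emg_channel,
    }

    all_events: list[Event] = []
    desc = hyp.description
    for code, start_s, length_s in _stage_runs(hyp):
        stage_name = desc.codes[code]
        kinds_here = [
            k for k, st in STAGE_OF_KIND.items() if st == stage_name
            and config.events_per_min.get(k, 0) > 0
        ]
        if not kinds_here:
            continue
        # joint slotting so co-resident kinds (spindle + kcomplex in N2)
        # never collide on the shared channel
        requests: list[str] = []
        for k in kinds_here:
            count = int(round(config.events_per_min[k] * length_s / 60.0))
            requests.extend([k] * count)
        if not requests:
            continue
        rng.shuffle(requests)
        max_dur = max(
            dict(DEFAULT_MORPHOLOGY[k], **config.morphology.get(k, {}))["duration"]
            for k in kinds_here
        )
        onsets = _slot_onsets(start_s, length_s, len(requests), max_dur, rng)
        for kind, onset in zip(requests, onsets):
            morph = dict(DEFAULT_MORPHOLOGY[kind])
            morph.update(config.morphology.get(kind, {}))
            label = home_channel[kind]
            channels[label], table = inject_events(
                channels[label], config.rate, kind, [onset], morph, channel=label
            )
            all_events.extend(table)

    labels = tuple(channels)
    data = np.vstack([channels[c] for c in labels])
    recording = Recording(data=data, rate=config.rate, channels=labels)
    truth = GroundTruth(
        events=EventTable(all_events),
        hypnogram=hyp,
        seed=seed,
        params={"config": config},
    )
    return recording, truth
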