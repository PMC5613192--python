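"""File formats: European Data Format recordings, hypnogram text files
with description-file conversion, event tables and annotations.

EDF reading delegates the signal path to MNE after a strict header
validation pass (continuous EDF/EDF+C only; degenerate physical
calibration rejected).  EDF writing is implemented here: plain EDF,
16-bit samples, 1-second data records, microvolt physical dimension.

Hypnogram files are single-column text (.txt/.csv/.hyp), one stage value
per line, with an optional sidecar description file giving the stage
name -> code mapping and the number of values per second; on read they
are converted to the native 1-value-per-second representation (expansion
by repetition, decimation by sampling the value at each whole second).
"""

from __future__ import annotations

import csv
import os
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    Annotation,
    EventTable,
    Hypnogram,
    Recording,
    StageDescription,
)

__all__ = [
    "EdfFormatError",
    "read_edf",
    "write_edf",
    "read_stage_description",
    "write_stage_description",
    "read_hypnogram",
    "write_hypnogram",
    "read_event_table",
    "write_event_table",
    "read_annotations",
    "write_annotations",
]

PathLike = Union[str, os.PathLike]


class EdfFormatError(ValueError):
    """Raised for structurally invalid or unsupported EDF files."""


# ---------------------------------------------------------------------------
# EDF header layout: 256 bytes of fixed-width ASCII fields, then
# 256 bytes per signal split across eight per-signal arrays.
# ---------------------------------------------------------------------------

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _edf_number(value: float, width: int = 8) -> str:
    """Format a float into <= width ASCII chars, round-trippable."""
    for prec in (7, 6, 5, 4, 3, 2, 1, 0):
        s = f"{value:.{prec}g}"
        if len(s) <= width:
            return s
    raise EdfFormatError(f"cannot encode {value} in {width} chars")


def _read_header(path: PathLike) -> dict:
    with open(path, "rb") as fh:
        fixed = fh.read(256)
        if len(fixed) < 256:
            raise EdfFormatError(f"{path}: truncated EDF header")
        try:
            version = fixed[0:8].decode("ascii").strip()
            start_time = fixed[176:184].decode("ascii").strip()
            reserved = fixed[192:236].decode("ascii").strip()
            n_records = int(fixed[236:244].decode("ascii").strip())
            record_dur = float(fixed[244:252].decode("ascii").strip())
            n_signals = int(fixed[252:256].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as exc:
            raise EdfFormatError(f"{path}: corrupt EDF header ({exc})") from exc
        if version != "0":
            raise EdfFormatError(f"{path}: unsupported EDF version {version!r}")
        if n_signals < 1:
            raise EdfFormatError(f"{path}: no signals declared")
        per = fh.read(256 * n_signals)
        if len(per) < 256 * n_signals:
            raise EdfFormatError(f"{path}: truncated per-signal header")

        def fields(offset: int, width: int) -> list[str]:
            base = offset * n_signals
            return [
                per[base + i * width : base + (i + 1) * width].decode("ascii").strip()
                for i in range(n_signals)
            ]

        labels = fields(0, 16)
        # per-signal arrays: label 16, transducer 80, dim 8, pmin 8, pmax 8,
        # dmin 8, dmax 8, prefilter 80, samples/record 8, reserved 32
        off = 16 + 80 + 8
        try:
            pmin = [float(v) for v in fields(off, 8)]
            pmax = [float(v) for v in fields(off + 8, 8)]
            dmin = [int(float(v)) for v in fields(off + 16, 8)]
            dmax = [int(float(v)) for v in fields(off + 24, 8)]
            spr = [int(v) for v in fields(off + 32 + 80, 8)]
        except ValueError as exc:
            raise EdfFormatError(f"{path}: corrupt per-signal header ({exc})") from exc
    return {
        "start_time": start_time,
        "reserved": reserved,
        "n_records": n_records,
        "record_dur": record_dur,
        "n_signals": n_signals,
        "labels": labels,
        "pmin": pmin,
        "pmax": pmax,
        "dmin": dmin,
        "dmax": dmax,
        "spr": spr,
    }


def read_edf(path: PathLike) -> Recording:
    """Read an EDF/EDF+C file into a :class:`Recording` in microvolts.

    Physical calibration (digital -> physical via the header min/max) is
    applied per channel; channel order is preserved.  Discontinuous EDF+D
    files and degenerate calibrations (physical min == max) are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EDF file not found: {path}")
    header = _read_header(path)
    if header["reserved"].startswith("EDF+D"):
        raise EdfFormatError(f"{path}: discontinuous EDF+D files are not supported")
    for label, lo, hi in zip(header["labels"], header["pmin"], header["pmax"]):
        if lo == hi:
            raise EdfFormatError(
                f"{path}: channel {label!r} has physical min == max ({lo}); "
                "degenerate calibration"
            )
    for label, lo, hi in zip(header["labels"], header["dmin"], header["dmax"]):
        if lo == hi:
            raise EdfFormatError(
                f"{path}: channel {label!r} has digital min == max; degenerate"
            )

    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE returns volts; the package works in uV
    start_time: Optional[float] = None
    st = header["start_time"]
    if len(st) == 8 and st[2] == "." and st[5] == ".":
        try:
            hh, mm, ss = (int(p) for p in st.split("."))
            start_time = float(hh * 3600 + mm * 60 + ss)
        except ValueError:
            start_time = None
    return Recording(
        data=data,
        rate=float(raw.info["sfreq"]),
        channels=tuple(raw.ch_names),
        start_time=start_time,
    )


def write_edf(recording: Recording, path: PathLike) -> Path:
    """Write a :class:`Recording` to a plain EDF file.

    16-bit samples, 1-second data records (the sampling rate must be a
    whole number of Hz).  A final partial second is padded by repeating
    each channel's last sample.  The round-trip error through
    :func:`read_edf` is bounded by one digital quantization step.
    """
    path = Path(path)
    data = np.asarray(recording.data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("cannot write non-finite samples to EDF")
    rate = recording.rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {rate}")
    spr = int(round(rate))
    n_ch, n_samp = data.shape
    n_records = int(np.ceil(n_samp / spr)) if n_samp else 0
    if n_records == 0:
        raise ValueError("cannot write an empty recording")

    # physical range per channel, re-parsed from its ASCII encoding so the
    # quantization used here matches what any reader will reconstruct
    pmins, pmaxs, scaled = [], [], []
    for row in data:
        lo, hi = float(row.min()), float(row.max())
        if lo == hi:
            lo, hi = lo - 1.0, hi + 1.0
        lo_s, hi_s = _edf_number(lo), _edf_number(hi)
        lo_p, hi_p = float(lo_s), float(hi_s)
        if lo_p >= row.min() or hi_p <= row.max():
            margin = max(1e-6, 1e-5 * (hi - lo))
            lo_s, hi_s = _edf_number(lo - margin), _edf_number(hi + margin)
            lo_p, hi_p = float(lo_s), float(hi_s)
        gain = (_DIG_MAX - _DIG_MIN) / (hi_p - lo_p)
        dig = np.rint((row - lo_p) * gain + _DIG_MIN)
        scaled.append(np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2"))
        pmins.append(lo_s)
        pmaxs.append(hi_s)

    if recording.start_time is not None:
        total = int(recording.start_time) % 86400
        st = f"{total // 3600:02d}.{(total % 3600) // 60:02d}.{total % 60:02d}"
    else:
        st = "00.00.00"

    with open(path, "wb") as fh:
        fh.write(_ascii("0", 8))
        fh.write(_ascii("X X X X", 80))  # patient id (anonymous)
        fh.write(_ascii("Startdate X X X X", 80))
        fh.write(_ascii("01.01.01", 8))  # dummy start date; clock time below
        fh.write(_ascii(st, 8))
        fh.write(_ascii(str(256 * (n_ch + 1)), 8))
        fh.write(_ascii("", 44))
        fh.write(_ascii(str(n_records), 8))
        fh.write(_ascii("1", 8))
        fh.write(_ascii(str(n_ch), 4))
        for label in recording.channels:
            fh.write(_ascii(label, 16))
        for _ in recording.channels:
            fh.write(_ascii("", 80))  # transducer
        for _ in recording.channels:
            fh.write(_ascii("uV", 8))
        for s in pmins:
            fh.write(_ascii(s, 8))
        for s in pmaxs:
            fh.write(_ascii(s, 8))
        for _ in recording.channels:
            fh.write(_ascii(str(_DIG_MIN), 8))
        for _ in recording.channels:
            fh.write(_ascii(str(_DIG_MAX), 8))
        for _ in recording.channels:
            fh.write(_ascii("", 80))  # prefiltering
        for _ in recording.channels:
            fh.write(_ascii(str(spr), 8))
        for _ in recording.channels:
            fh.write(_ascii("", 32))
        pad = n_records * spr - n_samp
        for rec in range(n_records):
            sl = slice(rec * spr, (rec + 1) * spr)
            for ch in range(n_ch):
                chunk = scaled[ch][sl]
                if chunk.size < spr:  # pad final record with the last sample
                    chunk = np.concatenate(
                        [chunk, np.full(spr - chunk.size, scaled[ch][-1], dtype="<i2")]
                    )
                fh.write(chunk.tobytes())
    return path


# ---------------------------------------------------------------------------
# Hypnogram text files and the stage-description sidecar
# ---------------------------------------------------------------------------


def _parse_vps(token: str) -> Fraction:
    token = token.strip()
    if "/" in token:
        num, den = token.split("/", 1)
        return Fraction(int(num), int(den))
    return Fraction(token).limit_denominator(10_000)


def read_stage_description(path: PathLike) -> StageDescription:
    """Read a description file: lines ``StageName<TAB>code`` plus a
    ``time`` line giving the number of hypnogram values per second
    (a decimal or a fraction like ``1/30``)."""
    mapping: dict = {}
    vps = Fraction(1)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace("\t", " ").split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'Name value', got {line!r}"
                )
            name, value = parts
            if name.lower() == "time":
                vps = _parse_vps(value)
            else:
                mapping[name] = int(value)
    if not mapping:
        raise ValueError(f"{path}: no stage definitions found")
    return StageDescription(mapping=mapping, values_per_second=vps)


def write_stage_description(description: StageDescription, path: PathLike) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for name, code in description.mapping.items():
            fh.write(f"{name}\t{code}\n")
        vps = description.values_per_second
        token = str(vps) if vps.denominator > 1 else str(int(vps))
        fh.write(f"time\t{token}\n")
    return path


def read_hypnogram(
    path: PathLike, description: Optional[StageDescription] = None
) -> Hypnogram:
    """Read a single-column hypnogram text file (.txt/.csv/.hyp) and
    convert it to the native one-value-per-second representation.

    With ``values_per_second`` v < 1 each file value is repeated over its
    1/v seconds; with v > 1 the value at each whole second is taken.
    Codes absent from the description mapping raise a conversion error
    naming the code and line.
    """
    if description is None:
        description = StageDescription()
    values: list[int] = []
    known = set(description.mapping.values())
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip().rstrip(",;")
            if not token or token.startswith("#"):
                continue
            try:
                code = int(float(token))
            except ValueError:
                if lineno == 1:
                    continue  # tolerate a single header line
                raise ValueError(
                    f"{path}:{lineno}: cannot parse stage value {token!r}"
                ) from None
            if code not in known:
                raise ValueError(
                    f"{path}:{lineno}: stage code {code} is not in the "
                    f"description mapping {description.mapping}"
                )
            values.append(code)
    if not values:
        raise ValueError(f"{path}: hypnogram file contains no stage values")
    vps = description.values_per_second
    duration_s = int(round(len(values) / vps))
    arr = np.asarray(values, dtype=np.int64)
    # value covering whole second i lives at file index floor(i * vps)
    idx = np.minimum(
        np.arange(duration_s) * vps.numerator // vps.denominator, len(values) - 1
    )
    return Hypnogram(arr[idx], StageDescription(description.mapping, Fraction(1)))


def write_hypnogram(
    hyp: Hypnogram, path: PathLike, description_path: Optional[PathLike] = None
) -> Path:
    """Write a native hypnogram (one value per line, one per second); with
    ``description_path``, also write the matching description sidecar."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for code in hyp.stages:
            fh.write(f"{int(code)}\n")
    if description_path is not None:
        write_stage_description(
            StageDescription(hyp.description.mapping, Fraction(1)), description_path
        )
    return path


# ---------------------------------------------------------------------------
# Event tables and annotations
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = ["kind", "channel", "start_s", "end_s", "duration_s", "stage"]


def write_event_table(
    events: EventTable, path: PathLike, delimiter: str = ","
) -> Path:
    """Write an event table (header ``kind,channel,start_s,end_s,
    duration_s,stage``), timestamps at 6-decimal fixed precision."""
    if delimiter not in (",", "\t"):
        raise ValueError("delimiter must be ',' or tab")
    path = Path(path)
    df = events.to_dataframe()[_EVENT_COLUMNS]
    df.to_csv(path, sep=delimiter, index=False, float_format="%.6f")
    return path


def read_event_table(path: PathLike, delimiter: Optional[str] = None) -> EventTable:
    path = Path(path)
    if delimiter is None:
        with open(path, encoding="utf-8") as fh:
            first = fh.readline()
        delimiter = "\t" if "\t" in first else ","
    df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in _EVENT_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: event table missing columns {missing}")
    return EventTable.from_dataframe(df)


def write_annotations(annotations: Sequence[Annotation], path: PathLike) -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["onset_s", "duration_s", "text"])
        for ann in sorted(annotations, key=lambda a: a.onset):
            writer.writerow([f"{ann.onset:.6f}", f"{ann.duration:.6f}", ann.text])
    return path


def read_annotations(path: PathLike) -> list[Annotation]:
    """Read annotations (``onset_s,duration_s,text`` rows, or
    ``onset_s,end_s,text`` if the second column is named ``end_s``).
    Returns the list sorted by onset; negative onsets are an error."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return []
    if df.empty and len(df.columns) == 0:
        return []
    cols = {c.strip().lower(): c for c in df.columns}
    onset_col = cols.get("onset_s") or cols.get("onset")
    if onset_col is None:
        raise ValueError(f"{path}: no onset column found")
    text_col = cols.get("text") or cols.get("description")
    annotations = []
    for _, row in df.iterrows():
        onset = float(row[onset_col])
        if "duration_s" in cols or "duration" in cols:
            dur = float(row[cols.get("duration_s") or cols.get("duration")])
        elif "end_s" in cols or "end" in cols:
            dur = float(row[cols.get("end_s") or cols.get("end")]) - onset
        else:
            dur = 0.0
        text = "" if text_col is None else str(row[text_col])
        annotations.append(Annotation(onset=onset, duration=dur, text=text))
    return sorted(annotations, key=lambda a: a.onset)
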