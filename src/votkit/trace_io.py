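"""Containers and on-disk I/O for vascular-occlusion-test (VOT) recordings.

A recording couples one or more uniformly sampled channel streams (NIRS
chromophores at 50 Hz, a DCS blood-flow index at ~38.5 Hz, plus derived
channels) with the cuff-event annotations that define the test phases and
with subject metadata.

On disk a recording is a directory holding one CSV per (sampling rate,
start time) group of channels — first column ``time_s`` in absolute seconds,
one column per channel, empty cells marking missing samples — plus a
``recording.json`` sidecar carrying units, sampling rates, cuff events and
subject metadata.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ChannelStream",
    "CuffEvents",
    "SubjectMeta",
    "VotRecording",
    "TraceIOError",
    "read_recording",
    "write_recording",
    "validate_recording",
    "CHANNEL_UNITS",
    "GROUPS",
]

#: canonical channel names -> default units
CHANNEL_UNITS = {
    "O2HB": "uM",
    "HHB": "uM",
    "TSI": "%",
    "BFI": "cm^2/s",
    "RBF": "%baseline",
    "D_O2HB": "uM",
    "D_HHB": "uM",
    "D_TSI": "%",
}

GROUPS = ("climber", "nonclimber")

SIDECAR_NAME = "recording.json"
#: significant digits used when writing sample values (declared precision)
VALUE_SIGFIGS = 12
TIME_DECIMALS = 6


class TraceIOError(ValueError):
    """Malformed file, missing column, or invariant violation during I/O."""


@dataclass
class ChannelStream:
    """One uniformly sampled channel; NaN marks a missing sample."""

    name: str
    unit: str
    fs: float
    t0: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise TraceIOError(f"stream {self.name!r}: fs must be > 0, got {self.fs}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise TraceIOError(f"stream {self.name!r}: values must be 1-D")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def t_end(self) -> float:
        return self.t0 + max(self.n - 1, 0) / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def window(self, t_start: float, t_end: float) -> tuple[np.ndarray, np.ndarray]:
        """Samples inside the closed interval [t_start, t_end].

        Edges are matched with a microsecond tolerance so that windows laid
        out in seconds pick up samples that land exactly on a boundary
        despite floating-point time arithmetic.
        """
        tol = 1e-6
        lo = int(math.ceil((t_start - self.t0 - tol) * self.fs))
        hi = int(math.floor((t_end - self.t0 + tol) * self.fs))
        lo = max(lo, 0)
        hi = min(hi, self.n - 1)
        if hi < lo:
            return np.empty(0), np.empty(0)
        idx = np.arange(lo, hi + 1)
        return self.t0 + idx / self.fs, self.values[idx]

    def shifted(self, dt: float) -> "ChannelStream":
        return replace(self, t0=self.t0 + dt, values=self.values.copy())


@dataclass
class CuffEvents:
    """Cuff inflation/release annotations defining the VOT phases."""

    t_inflate: float
    t_release: float
    end_time: float
    t_contract: float | None = None

    def __post_init__(self) -> None:
        if not (self.t_inflate < self.t_release < self.end_time):
            raise TraceIOError(
                "events out of order: require t_inflate < t_release < end_time, "
                f"got inflate={self.t_inflate}, release={self.t_release}, "
                f"end={self.end_time}"
            )
        if self.t_contract is not None and not self.t_contract < self.t_inflate:
            raise TraceIOError(
                f"events out of order: t_contract={self.t_contract} must precede "
                f"t_inflate={self.t_inflate}"
            )

    def shifted(self, dt: float) -> "CuffEvents":
        return CuffEvents(
            t_inflate=self.t_inflate + dt,
            t_release=self.t_release + dt,
            end_time=self.end_time + dt,
            t_contract=None if self.t_contract is None else self.t_contract + dt,
        )


@dataclass
class SubjectMeta:
    subject_id: str
    group: str
    notes: str = ""

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise TraceIOError(
                f"subject {self.subject_id!r}: group must be one of {GROUPS}, "
                f"got {self.group!r}"
            )


@dataclass
class VotRecording:
    """A subject's multi-rate VOT recording."""

    meta: SubjectMeta
    streams: dict[str, ChannelStream] = field(default_factory=dict)
    events: CuffEvents = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.events is None:
            raise TraceIOError("recording requires cuff events")
        for name, s in self.streams.items():
            if s.name != name:
                raise TraceIOError(f"stream key {name!r} != stream name {s.name!r}")

    def has(self, *names: str) -> bool:
        return all(n in self.streams for n in names)

    def get(self, name: str) -> ChannelStream:
        try:
            return self.streams[name]
        except KeyError:
            raise TraceIOError(
                f"recording {self.meta.subject_id!r} has no {name!r} stream"
            ) from None

    def shifted(self, dt: float) -> "VotRecording":
        """Recording translated in time by +dt seconds (for invariance tests)."""
        return VotRecording(
            meta=self.meta,
            streams={k: s.shifted(dt) for k, s in self.streams.items()},
            events=self.events.shifted(dt),
        )


# ---------------------------------------------------------------------------
# reading / writing


def _stream_groups(rec: VotRecording) -> dict[tuple[float, float], list[str]]:
    groups: dict[tuple[float, float], list[str]] = {}
    for name in sorted(rec.streams):
        s = rec.streams[name]
        groups.setdefault((s.fs, s.t0), []).append(name)
    return groups


def _group_filename(fs: float) -> str:
    return f"channels_{fs:g}hz.csv"


def write_recording(rec: VotRecording, path: str | Path) -> None:
    """Write ``rec`` as CSVs (one per sampling-rate group) plus a JSON sidecar.

    Lossless up to :data:`VALUE_SIGFIGS` significant digits on sample values
    and :data:`TIME_DECIMALS` decimals on the time column.
    """
    if not rec.streams:
        raise TraceIOError("no channels: refusing to write an empty recording")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    sidecar: dict = {
        "subject_id": rec.meta.subject_id,
        "group": rec.meta.group,
        "notes": rec.meta.notes,
        "events": {
            "t_inflate": rec.events.t_inflate,
            "t_release": rec.events.t_release,
            "end_time": rec.events.end_time,
            "t_contract": rec.events.t_contract,
        },
        "streams": {},
    }

    used_names: set[str] = set()
    for (fs, t0), names in _stream_groups(rec).items():
        fname = _group_filename(fs)
        if fname in used_names:  # same fs, different t0
            fname = f"channels_{fs:g}hz_{len(used_names)}.csv"
        used_names.add(fname)
        n = max(rec.streams[c].n for c in names)
        cols = {"time_s": [f"{t0 + k / fs:.{TIME_DECIMALS}f}" for k in range(n)]}
        for c in names:
            v = rec.streams[c].values
            cols[c] = [
                "" if not np.isfinite(x) else f"{x:.{VALUE_SIGFIGS}g}" for x in v
            ] + [""] * (n - v.size)
            sidecar["streams"][c] = {
                "file": fname,
                "unit": rec.streams[c].unit,
                "fs": fs,
                "t0": t0,
            }
        pd.DataFrame(cols).to_csv(path / fname, index=False)

    with open(path / SIDECAR_NAME, "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=1)


def read_recording(path: str | Path) -> VotRecording:
    """Read a recording directory written in the documented CSV+JSON layout."""
    path = Path(path)
    sidecar_path = path / SIDECAR_NAME
    if not sidecar_path.exists():
        raise TraceIOError(f"{sidecar_path}: sidecar not found")
    try:
        with open(sidecar_path, encoding="utf-8") as fh:
            sidecar = json.load(fh)
    except json.JSONDecodeError as exc:
        raise TraceIOError(f"{sidecar_path}: malformed JSON ({exc})") from exc

    for key in ("subject_id", "group", "events", "streams"):
        if key not in sidecar:
            raise TraceIOError(f"{sidecar_path}: missing field {key!r}")
    ev = sidecar["events"]
    for key in ("t_inflate", "t_release", "end_time"):
        if key not in ev:
            raise TraceIOError(f"{sidecar_path}: events missing field {key!r}")
    events = CuffEvents(
        t_inflate=float(ev["t_inflate"]),
        t_release=float(ev["t_release"]),
        end_time=float(ev["end_time"]),
        t_contract=None if ev.get("t_contract") is None else float(ev["t_contract"]),
    )
    meta = SubjectMeta(
        subject_id=str(sidecar["subject_id"]),
        group=str(sidecar["group"]),
        notes=str(sidecar.get("notes", "")),
    )

    frames: dict[str, pd.DataFrame] = {}
    streams: dict[str, ChannelStream] = {}
    for name, info in sidecar["streams"].items():
        fname = info["file"]
        if fname not in frames:
            fpath = path / fname
            if not fpath.exists():
                raise TraceIOError(f"{fpath}: channel file not found")
            try:
                frames[fname] = pd.read_csv(fpath)
            except Exception as exc:  # pragma: no cover - pandas message varies
                raise TraceIOError(f"{fpath}: malformed CSV ({exc})") from exc
        df = frames[fname]
        if "time_s" not in df.columns:
            raise TraceIOError(f"{path / fname}: missing required column 'time_s'")
        if name not in df.columns:
            raise TraceIOError(f"{path / fname}: missing required column {name!r}")
        streams[name] = ChannelStream(
            name=name,
            unit=str(info["unit"]),
            fs=float(info["fs"]),
            t0=float(info["t0"]),
            values=df[name].to_numpy(dtype=float),
        )

    return VotRecording(meta=meta, streams=streams, events=events)


# ---------------------------------------------------------------------------
# validation


def _nan_runs(times: np.ndarray, mask: np.ndarray) -> Iterable[tuple[float, float]]:
    """Yield (start, end) spans of consecutive missing samples."""
    if not mask.any():
        return
    idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    for a, b in zip(starts, ends):
        yield float(times[idx[a]]), float(times[idx[b]])


def validate_recording(
    rec: VotRecording,
    *,
    min_ba_s: float = 60.0,
    min_hy_s: float = 180.0,
    max_gap_s: float = 1.0,
) -> list[str]:
    """Structural validation; returns one deterministic finding per violation.

    Checks the channel-set requirement (both chromophores or a BFI stream),
    baseline coverage of at least ``min_ba_s`` before inflation, post-release
    coverage of ``min_hy_s`` (or to the recording end), and flags runs of
    missing samples longer than ``max_gap_s`` inside the occlusion or
    hyperemia phase.
    """
    findings: list[str] = []
    ev = rec.events

    if not (rec.has("O2HB", "HHB") or rec.has("BFI")):
        findings.append("recording must contain O2HB and HHB, or BFI")

    ba_start = max(0.0, ev.t_inflate - min_ba_s)
    hy_end = min(ev.t_release + min_hy_s, ev.end_time)
    tol = 1e-6
    for name in sorted(rec.streams):
        s = rec.streams[name]
        if s.n == 0:
            findings.append(f"{name}: empty stream")
            continue
        if s.t0 > ba_start + tol:
            findings.append(
                f"{name}: baseline window shorter than {min_ba_s:g} s "
                f"(stream starts at {s.t0:g} s, needs {ba_start:g} s)"
            )
        if s.t_end < hy_end - 0.5 / s.fs - tol:
            findings.append(
                f"{name}: post-release coverage ends at {s.t_end:g} s, "
                f"needs {hy_end:g} s"
            )
        mask = ~np.isfinite(s.values)
        if mask.any():
            t = s.times()
            for g0, g1 in _nan_runs(t, mask):
                length = g1 - g0 + 1.0 / s.fs
                if length <= max_gap_s:
                    continue
                for phase, lo, hi in (
                    ("OC", ev.t_inflate, ev.t_release),
                    ("HY", ev.t_release, hy_end),
                ):
                    if g0 < hi and g1 > lo:
                        findings.append(
                            f"{name}: gap in {phase} phase "
                            f"({length:.2f} s at {max(g0, lo):.2f} s)"
                        )
    return findings
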