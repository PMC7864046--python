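"""Multichannel sensor recordings and sliding-window segments.

A :class:`SignalRecording` holds named channels sampled at per-channel
rates (sEMG is typically recorded an order of magnitude faster than the
inertial channels), an activity-label annotation track, and the
quasi-static calibration phases (standing, optionally lying) used for
normalization and sensor-to-segment alignment.

Recordings are persisted as plain CSV files (one per sampling rate, with
a ``time`` column) plus a JSON sidecar carrying channel metadata, label
intervals and calibration phases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Channel",
    "LabelInterval",
    "SignalRecording",
    "WindowSet",
    "read_recording",
    "write_recording",
    "ParseError",
]


class ParseError(ValueError):
    """Raised when a recording file violates the expected dialect."""


@dataclass
class Channel:
    """One named sample stream.

    Parameters
    ----------
    name : str
        Unique channel name, e.g. ``"acc_LT_x"``.
    data : ndarray
        Samples, finite floats.
    rate : float
        Sampling rate in Hz.
    modality : str
        One of ``"emg"``, ``"acc"``, ``"gyr"``, ``"angle"``.
    sensor : str or None
        Physical unit the channel belongs to (groups tri-axial
        accelerometer/gyroscope axes), e.g. ``"acc_LT"``.
    axis : str or None
        Axis letter for tri-axial sensors (``"x"``, ``"y"``, ``"z"``).
    segment : str or None
        Body segment the sensor is mounted on (``"lower_back"``,
        ``"thigh"``, ``"shank"``), used by calibration.
    """

    name: str
    data: np.ndarray
    rate: float
    modality: str
    sensor: str | None = None
    axis: str | None = None
    segment: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.rate <= 0:
            raise ValueError(f"channel {self.name!r}: rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"channel {self.name!r}: non-finite samples")

    @property
    def duration(self) -> float:
        return len(self.data) / self.rate

    def times(self) -> np.ndarray:
        return np.arange(len(self.data)) / self.rate


@dataclass(frozen=True)
class LabelInterval:
    start: float
    end: float
    label: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"label {self.label!r}: end must exceed start")


@dataclass
class SignalRecording:
    """A set of synchronized channels with annotations.

    All channels start at t = 0; different sampling rates are allowed.
    ``standing_phase`` (and optionally ``lying_phase`` / ``motion_phase``)
    delimit quasi-static or calibration-movement intervals in seconds.
    """

    channels: dict[str, Channel]
    labels: list[LabelInterval] = field(default_factory=list)
    standing_phase: tuple[float, float] | None = None
    lying_phase: tuple[float, float] | None = None
    motion_phase: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        ivs = sorted(self.labels, key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end - 1e-9:
                raise ValueError(
                    f"label intervals overlap: {a.label!r} and {b.label!r}"
                )
        if self.standing_phase is not None:
            s, e = self.standing_phase
            if e - s < 1.0:
                raise ValueError("standing phase must last at least 1 s")

    @property
    def duration(self) -> float:
        return max(ch.duration for ch in self.channels.values())

    def sensors(self) -> dict[str, list[Channel]]:
        """Group channels by physical sensor unit (insertion order kept)."""
        groups: dict[str, list[Channel]] = {}
        for ch in self.channels.values():
            key = ch.sensor or ch.name
            groups.setdefault(key, []).append(ch)
        return groups

    def phase_slice(self, channel: str, phase: tuple[float, float]) -> np.ndarray:
        ch = self.channels[channel]
        i0 = int(round(phase[0] * ch.rate))
        i1 = int(round(phase[1] * ch.rate))
        return ch.data[i0:i1]

    def copy(self) -> "SignalRecording":
        return SignalRecording(
            channels={
                k: replace(v, data=v.data.copy()) for k, v in self.channels.items()
            },
            labels=list(self.labels),
            standing_phase=self.standing_phase,
            lying_phase=self.lying_phase,
            motion_phase=self.motion_phase,
        )


@dataclass
class WindowSet:
    """Sliding-window segmentation of a recording.

    ``arrays[name]`` is an (n_windows, n_samples) matrix for one channel;
    window lengths differ between channels when rates differ.  ``starts``
    are window start times in seconds, shared across channels.
    """

    arrays: dict[str, np.ndarray]
    channel_meta: dict[str, Channel]
    labels: list[str]
    starts: np.ndarray
    window_ms: float
    overlap: float

    @property
    def n_windows(self) -> int:
        return len(self.labels)

    @property
    def step_ms(self) -> float:
        return self.window_ms * (1.0 - self.overlap)


# ---------------------------------------------------------------------------
# persistence: CSV (one file per sampling rate) + JSON sidecar


def _rate_files(stem: Path, rates: Sequence[float]) -> dict[float, Path]:
    if len(rates) == 1:
        return {rates[0]: stem.with_suffix(".csv")}
    return {
        r: stem.with_name(f"{stem.name}_{r:g}hz").with_suffix(".csv") for r in rates
    }


def write_recording(rec: SignalRecording, path: str | Path) -> Path:
    """Write ``rec`` as CSV file(s) plus a JSON sidecar.

    ``path`` names the primary CSV; the sidecar is written next to it
    with a ``.json`` suffix.  Returns the sidecar path.
    """
    path = Path(path)
    stem = path.with_suffix("")
    rates = sorted({ch.rate for ch in rec.channels.values()}, reverse=True)
    files = _rate_files(stem, rates)
    for rate, fpath in files.items():
        cols = {"time": None}
        names = [n for n, c in rec.channels.items() if c.rate == rate]
        n = len(rec.channels[names[0]].data)
        cols["time"] = np.arange(n) / rate
        for name in names:
            cols[name] = rec.channels[name].data
        pd.DataFrame(cols).to_csv(fpath, index=False)
    sidecar = {
        "channels": {
            name: {
                "rate": ch.rate,
                "modality": ch.modality,
                "sensor": ch.sensor,
                "axis": ch.axis,
                "segment": ch.segment,
                "file": files[ch.rate].name,
            }
            for name, ch in rec.channels.items()
        },
        "labels": [[iv.start, iv.end, iv.label] for iv in rec.labels],
        "standing_phase": list(rec.standing_phase) if rec.standing_phase else None,
        "lying_phase": list(rec.lying_phase) if rec.lying_phase else None,
        "motion_phase": list(rec.motion_phase) if rec.motion_phase else None,
    }
    sidecar_path = stem.with_suffix(".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=1))
    return sidecar_path


def _check_time_column(time: np.ndarray, rate: float, fname: str) -> None:
    if len(time) < 2:
        return
    dt = np.diff(time)
    if np.any(dt <= 0):
        i = int(np.argmax(dt <= 0))
        raise ParseError(f"{fname}: time not strictly increasing at row {i + 1}")
    expected = 1.0 / rate
    bad = np.abs(dt - expected) > 0.01 * expected
    if np.any(bad):
        i = int(np.argmax(bad))
        raise ParseError(
            f"{fname}: gap in time stamps at row {i + 1} "
            f"(step {dt[i]:.6g} s, expected {expected:.6g} s)"
        )


def read_recording(path: str | Path) -> SignalRecording:
    """Read a recording written by :func:`write_recording`.

    ``path`` may point at the primary CSV or directly at the sidecar.
    """
    path = Path(path)
    sidecar_path = path if path.suffix == ".json" else path.with_suffix(".json")
    if not sidecar_path.exists():
        raise ParseError(f"sidecar not found: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("channels", "labels", "standing_phase"):
        if key not in meta:
            raise ParseError(f"{sidecar_path.name}: sidecar missing {key!r}")
    frames: dict[str, pd.DataFrame] = {}
    channels: dict[str, Channel] = {}
    for name, cmeta in meta["channels"].items():
        fname = cmeta["file"]
        if fname not in frames:
            fpath = sidecar_path.with_name(fname)
            frames[fname] = pd.read_csv(fpath)
            if "time" not in frames[fname].columns:
                raise ParseError(f"{fname}: missing 'time' column")
            _check_time_column(
                frames[fname]["time"].to_numpy(), float(cmeta["rate"]), fname
            )
        df = frames[fname]
        if name not in df.columns:
            raise ParseError(f"{fname}: missing channel column {name!r}")
        channels[name] = Channel(
            name=name,
            data=df[name].to_numpy(dtype=float),
            rate=float(cmeta["rate"]),
            modality=cmeta["modality"],
            sensor=cmeta.get("sensor"),
            axis=cmeta.get("axis"),
            segment=cmeta.get("segment"),
        )
    try:
        labels = [LabelInterval(float(a), float(b), str(l)) for a, b, l in meta["labels"]]
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{sidecar_path.name}: malformed label row ({exc})") from exc

    def _phase(key: str) -> tuple[float, float] | None:
        v = meta.get(key)
        return (float(v[0]), float(v[1])) if v else None

    return SignalRecording(
        channels=channels,
        labels=labels,
        standing_phase=_phase("standing_phase"),
        lying_phase=_phase("lying_phase"),
        motion_phase=_phase("motion_phase"),
    )
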