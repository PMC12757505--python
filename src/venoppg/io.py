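"""On-disk format for multichannel PPG recordings.

A recording for one patient is a directory::

    <subject_id>/
        finger_left.csv    # time_s,value,valid  (125 Hz arterial)
        finger_right.csv
        ear.csv
        venous_left.csv    # 4 Hz venous
        venous_right.csv
        meta.json          # subject id, rates, timeline, calibration refs

Timestamps are seconds relative to manoeuvre start (Su onset at t = 0;
the rest calibration tail occupies negative times). CSVs are comma
separated, '.' decimal, UTF-8 with LF endings, and floats are written
with 17 significant digits so that a write/read round-trip is lossless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .phases import PhaseTimeline

ARTERIAL_CHANNELS = ("finger_left", "finger_right", "ear")
VENOUS_CHANNELS = ("venous_left", "venous_right")
CHANNEL_NAMES = ARTERIAL_CHANNELS + VENOUS_CHANNELS

ARTERIAL_RATE_HZ = 125.0
VENOUS_RATE_HZ = 4.0


@dataclass
class Channel:
    """One PPG channel: uniformly sampled values with a validity mask."""

    name: str
    sampling_rate: float
    times: np.ndarray
    values: np.ndarray
    valid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.times.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.name not in CHANNEL_NAMES:
            raise ConfigurationError(f"unknown channel name {self.name!r}")
        if not (len(self.times) == len(self.values) == len(self.valid)):
            raise ConfigurationError("times/values/valid length mismatch")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            expected = 1.0 / self.sampling_rate
            if np.any(dt <= 0) or np.any(np.abs(dt - expected) > 1e-9):
                raise ConfigurationError(
                    f"channel {self.name}: sample spacing must be "
                    f"1/{self.sampling_rate} s (strictly increasing)")
        expected_rate = (ARTERIAL_RATE_HZ if self.name in ARTERIAL_CHANNELS
                         else VENOUS_RATE_HZ)
        if abs(self.sampling_rate - expected_rate) > 1e-9:
            raise ConfigurationError(
                f"channel {self.name} must be sampled at {expected_rate} Hz")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class PPGRecording:
    """All channels, phase timeline and calibration metadata for one patient."""

    subject_id: str
    channels: dict  # name -> Channel
    timeline: PhaseTimeline
    venous_full_emptying_reference_left: float
    venous_full_emptying_reference_right: float

    def __post_init__(self):
        missing = set(CHANNEL_NAMES) - set(self.channels)
        if missing:
            raise ConfigurationError(f"missing channels: {sorted(missing)}")
        if (self.venous_full_emptying_reference_left <= 0
                or self.venous_full_emptying_reference_right <= 0):
            raise ConfigurationError("full-emptying references must be > 0")
        lo, hi = self.timeline.span()
        for ch in self.channels.values():
            if ch.times[0] > lo + 1e-9 or ch.times[-1] < hi - 1.0 / ch.sampling_rate - 1e-9:
                raise ConfigurationError(
                    f"channel {ch.name} does not cover the timeline span")

    def venous_reference(self, side: str) -> float:
        if side == "left":
            return self.venous_full_emptying_reference_left
        if side == "right":
            return self.venous_full_emptying_reference_right
        raise ConfigurationError(f"side must be 'left' or 'right', got {side!r}")


def write_recording(rec: PPGRecording, path) -> Path:
    """Write ``rec`` under ``path/<subject_id>/``; returns the directory."""
    base = Path(path) / rec.subject_id
    try:
        base.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create recording directory {base}: {exc}") from exc
    for name, ch in rec.channels.items():
        df = pd.DataFrame({
            "time_s": ch.times,
            "value": ch.values,
            "valid": ch.valid.astype(int),
        })
        # 17 significant digits guarantee a lossless float round-trip
        df.to_csv(base / f"{name}.csv", index=False, lineterminator="\n",
                  float_format="%.17g")
    meta = {
        "subject_id": rec.subject_id,
        "sampling_rates": {name: ch.sampling_rate for name, ch in rec.channels.items()},
        "timeline": rec.timeline.to_dict(),
        "venous_full_emptying_reference_left": rec.venous_full_emptying_reference_left,
        "venous_full_emptying_reference_right": rec.venous_full_emptying_reference_right,
    }
    with open(base / "meta.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return base


def read_recording(path) -> PPGRecording:
    """Read a recording directory written by :func:`write_recording`."""
    base = Path(path)
    meta_path = base / "meta.json"
    if not meta_path.exists():
        raise IOError(f"missing meta.json in {base}")
    with open(meta_path, encoding="utf-8") as fh:
        meta = json.load(fh)
    channels = {}
    for name, rate in meta["sampling_rates"].items():
        csv_path = base / f"{name}.csv"
        if not csv_path.exists():
            raise IOError(f"recording {base}: missing channel file for {name!r}")
        df = pd.read_csv(csv_path, float_precision="round_trip")
        channels[name] = Channel(
            name=name,
            sampling_rate=float(rate),
            times=df["time_s"].to_numpy(),
            values=df["value"].to_numpy(),
            valid=df["valid"].to_numpy().astype(bool),
        )
    return PPGRecording(
        subject_id=meta["subject_id"],
        channels=channels,
        timeline=PhaseTimeline.from_dict(meta["timeline"]),
        venous_full_emptying_reference_left=float(
            meta["venous_full_emptying_reference_left"]),
        venous_full_emptying_reference_right=float(
            meta["venous_full_emptying_reference_right"]),
    )
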