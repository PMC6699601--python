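"""Core data containers shared across the pipeline.

All time axes are integer seconds on a common task clock; a second labelled
``t`` covers the half-open interval [t, t+1). Missing data is represented by
NaN in floating-point arrays (power, NI) and by sentinel codes in integer
symbol arrays (see :mod:`teamneuro.symbols`), never by zeros — zero is a
valid power value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError

__all__ = ["EventSegment", "RawRecording", "PowerTensor", "align_members"]

DEFAULT_FREQS: tuple[int, ...] = tuple(range(1, 41))


@dataclass(frozen=True)
class EventSegment:
    """A labelled half-open interval [start_s, end_s) on the task clock."""

    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError(
                f"event {self.label!r}: end ({self.end_s}) must exceed start ({self.start_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def __contains__(self, t: float) -> bool:
        return self.start_s <= t < self.end_s


@dataclass
class RawRecording:
    """Multichannel raw EEG for one team member.

    samples: array of shape (n_channels, n_samples), microvolts (arbitrary
    scale accepted). ``start_s`` places sample 0 on the task clock.
    """

    member: str
    channels: tuple[str, ...]
    fs: float
    samples: np.ndarray
    start_s: float = 0.0
    flagged_channels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channels = tuple(self.channels)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if self.samples.shape[0] != len(self.channels):
            raise ValueError(
                f"{len(self.channels)} channel labels but {self.samples.shape[0]} sample rows"
            )
        if not self.fs > 80:
            raise ValueError(f"sampling rate must exceed 80 Hz, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class PowerTensor:
    """Per-second EEG power indexed by (member, sensor, frequency bin, second).

    values: float array of shape (n_members, n_sensors, n_freqs, n_seconds);
    NaN marks missing seconds (e.g. a member outside the room). The seconds
    axis starts at ``start_second`` on the task clock.
    """

    values: np.ndarray
    members: tuple[str, ...]
    sensors: tuple[str, ...]
    freqs: tuple[int, ...] = DEFAULT_FREQS
    start_second: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.members = tuple(self.members)
        self.sensors = tuple(self.sensors)
        self.freqs = tuple(int(f) for f in self.freqs)
        expected = (len(self.members), len(self.sensors), len(self.freqs))
        if self.values.ndim != 4 or self.values.shape[:3] != expected:
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"(members, sensors, freqs, seconds) = {expected + ('*',)}"
            )
        with np.errstate(invalid="ignore"):
            if np.any(self.values < 0):
                raise ValueError("power values must be non-negative where present")

    # -- indexing helpers -------------------------------------------------

    @property
    def n_seconds(self) -> int:
        return self.values.shape[3]

    @property
    def seconds(self) -> np.ndarray:
        return np.arange(self.start_second, self.start_second + self.n_seconds)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def member_index(self, member: str) -> int:
        try:
            return self.members.index(member)
        except ValueError:
            raise KeyError(f"unknown member {member!r}; have {self.members}") from None

    def sensor_index(self, sensor: str) -> int:
        try:
            return self.sensors.index(sensor)
        except ValueError:
            raise KeyError(f"unknown sensor {sensor!r}; have {self.sensors}") from None

    def freq_index(self, freq: int) -> int:
        try:
            return self.freqs.index(int(freq))
        except ValueError:
            raise KeyError(f"unknown frequency bin {freq}; have {self.freqs}") from None

    def select_member(self, member: str) -> "PowerTensor":
        i = self.member_index(member)
        return replace(self, values=self.values[i : i + 1], members=(member,))

    # -- tidy interchange -------------------------------------------------

    def to_frame(self, drop_missing: bool = True) -> pd.DataFrame:
        """Long-format frame with columns member,sensor,freq_hz,second,power."""
        m, s, f, t = np.meshgrid(
            np.arange(len(self.members)),
            np.arange(len(self.sensors)),
            np.arange(len(self.freqs)),
            np.arange(self.n_seconds),
            indexing="ij",
        )
        df = pd.DataFrame(
            {
                "member": np.asarray(self.members)[m.ravel()],
                "sensor": np.asarray(self.sensors)[s.ravel()],
                "freq_hz": np.asarray(self.freqs)[f.ravel()],
                "second": t.ravel() + self.start_second,
                "power": self.values.ravel(),
            }
        )
        if drop_missing:
            df = df.dropna(subset=["power"]).reset_index(drop=True)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PowerTensor":
        required = {"member", "sensor", "freq_hz", "second", "power"}
        missing_cols = required - set(df.columns)
        if missing_cols:
            raise ValueError(f"power table is missing columns: {sorted(missing_cols)}")
        members = tuple(pd.unique(df["member"]).astype(str))
        sensors = tuple(pd.unique(df["sensor"]).astype(str))
        freqs = tuple(int(f) for f in sorted(pd.unique(df["freq_hz"])))
        t0 = int(df["second"].min())
        t1 = int(df["second"].max())
        values = np.full((len(members), len(sensors), len(freqs), t1 - t0 + 1), np.nan)
        mi = {m: i for i, m in enumerate(members)}
        si = {s: i for i, s in enumerate(sensors)}
        fi = {f: i for i, f in enumerate(freqs)}
        values[
            df["member"].astype(str).map(mi).to_numpy(),
            df["sensor"].astype(str).map(si).to_numpy(),
            df["freq_hz"].astype(int).map(fi).to_numpy(),
            df["second"].astype(int).to_numpy() - t0,
        ] = df["power"].to_numpy(dtype=float)
        return cls(values, members, sensors, freqs, start_second=t0)


def align_members(
    tensors: Sequence[PowerTensor],
    events: Sequence[EventSegment] | None = None,
) -> PowerTensor:
    """Merge single-member tensors onto a common task clock.

    The output spans the union of the members' time spans; seconds where a
    member is absent are marked missing for that member only (never dropped),
    so prolonged absences — a member outside the room — stay representable.
    Sensors are reconciled by the intersection of labels (montages may
    differ); frequency bins must agree. Spans whose overall intersection is
    empty cannot share a task clock and are rejected. ``events``, when given,
    crop the result to the span covered by the annotations (padded to whole
    seconds).
    """
    if not tensors:
        raise ValueError("need at least one tensor")
    members: list[str] = []
    for t in tensors:
        if len(t.members) != 1:
            raise ValueError("align_members expects single-member tensors")
        members.append(t.members[0])
    if len(set(members)) != len(members):
        raise ValueError(f"duplicate member ids: {members}")

    freqs = tensors[0].freqs
    for t in tensors[1:]:
        if t.freqs != freqs:
            raise AlignmentError("frequency bins differ between members")
    sensors = [s for s in tensors[0].sensors if all(s in t.sensors for t in tensors)]
    if not sensors:
        raise AlignmentError("no sensor labels common to all members")

    starts = [t.start_second for t in tensors]
    ends = [t.start_second + t.n_seconds for t in tensors]
    if max(starts) >= min(ends):
        raise AlignmentError(
            f"member time spans are disjoint: starts {starts}, ends {ends}"
        )
    t0, t1 = min(starts), max(ends)
    if events:
        t0 = max(t0, int(np.floor(min(e.start_s for e in events))))
        t1 = min(t1, int(np.ceil(max(e.end_s for e in events))))
        if t0 >= t1:
            raise AlignmentError("event annotations do not overlap the recordings")

    values = np.full((len(members), len(sensors), len(freqs), t1 - t0), np.nan)
    for i, t in enumerate(tensors):
        s_idx = [t.sensor_index(s) for s in sensors]
        lo = max(t.start_second, t0)
        hi = min(t.start_second + t.n_seconds, t1)
        if lo < hi:
            values[i, :, :, lo - t0 : hi - t0] = t.values[
                0, s_idx, :, lo - t.start_second : hi - t.start_second
            ]
    return PowerTensor(values, tuple(members), tuple(sensors), freqs, start_second=t0)
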