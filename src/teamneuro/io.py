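"""File formats and run configuration.

All tabular artifacts are tidy CSV; manifests, ground truth and lookup
tables are JSON; run configuration is YAML (or JSON). Raw recordings come
in as EDF (via mne, when installed) or as a long-format CSV with columns
``member,channel,fs,sample_index,value``. Power tensors travel as
``member,sensor,freq_hz,second,power`` with missing rows omitted and a
sidecar JSON listing the missing spans.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .containers import DEFAULT_FREQS, EventSegment, PowerTensor, RawRecording
from .errors import ConfigError
from .synthetic import SIMULATION_SENSORS

#: 10-20 sensor labels recognized without flagging
KNOWN_1020_LABELS = frozenset(
    {
        "Fp1", "Fpz", "Fp2", "F7", "F3", "Fz", "F4", "F8",
        "T3", "T7", "C3", "Cz", "C4", "T4", "T8",
        "T5", "P7", "P3", "Pz", "P4", "T6", "P8",
        "O1", "Oz", "O2", "A1", "A2",
    }
)

__all__ = [
    "KNOWN_1020_LABELS",
    "read_recording",
    "write_recording_csv",
    "write_power_csv",
    "read_power_csv",
    "read_events",
    "write_events_csv",
    "write_ni_csv",
    "read_ni_csv",
    "write_envelope_csv",
    "RunConfig",
]


# ---------------------------------------------------------------------------
# raw recordings


def read_recording(path: str | Path, format: str | None = None) -> list[RawRecording]:
    """Read raw recordings (one per member) from EDF or long-format CSV.

    Channel labels outside the 10-20 vocabulary are preserved but flagged
    in ``flagged_channels``. Malformed files raise :class:`ConfigError`
    with record context.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "edf":
        return [_read_edf(path)]
    if format == "csv":
        return _read_recording_csv(path)
    raise ConfigError(f"unknown recording format {format!r}")


def _read_edf(path: Path) -> RawRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - env-dependent
        raise ConfigError("EDF input requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    channels = tuple(raw.ch_names)
    flagged = tuple(c for c in channels if c not in KNOWN_1020_LABELS)
    return RawRecording(
        member=path.stem,
        channels=channels,
        fs=float(raw.info["sfreq"]),
        samples=raw.get_data(),
        flagged_channels=flagged,
    )


def _read_recording_csv(path: Path) -> list[RawRecording]:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    required = {"member", "channel", "fs", "sample_index", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing columns {sorted(missing)}")
    recordings = []
    for member, g in df.groupby("member", sort=False):
        fs_vals = g["fs"].unique()
        if len(fs_vals) != 1:
            raise ConfigError(f"{path}: member {member!r} has mixed sampling rates")
        channels = tuple(pd.unique(g["channel"]).astype(str))
        n = int(g["sample_index"].max()) + 1
        samples = np.full((len(channels), n), np.nan)
        for i, ch in enumerate(channels):
            sub = g[g["channel"] == ch]
            idx = sub["sample_index"].to_numpy(dtype=int)
            if idx.size != n or len(np.unique(idx)) != n:
                raise ConfigError(
                    f"{path}: member {member!r} channel {ch!r} has "
                    f"{idx.size} samples, expected {n} (truncated or duplicated?)"
                )
            samples[i, idx] = sub["value"].to_numpy(dtype=float)
        flagged = tuple(c for c in channels if c not in KNOWN_1020_LABELS)
        recordings.append(
            RawRecording(
                member=str(member),
                channels=channels,
                fs=float(fs_vals[0]),
                samples=samples,
                flagged_channels=flagged,
            )
        )
    if not recordings:
        raise ConfigError(f"{path}: no recordings found")
    return recordings


def write_recording_csv(recordings: Sequence[RawRecording], path: str | Path) -> None:
    frames = []
    for rec in recordings:
        for i, ch in enumerate(rec.channels):
            frames.append(
                pd.DataFrame(
                    {
                        "member": rec.member,
                        "channel": ch,
                        "fs": rec.fs,
                        "sample_index": np.arange(rec.n_samples),
                        "value": rec.samples[i],
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# power tensors


def _missing_spans(tensor: PowerTensor) -> list[dict]:
    """Contiguous all-missing spans per member, for the sidecar JSON."""
    spans = []
    # a second counts as missing for a member when every (sensor, bin) is NaN
    all_nan = np.isnan(tensor.values).all(axis=(1, 2))
    for i, member in enumerate(tensor.members):
        idx = np.nonzero(all_nan[i])[0]
        if idx.size == 0:
            continue
        breaks = np.nonzero(np.diff(idx) > 1)[0]
        starts = np.concatenate([[idx[0]], idx[breaks + 1]])
        ends = np.concatenate([idx[breaks], [idx[-1]]]) + 1
        for a, b in zip(starts, ends):
            spans.append(
                {
                    "member": member,
                    "start_s": int(a + tensor.start_second),
                    "end_s": int(b + tensor.start_second),
                }
            )
    return spans


def write_power_csv(tensor: PowerTensor, path: str | Path) -> None:
    """Tidy power CSV (missing rows omitted) plus a ``.missing.json`` sidecar."""
    path = Path(path)
    tensor.to_frame(drop_missing=True).to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".missing.json")
    sidecar.write_text(json.dumps({"missing_spans": _missing_spans(tensor)}, indent=1))


def read_power_csv(path: str | Path) -> PowerTensor:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    try:
        return PowerTensor.from_frame(df)
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# events, NI traces, envelopes


def read_events(path: str | Path) -> list[EventSegment]:
    """Events from CSV (label,start_s,end_s) or JSON (list of objects)."""
    path = Path(path)
    try:
        if path.suffix.lower() == ".json":
            records = json.loads(path.read_text())
        else:
            records = pd.read_csv(path).to_dict("records")
        return [
            EventSegment(str(r["label"]), float(r["start_s"]), float(r["end_s"]))
            for r in records
        ]
    except (KeyError, ValueError, TypeError) as exc:
        raise ConfigError(f"cannot parse events file {path}: {exc}") from exc


def write_events_csv(events: Sequence[EventSegment], path: str | Path) -> None:
    pd.DataFrame(
        [{"label": e.label, "start_s": e.start_s, "end_s": e.end_s} for e in events]
    ).to_csv(path, index=False)


def write_ni_csv(trace, path: str | Path) -> None:
    """NI trace as CSV with columns second,ni_bits,n_streams,flag."""
    flag = np.where(np.isnan(trace.values), "missing", "ok")
    flag[: min(trace.window_s - 1, trace.n_seconds)] = "warmup"
    pd.DataFrame(
        {
            "second": trace.seconds,
            "ni_bits": trace.values,
            "n_streams": trace.n_streams,
            "flag": flag,
        }
    ).to_csv(path, index=False, float_format="%.12g")


def read_ni_csv(path: str | Path, n_states: int, window_s: int = 60):
    from .entropy import NITrace

    df = pd.read_csv(path)
    return NITrace(
        df["ni_bits"].to_numpy(),
        n_states=n_states,
        window_s=window_s,
        start_second=int(df["second"].iloc[0]),
        n_streams=df["n_streams"].to_numpy(),
    )


def write_envelope_csv(envelope, path: str | Path) -> None:
    q25 = np.atleast_1d(envelope.q25)
    q75 = np.atleast_1d(envelope.q75)
    pd.DataFrame({"q25": q25, "q75": q75}).to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Everything an end-to-end run needs; validated before any computation.

    Either ``power_csv`` (precomputed per-second power) or ``recording``
    (raw EDF/CSV) or ``synthetic: true`` must be chosen as the input mode.
    The config is serialized verbatim into the output directory.
    """

    out_dir: str = "teamneuro_out"
    synthetic: bool = True
    power_csv: str | None = None
    recording: str | None = None
    events: str | None = None
    members: tuple[str, ...] = ()
    sensors: tuple[str, ...] = SIMULATION_SENSORS
    bins: tuple[int, ...] = DEFAULT_FREQS
    duration_s: int = 800
    window_s: int = 60
    step_s: int = 1
    levels_k: int = 3
    shuffles: int = 100
    seed: int = 0
    band_scheme: str = "A"
    region_map: dict[str, list[str]] | None = None
    noise_model: str = "iid-lognormal"

    def __post_init__(self) -> None:
        self.sensors = tuple(self.sensors)
        self.bins = tuple(int(b) for b in self.bins)
        self.members = tuple(self.members)
        modes = sum(
            [bool(self.synthetic), self.power_csv is not None, self.recording is not None]
        )
        if modes != 1:
            raise ConfigError(
                "exactly one input mode required: synthetic, power_csv, or recording"
            )
        if self.window_s < 2:
            raise ConfigError("window_s must be >= 2")
        if self.step_s < 1:
            raise ConfigError("step_s must be >= 1")
        if self.levels_k != 3:
            raise ConfigError("only levels_k = 3 is implemented in the pipeline")
        if self.shuffles < 2:
            raise ConfigError("shuffles must be >= 2")
        if self.band_scheme not in ("A", "B"):
            raise ConfigError(f"band_scheme must be 'A' or 'B', got {self.band_scheme!r}")
        if self.region_map is not None:
            for name, labels in self.region_map.items():
                unknown = [s for s in labels if s not in self.sensors]
                if unknown:
                    raise ConfigError(
                        f"region {name!r} names sensors missing from the montage: {unknown}"
                    )
        for p in (self.power_csv, self.recording, self.events):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input file not found: {p}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        try:
            if path.suffix.lower() == ".json":
                data = json.loads(path.read_text())
            else:
                data = yaml.safe_load(path.read_text())
        except Exception as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} is not a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sensors"] = list(self.sensors)
        d["bins"] = list(self.bins)
        d["members"] = list(self.members)
        return d
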