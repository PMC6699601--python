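"""Symbolic transformation of per-second power into team neurodynamic symbols.

Each (member, sensor, 1-Hz bin) power stream is discretized into three
levels — low (-1), average (1), high (3) — by the empirical tertiles of the
stream's own whole-recording distribution. The three member levels at a
second form a team neurodynamic symbol; with 3 members and 3 levels the
state space holds 3^3 = 27 symbols. Sequences of symbols per (sensor, bin)
are the neurodynamic data streams (NDS) that the entropy layer consumes.

Discretization is rank-based, so it is invariant under any strictly
monotone transform of power (log, affine rescaling, unit changes). Boundary
ties go to the lower category; a constant stream is degenerate and maps to
the "average" level everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import numpy as np

from .containers import PowerTensor

__all__ = [
    "LEVELS",
    "MISSING_LEVEL",
    "MISSING_SYMBOL",
    "Thresholds",
    "LevelStream",
    "TeamNDS",
    "tertile_thresholds",
    "quantile_thresholds",
    "discretize_stream",
    "discretize_values",
    "encode_team_symbol",
    "decode_team_symbol",
    "encode_level_matrix",
    "build_team_nds",
    "symbol_lookup_table",
    "discretize_tensor",
    "team_nds_from_levels",
]

LEVELS: tuple[int, ...] = (-1, 1, 3)
_LEVEL_TO_DIGIT = {-1: 0, 1: 1, 3: 2}
_DIGIT_TO_LEVEL = np.array(LEVELS, dtype=np.int8)

#: sentinel for a missing second in a level array (0 is not a valid level)
MISSING_LEVEL: int = 0
#: sentinel for a missing second in a symbol array
MISSING_SYMBOL: int = -1


@dataclass(frozen=True)
class Thresholds:
    """Tertile cut points for one stream; ``degenerate`` marks a constant stream."""

    low_cut: float
    high_cut: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.low_cut > self.high_cut:
            raise ValueError(
                f"low_cut ({self.low_cut}) must not exceed high_cut ({self.high_cut})"
            )

    def __iter__(self):
        return iter((self.low_cut, self.high_cut))


@dataclass
class LevelStream:
    """Per-second levels for one (member, sensor, frequency-bin) stream.

    ``levels`` is int8 with values in {-1, 1, 3} or MISSING_LEVEL (0).
    """

    member: str
    sensor: str
    freq_hz: int
    levels: np.ndarray
    thresholds: Thresholds
    start_second: int = 0

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int8)
        bad = ~np.isin(self.levels, LEVELS + (MISSING_LEVEL,))
        if bad.any():
            raise ValueError(f"invalid level values: {np.unique(self.levels[bad])}")

    @property
    def n_seconds(self) -> int:
        return self.levels.size

    @property
    def valid_mask(self) -> np.ndarray:
        return self.levels != MISSING_LEVEL


@dataclass
class TeamNDS:
    """Team neurodynamic data stream for one (sensor, frequency bin).

    ``symbols`` holds encoded team-symbol indices in [0, n_levels^n_members)
    or MISSING_SYMBOL (-1) where any member is missing.
    """

    sensor: str
    freq_hz: int
    symbols: np.ndarray
    members: tuple[str, ...]
    n_levels: int = 3
    start_second: int = 0

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.int16)
        if np.any(self.symbols >= self.n_states) or np.any(
            (self.symbols < 0) & (self.symbols != MISSING_SYMBOL)
        ):
            raise ValueError(f"symbol indices out of range [0, {self.n_states})")

    @property
    def n_states(self) -> int:
        """Size of the neurodynamic state space, n_levels ** n_members."""
        return self.n_levels ** len(self.members)

    @property
    def n_seconds(self) -> int:
        return self.symbols.size

    @property
    def valid_mask(self) -> np.ndarray:
        return self.symbols != MISSING_SYMBOL


# ---------------------------------------------------------------------------
# discretization


def quantile_thresholds(values: Sequence[float], k: int = 3) -> np.ndarray:
    """k-quantile cut points (k-1 of them) of the non-missing values."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < k:
        raise ValueError(f"need at least {k} non-missing values, got {v.size}")
    qs = 100.0 * np.arange(1, k) / k
    return np.percentile(v, qs)  # linear interpolation

def tertile_thresholds(values: Sequence[float]) -> Thresholds:
    """Empirical tertile cuts (33.33rd / 66.67th percentiles) of a stream.

    Computed over the whole recording's non-missing values. A constant
    stream is flagged degenerate: it carries no rank information and
    discretizes to the "average" level everywhere.
    """
    low, high = quantile_thresholds(values, k=3)
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    return Thresholds(float(low), float(high), degenerate=bool(v.min() == v.max()))


def discretize_values(values: np.ndarray, thresholds: Thresholds) -> np.ndarray:
    """Map power to levels: <= low_cut -> -1; <= high_cut -> 1; above -> 3.

    Boundary ties go to the lower category. NaN propagates as MISSING_LEVEL.
    """
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, MISSING_LEVEL, dtype=np.int8)
    present = ~np.isnan(v)
    if thresholds.degenerate:
        out[present] = 1
        return out
    out[present & (v <= thresholds.low_cut)] = -1
    out[present & (v > thresholds.low_cut) & (v <= thresholds.high_cut)] = 1
    out[present & (v > thresholds.high_cut)] = 3
    return out


def discretize_stream(
    values: np.ndarray,
    thresholds: Thresholds | None = None,
    *,
    member: str = "",
    sensor: str = "",
    freq_hz: int = 0,
    start_second: int = 0,
) -> LevelStream:
    """Discretize one power stream into a :class:`LevelStream`.

    Thresholds default to the stream's own whole-recording tertiles; frozen
    thresholds may be supplied for streaming use.
    """
    if thresholds is None:
        thresholds = tertile_thresholds(values)
    return LevelStream(
        member=member,
        sensor=sensor,
        freq_hz=freq_hz,
        levels=discretize_values(values, thresholds),
        thresholds=thresholds,
        start_second=start_second,
    )


# ---------------------------------------------------------------------------
# team-symbol encoding


def encode_team_symbol(levels: Sequence[int]) -> int:
    """Encode an ordered member-level tuple as a base-3 state index.

    Digit map -1 -> 0, 1 -> 1, 3 -> 2, with member 1 most significant;
    bijective on [0, 3^n). Example: (-1, 3, 1) -> 0*9 + 2*3 + 1 = 7.
    """
    idx = 0
    for lv in levels:
        try:
            idx = idx * 3 + _LEVEL_TO_DIGIT[lv]
        except KeyError:
            raise ValueError(f"invalid level {lv!r}; levels are {LEVELS}") from None
    return idx


def decode_team_symbol(index: int, n_members: int) -> tuple[int, ...]:
    """Inverse of :func:`encode_team_symbol`."""
    if not 0 <= index < 3**n_members:
        raise ValueError(f"index {index} outside [0, {3 ** n_members})")
    digits = []
    for _ in range(n_members):
        index, d = divmod(index, 3)
        digits.append(int(_DIGIT_TO_LEVEL[d]))
    return tuple(reversed(digits))


def symbol_lookup_table(n_members: int = 3) -> dict[int, tuple[int, ...]]:
    """Full state-space lookup table: index -> member-level tuple."""
    return {
        encode_team_symbol(levels): levels
        for levels in product(LEVELS, repeat=n_members)
    }


def encode_level_matrix(levels: np.ndarray) -> np.ndarray:
    """Vectorized encoding of an (n_members, T) level matrix to symbol indices.

    Any member missing at a second makes the team symbol missing there.
    """
    lv = np.asarray(levels, dtype=np.int8)
    if lv.ndim != 2:
        raise ValueError("expected a (n_members, T) level matrix")
    digits = np.empty(lv.shape, dtype=np.int16)
    for level, digit in _LEVEL_TO_DIGIT.items():
        digits[lv == level] = digit
    missing = lv == MISSING_LEVEL
    digits[missing] = 0
    idx = np.zeros(lv.shape[1], dtype=np.int16)
    for row in digits:
        idx = idx * 3 + row
    idx[missing.any(axis=0)] = MISSING_SYMBOL
    return idx


def build_team_nds(streams: Sequence[LevelStream]) -> TeamNDS:
    """Assemble one team NDS from per-member level streams of one (sensor, bin).

    Streams must share the sensor, frequency bin and time axis; a montage
    mismatch is an error (sensor reconciliation happens upstream by label
    intersection, never positionally).
    """
    if len(streams) < 2:
        raise ValueError("a team stream needs at least 2 members")
    ref = streams[0]
    for s in streams[1:]:
        if (s.sensor, s.freq_hz) != (ref.sensor, ref.freq_hz):
            raise ValueError(
                f"montage mismatch: ({s.sensor}, {s.freq_hz} Hz) vs "
                f"({ref.sensor}, {ref.freq_hz} Hz)"
            )
        if s.n_seconds != ref.n_seconds or s.start_second != ref.start_second:
            raise ValueError("member streams do not share a time axis")
    matrix = np.stack([s.levels for s in streams])
    return TeamNDS(
        sensor=ref.sensor,
        freq_hz=ref.freq_hz,
        symbols=encode_level_matrix(matrix),
        members=tuple(s.member for s in streams),
        start_second=ref.start_second,
    )


# ---------------------------------------------------------------------------
# tensor-level drivers


def discretize_tensor(tensor: PowerTensor) -> list[LevelStream]:
    """Discretize every (member, sensor, bin) stream of a power tensor.

    Returns m*c*f individual level streams (1,200 for a triad wearing
    10-sensor headsets analyzed over forty 1-Hz bins).
    """
    streams = []
    for i, member in enumerate(tensor.members):
        for j, sensor in enumerate(tensor.sensors):
            for k, freq in enumerate(tensor.freqs):
                streams.append(
                    discretize_stream(
                        tensor.values[i, j, k],
                        member=member,
                        sensor=sensor,
                        freq_hz=freq,
                        start_second=tensor.start_second,
                    )
                )
    return streams


def team_nds_from_levels(streams: Iterable[LevelStream]) -> list[TeamNDS]:
    """Group individual level streams by (sensor, bin) and build team NDSs.

    Yields c*f team streams (400 for 10 sensors x 40 bins), each combining
    all members present for that sensor/bin; member order follows first
    appearance and is consistent across streams.
    """
    groups: dict[tuple[str, int], list[LevelStream]] = {}
    for s in streams:
        groups.setdefault((s.sensor, s.freq_hz), []).append(s)
    counts = {len(g) for g in groups.values()}
    if len(counts) > 1:
        raise ValueError(f"inconsistent member counts across streams: {sorted(counts)}")
    return [build_team_nds(g) for g in groups.values()]
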