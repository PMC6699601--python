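"""Sliding-window entropy and neurodynamic information (NI).

Organization in a symbol stream shows up as locally lowered entropy: when a
team dwells in a small subset of its state space for tens of seconds, the
Shannon entropy of a 60-s moving window drops below the near-maximal value
an unorganized stream produces. NI inverts the scale,

    NI(t) = log2(S) - H(window ending at t),

so that more organization means more bits. S is the full state-space size
(3^n for a team of n members with 3 levels, 3 for an individual stream),
not the number of symbols observed in the window.

The window is causal: NI at second t summarizes [t - window + 1, t], so the
first window-1 seconds are warm-up (missing) and an organization epoch's NI
elevation trails its end by up to one window length. The plug-in entropy
estimator is biased low on short windows (hence a small positive NI floor
even for i.i.d. streams); the randomized-baseline envelope quantifies that
floor empirically, which is why observed NI is judged against shuffled
data rather than against zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .symbols import (
    MISSING_LEVEL,
    MISSING_SYMBOL,
    LevelStream,
    TeamNDS,
    encode_level_matrix,
)

__all__ = [
    "NITrace",
    "BaselineEnvelope",
    "shannon_entropy",
    "window_entropies",
    "sliding_ni",
    "average_ni",
    "iqr_profile",
    "shuffle_baseline",
]

DEFAULT_WINDOW_S = 60
DEFAULT_MISSING_TOL = 0.2


@dataclass
class NITrace:
    """Per-second neurodynamic information in bits.

    ``values`` has one entry per second of the source stream; NaN marks
    warm-up, missing-dominated windows, or off-step seconds. ``n_streams``
    records how many traces contributed at each second after averaging.
    """

    values: np.ndarray
    n_states: int
    window_s: int = DEFAULT_WINDOW_S
    step_s: int = 1
    start_second: int = 0
    n_streams: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any(self.values < -1e-9) or np.any(self.values > self.hmax + 1e-9):
                raise ValueError(f"NI values outside [0, {self.hmax:.4f}] bits")
        if self.n_streams is None:
            self.n_streams = np.where(np.isnan(self.values), 0, 1)
        self.n_streams = np.asarray(self.n_streams, dtype=int)

    @property
    def hmax(self) -> float:
        """Maximum entropy of the state space, log2(S) bits."""
        return math.log2(self.n_states)

    @property
    def n_seconds(self) -> int:
        return self.values.size

    @property
    def seconds(self) -> np.ndarray:
        return np.arange(self.start_second, self.start_second + self.n_seconds)

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass
class BaselineEnvelope:
    """IQR envelope (25th/75th percentile NI) of member-shuffled data.

    ``mode`` is "pooled" (scalars pooled over shuffles and seconds, the
    default) or "per-second" (arrays across shuffles at each second).
    """

    q25: float | np.ndarray
    q75: float | np.ndarray
    n_shuffles: int
    seed: int
    mode: str = "pooled"
    window_s: int = DEFAULT_WINDOW_S
    n_states: int = 27

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.q25) > np.asarray(self.q75)):
            raise ValueError("q25 must not exceed q75")


# ---------------------------------------------------------------------------
# entropy primitives


def shannon_entropy(symbols: Sequence[int], base: float = 2.0) -> float:
    """Plug-in Shannon entropy of a symbol multiset, with 0*log(0) = 0.

    Missing symbols (MISSING_SYMBOL) are excluded; an all-missing window
    yields NaN.
    """
    sym = np.asarray(symbols)
    sym = sym[sym != MISSING_SYMBOL]
    if sym.size == 0:
        return float("nan")
    _, counts = np.unique(sym, return_counts=True)
    return float(stats.entropy(counts, base=base))


def window_entropies(
    symbols: np.ndarray,
    n_states: int,
    window_s: int = DEFAULT_WINDOW_S,
    *,
    missing_tol: float = DEFAULT_MISSING_TOL,
    miller_madow: bool = False,
) -> np.ndarray:
    """Entropy (bits) of every causal window, vectorized via cumulative counts.

    Returns an array aligned with the input: entry t holds H over
    [t - window + 1, t], NaN during warm-up and wherever the window's
    missing fraction exceeds ``missing_tol``.
    """
    sym = np.asarray(symbols, dtype=np.int64)
    T = sym.size
    out = np.full(T, np.nan)
    if T < window_s:
        return out
    valid = sym != MISSING_SYMBOL
    onehot = np.zeros((T, n_states), dtype=np.int32)
    onehot[np.nonzero(valid)[0], sym[valid]] = 1
    cum = np.vstack([np.zeros((1, n_states), dtype=np.int64), np.cumsum(onehot, axis=0)])
    counts = cum[window_s:] - cum[:-window_s]  # windows ending at window_s-1 .. T-1
    n = counts.sum(axis=1)
    ok = (window_s - n) <= missing_tol * window_s
    ok &= n > 0
    H = np.full(counts.shape[0], np.nan)
    if ok.any():
        H[ok] = stats.entropy(counts[ok], base=2, axis=1)
        if miller_madow:
            support = (counts[ok] > 0).sum(axis=1)
            H[ok] += (support - 1) / (2.0 * n[ok] * math.log(2))
    out[window_s - 1 :] = H
    return out


def sliding_ni(
    stream: TeamNDS | LevelStream | np.ndarray,
    n_states: int | None = None,
    window_s: int = DEFAULT_WINDOW_S,
    step_s: int = 1,
    *,
    missing_tol: float = DEFAULT_MISSING_TOL,
    miller_madow: bool = False,
    start_second: int | None = None,
) -> NITrace:
    """Sliding-window NI of a symbol or level stream.

    Accepts a :class:`TeamNDS` (S = 3^n), a :class:`LevelStream` (S = 3), or
    a raw integer symbol array with an explicit ``n_states``. A stream
    shorter than the window yields an all-missing trace (with a warning).
    """
    if isinstance(stream, TeamNDS):
        symbols, S = stream.symbols, stream.n_states
        t0 = stream.start_second
    elif isinstance(stream, LevelStream):
        lv = stream.levels
        symbols = np.where(lv == MISSING_LEVEL, MISSING_SYMBOL,
                           np.searchsorted([-1, 1, 3], lv)).astype(np.int64)
        S = 3
        t0 = stream.start_second
    else:
        if n_states is None:
            raise ValueError("n_states is required for a raw symbol array")
        symbols, S = np.asarray(stream, dtype=np.int64), int(n_states)
        t0 = 0
    if n_states is not None:
        S = int(n_states)
    if start_second is not None:
        t0 = start_second

    if symbols.size < window_s:
        import warnings

        warnings.warn(
            f"stream length {symbols.size} < window {window_s}: empty NI trace",
            stacklevel=2,
        )
    H = window_entropies(
        symbols, S, window_s, missing_tol=missing_tol, miller_madow=miller_madow
    )
    ni = math.log2(S) - H
    np.clip(ni, 0.0, math.log2(S), out=ni)
    if step_s > 1:
        keep = np.zeros(ni.size, dtype=bool)
        keep[window_s - 1 :: step_s] = True
        ni[~keep] = np.nan
    return NITrace(ni, S, window_s, step_s, start_second=t0)


def average_ni(traces: Sequence[NITrace]) -> NITrace:
    """Per-second arithmetic mean NI over non-missing traces.

    All traces must share the time axis, window and state-space size; the
    count of contributing traces per second is kept in ``n_streams``.
    Seconds with no contributing trace stay missing.
    """
    if not traces:
        raise ValueError("need at least one trace")
    ref = traces[0]
    for t in traces[1:]:
        if (t.n_seconds, t.start_second, t.n_states, t.window_s) != (
            ref.n_seconds,
            ref.start_second,
            ref.n_states,
            ref.window_s,
        ):
            raise ValueError("traces do not share time axis / window / state space")
    stack = np.stack([t.values for t in traces])
    n = (~np.isnan(stack)).sum(axis=0)
    total = np.nansum(stack, axis=0)
    mean = np.divide(total, n, out=np.full(ref.n_seconds, np.nan), where=n > 0)
    return replace(ref, values=mean, n_streams=n)


def iqr_profile(trace: NITrace | np.ndarray) -> tuple[float, float]:
    """25th/75th percentiles (linear interpolation) of a trace's valid values."""
    values = trace.values if isinstance(trace, NITrace) else np.asarray(trace, float)
    v = values[~np.isnan(values)]
    if v.size < 4:
        raise ValueError(f"need >= 4 valid seconds for an IQR, got {v.size}")
    q25, q75 = np.percentile(v, [25, 75])
    return float(q25), float(q75)


# ---------------------------------------------------------------------------
# randomized baseline


def shuffle_baseline(
    member_levels: np.ndarray | Sequence[np.ndarray],
    n_shuffles: int = 100,
    seed: int = 0,
    *,
    window_s: int = DEFAULT_WINDOW_S,
    missing_tol: float = DEFAULT_MISSING_TOL,
    mode: str = "pooled",
    block_s: int | None = None,
) -> BaselineEnvelope:
    """IQR envelope of NI after destroying temporal structure by shuffling.

    ``member_levels`` is an (n_members, ..., T) array (or list over members)
    of level values; the trailing axis is time and any middle axes index
    streams (sensor, bin). Each member's level stream is permuted
    independently and uniformly over its non-missing positions, team symbols
    are rebuilt, NI recomputed per stream and averaged across streams —
    exactly the observed-data path. The envelope is the 25th/75th percentile
    of NI pooled over shuffles (and seconds, in "pooled" mode) or across
    shuffles at each second ("per-second").

    The shuffle preserves each stream's level marginals, so the envelope
    sits at the plug-in estimator's bias floor: it is the reference against
    which observed NI peaks are judged. ``block_s`` switches to a block
    shuffle (contiguous blocks of that many seconds permuted as units),
    which preserves short-range autocorrelation in the null.
    """
    lv = np.asarray(member_levels, dtype=np.int8)
    if lv.ndim < 2:
        raise ValueError("expected (n_members, ..., T) level array")
    if n_shuffles < 2:
        raise ValueError("need at least 2 shuffles")
    M = lv.shape[0]
    T = lv.shape[-1]
    flat = lv.reshape(M, -1, T)  # (members, streams, T)
    n_stream = flat.shape[1]
    rng = np.random.default_rng(seed)
    S = 3**M

    traces = np.empty((n_shuffles, T))
    for r in range(n_shuffles):
        per_stream = np.empty((n_stream, T))
        shuffled = flat.copy()
        for m in range(M):
            for j in range(n_stream):
                pos = np.nonzero(flat[m, j] != MISSING_LEVEL)[0]
                if block_s is None:
                    order = rng.permutation(pos.size)
                else:
                    n_blocks = -(-pos.size // block_s)
                    blocks = [
                        np.arange(b * block_s, min((b + 1) * block_s, pos.size))
                        for b in rng.permutation(n_blocks)
                    ]
                    order = np.concatenate(blocks)
                shuffled[m, j, pos] = flat[m, j, pos][order]
        for j in range(n_stream):
            sym = encode_level_matrix(shuffled[:, j, :])
            H = window_entropies(sym, S, window_s, missing_tol=missing_tol)
            per_stream[j] = math.log2(S) - H
        n = (~np.isnan(per_stream)).sum(axis=0)
        traces[r] = np.divide(
            np.nansum(per_stream, axis=0), n, out=np.full(T, np.nan), where=n > 0
        )

    if mode == "pooled":
        pool = traces[~np.isnan(traces)]
        if pool.size == 0:
            raise ValueError("no valid NI values in any shuffle")
        q25, q75 = (float(q) for q in np.percentile(pool, [25, 75]))
    elif mode == "per-second":
        with np.errstate(all="ignore"):
            q25 = np.nanpercentile(traces, 25, axis=0)
            q75 = np.nanpercentile(traces, 75, axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return BaselineEnvelope(
        q25, q75, n_shuffles, seed, mode=mode, window_s=window_s, n_states=S
    )
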