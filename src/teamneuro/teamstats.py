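"""Downstream analyses over NI traces and level streams.

Covers the analysis layer that sits on top of the NI machinery: member
decomposition, lead/lag cross-correlation between member NI traces,
frequency-band and scalp-region aggregation, event bracketing, raw-level
composition, and the nonparametric contrasts (Wilcoxon/Mann-Whitney
rank-sum, Kruskal-Wallis).

Conventions: a positive cross-correlation lag means the *first* series
leads; rank tests use the normal approximation with tie correction (exact
p for small samples); the fold change between regions is the ratio of
means; no multiple-testing correction is applied — reports carry raw
p-values plus the number of tests performed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .containers import EventSegment
from .entropy import NITrace, average_ni, sliding_ni
from .symbols import LEVELS, MISSING_LEVEL, LevelStream

__all__ = [
    "BandScheme",
    "SCHEME_A",
    "SCHEME_B",
    "RegionMap",
    "SIMULATION_REGIONS",
    "LIVE_REGIONS",
    "CrossCorrResult",
    "RegionContrastResult",
    "LevelComposition",
    "member_ni",
    "cross_correlate",
    "band_aggregate",
    "region_contrast",
    "bracket_event",
    "BracketedSegment",
    "level_composition",
    "time_frequency_map",
    "sensor_time_frequency_map",
]


# ---------------------------------------------------------------------------
# schemes and maps


@dataclass(frozen=True)
class BandScheme:
    """Named frequency bands as inclusive Hz ranges within 1-40."""

    name: str
    bands: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        covered: set[int] = set()
        for label, lo, hi in self.bands:
            if not (1 <= lo <= hi <= 40):
                raise ValueError(f"band {label!r} range {lo}-{hi} outside 1-40 Hz")
            hz = set(range(lo, hi + 1))
            if covered & hz:
                raise ValueError(f"band {label!r} overlaps another band")
            covered |= hz

    def band_bins(self, label: str) -> tuple[int, ...]:
        for name, lo, hi in self.bands:
            if name == label:
                return tuple(range(lo, hi + 1))
        raise KeyError(f"unknown band {label!r} in scheme {self.name!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.bands)


#: five-band scheme used for the surgical-procedure frequency profiles
SCHEME_A = BandScheme(
    "A",
    (
        ("delta/theta", 3, 7),
        ("alpha", 8, 11),
        ("mu", 12, 17),
        ("low beta", 18, 22),
        ("high beta/gamma", 23, 40),
    ),
)
#: six-band scheme splitting high beta and gamma
SCHEME_B = BandScheme(
    "B",
    (
        ("delta/theta", 3, 7),
        ("alpha", 8, 11),
        ("mu", 12, 17),
        ("low beta", 18, 22),
        ("high beta", 23, 32),
        ("gamma", 33, 40),
    ),
)


@dataclass(frozen=True)
class RegionMap:
    """Disjoint scalp regions as sets of 10-20 sensor labels."""

    regions: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, sensors in self.regions:
            overlap = seen & set(sensors)
            if overlap:
                raise ValueError(f"region {name!r} shares sensors {sorted(overlap)}")
            seen |= set(sensors)

    def __getitem__(self, name: str) -> tuple[str, ...]:
        for label, sensors in self.regions:
            if label == name:
                return sensors
        raise KeyError(f"unknown region {name!r}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.regions)


#: anterior/posterior groupings for the simulation (wet) montage
SIMULATION_REGIONS = RegionMap(
    (("anterior", ("F3", "Fz", "F4")), ("posterior", ("P3", "Pz", "P4")))
)
#: anterior/posterior groupings for the live-patient (dry headband) montage
LIVE_REGIONS = RegionMap(
    (
        ("anterior", ("Fp1", "Fpz", "Fp2", "F7", "F8")),
        ("posterior", ("P7", "O1", "Oz", "O2", "P8")),
    )
)


# ---------------------------------------------------------------------------
# member decomposition


def member_ni(
    streams: Sequence[LevelStream],
    window_s: int = 60,
    step_s: int = 1,
    **kwargs,
) -> NITrace:
    """One member's NI: sliding NI per level stream (S = 3), then the mean
    across the member's sensors and bins."""
    if not streams:
        raise ValueError("need at least one level stream")
    members = {s.member for s in streams}
    if len(members) > 1:
        raise ValueError(f"streams span several members: {sorted(members)}")
    traces = [sliding_ni(s, window_s=window_s, step_s=step_s, **kwargs) for s in streams]
    return average_ni(traces)


# ---------------------------------------------------------------------------
# lead/lag cross-correlation


@dataclass
class CrossCorrResult:
    """Best lagged Pearson correlation between two NI traces.

    ``lag_s`` is signed: positive means the first series leads the second
    by that many seconds. ``profile`` maps every searched lag to its r
    (NaN where too few overlapping valid pairs existed).
    """

    r: float
    lag_s: int
    lags: np.ndarray
    profile: np.ndarray
    n_overlap: int

    def __post_init__(self) -> None:
        if np.isfinite(self.r) and abs(self.r) > 1 + 1e-9:
            raise ValueError(f"|r| = {abs(self.r)} exceeds 1")


def cross_correlate(
    a: NITrace | np.ndarray,
    b: NITrace | np.ndarray,
    max_lag_s: int = 60,
    min_pairs: int = 30,
) -> CrossCorrResult:
    """Pearson correlation of two traces at every integer lag in [-L, L].

    At lag k > 0 the pairs are (a[t-k], b[t]) — series a shifted earlier,
    i.e. a leading. Only overlapping non-missing pairs enter each
    correlation; the best lag maximizes |r|, ties going to the smaller
    |lag|. Requires at least 3 * max_lag overlapping valid seconds overall.
    """
    x = a.values if isinstance(a, NITrace) else np.asarray(a, dtype=float)
    y = b.values if isinstance(b, NITrace) else np.asarray(b, dtype=float)
    if x.size != y.size:
        raise ValueError("traces must share a time axis")
    overlap = int((~np.isnan(x) & ~np.isnan(y)).sum())
    if overlap < 3 * max_lag_s:
        raise ValueError(
            f"only {overlap} overlapping valid seconds; need >= {3 * max_lag_s}"
        )
    lags = np.arange(-max_lag_s, max_lag_s + 1)
    profile = np.full(lags.size, np.nan)
    for i, k in enumerate(lags):
        if k >= 0:
            xs, ys = x[: x.size - k], y[k:]
        else:
            xs, ys = x[-k:], y[: y.size + k]
        ok = ~np.isnan(xs) & ~np.isnan(ys)
        if ok.sum() < min_pairs:
            continue
        xv, yv = xs[ok], ys[ok]
        if np.ptp(xv) == 0 or np.ptp(yv) == 0:
            continue  # constant segment: correlation undefined
        profile[i] = stats.pearsonr(xv, yv).statistic
    if np.all(np.isnan(profile)):
        raise ValueError("no lag had enough valid, non-constant pairs")
    # best |r|, ties to the smallest |lag|
    order = np.lexsort((np.abs(lags), -np.abs(np.nan_to_num(profile, nan=-2.0))))
    best = order[0]
    return CrossCorrResult(
        r=float(profile[best]),
        lag_s=int(lags[best]),
        lags=lags,
        profile=profile,
        n_overlap=overlap,
    )


# ---------------------------------------------------------------------------
# band / region aggregation


def band_aggregate(
    ni_by_bin: Mapping[int, NITrace],
    scheme: BandScheme,
) -> dict[str, NITrace]:
    """Mean NI trace per named band, averaging the band's 1-Hz bin traces."""
    out: dict[str, NITrace] = {}
    for label in scheme.labels:
        traces = [ni_by_bin[hz] for hz in scheme.band_bins(label) if hz in ni_by_bin]
        if not traces:
            raise ValueError(
                f"band {label!r} has no bins among {sorted(ni_by_bin)}"
            )
        out[label] = average_ni(traces)
    return out


@dataclass
class RegionContrastResult:
    """Rank-sum contrast of per-sensor-per-second NI between two regions."""

    regions: tuple[str, str]
    z: float
    p: float
    n: tuple[int, int]
    medians: tuple[float, float]
    fold_ratio: float  # ratio of means, first region over second
    method: str
    n_tests: int = 1


def _rank_sum_z(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected normal-approximation Z for the Mann-Whitney U statistic."""
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = stats.rankdata(np.concatenate([x, y]))
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    _, t_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = float(((t_counts**3 - t_counts).sum())) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0
    return float((u1 - mu) / math.sqrt(var))


def region_contrast(
    ni_by_sensor: Mapping[str, np.ndarray],
    region_map: RegionMap,
    regions: tuple[str, str] = ("anterior", "posterior"),
    exact_below: int = 20,
) -> RegionContrastResult:
    """Two-sided rank-sum test of NI between two scalp regions.

    Samples are the pooled per-sensor-per-second valid NI values of each
    region's sensors. Z uses the tie-corrected normal approximation
    (positive when the first region's values rank higher); p comes from the
    exact Mann-Whitney distribution when either group has fewer than
    ``exact_below`` samples, the asymptotic one otherwise.
    """
    samples = []
    for name in regions:
        wanted = region_map[name]
        present = [s for s in wanted if s in ni_by_sensor]
        absent = [s for s in wanted if s not in ni_by_sensor]
        if not present:
            raise ValueError(
                f"region {name!r}: no mapped sensors present (missing {absent})"
            )
        pooled = np.concatenate([np.asarray(ni_by_sensor[s], float) for s in present])
        pooled = pooled[~np.isnan(pooled)]
        if pooled.size == 0:
            raise ValueError(f"region {name!r} has no valid NI samples")
        samples.append(pooled)
    x, y = samples
    method = "exact" if min(x.size, y.size) < exact_below else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    mean_y = float(np.mean(y))
    fold = float(np.mean(x)) / mean_y if mean_y != 0 else float("inf")
    return RegionContrastResult(
        regions=regions,
        z=_rank_sum_z(x, y),
        p=float(res.pvalue),
        n=(x.size, y.size),
        medians=(float(np.median(x)), float(np.median(y))),
        fold_ratio=fold,
        method=f"mannwhitneyu-{method}",
    )


# ---------------------------------------------------------------------------
# event bracketing


@dataclass
class BracketedSegment:
    """A trace restricted to an event plus padding, with the core flagged."""

    event: EventSegment
    window: tuple[int, int]  # half-open, clipped to the recording span
    core: tuple[int, int]
    values: np.ndarray
    start_second: int

    @property
    def core_mask(self) -> np.ndarray:
        t = np.arange(self.window[0], self.window[1])
        return (t >= self.core[0]) & (t < self.core[1])


def bracket_event(
    trace: NITrace,
    event: EventSegment,
    pad_s: int = 60,
) -> BracketedSegment:
    """Restrict a trace to [start - pad, end + pad), clipped to the recording.

    The unpadded event interval is flagged as the core. An event wholly
    outside the recording is an error; an event at the recording edge is
    simply truncated.
    """
    span = (trace.start_second, trace.start_second + trace.n_seconds)
    core = (int(event.start_s), int(math.ceil(event.end_s)))
    if core[1] <= span[0] or core[0] >= span[1]:
        raise ValueError(
            f"event {event.label!r} {core} outside the recording span {span}"
        )
    w0 = max(core[0] - pad_s, span[0])
    w1 = min(core[1] + pad_s, span[1])
    return BracketedSegment(
        event=event,
        window=(w0, w1),
        core=(max(core[0], span[0]), min(core[1], span[1])),
        values=trace.values[w0 - span[0] : w1 - span[0]],
        start_second=w0,
    )


# ---------------------------------------------------------------------------
# raw-level composition


@dataclass
class LevelComposition:
    """Distribution over the three levels within one event window."""

    label: str
    counts: dict[int, int]
    distribution: dict[int, float]
    mean_level: float
    n: int

    def __post_init__(self) -> None:
        total = sum(self.distribution.values())
        if self.n and abs(total - 1.0) > 1e-9:
            raise ValueError(f"distribution sums to {total}, not 1")


def level_composition(
    event_levels: Mapping[str, np.ndarray],
) -> tuple[dict[str, LevelComposition], dict]:
    """Per-event level composition and a Kruskal-Wallis contrast across events.

    ``event_levels`` maps event labels to pooled per-second level samples
    (values in {-1, 1, 3}; MISSING_LEVEL entries are dropped). Returns the
    per-event compositions and, when at least two events have data, the
    Kruskal-Wallis H, df = k - 1 and p over the raw level values.
    All-missing events are excluded with a warning.
    """
    comps: dict[str, LevelComposition] = {}
    groups: list[np.ndarray] = []
    for label, values in event_levels.items():
        v = np.asarray(values)
        v = v[np.isin(v, LEVELS)]
        if v.size == 0:
            warnings.warn(f"event {label!r} has no valid levels; excluded", stacklevel=2)
            continue
        counts = {lv: int((v == lv).sum()) for lv in LEVELS}
        comps[label] = LevelComposition(
            label=label,
            counts=counts,
            distribution={lv: c / v.size for lv, c in counts.items()},
            mean_level=float(v.mean()),
            n=int(v.size),
        )
        groups.append(v.astype(float))

    test: dict = {}
    if len(groups) >= 2:
        pooled = np.concatenate(groups)
        if np.ptp(pooled) == 0:  # all ties: no variation to test
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*groups)
        test = {"H": float(h), "df": len(groups) - 1, "p": float(p)}
    return comps, test


# ---------------------------------------------------------------------------
# time x frequency maps


def time_frequency_map(
    ni_by_bin: Mapping[int, NITrace],
    freqs: Sequence[int] | None = None,
) -> "np.ndarray":
    """Dense (bins x seconds) NI matrix for one sensor, NaN where missing.

    Row order follows ``freqs`` (default: sorted bin keys). Suitable for
    heat-map export; row means over singleton bands agree with
    :func:`band_aggregate` by construction.
    """
    if not ni_by_bin:
        raise ValueError("no NI traces supplied")
    order = tuple(freqs) if freqs is not None else tuple(sorted(ni_by_bin))
    missing = [hz for hz in order if hz not in ni_by_bin]
    if missing:
        raise KeyError(f"no NI trace for bins {missing}")
    return np.stack([ni_by_bin[hz].values for hz in order])


def sensor_time_frequency_map(
    ni_by_sensor: Mapping[str, Mapping[int, NITrace]],
    sensor: str,
    freqs: Sequence[int] | None = None,
) -> np.ndarray:
    """Time x frequency NI matrix for one named sensor of an NI tensor."""
    if sensor not in ni_by_sensor:
        raise KeyError(
            f"unknown sensor {sensor!r}; have {sorted(ni_by_sensor)}"
        )
    return time_frequency_map(ni_by_sensor[sensor], freqs=freqs)
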