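"""Synthetic power tensors and raw signals with known ground truth.

The study's recordings are not released, so every downstream stage is
validated against generated data whose organization is known by
construction. The generator emulates per-second band-power streams for a
small team (default: a triad wearing the simulation montage, forty 1-Hz
bins, 800 s — the duration of the first training scenario), with:

* a log-normal i.i.d. background per stream (power is positive and
  right-skewed; an AR(1) latent option adds short-range autocorrelation
  while keeping the same marginal),
* injected *organization epochs*: intervals where designated streams
  persistently occupy one tertile (high/average/low) with a configurable
  occupancy probability — the synthetic analogue of prolonged metastable
  neurodynamic relationships, and the ground truth for NI-peak recovery,
* optional member-to-member coupling with a signed lag, for lead/lag
  cross-correlation recovery,
* optional missing spans (a member outside the room), emitted as missing
  markers, never zeros.

Epochs force membership in the *theoretical* tertile of the background
law via inverse-CDF draws, so forcing is invariant to the power scale.
Because downstream discretization uses whole-recording empirical tertiles,
heavy occupancy of one tertile nudges the empirical cuts and dilutes
realized occupancy slightly; recovery checks are designed around NI-peak
location and baseline exceedance, which are robust to this.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .containers import DEFAULT_FREQS, PowerTensor, RawRecording
from .errors import ConfigError
from .symbols import LEVELS

__all__ = [
    "SIMULATION_SENSORS",
    "LIVE_SENSORS",
    "GroundTruthEpoch",
    "SynthConfig",
    "generate_power_tensor",
    "inject_coupling",
    "generate_raw_eeg",
]

#: nine-sensor wet montage used in the simulation scenarios
SIMULATION_SENSORS = ("F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "Pz", "P4")
#: ten-sensor dry headband montage used with the live patient
LIVE_SENSORS = ("Fp1", "Fpz", "Fp2", "F7", "F8", "P7", "O1", "Oz", "O2", "P8")

_LEVEL_TO_TERTILE = {-1: 0, 1: 1, 3: 2}
_AR1_PHI = 0.6  # latent AR(1) coefficient for the "ar1-lognormal" null


@dataclass(frozen=True)
class GroundTruthEpoch:
    """A known organization epoch: streams forced into one power tertile.

    ``member`` is a member index or "team" (all members). ``occupancy_prob``
    is the probability per second that the stream sits in the forced
    tertile; it must exceed chance (1/3) to create organization.
    ``sensors``/``bins`` restrict the epoch to a subset ("all" by default).
    """

    member: int | str
    interval: tuple[float, float]
    forced_level: int
    occupancy_prob: float = 1.0
    sensors: tuple[str, ...] | str = "all"
    bins: tuple[int, ...] | str = "all"

    def __post_init__(self) -> None:
        start, end = self.interval
        if not end > start:
            raise ConfigError(f"epoch interval {self.interval} is empty")
        if self.forced_level not in LEVELS:
            raise ConfigError(f"forced_level must be one of {LEVELS}")
        if not 1 / 3 < self.occupancy_prob <= 1:
            raise ConfigError(
                f"occupancy_prob must lie in (1/3, 1], got {self.occupancy_prob}"
            )


@dataclass
class SynthConfig:
    """Configuration for the synthetic power generator.

    Defaults emulate the study conditions: a 3-member team, the 9-sensor
    simulation montage, forty 1-Hz bins, and an 800-s scenario. A fixed
    seed makes output byte-identical across runs.
    """

    n_members: int = 3
    sensors: tuple[str, ...] = SIMULATION_SENSORS
    bins: tuple[int, ...] = DEFAULT_FREQS
    duration_s: int = 800
    epochs: tuple[GroundTruthEpoch, ...] = ()
    coupling_lag_s: int = 0
    missing_spans: tuple[tuple[int, tuple[float, float]], ...] = ()
    noise_model: str = "iid-lognormal"
    seed: int = 0

    def __post_init__(self) -> None:
        self.sensors = tuple(self.sensors)
        self.bins = tuple(int(b) for b in self.bins)
        self.epochs = tuple(self.epochs)
        self.missing_spans = tuple(
            (int(m), (float(a), float(b))) for m, (a, b) in self.missing_spans
        )
        if self.n_members < 2:
            raise ConfigError("need at least 2 members for a team")
        if self.duration_s < 120:
            raise ConfigError(
                "duration_s must be >= 120 (one entropy window plus warm-up), "
                f"got {self.duration_s}"
            )
        if self.noise_model not in ("iid-lognormal", "ar1-lognormal"):
            raise ConfigError(f"unknown noise_model {self.noise_model!r}")
        for ep in self.epochs:
            start, end = ep.interval
            if start < 0 or end > self.duration_s:
                raise ConfigError(
                    f"epoch interval {ep.interval} outside [0, {self.duration_s})"
                )
            if ep.member != "team" and not 0 <= int(ep.member) < self.n_members:
                raise ConfigError(f"epoch member {ep.member} out of range")

    @property
    def members(self) -> tuple[str, ...]:
        return tuple(f"M{i + 1}" for i in range(self.n_members))


def _background_latent(rng: np.random.Generator, shape: tuple, model: str) -> np.ndarray:
    """Latent standard-normal field; AR(1) keeps the N(0,1) marginal."""
    z = rng.standard_normal(shape)
    if model == "ar1-lognormal":
        out = np.empty_like(z)
        out[..., 0] = z[..., 0]
        c = np.sqrt(1 - _AR1_PHI**2)
        for t in range(1, shape[-1]):
            out[..., t] = _AR1_PHI * out[..., t - 1] + c * z[..., t]
        return out
    return z


def _tertile_draw(rng: np.random.Generator, level: int, size: int) -> np.ndarray:
    """Inverse-CDF draw from the forced level's tertile of the log-normal null."""
    d = _LEVEL_TO_TERTILE[level]
    u = rng.uniform(d / 3, (d + 1) / 3, size=size)
    return np.exp(norm.ppf(u))


def _epoch_targets(
    cfg: SynthConfig, ep: GroundTruthEpoch
) -> tuple[list[int], list[int], list[int]]:
    members = (
        list(range(cfg.n_members)) if ep.member == "team" else [int(ep.member)]
    )
    sensors = (
        list(range(len(cfg.sensors)))
        if ep.sensors == "all"
        else [cfg.sensors.index(s) for s in ep.sensors]
    )
    bins = (
        list(range(len(cfg.bins)))
        if ep.bins == "all"
        else [cfg.bins.index(int(b)) for b in ep.bins]
    )
    return members, sensors, bins


def generate_power_tensor(
    config: SynthConfig,
) -> tuple[PowerTensor, list[GroundTruthEpoch]]:
    """Generate a power tensor realizing the configured ground truth.

    Background power is exp(latent N(0,1)) per (member, sensor, bin, second),
    so whole-recording tertiles split the three levels approximately
    uniformly in the absence of epochs. Within an epoch, each designated
    second is redrawn from the forced level's tertile with probability
    ``occupancy_prob`` and uniformly from the other two tertiles otherwise.
    Missing spans become NaN. Returns the tensor and the ground truth,
    unchanged, for downstream recovery checks.
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.n_members, len(config.sensors), len(config.bins), config.duration_s)
    values = np.exp(_background_latent(rng, shape, config.noise_model))

    for ep in config.epochs:
        members, sensors, bins = _epoch_targets(config, ep)
        t0, t1 = int(ep.interval[0]), int(ep.interval[1])
        n_t = t1 - t0
        others = [lv for lv in LEVELS if lv != ep.forced_level]
        for m in members:
            for c in sensors:
                for f in bins:
                    forced = rng.random(n_t) < ep.occupancy_prob
                    lvl = np.where(
                        forced, ep.forced_level, rng.choice(others, size=n_t)
                    )
                    seg = np.empty(n_t)
                    for level in LEVELS:
                        sel = lvl == level
                        if sel.any():
                            seg[sel] = _tertile_draw(rng, level, int(sel.sum()))
                    values[m, c, f, t0:t1] = seg

    for m, (a, b) in config.missing_spans:
        values[int(m), :, :, int(a) : int(b)] = np.nan

    tensor = PowerTensor(
        values, config.members, config.sensors, config.bins, start_second=0
    )
    return tensor, list(config.epochs)


def inject_coupling(
    tensor: PowerTensor,
    leader: int | str,
    follower: int | str,
    lag_s: int,
    interval: tuple[float, float],
    seed: int = 0,
) -> PowerTensor:
    """Make the follower's levels replicate the leader's, shifted by a lag.

    Within ``interval``, the follower's power at second t is resampled from
    the follower's own values in the tertile that the leader occupies at
    t - lag_s (positive lag: leader leads). Seconds whose lagged source
    falls outside the recording, or is missing, are left unchanged. Power
    values are bootstrap-resampled within the matching empirical tertile,
    so the follower's marginal distribution is preserved.
    """
    li = tensor.member_index(leader) if isinstance(leader, str) else int(leader)
    fi = tensor.member_index(follower) if isinstance(follower, str) else int(follower)
    if li == fi:
        raise ConfigError("leader and follower must differ")
    t0, t1 = int(interval[0]), int(interval[1])
    if abs(lag_s) >= t1 - t0:
        raise ConfigError(
            f"|lag_s| = {abs(lag_s)} must be smaller than the interval length {t1 - t0}"
        )
    t0 -= tensor.start_second
    t1 -= tensor.start_second
    if t0 < 0 or t1 > tensor.n_seconds:
        raise ConfigError("coupling interval outside the recording span")

    rng = np.random.default_rng(seed)
    values = tensor.values.copy()
    for c in range(len(tensor.sensors)):
        for f in range(len(tensor.freqs)):
            lead = tensor.values[li, c, f]
            foll = tensor.values[fi, c, f]
            lead_ok = ~np.isnan(lead)
            foll_ok = ~np.isnan(foll)
            if lead_ok.sum() < 3 or foll_ok.sum() < 3:
                continue
            lead_cuts = np.percentile(lead[lead_ok], [100 / 3, 200 / 3])
            foll_cuts = np.percentile(foll[foll_ok], [100 / 3, 200 / 3])
            foll_pools = [
                foll[foll_ok & (foll <= foll_cuts[0])],
                foll[foll_ok & (foll > foll_cuts[0]) & (foll <= foll_cuts[1])],
                foll[foll_ok & (foll > foll_cuts[1])],
            ]
            for t in range(t0, t1):
                src = t - lag_s
                if not 0 <= src < tensor.n_seconds or np.isnan(lead[src]):
                    continue
                tert = int(np.searchsorted(lead_cuts, lead[src], side="left"))
                pool = foll_pools[tert]
                if pool.size:
                    values[fi, c, f, t] = rng.choice(pool)
    return replace(tensor, values=values)


def generate_raw_eeg(
    config: SynthConfig,
    fs: float,
    *,
    amplitude: float = 1.0,
    noise_scale: float = 0.1,
) -> list[RawRecording]:
    """Raw signals whose per-second band power realizes the configured epochs.

    Each (member, sensor) channel is a sum of sinusoids at the configured
    1-Hz bin centers with per-stream random baseline amplitudes, plus
    broadband Gaussian noise; during an epoch the designated bins'
    amplitudes are scaled up (forced high) or down (forced low). The whole
    signal scales with ``amplitude`` (zero gives an all-zero recording) and
    is deterministic under the config seed.
    """
    if fs < 128:
        raise ConfigError(f"sampling rate must be >= 128 Hz, got {fs}")
    if fs < 2 * max(config.bins):
        raise ConfigError(
            f"sampling rate {fs} Hz aliases the {max(config.bins)}-Hz bin "
            f"(need >= {2 * max(config.bins)} Hz)"
        )
    rng = np.random.default_rng(config.seed)
    n = int(round(fs * config.duration_s))
    t = np.arange(n) / fs
    second = np.minimum((t).astype(int), config.duration_s - 1)
    scale = {3: 4.0, 1: 1.0, -1: 0.25}

    recordings = []
    for m in range(config.n_members):
        samples = np.empty((len(config.sensors), n))
        for c in range(len(config.sensors)):
            base = rng.lognormal(mean=0.0, sigma=0.3, size=len(config.bins))
            phases = rng.uniform(0, 2 * np.pi, size=len(config.bins))
            gain = np.ones((len(config.bins), config.duration_s))
            for ep in config.epochs:
                members, sensors, bins = _epoch_targets(config, ep)
                if m in members and c in sensors:
                    e0, e1 = int(ep.interval[0]), int(ep.interval[1])
                    for f in bins:
                        gain[f, e0:e1] = scale[ep.forced_level]
            sig = np.zeros(n)
            for f, hz in enumerate(config.bins):
                sig += base[f] * gain[f, second] * np.sin(2 * np.pi * hz * t + phases[f])
            sig += noise_scale * rng.standard_normal(n)
            samples[c] = amplitude * sig
        recordings.append(
            RawRecording(
                member=config.members[m],
                channels=config.sensors,
                fs=fs,
                samples=samples,
            )
        )
    return recordings
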