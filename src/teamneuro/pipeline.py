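"""End-to-end orchestration: power -> symbols -> NI -> reports.

``run_pipeline`` executes the whole modeling chain on synthetic, raw, or
precomputed-power input and writes every artifact plus a manifest (package
version, seed, config hash). Identical config and seed produce
byte-identical outputs. A failure in any stage aborts with the stage name
and removes partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .containers import PowerTensor, align_members
from .entropy import average_ni, shuffle_baseline, sliding_ni, iqr_profile
from .errors import ConfigError, TeamNeuroError
from .io import (
    RunConfig,
    read_events,
    read_power_csv,
    read_recording,
    write_envelope_csv,
    write_ni_csv,
    write_power_csv,
)
from .spectral import band_power_per_second
from .symbols import (
    MISSING_LEVEL,
    discretize_tensor,
    symbol_lookup_table,
    team_nds_from_levels,
)
from .synthetic import SynthConfig, generate_power_tensor
from .teamstats import SCHEME_A, SCHEME_B, band_aggregate, member_ni

logger = logging.getLogger("teamneuro")

__all__ = ["run_pipeline"]


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _load_power(config: RunConfig) -> PowerTensor:
    if config.synthetic:
        synth = SynthConfig(
            n_members=len(config.members) or 3,
            sensors=config.sensors,
            bins=config.bins,
            duration_s=config.duration_s,
            noise_model=config.noise_model,
            seed=config.seed,
        )
        tensor, _ = generate_power_tensor(synth)
        return tensor
    if config.power_csv is not None:
        return read_power_csv(config.power_csv)
    recordings = read_recording(config.recording)
    tensors = [band_power_per_second(rec, bins=config.bins) for rec in recordings]
    return align_members(tensors)


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full pipeline; returns the manifest dictionary.

    Artifacts written to the output directory: config.json, power.csv (+
    missing sidecar), thresholds.json, lookup_table.json, team_ni.csv,
    member_ni_<member>.csv, baseline.csv, band_ni.csv, and manifest.json.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"

    def _write(name: str, writer, *args) -> Path:
        p = out / name
        writer(*args, p)
        written.append(p)
        return p

    try:
        stage = "config"
        t_start = time.time()
        (out / "config.json").write_text(json.dumps(config.to_dict(), indent=1))
        written.append(out / "config.json")

        stage = "power"
        t0 = time.time()
        tensor = _load_power(config)
        _write("power.csv", write_power_csv, tensor)
        written.append(out / "power.csv.missing.json")
        logger.info("stage power: %.1fs (%d members, %d sensors, %d bins, %d s)",
                    time.time() - t0, len(tensor.members), len(tensor.sensors),
                    len(tensor.freqs), tensor.n_seconds)

        stage = "symbolize"
        t0 = time.time()
        streams = discretize_tensor(tensor)
        team_streams = team_nds_from_levels(streams)
        thresholds = [
            {
                "member": s.member,
                "sensor": s.sensor,
                "freq_hz": s.freq_hz,
                "low_cut": s.thresholds.low_cut,
                "high_cut": s.thresholds.high_cut,
                "degenerate": s.thresholds.degenerate,
            }
            for s in streams
        ]
        (out / "thresholds.json").write_text(json.dumps(thresholds, indent=1))
        written.append(out / "thresholds.json")
        lookup = {
            str(idx): list(levels)
            for idx, levels in sorted(symbol_lookup_table(len(tensor.members)).items())
        }
        (out / "lookup_table.json").write_text(json.dumps(lookup, indent=1))
        written.append(out / "lookup_table.json")
        logger.info("stage symbolize: %.1fs (%d individual, %d team streams)",
                    time.time() - t0, len(streams), len(team_streams))

        stage = "ni"
        t0 = time.time()
        team_traces = [
            sliding_ni(nds, window_s=config.window_s, step_s=config.step_s)
            for nds in team_streams
        ]
        team_avg = average_ni(team_traces)
        _write("team_ni.csv", write_ni_csv, team_avg)
        member_traces = {}
        for member in tensor.members:
            mine = [s for s in streams if s.member == member]
            member_traces[member] = member_ni(
                mine, window_s=config.window_s, step_s=config.step_s
            )
            _write(f"member_ni_{member}.csv", write_ni_csv, member_traces[member])
        logger.info("stage ni: %.1fs", time.time() - t0)

        stage = "baseline"
        t0 = time.time()
        by_key = {(s.member, s.sensor, s.freq_hz): s.levels for s in streams}
        level_array = np.stack(
            [
                np.stack(
                    [
                        np.stack([by_key[m, c, f] for f in tensor.freqs])
                        for c in tensor.sensors
                    ]
                )
                for m in tensor.members
            ]
        )
        envelope = shuffle_baseline(
            level_array,
            n_shuffles=config.shuffles,
            seed=config.seed,
            window_s=config.window_s,
        )
        _write("baseline.csv", write_envelope_csv, envelope)
        logger.info("stage baseline: %.1fs (R=%d)", time.time() - t0, config.shuffles)

        stage = "analyze"
        t0 = time.time()
        scheme = SCHEME_A if config.band_scheme == "A" else SCHEME_B
        # per-bin traces averaged over sensors, then banded
        ni_by_bin = {}
        for k, hz in enumerate(tensor.freqs):
            per_sensor = [
                team_traces[i]
                for i, nds in enumerate(team_streams)
                if nds.freq_hz == hz
            ]
            ni_by_bin[hz] = average_ni(per_sensor)
        covered = tuple(
            (label, lo, hi)
            for label, lo, hi in scheme.bands
            if any(lo <= hz <= hi for hz in tensor.freqs)
        )
        from .teamstats import BandScheme

        bands = (
            band_aggregate(ni_by_bin, BandScheme(scheme.name, covered))
            if covered
            else {}
        )
        import pandas as pd

        band_df = pd.DataFrame(
            {"second": team_avg.seconds}
            | {label: tr.values for label, tr in bands.items()}
        )
        band_df.to_csv(out / "band_ni.csv", index=False, float_format="%.12g")
        written.append(out / "band_ni.csv")

        events = read_events(config.events) if config.events else []
        q25, q75 = iqr_profile(team_avg)
        logger.info("stage analyze: %.1fs", time.time() - t0)

        stage = "manifest"
        manifest = {
            "package": "teamneuro",
            "version": __version__,
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "n_members": len(tensor.members),
            "n_sensors": len(tensor.sensors),
            "n_bins": len(tensor.freqs),
            "n_seconds": tensor.n_seconds,
            "n_team_streams": len(team_streams),
            "n_individual_streams": len(streams),
            "state_space_size": team_streams[0].n_states,
            "hmax_bits": team_traces[0].hmax,
            "team_ni_iqr": [q25, q75],
            "baseline_iqr": [float(np.atleast_1d(envelope.q25)[0]),
                             float(np.atleast_1d(envelope.q75)[0])],
            "n_events": len(events),
            "elapsed_s": round(time.time() - t_start, 2),
            "artifacts": sorted(p.name for p in written) + ["manifest.json"],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return manifest
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(exc, (ConfigError,)):
            raise
        raise TeamNeuroError(f"pipeline failed in stage {stage!r}: {exc}") from exc
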