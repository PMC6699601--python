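"""Member decomposition, cross-correlation, aggregation, contrasts."""

import math

import numpy as np
import pytest
from scipy import stats

from teamneuro import (
    EventSegment,
    LIVE_REGIONS,
    NITrace,
    SCHEME_A,
    SCHEME_B,
    SIMULATION_REGIONS,
    band_aggregate,
    bracket_event,
    cross_correlate,
    level_composition,
    member_ni,
    region_contrast,
    sensor_time_frequency_map,
    time_frequency_map,
)
from teamneuro.symbols import Thresholds, discretize_stream
from teamneuro.teamstats import BandScheme, RegionMap


def _trace(values, n_states=27, **kw):
    return NITrace(np.asarray(values, float), n_states=n_states, **kw)


class TestMemberNI:
    def test_constant_member_hits_log2_three(self):
        stream = discretize_stream(
            np.full(200, 9.0), Thresholds(1.0, 2.0),
            member="A", sensor="Cz", freq_hz=10,
        )
        trace = member_ni([stream])
        assert np.allclose(trace.values[59:], math.log2(3))

    def test_mixed_members_rejected(self):
        s1 = discretize_stream(np.arange(9.0), member="A", sensor="Cz", freq_hz=10)
        s2 = discretize_stream(np.arange(9.0), member="B", sensor="Cz", freq_hz=10)
        with pytest.raises(ValueError, match="several members"):
            member_ni([s1, s2])


class TestCrossCorrelate:
    def test_identical_traces_r_one_lag_zero(self, rng):
        v = rng.uniform(0, 2, size=400)
        res = cross_correlate(v, v.copy(), max_lag_s=30)
        assert res.lag_s == 0
        assert res.r == pytest.approx(1.0)

    def test_constructed_delay_recovered(self, rng):
        v = rng.uniform(0, 2, size=500)
        delayed = np.full(500, np.nan)
        delayed[10:] = v[:-10]  # b lags a by 10 s => a leads
        res = cross_correlate(v, delayed, max_lag_s=30)
        assert res.lag_s == 10
        assert res.r == pytest.approx(1.0)

    def test_antisymmetry_of_lag(self, rng):
        a = rng.uniform(size=400)
        b = np.roll(a, 7) + 0.05 * rng.standard_normal(400)
        r1 = cross_correlate(a, b, max_lag_s=20)
        r2 = cross_correlate(b, a, max_lag_s=20)
        assert r1.lag_s == -r2.lag_s
        assert r1.r == pytest.approx(r2.r, abs=1e-12)

    def test_insufficient_overlap_rejected(self):
        v = np.full(100, np.nan)
        v[:50] = 1.0
        with pytest.raises(ValueError, match="overlapping"):
            cross_correlate(v, v, max_lag_s=60)

    def test_injected_lag_recovered_from_generator(self):
        """Coupled synthetic members: NI lead/lag within +/-2 s of truth."""
        from teamneuro import (
            GroundTruthEpoch, SynthConfig, generate_power_tensor, inject_coupling,
        )
        from teamneuro.symbols import discretize_tensor

        hits = 0
        for seed in range(5):
            cfg = SynthConfig(
                sensors=("Cz",), bins=(9, 10, 11), duration_s=600, seed=seed,
                epochs=(GroundTruthEpoch(0, (250, 350), 3),),
            )
            tensor, _ = generate_power_tensor(cfg)
            tensor = inject_coupling(
                tensor, 0, 1, lag_s=10, interval=(200, 500), seed=seed
            )
            streams = discretize_tensor(tensor)
            lead = member_ni([s for s in streams if s.member == "M1"])
            foll = member_ni([s for s in streams if s.member == "M2"])
            res = cross_correlate(lead, foll, max_lag_s=60)
            hits += abs(res.lag_s - 10) <= 2
        assert hits >= 4


class TestBandAggregate:
    def _by_bin(self, values_fn, n=100):
        return {hz: _trace(values_fn(hz) * np.ones(n)) for hz in range(1, 41)}

    def test_indicator_band_isolated(self):
        by_bin = self._by_bin(lambda hz: 1.0 if 3 <= hz <= 7 else 0.0)
        bands = band_aggregate(by_bin, SCHEME_A)
        assert np.allclose(bands["delta/theta"].values, 1.0)
        for label in ("alpha", "mu", "low beta", "high beta/gamma"):
            assert np.allclose(bands[label].values, 0.0)

    def test_schemes_agree_on_shared_bands(self, rng):
        by_bin = {hz: _trace(rng.uniform(0, 2, 50)) for hz in range(1, 41)}
        a = band_aggregate(by_bin, SCHEME_A)
        b = band_aggregate(by_bin, SCHEME_B)
        for label in ("delta/theta", "alpha", "mu", "low beta"):
            assert np.allclose(a[label].values, b[label].values)

    def test_matches_direct_mean_oracle(self, rng):
        mat = rng.uniform(0, 3, size=(40, 60))
        by_bin = {hz: _trace(mat[hz - 1]) for hz in range(1, 41)}
        bands = band_aggregate(by_bin, SCHEME_A)
        assert np.allclose(
            bands["high beta/gamma"].values, mat[22:40].mean(axis=0), atol=1e-12
        )

    def test_partition_consistency_with_overall_mean(self, rng):
        """Equal-width bands averaged with equal weight equal the pooled mean."""
        scheme = BandScheme("eq", (("a", 1, 10), ("b", 11, 20), ("c", 21, 30), ("d", 31, 40)))
        mat = rng.uniform(0, 3, size=(40, 30))
        by_bin = {hz: _trace(mat[hz - 1]) for hz in range(1, 41)}
        bands = band_aggregate(by_bin, scheme)
        stacked = np.mean([tr.values for tr in bands.values()], axis=0)
        assert np.allclose(stacked, mat.mean(axis=0), atol=1e-12)

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError, match="no bins"):
            band_aggregate({10: _trace(np.ones(30))}, SCHEME_A)


class TestRegionContrast:
    def test_identical_regions_fold_one_p_near_one(self, rng):
        v = rng.uniform(size=300)
        ni = {s: v for s in ("F3", "Fz", "F4", "P3", "Pz", "P4")}
        res = region_contrast(ni, SIMULATION_REGIONS)
        assert res.fold_ratio == pytest.approx(1.0)
        assert res.p > 0.9
        assert abs(res.z) < 0.2

    def test_shifted_region_detected(self, rng):
        base = rng.uniform(size=200)
        ni = {
            "F3": base + 1.0, "Fz": base + 1.0, "F4": base + 1.0,
            "P3": base, "Pz": base, "P4": base,
        }
        res = region_contrast(ni, SIMULATION_REGIONS)
        assert res.p < 0.01
        assert res.z > 0  # anterior ranks higher

    def test_matches_scipy_reference(self, rng):
        x, y = rng.uniform(size=150), rng.uniform(size=150) + 0.2
        ni = {"F3": x, "Fz": x, "F4": x, "P3": y, "Pz": y, "P4": y}
        res = region_contrast(ni, SIMULATION_REGIONS)
        ref = stats.mannwhitneyu(
            np.tile(x, 3), np.tile(y, 3), alternative="two-sided"
        )
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_z_invariant_under_common_monotone_transform(self, rng):
        ni = {s: rng.uniform(size=80) for s in ("F3", "Fz", "F4", "P3", "Pz", "P4")}
        r1 = region_contrast(ni, SIMULATION_REGIONS)
        r2 = region_contrast({k: np.exp(3 * v) for k, v in ni.items()}, SIMULATION_REGIONS)
        assert r1.z == pytest.approx(r2.z, abs=1e-12)

    def test_sensor_order_irrelevant(self, rng):
        ni = {s: rng.uniform(size=50) for s in ("F3", "Fz", "F4", "P3", "Pz", "P4")}
        r1 = region_contrast(ni, SIMULATION_REGIONS)
        r2 = region_contrast(dict(reversed(list(ni.items()))), SIMULATION_REGIONS)
        assert (r1.z, r1.p) == (r2.z, r2.p)

    def test_absent_region_sensors_named_in_error(self, rng):
        ni = {s: rng.uniform(size=50) for s in ("F3", "Fz", "F4")}
        with pytest.raises(ValueError, match="P3"):
            region_contrast(ni, SIMULATION_REGIONS)

    def test_live_montage_regions_disjoint(self):
        assert set(LIVE_REGIONS["anterior"]).isdisjoint(LIVE_REGIONS["posterior"])
        with pytest.raises(ValueError, match="shares"):
            RegionMap((("a", ("F3",)), ("b", ("F3", "Fz"))))


class TestBracketEvent:
    def test_padded_window_with_core(self):
        trace = _trace(np.arange(300.0) / 300)
        seg = bracket_event(trace, EventSegment("INTB", 100, 140), pad_s=60)
        assert seg.window == (40, 200)
        assert seg.core == (100, 140)
        assert seg.values.size == 160
        assert seg.core_mask.sum() == 40

    def test_event_at_start_truncates_left(self):
        trace = _trace(np.ones(300))
        seg = bracket_event(trace, EventSegment("e", 10, 50), pad_s=60)
        assert seg.window == (0, 110)

    def test_event_outside_recording_rejected(self):
        trace = _trace(np.ones(100))
        with pytest.raises(ValueError, match="outside"):
            bracket_event(trace, EventSegment("e", 500, 550))


class TestLevelComposition:
    def test_all_low_distribution(self):
        comps, _ = level_composition({"e": np.full(60, -1)})
        c = comps["e"]
        assert c.distribution == {-1: 1.0, 1: 0.0, 3: 0.0}
        assert c.mean_level == -1.0

    def test_identical_events_h_zero(self):
        ev = np.tile([-1, 1, 3], 20)
        comps, test = level_composition({f"e{i}": ev for i in range(4)})
        assert test["H"] == pytest.approx(0.0, abs=1e-9)
        assert test["p"] > 0.9
        assert test["df"] == 3

    def test_forced_levels_differ_significantly(self):
        comps, test = level_composition(
            {"low": np.full(60, -1), "avg": np.full(60, 1), "high": np.full(60, 3)}
        )
        assert test["p"] < 0.01
        ref = stats.kruskal(
            np.full(60, -1.0), np.full(60, 1.0), np.full(60, 3.0)
        )
        assert test["H"] == pytest.approx(ref.statistic, rel=1e-9)

    def test_all_missing_event_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            comps, _ = level_composition({"empty": np.zeros(10), "ok": np.full(10, 1)})
        assert list(comps) == ["ok"]


class TestTimeFrequencyMap:
    def test_single_bin_one_nonzero_row(self):
        by_bin = {hz: _trace(np.zeros(50)) for hz in (9, 10, 11)}
        by_bin[10] = _trace(np.ones(50))
        mat = time_frequency_map(by_bin)
        assert mat.shape == (3, 50)
        assert mat[1].all() and not mat[0].any() and not mat[2].any()

    def test_unknown_sensor_rejected(self):
        with pytest.raises(KeyError, match="unknown sensor"):
            sensor_time_frequency_map({"Cz": {}}, "Oz")

    def test_row_means_match_singleton_band_aggregate(self, rng):
        by_bin = {hz: _trace(rng.uniform(0, 2, 40)) for hz in range(1, 6)}
        mat = time_frequency_map(by_bin)
        scheme = BandScheme("s", tuple((str(hz), hz, hz) for hz in range(1, 6)))
        bands = band_aggregate(by_bin, scheme)
        for i, hz in enumerate(range(1, 6)):
            assert np.allclose(mat[i], bands[str(hz)].values)

    def test_epoch_restricted_to_bins_shows_only_those_rows(self):
        from teamneuro import GroundTruthEpoch, SynthConfig, generate_power_tensor, sliding_ni
        from teamneuro.symbols import discretize_tensor, team_nds_from_levels

        cfg = SynthConfig(
            sensors=("Cz",), bins=tuple(range(3, 15)), duration_s=400, seed=4,
            epochs=(GroundTruthEpoch("team", (200, 320), 3, bins=tuple(range(3, 12))),),
        )
        tensor, _ = generate_power_tensor(cfg)
        team = team_nds_from_levels(discretize_tensor(tensor))
        by_bin = {nds.freq_hz: sliding_ni(nds) for nds in team}
        mat = time_frequency_map(by_bin, freqs=sorted(by_bin))
        inside = np.nanmean(mat[:9, 260:320], axis=1)   # bins 3-11, epoch
        outside = np.nanmean(mat[9:, 260:320], axis=1)  # bins 12-14
        assert inside.min() > outside.max() + 0.5
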