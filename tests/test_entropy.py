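"""Sliding-window entropy, NI, baselines."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from teamneuro import (
    NITrace,
    average_ni,
    iqr_profile,
    shannon_entropy,
    shuffle_baseline,
    sliding_ni,
)
from teamneuro.symbols import MISSING_SYMBOL

from conftest import window_entropy_oracle


class TestShannonEntropy:
    def test_single_symbol_zero_bits(self):
        assert shannon_entropy([5] * 60) == 0.0

    def test_two_equal_symbols_one_bit(self):
        assert shannon_entropy([0] * 30 + [1] * 30) == pytest.approx(1.0)

    def test_three_symbol_cycle(self):
        assert shannon_entropy([0, 1, 2] * 20) == pytest.approx(math.log2(3))

    def test_matches_counting_oracle(self, rng):
        win = rng.integers(0, 27, size=60)
        expected = window_entropy_oracle(list(win), window=60)[-1]
        assert shannon_entropy(win) == pytest.approx(expected, abs=1e-12)

    def test_all_missing_is_nan(self):
        assert np.isnan(shannon_entropy([MISSING_SYMBOL] * 10))


class TestSlidingNI:
    def test_constant_stream_full_ni(self):
        trace = sliding_ni(np.zeros(200, dtype=int), n_states=27)
        valid = trace.values[59:]
        assert np.allclose(valid, math.log2(27))
        assert trace.hmax == pytest.approx(4.7549, abs=1e-4)

    def test_three_symbol_cycle_gives_log2_nine(self):
        sym = np.tile([0, 1, 2], 100)
        trace = sliding_ni(sym, n_states=27)
        assert np.allclose(trace.values[59:], math.log2(27) - math.log2(3))
        assert trace.values[100] == pytest.approx(3.17, abs=0.005)

    def test_warmup_is_missing(self):
        trace = sliding_ni(np.zeros(100, dtype=int), n_states=27)
        assert np.isnan(trace.values[:59]).all()
        assert not np.isnan(trace.values[59:]).any()

    def test_matches_windowed_oracle(self, rng):
        sym = rng.integers(0, 27, size=500)
        trace = sliding_ni(sym, n_states=27)
        oracle = math.log2(27) - window_entropy_oracle(list(sym), window=60)
        ok = ~np.isnan(oracle)
        assert np.allclose(trace.values[ok], oracle[ok], atol=1e-12)

    def test_missing_tolerance_twenty_percent(self):
        sym = np.zeros(250, dtype=int)
        sym[100:113] = MISSING_SYMBOL  # a 13-second missing run
        trace = sliding_ni(sym, n_states=27)
        # any window holding all 13 missing seconds exceeds 20% of 60
        assert np.isnan(trace.values[112:160]).all()
        # windows holding only 12 of them (exactly 20%) are computed
        assert not np.isnan(trace.values[111])
        assert not np.isnan(trace.values[160])

    def test_short_stream_warns_and_is_empty(self):
        with pytest.warns(UserWarning, match="empty NI trace"):
            trace = sliding_ni(np.zeros(30, dtype=int), n_states=27)
        assert np.isnan(trace.values).all()

    def test_ni_bounds_and_max_iff_single_symbol(self, rng):
        sym = rng.integers(0, 27, size=400)
        trace = sliding_ni(sym, n_states=27)
        v = trace.values[~np.isnan(trace.values)]
        assert (v >= 0).all() and (v <= trace.hmax + 1e-12).all()
        assert not np.any(v == trace.hmax)  # random window never single-symbol

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 9999))
    def test_invariant_under_symbol_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        sym = rng.integers(0, 27, size=300)
        perm = rng.permutation(27)
        a = sliding_ni(sym, n_states=27).values
        b = sliding_ni(perm[sym], n_states=27).values
        assert np.allclose(a, b, equal_nan=True)

    def test_team_entropy_between_member_max_and_sum(self, rng):
        """Subadditivity: max_m H_m <= H_team <= sum_m H_m per window."""
        from teamneuro.symbols import encode_level_matrix, LEVELS
        from teamneuro.entropy import window_entropies

        lv = rng.choice(LEVELS, size=(3, 400)).astype(np.int8)
        lv[1] = lv[0]  # couple two members to exercise the lower bound
        team = window_entropies(encode_level_matrix(lv), 27, 60)
        digits = [np.searchsorted([-1, 1, 3], row) for row in lv]
        members = [window_entropies(d.astype(np.int64), 3, 60) for d in digits]
        ok = ~np.isnan(team)
        lower = np.max(members, axis=0)[ok]
        upper = np.sum(members, axis=0)[ok]
        assert (team[ok] >= lower - 1e-9).all()
        assert (team[ok] <= upper + 1e-9).all()

    def test_plugin_bias_floor_on_uniform_streams(self, rng):
        """Mean NI of i.i.d. uniform 27-symbol streams sits in [0.2, 0.9] bits."""
        means = []
        for _ in range(10):
            sym = rng.integers(0, 27, size=1000)
            tr = sliding_ni(sym, n_states=27)
            means.append(np.nanmean(tr.values))
        assert 0.2 <= np.mean(means) <= 0.9


class TestAverageNI:
    def _trace(self, values, **kw):
        return NITrace(np.asarray(values, float), n_states=27, **kw)

    def test_idempotent_on_identical_traces(self):
        t = self._trace([np.nan, 1.0, 2.0])
        out = average_ni([t, t])
        assert np.allclose(out.values, t.values, equal_nan=True)

    def test_zero_and_hmax_average_to_half(self):
        hmax = math.log2(27)
        out = average_ni([self._trace([0.0]), self._trace([hmax])])
        assert out.values[0] == pytest.approx(hmax / 2)

    def test_matches_direct_mean_oracle(self, rng):
        stacks = rng.uniform(0, 4, size=(5, 100))
        traces = [self._trace(row) for row in stacks]
        out = average_ni(traces)
        assert np.allclose(out.values, stacks.mean(axis=0), atol=1e-12)

    def test_missing_only_seconds_stay_missing(self):
        out = average_ni([self._trace([np.nan, 1.0]), self._trace([np.nan, np.nan])])
        assert np.isnan(out.values[0])
        assert out.values[1] == 1.0
        assert list(out.n_streams) == [0, 1]


class TestIQRProfile:
    def test_linear_interpolation_convention(self):
        q25, q75 = iqr_profile(np.arange(1.0, 101.0))
        assert (q25, q75) == (25.75, 75.25)

    def test_constant_trace(self):
        assert iqr_profile(np.full(10, 2.0)) == (2.0, 2.0)

    def test_matches_sort_based_oracle(self, rng):
        v = rng.uniform(size=500)
        assert iqr_profile(v) == pytest.approx(
            tuple(np.percentile(np.sort(v), [25, 75]))
        )

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError, match=">= 4 valid"):
            iqr_profile(np.array([1.0, 2.0, np.nan, np.nan]))


class TestShuffleBaseline:
    def test_constant_streams_degenerate_envelope(self):
        lv = np.tile(np.int8(3), (3, 1, 200))
        env = shuffle_baseline(lv, n_shuffles=5, seed=0)
        assert env.q25 == env.q75 == pytest.approx(math.log2(27))

    def test_same_seed_reproducible(self, rng):
        lv = rng.choice([-1, 1, 3], size=(3, 1, 300)).astype(np.int8)
        e1 = shuffle_baseline(lv, n_shuffles=10, seed=42)
        e2 = shuffle_baseline(lv, n_shuffles=10, seed=42)
        assert (e1.q25, e1.q75) == (e2.q25, e2.q75)

    def test_uniform_streams_rarely_exceed_q75(self, rng):
        """Original i.i.d. NI exceeds the shuffle q75 at <= 30% of seconds."""
        from teamneuro.symbols import encode_level_matrix

        lv = rng.choice([-1, 1, 3], size=(3, 400)).astype(np.int8)
        env = shuffle_baseline(lv[:, None, :], n_shuffles=50, seed=1)
        ni = sliding_ni(encode_level_matrix(lv), n_states=27).values
        valid = ni[~np.isnan(ni)]
        assert (valid > env.q75).mean() <= 0.30

    def test_too_few_shuffles_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            shuffle_baseline(np.ones((3, 1, 200), dtype=np.int8), n_shuffles=1)
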