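"""Circadian metrics: periodogram, IS/IV closed forms, onsets, the sleep-offset
rule, nap/bout scoring, and activity summaries, validated against generator
ground truth and brute-force oracles."""

import warnings

import numpy as np
import pytest

from chronopheno.actogram import ActogramError
from chronopheno.circadian import (DegenerateInputError, activity_summary,
                                   active_windows_from_onsets,
                                   chi_squared_periodogram, detect_onsets,
                                   detect_sleep_offsets, interdaily_stability,
                                   intradaily_variability, score_naps_bouts)
from chronopheno.simulate import ActogramParams, simulate_actogram
from conftest import make_record


def square_wave_record(period_h=24.0, days=12, bin_minutes=5, high=100, low=0,
                       duty=0.5):
    n = days * 24 * 60 // bin_minutes
    t = (np.arange(n) + 0.5) * bin_minutes / 60.0
    counts = np.where((t % period_h) < duty * period_h, high, low)
    return make_record(counts, bin_minutes=bin_minutes)


class TestPeriodogram:
    def test_pure_24h_square_wave_peaks_at_24(self):
        res = chi_squared_periodogram(square_wave_record(24.0))
        assert res.peak_period_h == pytest.approx(24.0, abs=5 / 60)
        assert res.significant

    def test_constant_record_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            chi_squared_periodogram(make_record(np.full(12 * 288, 7)))

    def test_unrepresentable_window_rejected(self):
        rec = square_wave_record(days=2)
        with pytest.raises(ActogramError):
            chi_squared_periodogram(rec, search_window_h=(30.0, 60.0))

    def test_qp_nonnegative_and_peak_inside_window(self):
        rec, _ = simulate_actogram(ActogramParams(tau_h=24.5, days=11, seed=7))
        res = chi_squared_periodogram(rec)
        assert np.all(res.qp >= 0) and np.all(res.significance_line > 0)
        assert 20.0 <= res.peak_period_h <= 28.0

    def test_recovers_tau_with_noise_naps_and_jitter(self):
        hits = 0
        for seed in range(20):
            tau = 23.0 + 2.0 * (seed / 20)
            rec, _ = simulate_actogram(ActogramParams(
                tau_h=tau, days=11, nap_prob_per_30min=0.1,
                onset_jitter_sd_h=0.25, seed=seed))
            err = abs(chi_squared_periodogram(rec).peak_period_h - tau)
            hits += err <= 0.1
        assert hits >= 18  # the full 200-seed check lives in the acceptance suite

    def test_null_family_wise_rate_is_small(self, rng):
        hits = 0
        for _ in range(100):
            rec = make_record(rng.poisson(10.0, 11 * 288))
            hits += chi_squared_periodogram(rec).any_significant
        assert hits <= 12  # ~alpha; the calibrated band is asserted at 500 reps


class TestRhythmStatistics:
    def test_is_exactly_one_for_day_repeating_input(self, rng):
        day = rng.poisson(20.0, 24)
        rec = make_record(np.tile(day, 8), bin_minutes=60)
        assert interdaily_stability(rec) == pytest.approx(1.0, abs=1e-12)

    def test_is_of_noise_has_expectation_one_over_days(self, rng):
        n_days, reps = 8, 400
        vals = [interdaily_stability(make_record(rng.poisson(20.0, 24 * n_days),
                                                 bin_minutes=60))
                for _ in range(reps)]
        se = np.std(vals) / np.sqrt(reps)
        assert np.mean(vals) == pytest.approx(1 / n_days, abs=4 * se + 0.005)

    def test_is_near_noise_floor_for_desynchronized_23h_rhythm(self):
        t = np.arange(24 * 24) + 0.5
        counts = np.round(100 + 80 * np.sin(2 * np.pi * t / 23.0)).astype(int)
        rec = make_record(counts, bin_minutes=60)
        assert interdaily_stability(rec) < 0.15

    def test_iv_closed_form_for_24h_sinusoid(self):
        n = 24 * 5000
        t = np.arange(n)
        x = np.round(2e5 + 1e5 * np.sin(2 * np.pi * t / 24.0)).astype(np.int64)
        iv = intradaily_variability(make_record(x, bin_minutes=60))
        assert iv == pytest.approx(2 * (1 - np.cos(2 * np.pi / 24)), abs=1e-6)

    def test_iv_of_white_noise_is_two(self, rng):
        vals = [intradaily_variability(make_record(rng.poisson(50.0, 24 * 10),
                                                   bin_minutes=60))
                for _ in range(300)]
        se = np.std(vals) / np.sqrt(len(vals))
        assert np.mean(vals) == pytest.approx(2.0, abs=4 * se)

    def test_iv_of_alternating_sequence_is_four(self):
        x = np.tile([10, 0], 5 * 24)
        n = x.size
        iv = intradaily_variability(make_record(x, bin_minutes=60))
        # direct evaluation: diffs all +-10, var = 25 -> IV = 4 exactly (up to
        # the odd-length end term)
        assert iv == pytest.approx(4.0, rel=0.01)
        assert iv == pytest.approx(n * (n - 1) * 100 / ((n - 1) * n * 25), rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            interdaily_stability(make_record(np.full(48, 5), bin_minutes=60))
        with pytest.raises(DegenerateInputError):
            intradaily_variability(make_record(np.full(48, 5), bin_minutes=60))


class TestOnsets:
    def test_noiseless_onsets_sit_at_ct12(self):
        rec, truth = simulate_actogram(ActogramParams(
            tau_h=24.0, days=11, deterministic=True, rest_rate=0.0, seed=0))
        onsets = detect_onsets(rec, 24.0)
        assert len(onsets) == len(truth.onsets_h)
        for z in onsets:
            assert z.reference == "CT"
            assert z.value == pytest.approx(12.0, abs=0.5)
        # absolute onsets track the truth up to the half-ramp template delay
        for z, o in zip(onsets, truth.onsets_h):
            assert abs(z.abs_hours - o) <= 0.75

    def test_uniform_activity_yields_no_onsets(self):
        rec = make_record(np.full(11 * 288, 50))
        with pytest.warns(UserWarning):
            assert detect_onsets(rec, 24.0) == []

    def test_phase_delay_is_tracked(self):
        # +3 h onset shift after day 6 of a deterministic 24-h rhythm
        p = ActogramParams(tau_h=24.0, days=12, deterministic=True,
                           rest_rate=0.0, seed=0)
        rec_a, _ = simulate_actogram(p)
        from dataclasses import replace
        rec_b, _ = simulate_actogram(replace(p, onset_offset_h=9.0))
        split = 6 * 288
        rec = make_record(np.concatenate([rec_a.counts[:split], rec_b.counts[split:]]))
        onsets = detect_onsets(rec, 24.0)
        early = [z.abs_hours % 24 for z in onsets if z.abs_hours < 5 * 24]
        late = [z.abs_hours % 24 for z in onsets if z.abs_hours > 7 * 24]
        assert np.mean(late) - np.mean(early) == pytest.approx(3.0, abs=0.5)


def block_record(active_hours, days=6, high=120, low=0):
    """Hourly-bin record: active for `active_hours` each 24-h day, then silent."""
    day = np.array([high] * active_hours + [low] * (24 - active_hours))
    return make_record(np.tile(day, days), bin_minutes=60)


class TestSleepOffsets:
    def test_offset_follows_activity_end(self):
        rec = block_record(12)
        wins = [(24.0 * d, 24.0 * d + 12.0) for d in range(6)]
        st = detect_sleep_offsets(rec, wins)
        assert len(st.offsets) == 6
        for d, z in enumerate(st.offsets):
            assert z.abs_hours == pytest.approx(24.0 * d + 12.0, abs=1.0)

    def test_injected_quiescent_block_found_exactly(self):
        # active phase ZT0-12 at 120 counts/h with a 3-h sub-threshold block
        # injected at ZT8 of day 2
        counts = np.tile([120] * 12 + [0] * 12, 4).astype(float)
        counts[24 + 8: 24 + 11] = 10.0  # < 20% of the 120-ish active mean
        rec = make_record(counts.astype(int), bin_minutes=60)
        wins = [(24.0 * d, 24.0 * d + 12.0) for d in range(4)]
        st = detect_sleep_offsets(rec, wins)
        assert st.offsets[1].abs_hours == pytest.approx(24 + 8)
        assert st.offsets[1].value == pytest.approx(8.0)

    def test_constant_high_activity_yields_no_offsets(self):
        rec = make_record(np.full(6 * 24, 100), bin_minutes=60)
        wins = [(24.0 * d, 24.0 * d + 12.0) for d in range(6)]
        with pytest.warns(UserWarning):
            st = detect_sleep_offsets(rec, wins)
        assert st.offsets == []

    def test_rule_is_translation_equivariant(self):
        shift = 5  # hours
        base = np.tile([120] * 12 + [0] * 12, 5)
        rec_a = make_record(base, bin_minutes=60)
        rec_b = make_record(np.concatenate([np.zeros(shift, int), base]),
                            bin_minutes=60)
        wins_a = [(24.0 * d, 24.0 * d + 12.0) for d in range(5)]
        wins_b = [(a + shift, b + shift) for a, b in wins_a]
        off_a = detect_sleep_offsets(rec_a, wins_a).offsets
        off_b = detect_sleep_offsets(rec_b, wins_b).offsets
        assert len(off_a) == len(off_b)
        for za, zb in zip(off_a, off_b):
            assert zb.abs_hours - za.abs_hours == pytest.approx(shift)


def brute_force_runs(binary, min_len=2):
    """Independent run-length oracle: maximal runs of True with length >= 2."""
    runs, start = [], None
    for i, b in enumerate(list(binary) + [False]):
        if b and start is None:
            start = i
        elif not b and start is not None:
            if i - start >= min_len:
                runs.append((start, i - start))
            start = None
    return runs


class TestNapsAndBouts:
    def test_constructed_nap_fixture(self):
        # active window 0-12 h; 30-min zero bins at positions 4-7 -> one 120-min nap
        bins = np.full(48, 10)
        bins[4:8] = 0
        rec = make_record(bins, bin_minutes=30)
        nb = score_naps_bouts(rec, [(0.0, 12.0)])
        assert nb.nap_count == 1
        start, length = nb.naps[0]
        assert start.abs_hours == pytest.approx(2.0) and length == 120
        assert nb.total_nap_minutes == 120

    def test_single_zero_bin_is_not_a_nap(self):
        bins = np.full(48, 10)
        bins[5] = 0
        rec = make_record(bins, bin_minutes=30)
        assert score_naps_bouts(rec, [(0.0, 12.0)]).nap_count == 0

    def test_matches_brute_force_oracle_on_random_sequences(self, rng):
        for _ in range(300):
            bins = rng.integers(0, 2, 48) * rng.integers(1, 5, 48)
            rec = make_record(bins, bin_minutes=30)
            active = [(0.0, 12.0)]
            nb = score_naps_bouts(rec, active)
            zero = bins == 0
            naps_oracle = [(s, l) for s, l in brute_force_runs(zero[:24])]
            bouts_oracle = [(24 + s, l) for s, l in brute_force_runs(~zero[24:])]
            assert [(int(z.abs_hours * 2), l // 30) for z, l in nb.naps] == naps_oracle
            assert [(int(z.abs_hours * 2), l // 30) for z, l in nb.bouts] == bouts_oracle

    def test_injected_naps_recovered_exactly(self):
        rec, truth = simulate_actogram(ActogramParams(
            tau_h=24.0, days=11, nap_prob_per_30min=0.15, seed=42))
        nb = score_naps_bouts(rec, truth.active_windows)
        found = {(z.abs_hours, length) for z, length in nb.naps}
        for start_bin, len_bins in truth.naps:
            assert (start_bin * 5 / 60.0, len_bins * 5) in found
        assert nb.nap_count == len(truth.naps)


class TestActivitySummary:
    def test_single_window_profile(self):
        day = np.zeros(24, dtype=int)
        day[12:16] = 600  # 10 counts/min for ZT12-16
        rec = make_record(np.tile(day, 3), bin_minutes=60)
        s = activity_summary(rec)
        assert s.peak4h_counts_per_min == pytest.approx(10.0)
        assert s.peak4h_start_hour == 12

    def test_percent_change_matches_reported_drop_arithmetic(self):
        day_hi = np.zeros(24, dtype=int)
        day_hi[12:16] = 600
        base = activity_summary(make_record(np.tile(day_hi, 2), bin_minutes=60))
        day_lo = np.zeros(24, dtype=int)
        day_lo[12:16] = 234  # 3.9 counts/min
        s = activity_summary(make_record(np.tile(day_lo, 2), bin_minutes=60),
                             baseline=base)
        assert s.percent_change_vs_baseline == pytest.approx(61.0)

    def test_peak_window_wraps_midnight(self):
        day = np.zeros(24, dtype=int)
        day[22:] = 600
        day[:2] = 600  # peak spans ZT22-02
        rec = make_record(np.tile(day, 2), bin_minutes=60)
        s = activity_summary(rec)
        assert s.peak4h_start_hour == 22
        assert s.peak4h_counts_per_min == pytest.approx(10.0)

    def test_all_zero_record_flags_undefined_change(self):
        rec = make_record(np.zeros(48, dtype=int), bin_minutes=60)
        with pytest.warns(UserWarning):
            s = activity_summary(rec)
        assert s.peak4h_counts_per_min == 0.0
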