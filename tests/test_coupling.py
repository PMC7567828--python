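"""Spike detection, bursts, rate curves and coupling analyses."""

import numpy as np
import pytest
from scipy import signal as sps

from spindletools.core import Interval, Signal
from spindletools.coupling import (Burst, SpikeTrain, UpState, central_peak,
                                   delta_power_during_spindles, detect_bursts,
                                   detect_spikes, detect_up_states,
                                   rate_curve, rate_modulation,
                                   spike_field_coupling,
                                   spindle_up_coincidence,
                                   sw_spindle_coupling)
from spindletools.filters import fir_bandpass

from conftest import tone


class TestSpikeDetection:
    def test_noise_only_empty(self):
        rng = np.random.default_rng(1)
        sig = Signal(5 * rng.standard_normal(200000), 20000.0)
        assert len(detect_spikes(sig)) == 0

    def test_flat_signal_warns(self):
        with pytest.warns(UserWarning, match="flat"):
            train = detect_spikes(Signal(np.zeros(200000), 20000.0))
        assert len(train) == 0

    def test_rate_floor(self):
        with pytest.raises(ValueError, match="rate"):
            detect_spikes(Signal(np.ones(1000), 1000.0))

    def test_injected_spikes_recovered_and_match_bruteforce(self):
        rate = 20000.0
        rng = np.random.default_rng(2)
        x = 5.0 * rng.standard_normal(int(10 * rate))
        # biphasic 1.5-ms spike templates well above the noise scale
        t = np.arange(int(0.0015 * rate)) / rate
        template = 60.0 * np.sin(2 * np.pi * 1500 * t) * np.hanning(t.size)
        truth = np.arange(0.25, 9.75, 0.19)
        center = t.size / 2 / rate
        for tt in truth:
            i = int(tt * rate)
            x[i:i + template.size] -= template
        train = detect_spikes(Signal(x, rate))
        hits = sum(np.min(np.abs(train.times - (tt + center))) <= 6e-4
                   for tt in truth)
        assert hits >= len(truth) - 1
        # brute-force oracle on the same filtered trace and threshold
        sos = sps.ellip(4, 0.1, 40.0, (600, 4000), btype="bandpass",
                        fs=rate, output="sos")
        xf = sps.sosfiltfilt(sos, x)
        thr = 7.5 * np.median(np.abs(xf))
        idx = np.flatnonzero(np.abs(xf) > thr)
        gap = int(0.001 * rate)
        n_groups = 0
        prev = None
        for i in idx:
            if prev is None or i - prev > gap:
                n_groups += 1
            prev = i
        assert len(train) == n_groups


def _bursts_oracle(times, max_isi=0.006, min_spikes=3, quiet=0.05):
    """Exhaustive window scan, independent of the implementation."""
    out = []
    n = len(times)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and times[j + 1] - times[j] < max_isi:
            j += 1
        if j - i + 1 >= min_spikes and (i == 0 or times[i] - times[i - 1] >= quiet):
            out.append((times[i], j - i + 1))
        i = j + 1
    return out


class TestBursts:
    def test_quiescence_rule(self):
        ok = SpikeTrain(np.array([0.900, 1.000, 1.004, 1.008]))
        bursts = detect_bursts(ok)
        assert len(bursts) == 1 and bursts[0] == Burst(1.000, 3)
        bad = SpikeTrain(np.array([0.970, 1.000, 1.004, 1.008]))
        assert detect_bursts(bad) == []

    def test_burst_requires_three_spikes(self):
        pair = SpikeTrain(np.array([1.000, 1.004]))
        assert detect_bursts(pair) == []
        with pytest.raises(ValueError):
            Burst(0.0, 2)

    def test_matches_bruteforce_on_random_trains(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            n = rng.integers(2, 40)
            isis = np.where(rng.random(n) < 0.5,
                            rng.uniform(0.001, 0.008, n),
                            rng.uniform(0.01, 0.3, n))
            times = np.cumsum(isis)
            got = [(b.start, b.n_spikes)
                   for b in detect_bursts(SpikeTrain(times))]
            assert got == _bursts_oracle(times)


class TestRateCurve:
    def test_empty_trials_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rate_curve([], -0.1, 0.1)

    def test_no_spikes_zero(self):
        t, r = rate_curve([np.array([])] * 3, -0.1, 0.1)
        assert np.allclose(r, 0.0)

    def test_single_spike_unit_mass(self):
        t, r = rate_curve([np.array([0.0])], -0.1, 0.1)
        step = t[1] - t[0]
        assert np.sum(r) * step == pytest.approx(1.0, rel=0.02)
        assert (r > 0).sum() <= 6  # ~10 ms of 2-ms steps

    def test_poisson_rate_recovered(self):
        rng = np.random.default_rng(6)
        trials = [np.sort(rng.uniform(-0.5, 0.5, rng.poisson(20)))
                  for _ in range(200)]
        _, r = rate_curve(trials, -0.4, 0.4)
        assert 18.0 <= r.mean() <= 22.0


class TestCentralPeak:
    def test_peak_at_midpoint(self):
        # cosine peaks at t = 1.5, the exact midpoint of [1, 2)
        x = np.cos(2 * np.pi * 11 * (np.arange(3000) / 1000.0 - 1.5))
        t = central_peak(Signal(x, 1000.0), Interval(1.0, 2.0))
        assert t == pytest.approx(1.5, abs=2e-3)

    def test_equidistant_tie_takes_earlier(self):
        x = np.zeros(3000)
        x[1400], x[1600] = 1.0, 1.0  # midpoint 1.5 equidistant
        t = central_peak(Signal(x, 1000.0), Interval(1.0, 2.0))
        assert t == pytest.approx(1.400, abs=1e-9)

    def test_no_peak_rejected(self):
        x = np.linspace(0, 1, 3000)  # monotone: no interior maximum
        with pytest.raises(ValueError, match="maximum"):
            central_peak(Signal(x, 1000.0), Interval(1.0, 2.0))

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(8)
        sig = fir_bandpass(Signal(rng.standard_normal(30000), 1000.0), (9, 16))
        for _ in range(25):
            a = rng.uniform(2.0, 26.0)
            iv = Interval(a, a + rng.uniform(0.5, 1.5))
            got = central_peak(sig, iv)
            i0 = sig.index_of(iv.start)
            seg = sig.segment(iv.start, iv.end)
            cand = [i for i in range(1, seg.size - 1)
                    if seg[i] > seg[i - 1] and seg[i] > seg[i + 1]]
            t_cand = np.array([(i0 + i) / 1000.0 for i in cand])
            best = t_cand[np.argmin(np.abs(t_cand - iv.midpoint))]
            assert got == pytest.approx(best, abs=2e-3)


def _locked_train(lfp, intervals, lag_ms=0.0, r0=150.0, depth=0.95, seed=1):
    """Poisson train whose intensity is affine in the spindle-filtered LFP."""
    filt = fir_bandpass(lfp, (9, 16))
    rng = np.random.default_rng(seed)
    sp = []
    for iv in intervals:
        a, b = iv.start - 0.4, iv.end + 0.4
        i0, i1 = int(a * lfp.rate), int(b * lfp.rate)
        A = np.abs(filt.samples[i0:i1]).max()
        lam_max = r0 * (1 + depth)
        cand = np.sort(rng.uniform(a, b, rng.poisson(lam_max * (b - a))))
        idx = np.clip(((cand - lag_ms / 1000.0) * lfp.rate).astype(int),
                      0, len(filt) - 1)
        lam = np.maximum(r0 * (1 + depth * filt.samples[idx] / A), 0)
        sp.append(cand[rng.uniform(0, lam_max, cand.size) < lam])
    return SpikeTrain(np.unique(np.concatenate(sp)))


class TestSpikeFieldCoupling:
    def test_locked_train_high_value_zero_lag(self, rec_dense):
        _, signals, gt = rec_dense
        lfp = signals["lfp"]
        res = spike_field_coupling(lfp, _locked_train(lfp, gt.spindle_intervals),
                                  gt.spindle_intervals)
        assert res.value >= 0.9
        assert abs(res.lag_ms) <= 2.0

    def test_injected_lag_recovered(self, rec_dense):
        _, signals, gt = rec_dense
        lfp = signals["lfp"]
        train = _locked_train(lfp, gt.spindle_intervals, lag_ms=10.0)
        res = spike_field_coupling(lfp, train, gt.spindle_intervals)
        assert res.lag_ms == pytest.approx(10.0, abs=2.0)

    def test_no_spindles_rejected(self, rec_dense):
        _, signals, _ = rec_dense
        with pytest.raises(ValueError):
            spike_field_coupling(signals["lfp"], SpikeTrain(np.array([1.0])),
                                 [])

    def test_amplitude_rescaling_invariance(self, rec_dense):
        _, signals, gt = rec_dense
        lfp = signals["lfp"]
        train = _locked_train(lfp, gt.spindle_intervals)
        r1 = spike_field_coupling(lfp, train, gt.spindle_intervals)
        r2 = spike_field_coupling(Signal(20 * lfp.samples, lfp.rate),
                                  train, gt.spindle_intervals)
        assert r2.value == pytest.approx(r1.value, abs=1e-6)
        assert r2.lag_ms == r1.lag_ms


class TestSwSpindleCoupling:
    def test_locked_spindles_couple(self):
        # a spindle on every SW positive half-wave, envelope matching it
        rate = 1000.0
        t = np.arange(int(120 * rate)) / rate
        rng = np.random.default_rng(3)
        x = 150.0 * np.sin(2 * np.pi * 1.0 * t) + 5 * rng.standard_normal(t.size)
        spindles = []
        for k in range(5, 115):
            n = int(0.5 * rate)
            u = np.arange(n) / n
            i0 = int(k * rate)
            x[i0:i0 + n] += 60.0 * np.sin(np.pi * u) * np.sin(
                2 * np.pi * 12 * u * 0.5)
            spindles.append(Interval(float(k), k + 0.5))
        res = sw_spindle_coupling(Signal(x, rate), spindles)
        assert res.value >= 0.7
        assert abs(res.lag_ms) <= 100

    def test_random_onsets_do_not_couple(self, rec_dense):
        # generator spindles are placed independently of the SW phase
        _, signals, gt = rec_dense
        res = sw_spindle_coupling(signals["lfp"], gt.spindle_intervals)
        assert res.n_events >= 30
        assert res.value <= 0.3

    def test_flat_delta_flagged(self):
        rate = 1000.0
        lfp = Signal(tone(12, 120.0, rate=rate, amp=50.0), rate)
        spindles = [Interval(5.0 + 2 * k, 5.8 + 2 * k) for k in range(40)]
        with pytest.raises(ValueError, match="degenerate|variance"):
            sw_spindle_coupling(lfp, spindles)


class TestUpStates:
    def test_pure_sine_half_waves(self):
        sig = Signal(tone(1.0, 10.0, amp=100.0), 1000.0)
        ups = detect_up_states(sig, already_filtered=True)
        assert len(ups) == 10
        for u in ups:
            assert u.interval.duration == pytest.approx(0.5, abs=0.01)
            # peak A exceeds mean |x| = 2A/pi
            assert u.peak_amplitude == pytest.approx(100.0, rel=0.01)

    def test_short_half_waves_excluded(self):
        # 3.33 Hz -> 150-ms half-waves, under the 200-ms floor
        sig = Signal(tone(10.0 / 3.0, 9.0, amp=100.0), 1000.0)
        assert detect_up_states(sig, already_filtered=True) == []

    def test_low_amplitude_half_waves_excluded(self):
        x = np.concatenate([tone(1.0, 5.0, amp=100.0),
                            tone(1.0, 5.0, amp=10.0)])
        ups = detect_up_states(Signal(x, 1000.0), already_filtered=True)
        assert len(ups) == 5
        assert all(u.peak_amplitude > 50 for u in ups)

    def test_strictly_negative_none(self):
        sig = Signal(-np.abs(tone(1.0, 5.0, amp=50.0)) - 1.0, 1000.0)
        assert detect_up_states(sig, already_filtered=True) == []

    def test_filter_applied_by_default(self):
        rng = np.random.default_rng(11)
        x = tone(1.0, 30.0, amp=100.0) + 5 * rng.standard_normal(30000)
        ups = detect_up_states(Signal(x, 1000.0))
        assert 25 <= len(ups) <= 30


class TestCoincidence:
    def test_fully_inside_counted(self):
        ups = [UpState(Interval(1.0, 3.0), 50.0)]
        assert spindle_up_coincidence([Interval(1.5, 2.5)], ups) == 1.0

    def test_forty_percent_not_counted(self):
        ups = [UpState(Interval(0.0, 1.4), 50.0)]
        assert spindle_up_coincidence([Interval(1.0, 2.0)], ups) == 0.0

    def test_empty_spindles_rejected(self):
        with pytest.raises(ValueError):
            spindle_up_coincidence([], [])

    def test_matches_interval_arithmetic_oracle(self):
        rng = np.random.default_rng(13)
        # integer centisecond grid keeps overlap fractions exact
        for _ in range(50):
            sp_cs, up_cs = [], []
            t = 0
            for _ in range(20):
                t += int(rng.integers(50, 300))
                d = int(rng.integers(40, 200))
                sp_cs.append((t, t + d))
                t += d
            t = 0
            for _ in range(30):
                t += int(rng.integers(20, 200))
                d = int(rng.integers(20, 150))
                up_cs.append((t, t + d))
                t += d
            spindles = [Interval(a / 100.0, b / 100.0) for a, b in sp_cs]
            ups = [UpState(Interval(a / 100.0, b / 100.0), 1.0)
                   for a, b in up_cs]
            got = spindle_up_coincidence(spindles, ups)
            grid = np.zeros(max(b for _, b in sp_cs + up_cs) + 1, dtype=bool)
            for a, b in up_cs:
                grid[a:b] = True
            n_co = sum(grid[a:b].sum() * 2 >= (b - a) for a, b in sp_cs)
            assert got == pytest.approx(n_co / len(spindles))


class TestDeltaPower:
    def test_sine_background_power(self):
        amp = 40.0
        sig = Signal(tone(2.0, 60.0, amp=amp), 1000.0)
        spindles = [Interval(10.0, 10.8), Interval(30.0, 30.8)]
        got = delta_power_during_spindles(sig, spindles)
        assert got == pytest.approx(amp ** 2 / 2, rel=0.05)

    def test_no_delta_near_zero(self):
        sig = Signal(tone(12.0, 60.0, amp=40.0), 1000.0)
        got = delta_power_during_spindles(sig, [Interval(10.0, 10.8)])
        assert got < 0.01 * 40 ** 2 / 2

    def test_quadratic_scaling(self):
        rng = np.random.default_rng(15)
        x = rng.standard_normal(60000)
        sig1 = Signal(x, 1000.0)
        sig2 = Signal(2 * x, 1000.0)
        spindles = [Interval(10.0, 10.8), Interval(40.0, 40.6)]
        p1 = delta_power_during_spindles(sig1, spindles)
        p2 = delta_power_during_spindles(sig2, spindles)
        assert p2 == pytest.approx(4 * p1, rel=1e-9)

    def test_out_of_bounds_event_dropped(self):
        sig = Signal(tone(2.0, 30.0, amp=10.0), 1000.0)
        with pytest.warns(UserWarning, match="bounds"):
            got = delta_power_during_spindles(
                sig, [Interval(0.5, 1.0), Interval(15.0, 15.8)])
        assert got == pytest.approx(10 ** 2 / 2, rel=0.05)


class TestRateModulation:
    def test_identical_statistics_ratio_near_one(self):
        rng = np.random.default_rng(17)
        times = np.sort(rng.uniform(0, 600, 3000))
        times = times[np.concatenate(([True], np.diff(times) > 1e-4))]
        on = [Interval(60 * k, 60 * k + 30) for k in range(10)]
        off = [Interval(60 * k + 30, 60 * (k + 1)) for k in range(10)]
        unit_ratio, _ = rate_modulation(SpikeTrain(times), on, off)
        assert 0.8 <= unit_ratio <= 1.25

    def test_burst_doubling_recovered(self):
        rng = np.random.default_rng(19)
        times = []
        t = 0.1
        while t < 600:
            in_on = (t % 60) < 30
            p_burst = 0.5 if in_on else 0.25
            if rng.random() < p_burst:
                times.extend([t, t + 0.003, t + 0.006])
            else:
                times.append(t)
            t += rng.uniform(0.15, 0.4)
        on = [Interval(60 * k, 60 * k + 30) for k in range(10)]
        off = [Interval(60 * k + 30, 60 * (k + 1)) for k in range(10)]
        _, burst_ratio = rate_modulation(SpikeTrain(np.array(times)), on, off)
        assert 1.6 <= burst_ratio <= 2.5

    def test_empty_train(self):
        assert rate_modulation(SpikeTrain(np.array([])),
                               [Interval(0, 10)], [Interval(10, 20)]) == (0.0, 0.0)

    def test_zero_baseline_flagged(self):
        train = SpikeTrain(np.array([1.0, 2.0, 3.0]))
        unit_ratio, burst_ratio = rate_modulation(
            train, [Interval(0, 5)], [Interval(10, 20)])
        assert unit_ratio is None

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            rate_modulation(SpikeTrain(np.array([1.0])), [], [Interval(0, 1)])
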