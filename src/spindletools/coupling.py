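"""Single-unit and coupling analyses.

Spike detection from wide-band traces (median-based threshold on the
600-4000 Hz elliptic-filtered signal), ISI-defined burst detection,
trial-averaged firing-rate curves, spike-field coupling during spindles,
slow-wave/spindle-envelope coupling, UP-state detection and the
spindle/UP-state coincidence ratio, delta power during spindles, and
firing-rate modulation between condition masks.

Coupling is quantified as the peak normalized cross-correlation between
two trial-averaged traces; positive lag means the second trace (unit
activity) follows the first (LFP).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import Interval, Signal
from .detect import SpindleEvent
from .filters import (Band, SPINDLE_BAND, SPINDLE_FIR_ORDER, SW_BAND,
                      SW_FIR_ORDER, bandpower, fir_bandpass, hilbert_envelope,
                      normalized_xcorr, scaled_fir_order)


@dataclass
class SpikeTrain:
    """Sorted spike times (s) of one unit."""

    times: np.ndarray
    unit_id: str = "unit0"
    source_channel: str = "ch0"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and (np.any(np.diff(self.times) <= 0)
                                or self.times[0] < 0):
            raise ValueError("spike times must be nonnegative and strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class Burst:
    """>= 3 spikes with all ISIs < 6 ms, preceded by >= 50 ms quiescence."""

    start: float
    n_spikes: int

    def __post_init__(self):
        if self.n_spikes < 3:
            raise ValueError("a burst holds at least three spikes")


@dataclass(frozen=True)
class CouplingResult:
    value: float
    lag_ms: float
    n_events: int

    def __post_init__(self):
        if abs(self.value) > 1 + 1e-9:
            raise ValueError("|coupling value| must be <= 1")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")


@dataclass(frozen=True)
class UpState:
    """Positive half-wave of the 0.5-4 Hz trace kept by the amplitude rules."""

    interval: Interval
    peak_amplitude: float


# ---------------------------------------------------------------------------
# spikes and bursts
# ---------------------------------------------------------------------------

def detect_spikes(wideband: Signal, band=(600.0, 4000.0),
                  threshold_factor: float = 7.5,
                  refractory_ms: float = 1.0,
                  unit_id: str = "mua") -> SpikeTrain:
    """Threshold crossings of the band-passed wide-band trace.

    Fourth-order elliptic band-pass (0.1 dB ripple, 40 dB stopband) applied
    zero-phase; the threshold is 7.5x the median of |filtered|.  Crossings of
    either polarity within one refractory window group into a single spike
    timed at the extremum of |filtered|.
    """
    if wideband.rate <= 2 * band[1]:
        raise ValueError("sampling rate too low for the 600-4000 Hz spike band")
    sos = sps.ellip(4, 0.1, 40.0, band, btype="bandpass", fs=wideband.rate,
                    output="sos")
    xf = sps.sosfiltfilt(sos, wideband.samples)
    thr = threshold_factor * float(np.median(np.abs(xf)))
    if thr == 0:
        warnings.warn("flat signal (median |x| = 0); no spikes detected",
                      stacklevel=2)
        return SpikeTrain(np.array([]), unit_id, wideband.label)
    above = np.flatnonzero(np.abs(xf) > thr)
    if above.size == 0:
        return SpikeTrain(np.array([]), unit_id, wideband.label)
    gap = max(1, int(round(refractory_ms / 1000.0 * wideband.rate)))
    splits = np.flatnonzero(np.diff(above) > gap)
    groups = np.split(above, splits + 1)
    times = []
    for g in groups:
        peak = g[np.argmax(np.abs(xf[g]))]
        times.append(wideband.t0 + peak / wideband.rate)
    times = np.array(times)
    # grouping guarantees increasing times; enforce strictness defensively
    keep = np.concatenate([[True], np.diff(times) > 0])
    return SpikeTrain(times[keep], unit_id, wideband.label)


def detect_bursts(train: SpikeTrain, max_isi_ms: float = 6.0,
                  min_spikes: int = 3, quiescence_ms: float = 50.0) -> list[Burst]:
    """Maximal ISI-defined spike runs qualifying as low-threshold bursts.

    A burst is a maximal run of spikes whose ISIs are all < ``max_isi_ms``,
    holding >= ``min_spikes`` spikes, whose first spike follows >=
    ``quiescence_ms`` of silence (or opens the train).
    """
    t = train.times
    if t.size < min_spikes:
        return []
    max_isi = max_isi_ms / 1000.0
    quiet = quiescence_ms / 1000.0
    isi_fast = np.diff(t) < max_isi
    bursts = []
    i = 0
    while i < t.size - 1:
        if not isi_fast[i]:
            i += 1
            continue
        j = i
        while j < isi_fast.size and isi_fast[j]:
            j += 1
        n = j - i + 1  # spikes i..j inclusive
        if n >= min_spikes and (i == 0 or t[i] - t[i - 1] >= quiet):
            bursts.append(Burst(float(t[i]), int(n)))
        i = j + 1
    return bursts


def rate_curve(trains_per_trial, t_start: float, t_end: float,
               window_ms: float = 10.0, overlap_ms: float = 8.0):
    """Trial-averaged firing rate with a sliding window.

    ``trains_per_trial`` is a list of per-trial spike-time arrays aligned to
    a common zero.  Windows of ``window_ms`` slide by ``window_ms -
    overlap_ms`` (2 ms by default); the returned times are window centers.

    Returns
    -------
    (times, mean_rate_hz)
    """
    trials = [np.asarray(tr, dtype=float) for tr in trains_per_trial]
    if not trials:
        raise ValueError("empty trial set")
    w = window_ms / 1000.0
    step = (window_ms - overlap_ms) / 1000.0
    if step <= 0:
        raise ValueError("overlap must be smaller than the window")
    centers = np.arange(t_start + w / 2, t_end - w / 2 + 1e-12, step)
    rates = np.zeros((len(trials), centers.size))
    for k, tr in enumerate(trials):
        if tr.size == 0:
            continue
        lo = np.searchsorted(tr, centers - w / 2, side="left")
        hi = np.searchsorted(tr, centers + w / 2, side="left")
        rates[k] = (hi - lo) / w
    return centers, rates.mean(axis=0)


# ---------------------------------------------------------------------------
# spike-field coupling
# ---------------------------------------------------------------------------

def central_peak(filtered_signal: Signal, event: Interval) -> float:
    """Time of the filtered-trace local maximum closest to the event center.

    An equidistant tie resolves to the earlier peak.
    """
    i0 = max(filtered_signal.index_of(event.start), 0)
    seg = filtered_signal.segment(event.start, event.end)
    peaks, _ = sps.find_peaks(seg)
    if peaks.size == 0:
        raise ValueError("no local maximum inside the event")
    t_peaks = filtered_signal.t0 + (i0 + peaks) / filtered_signal.rate
    dist = np.abs(t_peaks - event.midpoint)
    # stable argmin returns the first (earlier) peak on exact ties
    return float(t_peaks[int(np.argmin(dist))])


def _event_intervals(events) -> list[Interval]:
    return [e.interval if isinstance(e, SpindleEvent) else e for e in events]


def spike_field_coupling(lfp: Signal, train: SpikeTrain, spindles,
                         max_lag_ms: float = 100.0,
                         half_window_s: float = 0.25,
                         window_ms: float = 10.0,
                         overlap_ms: float = 8.0) -> CouplingResult:
    """Peak normalized cross-correlation between spindle-averaged LFP and rate.

    Per spindle, the 9-16 Hz filtered LFP and the unit's spikes are extracted
    in a +/- ``half_window_s`` frame around the spindle's central peak; the
    across-spindle average LFP (interpolated onto the rate-curve grid) is
    cross-correlated with the trial-averaged firing rate.  Positive lag means
    spikes follow the LFP.
    """
    intervals = _event_intervals(spindles)
    if not intervals:
        raise ValueError("no spindle events supplied")
    if len(intervals) < 10:
        warnings.warn("fewer than 10 spindles; coupling estimate is noisy",
                      stacklevel=2)
    filt = fir_bandpass(lfp, SPINDLE_BAND,
                        scaled_fir_order(SPINDLE_FIR_ORDER, lfp.rate))
    half_n = int(round(half_window_s * lfp.rate))
    segs, trials = [], []
    for iv in intervals:
        try:
            cp = central_peak(filt, iv)
        except ValueError:
            continue
        ic = filt.index_of(cp)
        if ic - half_n < 0 or ic + half_n + 1 > len(filt):
            continue
        segs.append(filt.samples[ic - half_n:ic + half_n + 1])
        rel = train.times - cp
        trials.append(rel[(rel >= -half_window_s) & (rel <= half_window_s)])
    if not segs:
        raise ValueError("no usable spindle windows")
    mean_lfp = np.mean(segs, axis=0)
    t_lfp = np.arange(-half_n, half_n + 1) / lfp.rate
    centers, mean_rate = rate_curve(trials, -half_window_s, half_window_s,
                                    window_ms, overlap_ms)
    if np.allclose(mean_rate.std(), 0):
        raise ValueError("zero-variance mean firing rate (no spikes in windows)")
    lfp_on_grid = np.interp(centers, t_lfp, mean_lfp)
    grid_rate = 1000.0 / (window_ms - overlap_ms)
    max_lag = int(round(max_lag_ms / 1000.0 * grid_rate))
    _, _, value, lag_ms = normalized_xcorr(lfp_on_grid, mean_rate, max_lag,
                                           rate=grid_rate)
    return CouplingResult(value, lag_ms, len(segs))


# ---------------------------------------------------------------------------
# slow-wave / spindle coupling
# ---------------------------------------------------------------------------

def sw_spindle_coupling(lfp: Signal, spindles, window=(-1.0, 2.0),
                        max_lag_ms: float = 500.0) -> CouplingResult:
    """Coupling between slow-wave activity and the spindle envelope.

    Per spindle, the 0.5-4 Hz filtered trace and the Hilbert envelope of the
    9-16 Hz trace are extracted on ``window`` around the spindle onset and
    averaged across spindles; the result is the peak normalized
    cross-correlation (|lag| <= ``max_lag_ms``) between the two averages.
    """
    intervals = _event_intervals(spindles)
    if not intervals:
        raise ValueError("no spindle events supplied")
    if len(intervals) < 10:
        warnings.warn("fewer than 10 spindles; coupling estimate is noisy",
                      stacklevel=2)
    sw = fir_bandpass(lfp, SW_BAND, scaled_fir_order(SW_FIR_ORDER, lfp.rate))
    env = hilbert_envelope(
        fir_bandpass(lfp, SPINDLE_BAND,
                     scaled_fir_order(SPINDLE_FIR_ORDER, lfp.rate)))
    n0 = int(round(window[0] * lfp.rate))
    n1 = int(round(window[1] * lfp.rate))
    sw_segs, env_segs = [], []
    for iv in intervals:
        i = lfp.index_of(iv.start)
        if i + n0 < 0 or i + n1 > len(lfp):
            continue
        sw_segs.append(sw.samples[i + n0:i + n1])
        env_segs.append(env.samples[i + n0:i + n1])
    if not sw_segs:
        raise ValueError("no usable spindle windows")
    mean_sw = np.mean(sw_segs, axis=0)
    mean_env = np.mean(env_segs, axis=0)
    floor = 1e-4 * float(lfp.samples.std())
    if mean_sw.std() <= floor or mean_env.std() <= floor:
        raise ValueError("degenerate averages (flat slow-wave or envelope)")
    max_lag = int(round(max_lag_ms / 1000.0 * lfp.rate))
    _, _, value, lag_ms = normalized_xcorr(mean_sw, mean_env, max_lag,
                                           rate=lfp.rate)
    return CouplingResult(value, lag_ms, len(sw_segs))


def detect_up_states(signal: Signal, band=SW_BAND, min_dur_s: float = 0.2,
                     already_filtered: bool = False) -> list[UpState]:
    """UP states as qualifying positive half-waves of the 0.5-4 Hz trace.

    Half-waves run from a negative-to-positive zero crossing to the next
    positive-to-negative one; those shorter than 200 ms or with peak
    amplitude below the global mean |filtered| are excluded.
    """
    if already_filtered:
        filt = signal
    else:
        filt = fir_bandpass(signal, band,
                            scaled_fir_order(SW_FIR_ORDER, signal.rate))
    x = filt.samples
    pos = x > 0
    rises = np.flatnonzero(~pos[:-1] & pos[1:]) + 1
    falls = np.flatnonzero(pos[:-1] & ~pos[1:]) + 1
    amp_floor = float(np.mean(np.abs(x)))
    out = []
    for r in rises:
        f = falls[np.searchsorted(falls, r)] if np.searchsorted(falls, r) < falls.size else None
        if f is None:
            continue
        dur = (f - r) / filt.rate
        peak = float(x[r:f].max())
        if dur >= min_dur_s and peak >= amp_floor:
            out.append(UpState(Interval(filt.t0 + r / filt.rate,
                                        filt.t0 + f / filt.rate), peak))
    return out


def spindle_up_coincidence(spindles, up_states: list[UpState]) -> float:
    """Fraction of spindles overlapping UP states by >= 50% of their duration."""
    intervals = _event_intervals(spindles)
    if not intervals:
        raise ValueError("empty spindle list")
    ups = sorted((u.interval for u in up_states), key=lambda iv: iv.start)
    n_co = 0
    for sp in intervals:
        ov = sum(sp.overlap(u) for u in ups)
        if ov >= 0.5 * sp.duration - 1e-9:  # tolerance for exact-tie floats
            n_co += 1
    return n_co / len(intervals)


def delta_power_during_spindles(signal: Signal, spindles, band=SW_BAND,
                                window_s: float = 4.0) -> float:
    """Mean 0.5-4 Hz power of 4-s Hann-windowed segments centered on spindles."""
    intervals = _event_intervals(spindles)
    if not intervals:
        raise ValueError("no spindle events supplied")
    half = window_s / 2.0
    powers = []
    for iv in intervals:
        mid = iv.midpoint
        if mid - half < signal.t0 or mid + half > signal.t0 + signal.duration:
            warnings.warn("spindle window exceeds recording bounds; event "
                          "dropped", stacklevel=2)
            continue
        seg = signal.segment(mid - half, mid + half)
        powers.append(bandpower(seg, signal.rate, band))
    if not powers:
        raise ValueError("no spindle windows inside the recording")
    return float(np.mean(powers))


def rate_modulation(train: SpikeTrain, on_intervals: list[Interval],
                    off_intervals: list[Interval]):
    """Spike- and burst-rate ratios between two condition masks.

    Returns ``(unit_ratio, burst_ratio)``: rate in the ON intervals divided
    by rate in the OFF (baseline) intervals, for single spikes and for burst
    events.  An undefined ratio (zero baseline rate) is returned as None;
    an empty train yields (0.0, 0.0).
    """
    on_dur = sum(iv.duration for iv in on_intervals)
    off_dur = sum(iv.duration for iv in off_intervals)
    if on_dur <= 0 or off_dur <= 0:
        raise ValueError("both interval sets need positive total duration")
    if len(train) == 0:
        return 0.0, 0.0

    def count_in(times, intervals):
        times = np.asarray(times, dtype=float)
        return sum(int(np.sum((times >= iv.start) & (times < iv.end)))
                   for iv in intervals)

    bursts = np.array([b.start for b in detect_bursts(train)])
    spike_on = count_in(train.times, on_intervals) / on_dur
    spike_off = count_in(train.times, off_intervals) / off_dur
    burst_on = count_in(bursts, on_intervals) / on_dur
    burst_off = count_in(bursts, off_intervals) / off_dur
    unit_ratio = spike_on / spike_off if spike_off > 0 else None
    burst_ratio = burst_on / burst_off if burst_off > 0 else None
    return unit_ratio, burst_ratio
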