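"""Wavelet-energy sleep-spindle detector and per-event features.

Pipeline: band-averaged wavelet energy (9-16 Hz, complex frequency B-spline)
-> 200-ms Hann smoothing -> dual threshold (candidate where energy exceeds
mean + 3 SD of the baseline, extended outward to the mean + 1 SD crossings)
-> duration filter (0.4-2 s) -> cycle-count filter (5-30 positive peaks of
the band-passed trace) -> band-specificity filter (spindle-band power must
dominate the 6-8.5 and 16.5-20 Hz flanks) -> feature extraction and
vigilance-state labeling.

Thresholds are data-relative (mean/SD of the smoothed energy over the
baseline samples), so detection is invariant to global amplitude rescaling.
When a hypnogram is supplied the baseline is restricted to NREM samples,
avoiding inflation of the SD by wake artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .core import Hypnogram, Interval, Signal, state_mask, NREM
from .filters import (Band, DEFAULT_WAVELET, SPINDLE_FIR_ORDER, WaveletSpec,
                      as_band, band_energy_series, bandpower, fir_bandpass,
                      scaled_fir_order)


@dataclass(frozen=True)
class DetectionConfig:
    band: Band = Band(9.0, 16.0)
    smooth_ms: float = 200.0
    hi_sd: float = 3.0
    lo_sd: float = 1.0
    min_dur_s: float = 0.4
    max_dur_s: float = 2.0
    min_cycles: int = 5
    max_cycles: int = 30
    flank_lo: Band = Band(6.0, 8.5)
    flank_hi: Band = Band(16.5, 20.0)
    wavelet: WaveletSpec = DEFAULT_WAVELET
    baseline_scope: str = "NREM"  # "NREM" (when a hypnogram is given) or "ALL"
    energy_step_hz: float = 0.5

    def __post_init__(self):
        if not self.hi_sd > self.lo_sd >= 0:
            raise ValueError("require hi_sd > lo_sd >= 0")
        if not self.min_dur_s < self.max_dur_s:
            raise ValueError("require min_dur_s < max_dur_s")
        if not self.min_cycles < self.max_cycles:
            raise ValueError("require min_cycles < max_cycles")
        if self.baseline_scope not in ("NREM", "ALL"):
            raise ValueError("baseline_scope must be 'NREM' or 'ALL'")


@dataclass(frozen=True)
class SpindleEvent:
    """A detected spindle with its features."""

    interval: Interval
    channel: str = "ch0"
    state: str | None = None
    central_freq: float = float("nan")
    n_cycles: int = 0
    p2p_amplitude: float = float("nan")
    symmetry: float = float("nan")
    energy_peak_t: float = float("nan")

    @property
    def duration(self) -> float:
        return self.interval.duration


def smooth_energy(energy: Signal, window_ms: float = 200.0) -> Signal:
    """Convolve with a unit-area Hann kernel (reflect-padded, same length)."""
    n = int(round(window_ms / 1000.0 * energy.rate))
    if n >= len(energy):
        raise ValueError("smoothing window longer than the series")
    if n < 2:
        return Signal(energy.samples.copy(), energy.rate, energy.label, energy.t0)
    kernel = sps.windows.hann(n, sym=True)
    kernel /= kernel.sum()
    xp = np.pad(energy.samples, n, mode="reflect")
    out = np.convolve(xp, kernel, mode="same")[n:n + len(energy)]
    return Signal(out, energy.rate, label=energy.label, t0=energy.t0)


def threshold_events(smoothed_energy: Signal, baseline_mask: np.ndarray | None,
                     hi_sd: float = 3.0, lo_sd: float = 1.0) -> list[Interval]:
    """Dual-threshold candidate extraction.

    Baseline mean/SD come from the masked samples only.  A candidate exists
    wherever energy exceeds mean + hi_sd*SD; each is extended outward to the
    surrounding crossings of mean + lo_sd*SD (overlapping extensions merge
    because extension stops at the same lo-threshold run).
    """
    x = smoothed_energy.samples
    if baseline_mask is None:
        baseline_mask = np.ones(x.size, dtype=bool)
    baseline = x[np.asarray(baseline_mask, bool)]
    if baseline.size == 0:
        raise ValueError("empty baseline")
    if baseline.size < 60 * smoothed_energy.rate:
        warnings.warn("baseline shorter than 60 s; threshold estimates may be "
                      "unstable", stacklevel=2)
    mu, sd = float(baseline.mean()), float(baseline.std())
    if sd == 0:
        warnings.warn("degenerate baseline (SD = 0); no events returned",
                      stacklevel=2)
        return []
    above_lo = x > mu + lo_sd * sd
    above_hi = x > mu + hi_sd * sd
    edges = np.flatnonzero(np.diff(above_lo.astype(np.int8)))
    starts = [0] if above_lo[0] else []
    starts += [int(e) + 1 for e in edges if not above_lo[e]]
    ends = [int(e) + 1 for e in edges if above_lo[e]]
    if above_lo[-1]:
        ends.append(x.size)
    rate, t0 = smoothed_energy.rate, smoothed_energy.t0
    out = []
    for i0, i1 in zip(starts, ends):
        if above_hi[i0:i1].any():
            out.append(Interval(t0 + i0 / rate, t0 + i1 / rate))
    return out


def count_cycles(filtered_signal: Signal, interval: Interval) -> int:
    """Number of positive local maxima of the band-passed trace in the event."""
    seg = filtered_signal.segment(interval.start, interval.end)
    if seg.size < 3:
        return 0
    peaks, _ = sps.find_peaks(seg)
    return int(np.sum(seg[peaks] > 0))


def band_specificity(signal: Signal, interval: Interval, band=Band(9, 16),
                     flank_lo=Band(6, 8.5), flank_hi=Band(16.5, 20)) -> bool:
    """True iff spindle-band power dominates both flanking bands."""
    seg = signal.segment(interval.start, interval.end)
    p = bandpower(seg, signal.rate, band)
    return p >= bandpower(seg, signal.rate, flank_lo) and \
        p >= bandpower(seg, signal.rate, flank_hi)


def central_frequency(signal: Signal, interval: Interval, band=Band(9, 16),
                      pad_factor: int = 8, resolution_hz: float = 0.15) -> float:
    """Peak of the zero-padded amplitude spectrum within the band (Hz)."""
    band = as_band(band)
    seg = signal.segment(interval.start, interval.end)
    seg = seg - seg.mean()
    nfft = max(pad_factor * seg.size, int(np.ceil(signal.rate / resolution_hz)))
    spec = np.abs(np.fft.rfft(seg * np.hanning(seg.size), n=nfft))
    f = np.fft.rfftfreq(nfft, 1.0 / signal.rate)
    sel = (f >= band.lo) & (f <= band.hi)
    return float(f[sel][np.argmax(spec[sel])])


def symmetry(smoothed_energy: Signal, interval: Interval) -> float:
    """Relative position of the energy peak within the event, in [0, 1].

    0.5 is a fully symmetric event; lower/higher values indicate a leftward/
    rightward-shifted energy peak.
    """
    i0 = max(smoothed_energy.index_of(interval.start), 0)
    seg = smoothed_energy.segment(interval.start, interval.end)
    if seg.size == 0:
        raise ValueError("interval outside the energy series")
    t_peak = smoothed_energy.t0 + (i0 + int(np.argmax(seg))) / smoothed_energy.rate
    return float((t_peak - interval.start) / interval.duration)


def assign_state(event_interval: Interval, hypnogram: Hypnogram) -> str:
    """Vigilance label with the largest temporal overlap; tie -> midpoint state."""
    if event_interval.start < 0 or event_interval.end > hypnogram.duration:
        raise ValueError("event outside hypnogram span")
    eps = hypnogram.epoch_s
    k0 = int(np.floor(event_interval.start / eps))
    k1 = int(np.ceil(event_interval.end / eps))
    overlaps: dict[str, float] = {}
    for k in range(k0, k1):
        epoch = Interval(k * eps, (k + 1) * eps)
        ov = epoch.overlap(event_interval)
        if ov > 0:
            lbl = hypnogram.labels[k]
            overlaps[lbl] = overlaps.get(lbl, 0.0) + ov
    best = max(overlaps.values())
    winners = [s for s, v in overlaps.items() if v >= best - 1e-12]
    if len(winners) > 1:
        return hypnogram.state_at(event_interval.midpoint)
    return winners[0]


def detect_spindles(signal: Signal, config: DetectionConfig | None = None,
                    hypnogram: Hypnogram | None = None,
                    return_intermediates: bool = False):
    """Detect sleep spindles on one channel.

    Returns a sorted, non-overlapping list of :class:`SpindleEvent`.  With
    ``return_intermediates=True`` also returns a dict holding the smoothed
    energy, the band-passed trace and the baseline statistics.
    """
    cfg = config or DetectionConfig()
    if signal.rate < 100:
        raise ValueError("sampling rate must be >= 100 Hz for spindle detection")
    energy = band_energy_series(signal, cfg.wavelet, cfg.band, cfg.energy_step_hz)
    smoothed = smooth_energy(energy, cfg.smooth_ms)
    scale = max(1.0, float(np.abs(signal.samples).max())) ** 2
    if smoothed.samples.max() <= 1e-12 * scale:
        warnings.warn("degenerate signal (no band energy); no events returned",
                      stacklevel=2)
        return ([], {"energy": energy, "smoothed": smoothed}) \
            if return_intermediates else []

    baseline_mask = None
    if hypnogram is not None and cfg.baseline_scope == "NREM":
        baseline_mask = state_mask(hypnogram, NREM, signal.rate, len(signal))
        if not baseline_mask.any():
            baseline_mask = None  # no NREM scored: fall back to the whole trace
    candidates = threshold_events(smoothed, baseline_mask, cfg.hi_sd, cfg.lo_sd)

    candidates = [c for c in candidates if cfg.min_dur_s <= c.duration <= cfg.max_dur_s]

    order = scaled_fir_order(SPINDLE_FIR_ORDER, signal.rate)
    filtered = fir_bandpass(signal, cfg.band, order)

    events = []
    for c in candidates:
        ncyc = count_cycles(filtered, c)
        if not cfg.min_cycles <= ncyc <= cfg.max_cycles:
            continue
        if not band_specificity(signal, c, cfg.band, cfg.flank_lo, cfg.flank_hi):
            continue
        seg = filtered.segment(c.start, c.end)
        i0 = max(smoothed.index_of(c.start), 0)
        eseg = smoothed.segment(c.start, c.end)
        peak_t = smoothed.t0 + (i0 + int(np.argmax(eseg))) / smoothed.rate
        state = None
        if hypnogram is not None and c.end <= hypnogram.duration and c.start >= 0:
            state = assign_state(c, hypnogram)
        events.append(SpindleEvent(
            interval=c,
            channel=signal.label,
            state=state,
            central_freq=central_frequency(signal, c, cfg.band),
            n_cycles=ncyc,
            p2p_amplitude=float(seg.max() - seg.min()),
            symmetry=symmetry(smoothed, c),
            energy_peak_t=peak_t,
        ))
    if return_intermediates:
        extras = {"energy": energy, "smoothed": smoothed, "filtered": filtered,
                  "baseline_mask": baseline_mask}
        return events, extras
    return events
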