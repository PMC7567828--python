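"""Shared DSP kernels.

Zero-phase FIR band-pass filtering, Hilbert envelopes, Welch spectra,
Hann-periodogram band power, continuous wavelet transforms over the
family set used for wavelet screening, band-averaged wavelet energy, and
normalized cross-correlation.

FIR orders follow the convention of being *defined at 1000 Hz* (the LFP
rate the defaults were designed for: 6000 taps for the 0.5-4 Hz slow-wave
band, 333 for the 9-16 Hz spindle band) and are scaled proportionally for
other sampling rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps

from .core import Signal

#: FIR orders at the 1000 Hz reference rate.
SPINDLE_FIR_ORDER = 333
SW_FIR_ORDER = 6000

SPINDLE_BAND = (9.0, 16.0)
SW_BAND = (0.5, 4.0)


@dataclass(frozen=True)
class Band:
    """Frequency band (lo, hi) in Hz, 0 < lo < hi."""

    lo: float
    hi: float

    def __post_init__(self):
        if not 0 < self.lo < self.hi:
            raise ValueError(f"invalid band ({self.lo}, {self.hi})")


def as_band(band) -> Band:
    return band if isinstance(band, Band) else Band(*band)


@dataclass(frozen=True)
class WaveletSpec:
    """A continuous wavelet and its free parameters.

    ``family`` is a pywavelets continuous-wavelet base name ("fbsp", "cmor",
    "shan", "morl", "mexh", "cgau1".."cgau8", "gaus1".."gaus8").  ``order_m``
    applies only to the frequency B-spline family; ``bandwidth_fb`` and
    ``center_fc`` apply to the parameterized complex families (fbsp, cmor,
    shan) and are ignored by the fixed families.
    """

    family: str = "fbsp"
    order_m: int = 2
    bandwidth_fb: float = 1.0
    center_fc: float = 1.0

    def __post_init__(self):
        if self.order_m < 1:
            raise ValueError("order_m must be >= 1")
        if self.bandwidth_fb <= 0 or self.center_fc <= 0:
            raise ValueError("bandwidth_fb and center_fc must be > 0")

    @property
    def pywt_name(self) -> str:
        fam = self.family.lower()
        if fam == "fbsp":
            return f"fbsp{self.order_m}-{self.bandwidth_fb:g}-{self.center_fc:g}"
        if fam in ("cmor", "shan"):
            return f"{fam}{self.bandwidth_fb:g}-{self.center_fc:g}"
        return fam

    def to_pywt(self) -> pywt.ContinuousWavelet:
        try:
            return pywt.ContinuousWavelet(self.pywt_name)
        except ValueError as exc:
            raise ValueError(f"unsupported wavelet family {self.family!r}") from exc


#: Complex frequency B-spline with the package defaults (order 2, fb=fc=1).
DEFAULT_WAVELET = WaveletSpec("fbsp", 2, 1.0, 1.0)
#: Complex Morlet used for time-frequency representations.
MORLET_WAVELET = WaveletSpec("cmor", 1, 1.0, 1.0)


def _as_wavelet(wavelet) -> pywt.ContinuousWavelet:
    if isinstance(wavelet, WaveletSpec):
        return wavelet.to_pywt()
    if isinstance(wavelet, str):
        return pywt.ContinuousWavelet(wavelet)
    return wavelet


def wavelet_center_frequency(wavelet) -> float:
    """Normalized center frequency of a wavelet (cycles per unit scale)."""
    w = _as_wavelet(wavelet)
    fc = getattr(w, "center_frequency", None)
    if not fc:  # families without an analytic value (morl, mexh, gaus, cgau)
        fc = pywt.central_frequency(w, precision=10)
    return float(fc)


def scaled_fir_order(reference_order: int, rate: float) -> int:
    """Scale a 1000-Hz-referenced FIR order to ``rate``."""
    return max(2, int(round(reference_order * rate / 1000.0)))


def _zero_phase_fir(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply an FIR filter forward and reverse with reflect padding.

    FFT convolution keeps the 6000-tap slow-wave filter tractable on
    hour-long traces; forward+reverse application squares the magnitude
    response and cancels the phase.
    """
    pad = min(len(x) - 1, 3 * len(taps))
    xp = np.pad(x, pad, mode="reflect")
    y = sps.fftconvolve(xp, taps, mode="same")
    y = sps.fftconvolve(y[::-1], taps, mode="same")[::-1]
    return y[pad:len(xp) - pad]


def fir_bandpass(signal: Signal, band, order: int | None = None) -> Signal:
    """Zero-phase window-based FIR band-pass.

    ``order`` is the number of taps minus one at the signal's own rate; by
    default the 333-tap spindle-band order (at 1000 Hz) is scaled to the
    signal rate.  The signal must be longer than 3x the order.
    """
    band = as_band(band)
    if order is None:
        order = scaled_fir_order(SPINDLE_FIR_ORDER, signal.rate)
    if order >= len(signal) / 3:
        raise ValueError(f"FIR order {order} too large for {len(signal)}-sample signal")
    if band.hi >= signal.rate / 2:
        raise ValueError("band exceeds Nyquist frequency")
    taps = sps.firwin(order + 1, [band.lo, band.hi], pass_zero=False, fs=signal.rate)
    return Signal(_zero_phase_fir(signal.samples, taps), signal.rate,
                  label=signal.label, t0=signal.t0)


def hilbert_envelope(signal: Signal) -> Signal:
    """Instantaneous amplitude via the analytic signal."""
    env = np.abs(sps.hilbert(signal.samples))
    return Signal(env, signal.rate, label=f"{signal.label}|env", t0=signal.t0)


def welch_psd(signal: Signal, window_s: float = 8.0, overlap: float = 0.75):
    """Welch power spectral density, 8-s Hann segments with 75% overlap.

    Returns
    -------
    (frequencies, psd) : one-sided grid in Hz, density in uV^2/Hz.
    """
    nperseg = int(round(window_s * signal.rate))
    if len(signal) < nperseg:
        raise ValueError(f"signal shorter than one {window_s}-s Welch segment")
    return sps.welch(signal.samples, fs=signal.rate, window="hann",
                     nperseg=nperseg, noverlap=int(overlap * nperseg))


def bandpower(segment: np.ndarray, rate: float, band) -> float:
    """Band power (uV^2) from a Hann-windowed modified periodogram."""
    band = as_band(band)
    if band.hi >= rate / 2:
        raise ValueError("band exceeds Nyquist frequency")
    segment = np.asarray(segment, dtype=float)
    f, pxx = sps.periodogram(segment, fs=rate, window="hann")
    sel = (f >= band.lo) & (f <= band.hi)
    df = f[1] - f[0]
    return float(np.sum(pxx[sel]) * df)


def _scales_for(wavelet, frequencies: np.ndarray, rate: float) -> np.ndarray:
    return wavelet_center_frequency(wavelet) * rate / np.asarray(frequencies, float)


def _support_samples(wavelet, scale: float) -> int:
    w = _as_wavelet(wavelet)
    width = float(w.upper_bound - w.lower_bound)
    return int(np.ceil(scale * width))


def cwt(signal: Signal, wavelet, frequencies) -> tuple[np.ndarray, np.ndarray]:
    """Continuous wavelet transform on a frequency grid.

    Returns the complex coefficient matrix (one row per requested frequency)
    and the realized frequency grid.  The signal is mirror-padded by the
    largest wavelet support before transforming so that |coefficient|^2 is an
    edge-safe wavelet energy.
    """
    frequencies = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if np.any(frequencies <= 0) or np.any(frequencies >= signal.rate / 2):
        raise ValueError("frequencies must lie in (0, rate/2)")
    w = _as_wavelet(wavelet)
    scales = _scales_for(w, frequencies, signal.rate)
    pad = min(len(signal) - 1, _support_samples(w, scales.max()))
    xp = np.pad(signal.samples, pad, mode="reflect")
    coefs, freqs = pywt.cwt(xp, scales, w, sampling_period=1.0 / signal.rate,
                            method="fft")
    coefs = coefs[:, pad:pad + len(signal)]
    return coefs, freqs


def band_energy_series(signal: Signal, wavelet=DEFAULT_WAVELET,
                       band=SPINDLE_BAND, step_hz: float = 0.5) -> Signal:
    """Mean wavelet energy across a band, per time sample.

    Energy is |CWT coefficient|^2 averaged over a ``step_hz``-spaced grid
    spanning the band (inclusive).  Scales are transformed one at a time to
    bound memory on hour-long recordings.
    """
    band = as_band(band)
    freqs = np.arange(band.lo, band.hi + step_hz / 2, step_hz)
    w = _as_wavelet(wavelet)
    scales = _scales_for(w, freqs, signal.rate)
    pad = min(len(signal) - 1, _support_samples(w, scales.max()))
    xp = np.pad(signal.samples, pad, mode="reflect")
    acc = np.zeros(len(signal))
    for s in scales:
        coef, _ = pywt.cwt(xp, [s], w, method="fft")
        acc += np.abs(coef[0, pad:pad + len(signal)]) ** 2
    acc /= len(scales)
    return Signal(acc, signal.rate, label=f"{signal.label}|energy", t0=signal.t0)


def normalized_xcorr(a: np.ndarray, b: np.ndarray, max_lag: int,
                     rate: float | None = None):
    """Normalized cross-correlation and its peak.

    r(lag) = sum (a - mean a)(b - mean b, shifted) / sqrt(ss_a * ss_b), so
    r in [-1, 1] and the peak is invariant to affine rescaling of either
    input.  Positive lag means ``b`` lags (follows) ``a``.

    Returns
    -------
    (lags, r, peak_value, peak_lag) : lags in samples (or ms when ``rate``
    is given, in which case peak_lag is in ms too).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("inputs must share one sampling grid")
    if max_lag >= len(a) / 2:
        raise ValueError("max_lag must be below half the series length")
    da, db = a - a.mean(), b - b.mean()
    denom = np.sqrt(np.sum(da ** 2) * np.sum(db ** 2))
    if denom == 0:
        raise ValueError("zero-variance input")
    full = sps.correlate(db, da, mode="full") / denom
    lags = sps.correlation_lags(len(b), len(a), mode="full")
    sel = np.abs(lags) <= max_lag
    lags, r = lags[sel], full[sel]
    k = int(np.argmax(r))
    peak_value, peak_lag = float(r[k]), float(lags[k])
    if rate is not None:
        lags = lags * 1000.0 / rate
        peak_lag = peak_lag * 1000.0 / rate
    return lags, r, peak_value, peak_lag


def tfr(signal: Signal, freq_grid, wavelet=MORLET_WAVELET) -> np.ndarray:
    """Time-frequency energy map (|CWT|^2) with the complex Morlet wavelet."""
    coefs, _ = cwt(signal, wavelet, freq_grid)
    return np.abs(coefs) ** 2
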