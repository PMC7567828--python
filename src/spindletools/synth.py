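"""Synthetic polysomnography with ground truth.

Generates state-structured recordings (Wake/NREM/REM bouts from a
semi-Markov chain), an LFP composed of 1/f background noise, NREM slow
waves, waxing-waning spindles and wake/REM theta, a state-scaled EMG, and
spike trains phase-locked to spindle cycles with controllable coupling
strength and lag.  Every generated event is returned as ground truth, so
detector sensitivity/FDR and all rate statistics can be validated without
external data.

Spindle amplitude is expressed as an SNR: the peak of the spindle envelope
divided by the SD of the 9-16 Hz component of the spindle-free NREM
background.  All draws come from one counter-based (Philox) stream keyed by
``seed``, so output is reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import (Episode, Hypnogram, Interval, NREM, REM, Signal, WAKE,
                   extract_episodes)
from .coupling import SpikeTrain, UpState, detect_up_states
from .filters import (SPINDLE_BAND, SPINDLE_FIR_ORDER, SW_BAND, SW_FIR_ORDER,
                      fir_bandpass, scaled_fir_order)


@dataclass
class SynthConfig:
    seed: int = 0
    duration_min: float = 10.0
    rate: float = 1000.0

    # semi-Markov bout model (exponential durations with floors, seconds)
    wake_mean_s: float = 80.0
    nrem_mean_s: float = 120.0
    rem_mean_s: float = 60.0
    wake_min_s: float = 10.0
    nrem_min_s: float = 30.0
    rem_min_s: float = 10.0
    p_nrem_to_rem: float = 0.5
    p_rem_to_wake: float = 0.8

    # background and state rhythms (amplitudes are target SDs, uV)
    noise_scale_uv: float = 30.0
    noise_exponent: float = 1.0
    sw_amp_uv: float = 100.0
    theta_band: tuple = (6.0, 10.0)
    theta_amp_uv: float = 40.0
    emg_wake_uv: float = 30.0
    emg_nrem_uv: float = 5.0
    emg_rem_uv: float = 2.0

    # spindles
    spindle_rate_per_min: float = 3.0
    spindle_freq: tuple = (9.0, 16.0)
    spindle_freq_mode: float = 12.5  # mode/SD of the truncated-normal draw
    spindle_freq_sd: float = 1.5
    spindle_dur: tuple = (0.4, 1.5)
    spindle_dur_mode: float = 0.85
    spindle_dur_sd: float = 0.3
    spindle_snr: float = 8.0
    spindle_peak_pos: tuple = (0.3, 0.7)
    spindle_gap_s: float = 1.0
    pre_rem_boost: float = 3.0
    pre_rem_window_s: float = 25.0
    sw_lock_spindles: bool = False

    # spikes
    spike_rate_hz: float = 5.0
    spike_kappa: float = 0.6
    spike_lag_ms: float = 0.0
    burst_p: float = 0.2

    def __post_init__(self):
        if not 0 <= self.spike_kappa <= 1:
            raise ValueError("spike coupling kappa must lie in [0, 1]")
        for name in ("duration_min", "rate", "spindle_rate_per_min",
                     "wake_mean_s", "nrem_mean_s", "rem_mean_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.spindle_dur[0] <= 0 or self.spindle_dur[1] < self.spindle_dur[0]:
            raise ValueError("invalid spindle duration range")
        busy = (self.spindle_rate_per_min * max(self.pre_rem_boost, 1.0) / 60.0
                * (self.spindle_dur[1] + self.spindle_gap_s))
        if busy > 0.8:
            raise ValueError("requested spindle rate exceeds NREM capacity")


@dataclass
class GroundTruth:
    hypnogram: Hypnogram
    spindle_intervals: list = field(default_factory=list)
    spindle_params: list = field(default_factory=list)  # dicts per event
    up_states: list = field(default_factory=list)
    spike_times: np.ndarray = field(default_factory=lambda: np.array([]))
    burst_times: np.ndarray = field(default_factory=lambda: np.array([]))


def _rng(seed: int, stream: int = 0) -> np.random.Generator:
    bg = np.random.Philox(seed)
    return np.random.Generator(bg.jumped(stream) if stream else bg)


def _trunc_normal(rng, mode, sd, lo, hi) -> float:
    """Normal draw truncated to [lo, hi] by rejection.

    Spindle carrier frequencies and durations are unimodal in real data,
    tapering toward the range edges rather than sitting on them.
    """
    for _ in range(64):
        x = rng.normal(mode, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(rng.normal(mode, sd), lo, hi))


def _draw_bout(rng, mean_s, min_s) -> float:
    return min_s + rng.exponential(max(mean_s - min_s, 1e-9))


def _hypnogram(rng, cfg: SynthConfig) -> Hypnogram:
    n_epochs = int(round(cfg.duration_min * 60))
    labels: list[str] = []
    state = WAKE
    while len(labels) < n_epochs:
        if state == WAKE:
            dur, nxt = _draw_bout(rng, cfg.wake_mean_s, cfg.wake_min_s), NREM
        elif state == NREM:
            dur = _draw_bout(rng, cfg.nrem_mean_s, cfg.nrem_min_s)
            nxt = REM if rng.random() < cfg.p_nrem_to_rem else WAKE
        else:  # REM is entered only from NREM
            dur = _draw_bout(rng, cfg.rem_mean_s, cfg.rem_min_s)
            nxt = WAKE if rng.random() < cfg.p_rem_to_wake else NREM
        labels.extend([state] * max(1, int(round(dur))))
        state = nxt
    return Hypnogram(np.array(labels[:n_epochs], dtype=object), epoch_s=1.0)


def generate_hypnogram(config: SynthConfig) -> Hypnogram:
    """Semi-Markov Wake/NREM/REM bout sequence at 1-s epochs."""
    return _hypnogram(_rng(config.seed), config)


def _one_over_f(rng, n: int, exponent: float, sd: float) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    return x / x.std() * sd


def _band_noise(rng, n: int, rate: float, band, order: int, sd: float) -> np.ndarray:
    white = Signal(rng.standard_normal(n), rate)
    x = fir_bandpass(white, band, scaled_fir_order(order, rate)).samples
    return x / x.std() * sd


def _smooth_mask(mask: np.ndarray, rate: float, ramp_s: float = 0.5) -> np.ndarray:
    n = max(2, int(round(ramp_s * rate)))
    k = sps.windows.hann(n)
    k /= k.sum()
    return np.convolve(mask.astype(float), k, mode="same")


def _spindle_waveform(rng, cfg, rate, dur, freq, peak_pos, amp,
                      ramp_frac: float = 0.25):
    """Waxing-waning spindle burst.

    The envelope is a quarter-sine rise and fall (each ``ramp_frac`` of the
    duration) around a gently tented sustained middle whose apex sits at
    ``peak_pos``, so the oscillation is visible over most of the nominal
    duration (as in real spindles) and the energy peak position encodes the
    event's asymmetry.
    """
    n = int(round(dur * rate))
    u = np.arange(n) / max(n - 1, 1)
    r = ramp_frac
    ramps = (np.sin(np.pi / 2 * np.minimum(u / r, 1.0))
             * np.sin(np.pi / 2 * np.minimum((1 - u) / r, 1.0)))
    p = float(np.clip(peak_pos, r + 0.05, 1 - r - 0.05))
    half_span = max(p - r, 1 - r - p)
    tent = 1.0 - 0.15 * np.abs(u - p) / half_span
    env = ramps * tent
    phase = rng.uniform(0, 2 * np.pi)
    return amp * env * np.sin(2 * np.pi * freq * u * dur + phase), phase


def _place_spindles(rng, cfg: SynthConfig, episodes: list[Episode]):
    """Inhomogeneous-Poisson spindle onsets inside NREM episodes.

    The intensity is the base rate, multiplied by ``pre_rem_boost`` inside
    the final ``pre_rem_window_s`` of episodes that transition to REM.
    Events are kept non-overlapping (>= ``spindle_gap_s`` apart) and fully
    inside their episode.
    """
    lam0 = cfg.spindle_rate_per_min / 60.0
    lam_max = lam0 * max(cfg.pre_rem_boost, 1.0)
    placements = []
    for ep in episodes:
        if ep.state != NREM:
            continue
        boost_from = (ep.interval.end - cfg.pre_rem_window_s
                      if ep.successor == REM else np.inf)
        t = ep.interval.start + 0.1
        last_end = -np.inf
        while True:
            t += rng.exponential(1.0 / lam_max)
            if t >= ep.interval.end:
                break
            lam = lam0 * (cfg.pre_rem_boost if t >= boost_from else 1.0)
            if rng.random() > lam / lam_max:
                continue
            freq = _trunc_normal(rng, cfg.spindle_freq_mode, cfg.spindle_freq_sd,
                                 *cfg.spindle_freq)
            # a spindle has >= 5 oscillation cycles by definition; keep the
            # drawn duration above that floor for the drawn carrier frequency
            dur_lo = max(cfg.spindle_dur[0], 5.5 / freq)
            dur = _trunc_normal(rng, cfg.spindle_dur_mode, cfg.spindle_dur_sd,
                                dur_lo, cfg.spindle_dur[1])
            if t < last_end + cfg.spindle_gap_s or t + dur > ep.interval.end - 0.1:
                continue
            placements.append((t, dur, freq))
            last_end = t + dur
    return placements


def generate_events(config: SynthConfig,
                    hypnogram: Hypnogram | None = None):
    """Spindle placements only, without rendering signals.

    Draws the hypnogram (unless given) and the ground-truth spindle
    placements from the same process as :func:`generate_recording`, which is
    much cheaper for long-duration rate statistics (hours of simulated
    state structure).

    Returns
    -------
    (hypnogram, intervals, params) : params is a list of per-event dicts.
    """
    rng = _rng(config.seed)
    hyp = _hypnogram(rng, config) if hypnogram is None else hypnogram
    placements = _place_spindles(rng, config, extract_episodes(hyp))
    intervals = [Interval(t, t + d) for t, d, _ in placements]
    params = [{"start_s": t, "dur_s": d, "freq_hz": f}
              for t, d, f in placements]
    return hyp, intervals, params


def generate_recording(config: SynthConfig,
                       hypnogram: Hypnogram | None = None):
    """Generate LFP and EMG channels plus ground truth.

    Returns
    -------
    (signals, ground_truth) : ``signals`` is ``{"lfp": Signal, "emg": Signal}``.
    """
    cfg = config
    rng = _rng(cfg.seed)
    hyp = _hypnogram(rng, cfg) if hypnogram is None else hypnogram
    rate = cfg.rate
    n = int(round(hyp.duration * rate))
    spe = int(round(rate * hyp.epoch_s))
    per_sample_state = np.repeat(hyp.labels, spe)[:n]

    lfp = _one_over_f(rng, n, cfg.noise_exponent, cfg.noise_scale_uv)
    nrem_mask = per_sample_state == NREM

    sw = np.zeros(n)
    if nrem_mask.any() and cfg.sw_amp_uv > 0:
        sw = _band_noise(rng, n, rate, SW_BAND, SW_FIR_ORDER, cfg.sw_amp_uv)
        sw *= _smooth_mask(nrem_mask, rate)
    lfp = lfp + sw

    theta_mask = (per_sample_state == WAKE) | (per_sample_state == REM)
    if theta_mask.any() and cfg.theta_amp_uv > 0:
        theta = _band_noise(rng, n, rate, cfg.theta_band, SPINDLE_FIR_ORDER,
                            cfg.theta_amp_uv)
        lfp = lfp + theta * _smooth_mask(theta_mask, rate)

    gt = GroundTruth(hypnogram=hyp)
    episodes = extract_episodes(hyp)

    if nrem_mask.any() and cfg.spindle_snr > 0:
        bg_sigma_band = fir_bandpass(
            Signal(lfp, rate), SPINDLE_BAND,
            scaled_fir_order(SPINDLE_FIR_ORDER, rate)).samples
        sigma = float(bg_sigma_band[nrem_mask].std())
        placements = _place_spindles(rng, cfg, episodes)
        if cfg.sw_lock_spindles and sw.any():
            placements = [(_snap_to_sw_rise(sw, rate, t), d, f)
                          for t, d, f in placements]
        for t0, dur, freq in placements:
            peak_pos = rng.uniform(*cfg.spindle_peak_pos)
            amp = cfg.spindle_snr * sigma * rng.uniform(0.85, 1.15)
            wave, phase = _spindle_waveform(rng, cfg, rate, dur, freq,
                                            peak_pos, amp)
            i0 = int(round(t0 * rate))
            lfp[i0:i0 + wave.size] += wave[:max(0, n - i0)]
            gt.spindle_intervals.append(Interval(t0, t0 + dur))
            gt.spindle_params.append({
                "start_s": t0, "dur_s": dur, "freq_hz": freq,
                "peak_pos": peak_pos, "amp_uv": amp, "phase": phase})

    if sw.any():
        gt.up_states = detect_up_states(Signal(sw, rate, label="sw"),
                                        already_filtered=True)

    emg_scale = np.select(
        [per_sample_state == WAKE, per_sample_state == NREM],
        [cfg.emg_wake_uv, cfg.emg_nrem_uv], default=cfg.emg_rem_uv)
    emg = rng.standard_normal(n) * emg_scale

    signals = {"lfp": Signal(lfp, rate, label="lfp"),
               "emg": Signal(emg, rate, label="emg")}
    return signals, gt


def _snap_to_sw_rise(sw: np.ndarray, rate: float, t: float) -> float:
    """Move an onset to the nearest negative-to-positive SW zero crossing."""
    pos = sw > 0
    rises = np.flatnonzero(~pos[:-1] & pos[1:]) + 1
    if rises.size == 0:
        return t
    i = int(round(t * rate))
    return float(rises[np.argmin(np.abs(rises - i))] / rate)


def generate_spikes(lfp: Signal, ground_truth: GroundTruth,
                    config: SynthConfig, unit_id: str = "synth0") -> SpikeTrain:
    """Spindle-phase-locked spike train by Poisson thinning.

    The intensity is the baseline rate everywhere, scaled inside each
    ground-truth spindle by ``1 + kappa * relu(sin(theta(t - lag)))`` where
    ``theta`` is the spindle's carrier phase (so the modulation peaks at the
    LFP cycle peak, shifted by ``spike_lag_ms``).  Accepted spikes are
    replaced by short (3-5 spike, < 6 ms ISI) bursts with probability
    ``burst_p``.
    """
    cfg = config
    rng = _rng(cfg.seed, stream=1)
    T = lfp.duration
    lam0 = cfg.spike_rate_hz
    kappa = cfg.spike_kappa
    lam_max = lam0 * (1 + kappa)
    n_cand = rng.poisson(lam_max * T)
    cand = np.sort(rng.uniform(0, T, n_cand))

    starts = np.array([iv.start for iv in ground_truth.spindle_intervals])
    ends = np.array([iv.end for iv in ground_truth.spindle_intervals])
    lam = np.full(cand.size, lam0)
    if starts.size and kappa > 0:
        idx = np.searchsorted(starts, cand, side="right") - 1
        inside = (idx >= 0) & (cand < ends[np.clip(idx, 0, None)])
        lag = cfg.spike_lag_ms / 1000.0
        for k in np.flatnonzero(inside):
            p = ground_truth.spindle_params[idx[k]]
            theta = (2 * np.pi * p["freq_hz"] * (cand[k] - lag - p["start_s"])
                     + p["phase"])
            lam[k] = lam0 * (1 + kappa * max(0.0, np.sin(theta)))
    accept = rng.uniform(0, lam_max, cand.size) < lam
    spikes = list(cand[accept])

    burst_starts = []
    out = []
    for t in spikes:
        if cfg.burst_p > 0 and rng.random() < cfg.burst_p:
            nb = int(rng.integers(3, 6))
            isis = rng.uniform(0.0025, 0.0055, nb - 1)
            out.extend(t + np.concatenate([[0.0], np.cumsum(isis)]))
            burst_starts.append(t)
        else:
            out.append(t)
    out = np.sort(np.asarray(out))
    if out.size:
        keep = np.concatenate([[True], np.diff(out) > 1e-3])
        out = out[keep]
        out = out[out < T]
    ground_truth.spike_times = out
    ground_truth.burst_times = np.asarray(burst_starts)
    return SpikeTrain(out, unit_id=unit_id, source_channel=lfp.label)


def generate_session(config: SynthConfig):
    """Full fixture: signals, ground truth and one coupled spike train."""
    signals, gt = generate_recording(config)
    train = generate_spikes(signals["lfp"], gt, config)
    return signals, gt, train
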