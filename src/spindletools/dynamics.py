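"""Spindle-rate statistics across vigilance states and transitions.

Rates are reported in spindles per minute.  Events are attributed to
episodes and windows by their temporal midpoint.  Undefined rates (zero
dwell time) are returned as ``None`` rather than 0, so downstream code can
distinguish "no data" from "no spindles".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Episode, Hypnogram, Interval, NREM, REM, STATES, WAKE
from .detect import SpindleEvent

DEFAULT_WINDOWS = tuple(range(5, 41, 5))


@dataclass(frozen=True)
class TransitionProfile:
    """Spindle rate in pre-transition windows of increasing length."""

    target_state: str
    window_lengths: tuple[float, ...]
    rates: tuple[float, ...]
    n_transitions: int

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.window_lengths, self.window_lengths[1:])):
            raise ValueError("window lengths must be strictly increasing")


@dataclass(frozen=True)
class EpisodeRates:
    """Pooled spindle rate of NREM episodes grouped by their successor."""

    n2r: float | None
    n2w: float | None
    n_n2r: int
    n_n2w: int


def _midpoints(events: list[SpindleEvent]) -> np.ndarray:
    return np.array([e.interval.midpoint for e in events], dtype=float)


def rate_by_state(events: list[SpindleEvent], hypnogram: Hypnogram) -> dict:
    """Per-state event rate (min^-1); states with zero dwell map to None."""
    out = {}
    for state in STATES:
        minutes = hypnogram.minutes_in(state)
        n = sum(1 for e in events if e.state == state)
        out[state] = (n / minutes) if minutes > 0 else None
    return out


def episode_rates_by_successor(events: list[SpindleEvent],
                               episodes: list[Episode],
                               min_episode_s: float = 0.0) -> EpisodeRates:
    """Spindle rate of N2R vs N2W episodes (events pooled, final episode excluded)."""
    mids = _midpoints(events)
    totals = {REM: [0, 0.0], WAKE: [0, 0.0]}  # successor -> [events, seconds]
    counts = {REM: 0, WAKE: 0}
    for ep in episodes:
        if ep.state != NREM or ep.successor not in (REM, WAKE):
            continue
        if ep.interval.duration < min_episode_s:
            continue
        n = int(np.sum((mids >= ep.interval.start) & (mids < ep.interval.end))) \
            if mids.size else 0
        totals[ep.successor][0] += n
        totals[ep.successor][1] += ep.interval.duration
        counts[ep.successor] += 1
    if counts[REM] + counts[WAKE] == 0:
        raise ValueError("no NREM episodes with a REM or WAKE successor")

    def rate(succ):
        n, sec = totals[succ]
        return (n / (sec / 60.0)) if sec > 0 else None

    return EpisodeRates(rate(REM), rate(WAKE), counts[REM], counts[WAKE])


def pre_transition_profile(events: list[SpindleEvent], episodes: list[Episode],
                           target_state: str,
                           windows=DEFAULT_WINDOWS) -> TransitionProfile:
    """Spindle rate in windows of 5..40 s preceding NREM -> target transitions.

    Windows are clipped to the episode start (no bleed into the preceding
    state); clipped windows contribute their actual covered duration to the
    denominator.
    """
    transitions = [ep for ep in episodes
                   if ep.state == NREM and ep.successor == target_state]
    if not transitions:
        raise ValueError(f"no NREM episodes followed by {target_state}")
    mids = _midpoints(events)
    rates = []
    for w in windows:
        n_events, seconds = 0, 0.0
        for ep in transitions:
            w0 = max(ep.interval.start, ep.interval.end - w)
            seconds += ep.interval.end - w0
            if mids.size:
                n_events += int(np.sum((mids >= w0) & (mids < ep.interval.end)))
        rates.append(n_events / (seconds / 60.0) if seconds > 0 else 0.0)
    return TransitionProfile(target_state, tuple(float(w) for w in windows),
                             tuple(rates), len(transitions))


def moving_window_rate(events: list[SpindleEvent], hypnogram: Hypnogram,
                       window_min: float = 30.0,
                       overlap_min: float = 25.0) -> pd.DataFrame:
    """Slow spindle-rate dynamics: NREM rate in sliding windows.

    Default 30-min windows sliding by 5 min (25-min overlap).  Each row
    reports the window bounds, NREM minutes inside it and the NREM spindle
    rate; windows with < 1 min of NREM are flagged and carry rate NaN.
    """
    if overlap_min >= window_min:
        raise ValueError("overlap must be smaller than the window")
    step = window_min - overlap_min
    total_min = hypnogram.duration / 60.0
    if total_min < window_min:
        raise ValueError("recording shorter than one window")
    epoch_min = hypnogram.epoch_s / 60.0
    nrem_epochs = hypnogram.labels == NREM
    mids = np.array([e.interval.midpoint / 60.0 for e in events
                     if e.state == NREM], dtype=float)
    rows = []
    start = 0.0
    while start + window_min <= total_min + 1e-9:
        end = start + window_min
        k0 = int(np.floor(start / epoch_min))
        k1 = int(np.ceil(end / epoch_min))
        nrem_min = float(np.sum(nrem_epochs[k0:k1])) * epoch_min
        n = int(np.sum((mids >= start) & (mids < end))) if mids.size else 0
        flagged = nrem_min < 1.0
        rows.append({"t_start_min": start, "t_end_min": end,
                     "nrem_min": nrem_min,
                     "rate_per_min": (n / nrem_min) if not flagged else np.nan,
                     "flagged": flagged})
        start += step
    return pd.DataFrame(rows)


def compare_epochs(rate_series_a, rate_series_b):
    """Paired comparison of two rate series (e.g. baseline vs recovery).

    Returns (per-window differences b - a, summary dict with means and the
    mean-rate ratio).  No inferential statistics are computed.
    """
    a = np.asarray(rate_series_a, dtype=float)
    b = np.asarray(rate_series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must be aligned (same length)")
    diffs = b - a
    mean_a, mean_b = float(np.nanmean(a)), float(np.nanmean(b))
    ratio = mean_b / mean_a if mean_a != 0 else np.nan
    return diffs, {"mean_a": mean_a, "mean_b": mean_b, "ratio": ratio}
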