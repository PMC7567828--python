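"""Core data model: signals, hypnograms, intervals, vigilance episodes.

Time convention: seconds from recording start; intervals are half-open
``[start, end)``; hypnogram epoch ``k`` covers ``[k*epoch_s, (k+1)*epoch_s)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

WAKE = "WAKE"
NREM = "NREM"
REM = "REM"
STATES = (WAKE, NREM, REM)


@dataclass
class Signal:
    """One uniformly sampled voltage channel.

    Parameters
    ----------
    samples : array-like
        Voltage samples in microvolts.
    rate : float
        Sampling rate in Hz, > 0.
    label : str
        Channel name.
    t0 : float
        Time of the first sample, in seconds from recording start.
    """

    samples: np.ndarray
    rate: float
    label: str = "ch0"
    t0: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not self.rate > 0:
            raise ValueError("rate must be > 0")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.samples.size / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.rate

    def index_of(self, t: float) -> int:
        """Sample index containing time ``t`` (floor convention)."""
        return int(np.floor((t - self.t0) * self.rate))

    def segment(self, start: float, end: float) -> np.ndarray:
        """Samples on ``[start, end)`` as a view."""
        i0 = max(self.index_of(start), 0)
        i1 = min(self.index_of(end), self.samples.size)
        return self.samples[i0:i1]


@dataclass(frozen=True)
class Interval:
    """Half-open time interval ``[start, end)`` in seconds."""

    start: float
    end: float

    def __post_init__(self):
        if not self.end > self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def overlap(self, other: "Interval") -> float:
        """Length of the intersection with ``other`` in seconds (>= 0)."""
        return max(0.0, min(self.end, other.end) - max(self.start, other.start))


_LABEL_MAP = {
    "W": WAKE, "WAKE": WAKE, "AW": WAKE,
    "N": NREM, "NREM": NREM, "NR": NREM, "SWS": NREM,
    "R": REM, "REM": REM,
}


def normalize_label(label: str, label_map: dict | None = None) -> str:
    """Map a free-form vigilance label onto {WAKE, NREM, REM}."""
    mapping = dict(_LABEL_MAP)
    if label_map:
        mapping.update({k.strip().upper(): v for k, v in label_map.items()})
    key = str(label).strip().upper()
    if key not in mapping:
        raise ValueError(f"unmappable vigilance label: {label!r}")
    return mapping[key]


@dataclass
class Hypnogram:
    """Vigilance-state labels at fixed epoch resolution (1 s by default)."""

    labels: np.ndarray
    epoch_s: float = 1.0

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.size == 0:
            raise ValueError("hypnogram must contain at least one epoch")
        if not self.epoch_s > 0:
            raise ValueError("epoch_s must be > 0")
        bad = set(self.labels) - set(STATES)
        if bad:
            raise ValueError(f"unknown vigilance labels: {sorted(bad)}")

    def __len__(self) -> int:
        return self.labels.size

    @property
    def duration(self) -> float:
        return self.labels.size * self.epoch_s

    def state_at(self, t: float) -> str:
        """Label of the epoch covering time ``t``."""
        k = int(np.floor(t / self.epoch_s))
        if not 0 <= k < self.labels.size:
            raise ValueError(f"time {t} outside hypnogram span")
        return self.labels[k]

    def minutes_in(self, state: str) -> float:
        return float(np.sum(self.labels == state)) * self.epoch_s / 60.0


@dataclass(frozen=True)
class Episode:
    """Maximal run of one vigilance state and the state that follows it.

    ``successor`` is ``None`` for the final (right-censored) episode.
    """

    interval: Interval
    state: str
    successor: str | None

    def __post_init__(self):
        if self.successor == self.state:
            raise ValueError("successor must differ from episode state")


def state_mask(hypnogram: Hypnogram, state: str, rate: float, n_samples: int) -> np.ndarray:
    """Boolean per-sample mask, true where the epoch label equals ``state``.

    The mask always has length ``n_samples``; samples beyond the hypnogram
    span are false (with a warning when the hypnogram is shorter than the
    signal).
    """
    spe = rate * hypnogram.epoch_s
    if abs(spe - round(spe)) > 1e-9:
        raise ValueError("rate * epoch_s must be an integer number of samples")
    spe = int(round(spe))
    per_epoch = hypnogram.labels == state
    mask = np.repeat(per_epoch, spe)
    if mask.size < n_samples:
        warnings.warn(
            f"hypnogram ({mask.size} samples) shorter than signal ({n_samples}); "
            "tail treated as unscored", stacklevel=2)
        mask = np.concatenate([mask, np.zeros(n_samples - mask.size, dtype=bool)])
    return mask[:n_samples]


def extract_episodes(hypnogram: Hypnogram, min_duration_s: float = 0.0) -> list[Episode]:
    """Split a hypnogram into maximal same-state runs.

    With ``min_duration_s == 0`` (the default) the returned intervals
    partition the hypnogram span exactly.  A positive value drops shorter
    episodes (for episode-level statistics) and then no longer partitions.
    """
    labels = hypnogram.labels
    eps = hypnogram.epoch_s
    boundaries = [0] + [i for i in range(1, labels.size) if labels[i] != labels[i - 1]]
    boundaries.append(labels.size)
    episodes = []
    for j in range(len(boundaries) - 1):
        i0, i1 = boundaries[j], boundaries[j + 1]
        successor = labels[i1] if i1 < labels.size else None
        episodes.append(Episode(Interval(i0 * eps, i1 * eps), labels[i0], successor))
    if min_duration_s > 0:
        episodes = [e for e in episodes if e.interval.duration >= min_duration_s]
    return episodes


def decimate_to_target(signal: Signal, target_rate: float = 1000.0) -> Signal:
    """Anti-alias low-pass then decimate to ``target_rate``.

    The filter is an order-8 Chebyshev type I low-pass (edge 400 Hz, 0.05 dB
    passband ripple) applied zero-phase (forward and reverse), matching a
    standard wide-band acquisition chain; every (rate/target)-th sample is
    then kept.  The decimation factor must be an integer.
    """
    factor = signal.rate / target_rate
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(
            f"rate {signal.rate} is not an integer multiple of target {target_rate}")
    factor = int(round(factor))
    sos = sps.cheby1(8, 0.05, 400.0, btype="low", fs=signal.rate, output="sos")
    filtered = sps.sosfiltfilt(sos, signal.samples)
    out = filtered[::factor] if factor > 1 else filtered
    return Signal(out, target_rate, label=signal.label, t0=signal.t0)
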