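"""Readers and writers for signals, hypnograms, event and spike tables.

Two signal containers are supported: EDF (read through mne; written by a
minimal built-in 16-bit EDF writer) and a raw little-endian float32 binary
with a JSON sidecar carrying rate, channel labels and units.  All tabular
interchange is plain CSV: hypnograms (`state` column, or run-length
`state,count` rows), spindle events
(`start_s,end_s,channel,state,freq_hz,n_cycles,p2p_uv,symmetry`), spike
times (`t_s,unit`), and annotation interval lists (`start_s,end_s`).
"""

from __future__ import annotations

import json
import struct
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Hypnogram, Interval, Signal, normalize_label
from .detect import SpindleEvent

EVENT_COLUMNS = ["start_s", "end_s", "channel", "state", "freq_hz",
                 "n_cycles", "p2p_uv", "symmetry"]


# ---------------------------------------------------------------------------
# signals
# ---------------------------------------------------------------------------

def write_edf(signals: list[Signal], path) -> None:
    """Write channels to a minimal EDF file (16-bit, 1-s data records).

    All channels must share one sampling rate with an integer number of
    samples per second; the recording is zero-padded to a whole second.
    """
    path = Path(path)
    rates = {s.rate for s in signals}
    if len(rates) != 1:
        raise ValueError("all channels must share one sampling rate")
    rate = rates.pop()
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(rate))
    n_max = max(len(s) for s in signals)
    n_rec = int(np.ceil(n_max / spr))
    ns = len(signals)

    def pad(text, width):
        b = str(text).encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate X X X X", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(256 * (1 + ns), 8), pad("", 44), pad(n_rec, 8), pad(1, 8), pad(ns, 4),
    ])
    phys_min, phys_max, scaled = [], [], []
    for s in signals:
        lo, hi = float(s.samples.min()), float(s.samples.max())
        amp = max(abs(lo), abs(hi), 1e-6)
        phys_min.append(-amp)
        phys_max.append(amp)
        dig = np.round(s.samples / amp * 32767).astype("<i2")
        full = np.zeros(n_rec * spr, dtype="<i2")
        full[:dig.size] = dig
        scaled.append(full)
    fields = [
        [pad(s.label, 16) for s in signals],
        [pad("", 80)] * ns,
        [pad("uV", 8)] * ns,
        [pad(f"{v:.6g}"[:8], 8) for v in phys_min],
        [pad(f"{v:.6g}"[:8], 8) for v in phys_max],
        [pad(-32768, 8)] * ns,
        [pad(32767, 8)] * ns,
        [pad("", 80)] * ns,
        [pad(spr, 8)] * ns,
        [pad("", 32)] * ns,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for group in fields:
            fh.write(b"".join(group))
        for r in range(n_rec):
            for ch in scaled:
                fh.write(ch[r * spr:(r + 1) * spr].tobytes())


def _read_edf(path) -> list[Signal]:
    import mne  # deferred: slow import
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts
    return [Signal(row, raw.info["sfreq"], label=name)
            for name, row in zip(raw.ch_names, data)]


def write_raw_binary(signals: list[Signal], path) -> None:
    """Write channels as little-endian float32 with a JSON sidecar."""
    path = Path(path)
    rates = {s.rate for s in signals}
    if len(rates) != 1:
        raise ValueError("all channels must share one sampling rate")
    lengths = {len(s) for s in signals}
    if len(lengths) != 1:
        raise ValueError("all channels must share one length")
    arr = np.stack([s.samples for s in signals]).astype("<f4")
    arr.tofile(path)
    sidecar = {"rate": rates.pop(), "channels": [s.label for s in signals],
               "units": "uV", "n_samples": lengths.pop()}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def _read_raw_binary(path) -> list[Signal]:
    path = Path(path)
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    data = np.fromfile(path, dtype="<f4")
    n_ch, n_s = len(meta["channels"]), int(meta["n_samples"])
    if data.size != n_ch * n_s:
        raise ValueError(
            f"payload holds {data.size} values, sidecar declares {n_ch}x{n_s}")
    data = data.reshape(n_ch, n_s).astype(float)
    return [Signal(row, meta["rate"], label=name)
            for name, row in zip(meta["channels"], data)]


def read_signals(path, format: str | None = None) -> list[Signal]:
    """Read all channels from an EDF or raw-binary+sidecar container."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "raw"
    if format.lower() == "edf":
        return _read_edf(path)
    if format.lower() in ("raw", "raw-binary", "bin"):
        return _read_raw_binary(path)
    raise ValueError(f"unknown signal format {format!r}")


def write_signals(signals: list[Signal], path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "raw"
    if format.lower() == "edf":
        write_edf(signals, path)
    elif format.lower() in ("raw", "raw-binary", "bin"):
        write_raw_binary(signals, path)
    else:
        raise ValueError(f"unknown signal format {format!r}")


# ---------------------------------------------------------------------------
# hypnograms
# ---------------------------------------------------------------------------

def read_hypnogram(path, epoch_s: float = 1.0,
                   label_map: dict | None = None) -> Hypnogram:
    """Read a hypnogram CSV (one label per row, or run-length ``label,count``).

    A header row named ``state`` (any case) is skipped.  Labels are mapped
    onto {WAKE, NREM, REM}; unknown labels raise unless covered by
    ``label_map``.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if lines and lines[0].split(",")[0].strip().lower() in ("state", "label", "stage"):
        lines = lines[1:]
    if not lines:
        raise ValueError(f"empty hypnogram file {path}")
    labels: list[str] = []
    for ln in lines:
        parts = [p.strip() for p in ln.split(",") if p.strip()]
        state = normalize_label(parts[0], label_map)
        count = 1
        if len(parts) == 2:
            count = int(parts[1])
            if count < 1:
                raise ValueError(f"non-positive run length in row {ln!r}")
        elif len(parts) > 2:
            raise ValueError(f"malformed hypnogram row {ln!r}")
        labels.extend([state] * count)
    return Hypnogram(np.array(labels, dtype=object), epoch_s=epoch_s)


def write_hypnogram(hypnogram: Hypnogram, path) -> None:
    Path(path).write_text("state\n" + "\n".join(hypnogram.labels) + "\n")


# ---------------------------------------------------------------------------
# event / annotation / spike tables
# ---------------------------------------------------------------------------

def events_to_frame(events: list[SpindleEvent]) -> pd.DataFrame:
    rows = [{
        "start_s": e.interval.start, "end_s": e.interval.end,
        "channel": e.channel, "state": e.state if e.state is not None else "",
        "freq_hz": e.central_freq, "n_cycles": e.n_cycles,
        "p2p_uv": e.p2p_amplitude, "symmetry": e.symmetry,
    } for e in events]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_events(events: list[SpindleEvent], path) -> None:
    """Serialize events to CSV; input must be sorted by start time."""
    starts = [e.interval.start for e in events]
    if any(b < a for a, b in zip(starts, starts[1:])):
        raise ValueError("events must be sorted by start time")
    events_to_frame(events).to_csv(path, index=False, float_format="%.8f")


def read_events(path) -> list[SpindleEvent]:
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        state = None if pd.isna(row.state) or row.state == "" else str(row.state)
        out.append(SpindleEvent(
            interval=Interval(float(row.start_s), float(row.end_s)),
            channel=str(row.channel), state=state,
            central_freq=float(row.freq_hz), n_cycles=int(row.n_cycles),
            p2p_amplitude=float(row.p2p_uv), symmetry=float(row.symmetry)))
    return out


def read_annotations(path, dialect: str = "intervals") -> list[Interval]:
    """Read expert spindle annotations.

    ``intervals``: CSV with ``start_s,end_s`` columns.  ``onset-duration``:
    whitespace-separated ``onset duration`` rows (the dialect used by public
    spindle-scoring archives), optionally with a one-line header.
    """
    if dialect == "intervals":
        df = pd.read_csv(path)
        return [Interval(float(a), float(b))
                for a, b in zip(df["start_s"], df["end_s"])]
    if dialect == "onset-duration":
        out = []
        for ln in Path(path).read_text().splitlines():
            parts = ln.split()
            if len(parts) != 2:
                continue
            try:
                onset, dur = float(parts[0]), float(parts[1])
            except ValueError:
                continue  # header line
            out.append(Interval(onset, onset + dur))
        return out
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def write_annotations(intervals: list[Interval], path) -> None:
    pd.DataFrame({"start_s": [i.start for i in intervals],
                  "end_s": [i.end for i in intervals]}).to_csv(path, index=False)


def read_spikes(path) -> dict[str, np.ndarray]:
    """Read a spike CSV (``t_s,unit``) into {unit: sorted times}."""
    df = pd.read_csv(path)
    return {str(u): np.sort(g["t_s"].to_numpy(float))
            for u, g in df.groupby("unit")}


def write_spikes(trains: dict[str, np.ndarray], path) -> None:
    rows = [(float(t), u) for u, ts in trains.items() for t in ts]
    rows.sort()
    pd.DataFrame(rows, columns=["t_s", "unit"]).to_csv(path, index=False,
                                                       float_format="%.8f")
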