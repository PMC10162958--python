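"""Readers and writers for the package's on-disk formats.

Continuous recordings travel either as EDF (read back via mne's native EDF
reader) or as the package CSV dialect: a ``time_s`` column plus one column
per channel, in µV. Event tables, designs, spike tables and metric tables
are plain CSV with documented headers; ground truth serialises to JSON.

The EDF writer implemented here is deliberately minimal: EDF (16-bit), one
data record per second, identical sampling rate on every channel — enough to
round-trip the simulator's output through standard EDF readers.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import Recording, SpikeData, SpikeUnit

__all__ = [
    "save_events_csv",
    "load_events_csv",
    "save_design_csv",
    "load_design_csv",
    "save_recording_csv",
    "load_recording_csv",
    "save_recording_edf",
    "load_recording_edf",
    "save_spikes_csv",
    "load_spikes_csv",
    "save_ground_truth_json",
]

EVENT_COLUMNS = ["onset_s", "event_type", "trial_id", "opto"]
DESIGN_COLUMNS = ["subject_id", "session_index", "treatment", "dose_mg_kg"]


def save_events_csv(events: pd.DataFrame, path: str | Path) -> None:
    events[EVENT_COLUMNS].to_csv(path, index=False)


def load_events_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    df["opto"] = df["opto"].astype(bool)
    return df[EVENT_COLUMNS]


def save_design_csv(design: pd.DataFrame, path: str | Path) -> None:
    design[DESIGN_COLUMNS].to_csv(path, index=False)


def load_design_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(DESIGN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    return df[DESIGN_COLUMNS]


def save_recording_csv(recording: Recording, path: str | Path) -> None:
    t = recording.start_time_s + np.arange(recording.n_samples) / recording.sampling_rate_hz
    df = pd.DataFrame({"time_s": t})
    for i, ch in enumerate(recording.channels):
        df[ch] = recording.data[i]
    df.to_csv(path, index=False)


def load_recording_csv(path: str | Path) -> Recording:
    df = pd.read_csv(path)
    if "time_s" not in df.columns or df.shape[1] < 2:
        raise ValueError("recording CSV needs time_s plus channel columns")
    t = df["time_s"].to_numpy()
    fs = 1.0 / np.median(np.diff(t))
    channels = [c for c in df.columns if c != "time_s"]
    return Recording(
        channels=channels,
        sampling_rate_hz=float(np.round(fs, 6)),
        data=df[channels].to_numpy().T,
        start_time_s=float(t[0]),
    )


def save_recording_edf(recording: Recording, path: str | Path) -> None:
    """Write a minimal EDF file (16-bit, µV, 1-s data records).

    The trace is zero-padded to a whole number of seconds; physical scaling
    is chosen per channel from the data range.
    """
    fs = recording.sampling_rate_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export needs an integer sampling rate")
    fs = int(round(fs))
    n_ch = len(recording.channels)
    n_rec = int(np.ceil(recording.n_samples / fs))
    data = np.zeros((n_ch, n_rec * fs))
    data[:, : recording.n_samples] = recording.data

    def pad(s: str, n: int) -> bytes:
        return s[:n].ljust(n).encode("ascii")

    header = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate X X X X", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 + n_ch * 256), 8), pad("", 44),
        pad(str(n_rec), 8), pad("1", 8), pad(str(n_ch), 4),
    ])
    phys_min, phys_max, dig_min, dig_max, scale = [], [], [], [], []
    for i in range(n_ch):
        lo = float(min(data[i].min(), -1.0))
        hi = float(max(data[i].max(), 1.0))
        phys_min.append(lo)
        phys_max.append(hi)
        dig_min.append(-32768)
        dig_max.append(32767)
        scale.append((hi - lo) / (32767 - (-32768)))
    sig_header = b"".join(
        [b"".join(pad(lbl, 16) for lbl in recording.channels)]
        + [b"".join(pad("", 80) for _ in range(n_ch))]
        + [b"".join(pad("uV", 8) for _ in range(n_ch))]
        + [b"".join(pad(f"{v:.6g}", 8) for v in phys_min)]
        + [b"".join(pad(f"{v:.6g}", 8) for v in phys_max)]
        + [b"".join(pad(str(v), 8) for v in dig_min)]
        + [b"".join(pad(str(v), 8) for v in dig_max)]
        + [b"".join(pad("", 80) for _ in range(n_ch))]
        + [b"".join(pad(str(fs), 8) for _ in range(n_ch))]
        + [b"".join(pad("", 32) for _ in range(n_ch))]
    )
    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for r in range(n_rec):
            for i in range(n_ch):
                seg = data[i, r * fs : (r + 1) * fs]
                dig = np.round(
                    (seg - phys_min[i]) / scale[i] + dig_min[i]
                ).astype("<i2")
                fh.write(dig.tobytes())


def load_recording_edf(path: str | Path, start_time_s: float = 0.0) -> Recording:
    """Read an EDF file through mne's native reader into a Recording (µV)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data(units="uV") if hasattr(raw, "get_data") else raw[:][0]
    return Recording(
        channels=list(raw.ch_names),
        sampling_rate_hz=float(raw.info["sfreq"]),
        data=np.asarray(data, dtype=float),
        start_time_s=start_time_s,
    )


def save_spikes_csv(spikes: SpikeData, path: str | Path) -> None:
    spikes.to_frame().to_csv(path, index=False)


def load_spikes_csv(path: str | Path) -> SpikeData:
    df = pd.read_csv(path)
    if not {"unit_id", "spike_time_s"} <= set(df.columns):
        raise ValueError("spike CSV needs unit_id and spike_time_s columns")
    units = [
        SpikeUnit(str(uid), np.sort(g["spike_time_s"].to_numpy()), False, np.nan)
        for uid, g in df.groupby("unit_id", sort=True)
    ]
    return SpikeData(units)


def save_ground_truth_json(recording: Recording, path: str | Path) -> None:
    truth = recording.ground_truth or {}
    out = {}
    for key, val in truth.items():
        if dataclasses.is_dataclass(val):
            out[key] = dataclasses.asdict(val)
        elif isinstance(val, dict):
            out[key] = {
                k: np.asarray(v).tolist() if isinstance(v, np.ndarray) else v
                for k, v in val.items()
            }
        else:
            out[key] = val
    Path(path).write_text(json.dumps(out, indent=1, default=float))
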