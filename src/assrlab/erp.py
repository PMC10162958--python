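"""Epoching and auditory evoked-potential metrics.

The n1 component — the first major negative deflection after a click — is
measured on the trial-averaged waveform, and sensory gating is quantified as
the S2/S1 ratio of n1 amplitudes in the paired-click paradigm (a difference
score S1 - S2 is also reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import Recording

__all__ = [
    "EpochSet",
    "ERPMetrics",
    "EmptyEpochsError",
    "extract_epochs",
    "average_erp",
    "measure_n1",
    "gating_ratio",
    "erp_metrics",
]


class EmptyEpochsError(ValueError):
    pass


@dataclass
class EpochSet:
    """Trial-aligned signal segments around one event type.

    ``data`` is trials x samples (µV); ``times`` gives each column's latency
    relative to the event. Rejected trials are not stored; their trial ids
    and reasons are in ``rejections``.
    """

    data: np.ndarray
    times: np.ndarray
    sampling_rate_hz: float
    event_type: str
    baseline_window: tuple[float, float] = (-0.1, 0.0)
    metadata: pd.DataFrame | None = None
    rejections: pd.DataFrame | None = None

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def time_mask(self, start_s: float, end_s: float) -> np.ndarray:
        return (self.times >= start_s) & (self.times < end_s)


@dataclass(frozen=True)
class ERPMetrics:
    n1_amp_s1_uv: float
    n1_amp_s2_uv: float
    n1_latency_s1_s: float
    n1_latency_s2_s: float
    gating_ratio: float
    gating_diff_uv: float
    n_trials_used: int


def extract_epochs(
    recording: Recording,
    events: pd.DataFrame,
    event_type: str,
    pre_s: float = 0.1,
    post_s: float = 0.3,
    reject_uv: float = np.inf,
    channel: str | None = None,
) -> EpochSet:
    """Cut ``[onset - pre_s, onset + post_s)`` segments around every event of
    the given type, dropping trials that fall off the recording edge or
    contain any sample with ``|x| > reject_uv``.
    """
    if pre_s < 0 or post_s < 0:
        raise ValueError("pre_s and post_s must be >= 0")
    sel = events[events.event_type == event_type]
    if sel.empty:
        raise ValueError(f"no events of type {event_type!r}")
    fs = recording.sampling_rate_hz
    trace = recording.channel(channel) if channel else recording.data[0]
    n_pre = int(round(pre_s * fs))
    n_post = int(round(post_s * fs))
    n_len = n_pre + n_post
    kept, meta, rej = [], [], []
    for _, row in sel.iterrows():
        i_on = int(round((row.onset_s - recording.start_time_s) * fs))
        i0, i1 = i_on - n_pre, i_on - n_pre + n_len
        if i0 < 0 or i1 > trace.size:
            rej.append((row.trial_id, "edge"))
            continue
        seg = trace[i0:i1]
        if np.any(np.abs(seg) > reject_uv):
            rej.append((row.trial_id, "amplitude"))
            continue
        kept.append(seg)
        meta.append((row.trial_id, bool(row.get("opto", False))))
    rejections = pd.DataFrame(rej, columns=["trial_id", "reason"])
    if not kept:
        raise EmptyEpochsError(
            f"no surviving epochs ({len(rej)} rejected: "
            f"{rejections.reason.value_counts().to_dict()})"
        )
    times = (np.arange(n_len) - n_pre) / fs
    return EpochSet(
        data=np.asarray(kept),
        times=times,
        sampling_rate_hz=fs,
        event_type=event_type,
        metadata=pd.DataFrame(meta, columns=["trial_id", "opto"]),
        rejections=rejections,
    )


def average_erp(epochs: EpochSet, baseline_correct: bool = True) -> np.ndarray:
    """Pointwise trial mean, optionally after per-trial baseline subtraction
    (mean over ``epochs.baseline_window``)."""
    if epochs.n_trials < 1:
        raise EmptyEpochsError("no trials to average")
    data = epochs.data
    if baseline_correct:
        mask = epochs.time_mask(*epochs.baseline_window)
        if mask.any():
            data = data - data[:, mask].mean(axis=1, keepdims=True)
    return data.mean(axis=0)


def measure_n1(
    avg_waveform: np.ndarray,
    times: np.ndarray,
    search_start_s: float = 0.010,
    search_end_s: float = 0.100,
) -> tuple[float, float]:
    """Signed amplitude (µV) and latency (s) of the waveform minimum in the
    search window; ties resolve to the earliest time."""
    mask = (times >= search_start_s) & (times <= search_end_s)
    if not mask.any():
        raise ValueError("empty n1 search window")
    seg = avg_waveform[mask]
    i = int(np.argmin(seg))  # argmin returns the first minimum
    return float(seg[i]), float(times[mask][i])


def gating_ratio(n1_s1_uv: float, n1_s2_uv: float) -> float:
    """S2/S1 n1-amplitude ratio (both amplitudes signed; two genuine negative
    n1 components give a positive ratio)."""
    if n1_s1_uv == 0:
        raise ZeroDivisionError("gating undefined for zero S1 amplitude")
    return n1_s2_uv / n1_s1_uv


def erp_metrics(
    epochs_s1: EpochSet,
    epochs_s2: EpochSet,
    search_window_s: tuple[float, float] = (0.010, 0.100),
    baseline_correct: bool = True,
) -> ERPMetrics:
    """n1 amplitude/latency for both clicks of the pair plus gating."""
    a1 = average_erp(epochs_s1, baseline_correct)
    a2 = average_erp(epochs_s2, baseline_correct)
    amp1, lat1 = measure_n1(a1, epochs_s1.times, *search_window_s)
    amp2, lat2 = measure_n1(a2, epochs_s2.times, *search_window_s)
    return ERPMetrics(
        n1_amp_s1_uv=amp1,
        n1_amp_s2_uv=amp2,
        n1_latency_s1_s=lat1,
        n1_latency_s2_s=lat2,
        gating_ratio=gating_ratio(amp1, amp2),
        gating_diff_uv=amp1 - amp2,
        n_trials_used=min(epochs_s1.n_trials, epochs_s2.n_trials),
    )
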