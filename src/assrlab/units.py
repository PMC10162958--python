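"""Single-unit firing metrics around steady-state click trains.

Spikes are aligned to train onsets and pooled over trains; the peristimulus
time histogram (PSTH) divides pooled counts by (n_trains x bin width) to give
Hz. Phase rates summarise the baseline (BL, -2..0 s), initial (In, first
50 ms) and maintenance (MP, 0.05..2 s) windows. Units whose rate drops under
light-on trials are classified as putative PV+ interneurons via a symmetric
suppression index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectral import PhaseWindows

__all__ = [
    "PSTH",
    "PhaseRates",
    "UnitClassification",
    "psth",
    "phase_rates",
    "classify_opto_suppressed",
    "rate_distribution_stats",
]

LOW_RATE_HZ = 0.1  # BL rate below which ratios are too unstable to report


@dataclass
class PSTH:
    bin_edges_s: np.ndarray
    rates_hz: np.ndarray
    n_trials: int
    unit_id: str | None = None
    label: str | None = None

    @property
    def bin_centers_s(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_s[:-1] + self.bin_edges_s[1:])


@dataclass(frozen=True)
class PhaseRates:
    bl_hz: float
    in_hz: float
    mp_hz: float
    ratio_in_bl: float  # NaN when BL rate is zero or below LOW_RATE_HZ
    ratio_mp_bl: float
    low_rate: bool


@dataclass(frozen=True)
class UnitClassification:
    unit_id: str
    opto_suppressed: bool
    suppression_index: float  # (opto - no-opto) / (opto + no-opto), in [-1, 1]
    unclassifiable: bool = False


def _align_pool(spike_times: np.ndarray, train_onsets: np.ndarray,
                lo: float, hi: float) -> np.ndarray:
    """Relative spike times pooled over trains, restricted to [lo, hi)."""
    spikes = np.asarray(spike_times, dtype=float)
    rel = []
    for t0 in train_onsets:
        s = spikes[np.searchsorted(spikes, t0 + lo): np.searchsorted(spikes, t0 + hi)]
        rel.append(s - t0)
    return np.concatenate(rel) if rel else np.empty(0)


def psth(
    spike_times: np.ndarray,
    train_onsets: np.ndarray,
    window_s: tuple[float, float] = (-2.0, 3.0),
    bin_s: float = 0.02,
    unit_id: str | None = None,
    label: str | None = None,
) -> PSTH:
    """Stimulus-aligned, trial-pooled firing-rate histogram (20 ms bins by
    default, window covering baseline, train and offset response)."""
    onsets = np.asarray(train_onsets, dtype=float)
    if onsets.size == 0:
        raise ValueError("need at least one train onset")
    lo, hi = window_s
    n_bins = (hi - lo) / bin_s
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin_s must divide the window length")
    edges = lo + bin_s * np.arange(int(round(n_bins)) + 1)
    rel = _align_pool(spike_times, onsets, lo, hi)
    counts, _ = np.histogram(rel, bins=edges)
    return PSTH(edges, counts / (onsets.size * bin_s), onsets.size, unit_id, label)


def phase_rates(
    spike_times: np.ndarray,
    train_onsets: np.ndarray,
    windows: PhaseWindows = PhaseWindows(),
) -> PhaseRates:
    """Pooled firing rate per BL/In/MP window and the In/BL, MP/BL ratios.

    Ratios are NaN (flagged) when the BL rate is below ``LOW_RATE_HZ``."""
    onsets = np.asarray(train_onsets, dtype=float)
    if onsets.size == 0:
        raise ValueError("need at least one train onset")

    def rate(w):
        n = _align_pool(spike_times, onsets, *w).size
        return n / (onsets.size * (w[1] - w[0]))

    bl, in_, mp = rate(windows.bl), rate(windows.initial), rate(windows.maintenance)
    low = bl < LOW_RATE_HZ
    return PhaseRates(
        bl_hz=bl, in_hz=in_, mp_hz=mp,
        ratio_in_bl=np.nan if low else in_ / bl,
        ratio_mp_bl=np.nan if low else mp / bl,
        low_rate=low,
    )


def classify_opto_suppressed(
    rate_noopto_hz: float,
    rate_opto_hz: float,
    threshold: float = 0.5,
    unit_id: str = "",
) -> UnitClassification:
    """Flag a unit as putatively PV+ when its firing drops under light.

    suppression_index = (opto - no-opto) / (opto + no-opto); suppressed when
    the index is below -threshold.
    """
    if rate_noopto_hz < 0 or rate_opto_hz < 0:
        raise ValueError("rates must be >= 0")
    total = rate_opto_hz + rate_noopto_hz
    if total == 0:
        return UnitClassification(unit_id, False, np.nan, unclassifiable=True)
    idx = (rate_opto_hz - rate_noopto_hz) / total
    return UnitClassification(unit_id, idx < -threshold, idx)


def rate_distribution_stats(units_rates: np.ndarray | pd.Series) -> dict:
    """Across-unit spread of firing rates: mean, SD and interquartile range.

    Used per (treatment x opto x phase) cell to quantify the widening of the
    rate distribution under PV+ silencing and its tightening under the
    agonist.
    """
    r = np.asarray(units_rates, dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 units")
    q25, q75 = np.percentile(r, [25, 75])
    return {"mean": float(r.mean()), "sd": float(r.std(ddof=1)),
            "iqr": float(q75 - q25), "n": int(r.size)}
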