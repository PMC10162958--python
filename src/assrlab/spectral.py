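"""Morlet time-frequency decomposition, band power and inter-trial coherence.

Conventions
-----------
* Complex Morlet coefficients are amplitude-calibrated: a pure sinusoid of
  amplitude A µV at an on-grid frequency yields ``|coef| = A``, so power
  (``|coef|**2``) is in µV² of matched-sinusoid amplitude squared.
* *Evoked* power is the power of the trial-averaged signal (by linearity,
  the squared magnitude of the trial-averaged complex coefficients);
  *total* power is the trial average of per-trial power. Jensen's inequality
  guarantees evoked <= total in every rectangle.
* Inter-trial coherence (ITC) is the mean resultant length of per-trial
  phase: ``ITC(f,t) = |mean_k exp(i phi_k(f,t))|`` in [0, 1].
* Samples within one wavelet half-width (``n_cycles / (2 f)`` seconds) of an
  epoch edge are flagged and excluded from window averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from mne.time_frequency import tfr_array_morlet

from .erp import EpochSet

__all__ = [
    "TFMap",
    "ITCResult",
    "PhaseWindows",
    "ASSRMetrics",
    "morlet_tf",
    "itc",
    "band_power",
    "basal_gamma",
    "assr_metrics",
]


@dataclass
class TFMap:
    """Trials x freqs x times complex Morlet coefficients."""

    coefficients: np.ndarray
    freqs_hz: np.ndarray
    times_s: np.ndarray
    sampling_rate_hz: float
    n_cycles: float
    edge_mask: np.ndarray  # freqs x times, True where edge-contaminated

    @property
    def n_trials(self) -> int:
        return self.coefficients.shape[0]

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.coefficients) ** 2

    def freq_index(self, f_hz: float) -> int:
        i = int(np.argmin(np.abs(self.freqs_hz - f_hz)))
        if abs(self.freqs_hz[i] - f_hz) > 1e-6:
            raise ValueError(f"{f_hz} Hz not on the frequency grid")
        return i


@dataclass
class ITCResult:
    itc: np.ndarray  # freqs x times in [0, 1]
    n_trials: int
    n_excluded: np.ndarray  # freqs x times count of zero-magnitude trials


@dataclass(frozen=True)
class PhaseWindows:
    """BL / initial / maintenance analysis windows relative to train onset."""

    bl: tuple[float, float] = (-2.0, 0.0)
    initial: tuple[float, float] = (0.0, 0.05)
    maintenance: tuple[float, float] = (0.05, 2.0)

    def __post_init__(self) -> None:
        for w in (self.bl, self.initial, self.maintenance):
            if w[1] <= w[0]:
                raise ValueError("window end must exceed start")
        if self.bl[1] > self.initial[0] or self.initial[1] > self.maintenance[0]:
            raise ValueError("windows must be ordered and non-overlapping")


@dataclass(frozen=True)
class ASSRMetrics:
    power40_in: float
    power40_mp: float
    itc40_in: float
    itc40_mp: float
    power40_in_total: float
    power40_mp_total: float


def morlet_tf(
    epochs: EpochSet | np.ndarray,
    freqs_hz: np.ndarray,
    n_cycles: float = 6.0,
    sampling_rate_hz: float | None = None,
    times_s: np.ndarray | None = None,
) -> TFMap:
    """Per-trial complex Morlet transform of an epoch set.

    Accepts an :class:`~assrlab.erp.EpochSet` (preferred) or a raw
    trials x samples array with explicit ``sampling_rate_hz`` and ``times_s``.
    """
    if isinstance(epochs, EpochSet):
        data, fs, times = epochs.data, epochs.sampling_rate_hz, epochs.times
    else:
        if sampling_rate_hz is None:
            raise ValueError("sampling_rate_hz required for array input")
        data = np.atleast_2d(np.asarray(epochs, dtype=float))
        fs = sampling_rate_hz
        times = (np.arange(data.shape[1]) / fs if times_s is None
                 else np.asarray(times_s))
    freqs = np.asarray(freqs_hz, dtype=float)
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("frequency grid must be strictly increasing")
    if freqs.max() >= fs / 2:
        raise ValueError("frequencies must be below Nyquist")
    if n_cycles < 3:
        raise ValueError("n_cycles must be >= 3")
    coefs = tfr_array_morlet(
        data[:, None, :], sfreq=fs, freqs=freqs, n_cycles=n_cycles,
        output="complex", zero_mean=True, verbose="error",
    )[:, 0]
    # amplitude calibration: an L2-normalised Morlet responds to a unit
    # sinusoid with magnitude sqrt(fs * sigma_t * sqrt(pi)), sigma_t the
    # Gaussian SD n_cycles / (2 pi f)
    sigma_t = n_cycles / (2 * np.pi * freqs)
    coefs /= np.sqrt(fs * sigma_t * np.sqrt(np.pi))[None, :, None]
    half_w = n_cycles / (2 * freqs)
    t0, t1 = times[0], times[-1]
    edge = (times[None, :] < t0 + half_w[:, None]) | (
        times[None, :] > t1 - half_w[:, None]
    )
    return TFMap(coefs, freqs, np.asarray(times), fs, n_cycles, edge)


def itc(tfmap: TFMap) -> ITCResult:
    """Inter-trial coherence: mean resultant length of per-trial phase.

    Trials with a zero-magnitude coefficient at a time-frequency point have
    no defined phase there and are excluded from that point's mean; the
    exclusion count is returned.
    """
    if tfmap.n_trials < 2:
        raise ValueError("ITC needs at least 2 trials")
    c = tfmap.coefficients
    mag = np.abs(c)
    valid = mag > 0
    unit = np.zeros_like(c)
    np.divide(c, mag, out=unit, where=valid)
    n_valid = valid.sum(axis=0)
    resultant = np.abs(unit.sum(axis=0))
    out = np.zeros(resultant.shape)
    np.divide(resultant, n_valid, out=out, where=n_valid > 0)
    return ITCResult(out, tfmap.n_trials, tfmap.n_trials - n_valid)


def _rectangle(tfmap: TFMap, band_hz, window_s) -> tuple[np.ndarray, np.ndarray]:
    fmask = (tfmap.freqs_hz >= band_hz[0]) & (tfmap.freqs_hz <= band_hz[1])
    tmask = (tfmap.times_s >= window_s[0]) & (tfmap.times_s < window_s[1])
    if not fmask.any() or not tmask.any():
        raise ValueError("empty time-frequency rectangle")
    return fmask, tmask


def band_power(
    tfmap: TFMap,
    band_hz: tuple[float, float],
    window_s: tuple[float, float],
    mode: str = "total",
) -> float:
    """Mean power (µV²) in a band x window rectangle, edge samples excluded.

    ``mode='total'``: trial-mean of per-trial power (induced + evoked);
    ``mode='evoked'``: power of the trial-averaged signal.
    """
    fmask, tmask = _rectangle(tfmap, band_hz, window_s)
    cell_ok = ~tfmap.edge_mask[np.ix_(fmask, tmask)]
    if not cell_ok.any():
        raise ValueError("rectangle entirely edge-flagged")
    if mode == "total":
        p = tfmap.power[:, fmask][:, :, tmask].mean(axis=0)
    elif mode == "evoked":
        mean_c = tfmap.coefficients[:, fmask][:, :, tmask].mean(axis=0)
        p = np.abs(mean_c) ** 2
    else:
        raise ValueError("mode must be 'total' or 'evoked'")
    return float(p[cell_ok].mean())


def basal_gamma(
    epochs: EpochSet,
    band_hz: tuple[float, float] = (30.0, 80.0),
    window_s: tuple[float, float] = (-1.5, -0.5),
    n_cycles: float = 6.0,
    freq_step_hz: float = 2.0,
) -> float:
    """Total-mode gamma-band power in a pre-stimulus window (µV²)."""
    if window_s[1] > 0:
        raise ValueError("basal window must lie before the event")
    freqs = np.arange(band_hz[0], band_hz[1] + 1e-9, freq_step_hz)
    tf = morlet_tf(epochs, freqs, n_cycles=n_cycles)
    return band_power(tf, band_hz, window_s, mode="total")


def _window_mean(values: np.ndarray, tfmap: TFMap, fi: int, window_s) -> float:
    tmask = (tfmap.times_s >= window_s[0]) & (tfmap.times_s < window_s[1])
    ok = tmask & ~tfmap.edge_mask[fi]
    if not ok.any():
        raise ValueError("window entirely edge-flagged")
    return float(values[ok].mean())


def assr_metrics(
    tfmap: TFMap,
    phase_windows: PhaseWindows = PhaseWindows(),
    f0_hz: float = 40.0,
) -> ASSRMetrics:
    """Steady-state metrics at the driving frequency, split into the initial
    and maintenance phases: evoked-mode power (total also reported) and ITC,
    each averaged within its window."""
    fi = tfmap.freq_index(f0_hz)
    mean_c = tfmap.coefficients[:, fi, :].mean(axis=0)
    evoked = np.abs(mean_c) ** 2
    total = (np.abs(tfmap.coefficients[:, fi, :]) ** 2).mean(axis=0)
    itc_row = itc(tfmap).itc[fi]
    return ASSRMetrics(
        power40_in=_window_mean(evoked, tfmap, fi, phase_windows.initial),
        power40_mp=_window_mean(evoked, tfmap, fi, phase_windows.maintenance),
        itc40_in=_window_mean(itc_row, tfmap, fi, phase_windows.initial),
        itc40_mp=_window_mean(itc_row, tfmap, fi, phase_windows.maintenance),
        power40_in_total=_window_mean(total, tfmap, fi, phase_windows.initial),
        power40_mp_total=_window_mean(total, tfmap, fi, phase_windows.maintenance),
    )
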