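"""Synthetic EEG/LFP sessions and spike trains with known ground truth.

The generative model is deliberately simple but drives every downstream
metric the package computes:

* continuous traces are 1/f background noise + band-limited (30-80 Hz)
  "basal gamma" noise + a deterministic evoked-potential template per click
  (the second click of a pair scaled by the gating factor) + a 40 Hz
  sinusoidal steady-state component per train whose phase is drawn per trial
  from a von Mises distribution (concentration ``assr_kappa`` is the single
  knob controlling inter-trial coherence);
* spike trains are inhomogeneous Poisson processes (thinning) whose rate is
  a baseline multiplied by a stimulus gain (initial / maintenance windows of
  a train) and an optogenetic gain (suppression for PV+ units, disinhibition
  for the rest, during light-on trials).

Condition presets encode the direction of the treatment effects reported for
the two perturbation models (systemic MK-801 and local PV+ silencing, each
with mGluR2/3-agonist rescue); magnitudes are package defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .protocol import StimulusProtocol

__all__ = [
    "ConditionParams",
    "Recording",
    "SpikeUnit",
    "SpikeData",
    "SimulationError",
    "condition_params",
    "erp_template",
    "pink_noise",
    "band_limited_noise",
    "synth_continuous",
    "synth_spike_trains",
]

SPIKE_DT = 1.0 / 40_000.0  # timestamp resolution, 40 kHz acquisition clock


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class ConditionParams:
    """Ground-truth parameters of one simulated condition.

    Defaults are the vehicle (control) condition. Amplitudes in µV, times in
    seconds, rates in Hz.
    """

    # evoked potential
    n1_amp_uv: float = 30.0
    n1_latency_s: float = 0.04
    gating_g: float = 0.5          # S2 amplitude multiplier, in [0, 1]
    # background
    basal_gamma_sd_uv: float = 2.0  # 30-80 Hz band-limited noise scale
    noise_alpha: float = 1.0        # 1/f exponent of the broadband background
    noise_sd_uv: float = 10.0
    # steady-state entrainment
    assr_amp_uv: float = 4.0
    assr_kappa: float = 8.0         # von Mises concentration of trial phase
    initial_boost: float = 1.5      # amplitude multiplier in the first 50 ms
    initial_boost_dur_s: float = 0.05
    # optogenetic modulation (applies to light-on trials only)
    opto_gamma_factor: float = 1.0  # basal gamma multiplier under light
    opto_kappa_factor: float = 1.0  # phase-concentration multiplier under light
    opto_suppression: float = 0.1   # PV-unit rate multiplier s in [0, 1]
    disinhibition: float = 1.5      # non-PV rate multiplier d >= 1
    opto_lead_s: float = 2.1        # light onset before train start
    opto_lag_s: float = 0.1         # light offset after train end
    # unit population
    n_units: int = 40
    pv_fraction: float = 0.15
    rate_median_hz: float = 5.0
    rate_sigma: float = 0.7         # lognormal spread of baseline rates
    in_gain: float = 3.0            # rate gain during the initial 50 ms
    mp_gain: float = 1.5            # rate gain during the maintenance phase
    mp_mod_depth: float = 0.5       # 40 Hz sinusoidal modulation depth in MP
    ly_tightening: float = 1.0      # shrinkage of across-unit rate spread

    def __post_init__(self) -> None:
        if not 0.0 <= self.gating_g <= 1.0:
            raise SimulationError("gating_g must be in [0, 1]")
        if not 0.0 <= self.opto_suppression <= 1.0:
            raise SimulationError("opto_suppression must be in [0, 1]")
        if self.disinhibition < 1.0:
            raise SimulationError("disinhibition must be >= 1")
        if not 0.0 <= self.pv_fraction <= 1.0:
            raise SimulationError("pv_fraction must be in [0, 1]")
        if not 0.0 < self.ly_tightening <= 1.0:
            raise SimulationError("ly_tightening must be in (0, 1]")
        for name in ("n1_amp_uv", "basal_gamma_sd_uv", "assr_amp_uv",
                     "noise_sd_uv", "assr_kappa"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")


_VEHICLE = ConditionParams()
_MK801 = replace(
    _VEHICLE,
    n1_amp_uv=15.0,       # reduced n1
    gating_g=0.8,         # reduced gating (S2/S1 closer to 1)
    basal_gamma_sd_uv=3.6,  # increased basal gamma
    assr_amp_uv=2.0,      # reduced 40 Hz power
    assr_kappa=1.5,       # reduced phase locking (ITC)
)
# agonist alone: slightly tighter locking, basal gamma below control
_LY_ALONE = replace(_VEHICLE, assr_kappa=10.0, basal_gamma_sd_uv=1.5,
                    ly_tightening=0.6, in_gain=4.5, initial_boost=2.5)
# local PV-silencing model, light-on effects (within-session overlay)
_OPTO_OVERLAY = dict(opto_gamma_factor=1.8, opto_kappa_factor=0.4)


def condition_params(treatment: str, opto_model: bool = False) -> ConditionParams:
    """Preset parameters for a treatment label.

    Labels: ``vehicle`` (or ``saline``), ``MK801``, ``MK801+LY@<dose>``,
    ``LY@<dose>``. The rescue by the mGluR2/3 agonist moves n1, gating, basal
    gamma and phase concentration monotonically back toward vehicle with dose
    (fraction ``dose / (dose + 1)``) but leaves the 40 Hz amplitude at the
    MK-801 level, matching the reported dissociation between 40 Hz power (not
    rescued) and ITC (rescued). With ``opto_model=True`` the preset carries
    the light-on overlay (raised basal gamma, lowered phase concentration,
    PV suppression / disinhibition of units).
    """
    label = treatment.strip()
    if label in ("vehicle", "saline"):
        p = _VEHICLE
    elif label == "MK801":
        p = _MK801
    elif label.startswith("MK801+LY@"):
        dose = float(label.split("@")[1])
        r = dose / (dose + 1.0)
        p = replace(
            _MK801,
            n1_amp_uv=_MK801.n1_amp_uv + r * (_VEHICLE.n1_amp_uv - _MK801.n1_amp_uv),
            gating_g=_MK801.gating_g + r * (_VEHICLE.gating_g - _MK801.gating_g),
            basal_gamma_sd_uv=_MK801.basal_gamma_sd_uv
            + r * (_VEHICLE.basal_gamma_sd_uv - _MK801.basal_gamma_sd_uv),
            assr_kappa=_MK801.assr_kappa + r * (_VEHICLE.assr_kappa - _MK801.assr_kappa),
        )
    elif label.startswith("LY@") or label == "LY":
        p = _LY_ALONE
    else:
        raise KeyError(f"unknown treatment label: {treatment!r}")
    if opto_model:
        p = replace(p, **_OPTO_OVERLAY)
    return p


@dataclass
class Recording:
    """Multichannel continuous trace in µV at a fixed sampling rate."""

    channels: list[str]
    sampling_rate_hz: float
    data: np.ndarray  # channels x samples
    start_time_s: float = 0.0
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.channels):
            raise ValueError("data rows must match channel count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite samples in recording")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channels.index(label)]


@dataclass
class SpikeUnit:
    unit_id: str
    spike_times_s: np.ndarray
    pv: bool
    baseline_rate_hz: float


@dataclass
class SpikeData:
    units: list[SpikeUnit]

    def to_frame(self) -> pd.DataFrame:
        rows = [(u.unit_id, t) for u in self.units for t in u.spike_times_s]
        return pd.DataFrame(rows, columns=["unit_id", "spike_time_s"])


def erp_template(
    n1_amp_uv: float, n1_latency_s: float, sampling_rate_hz: float,
    support_s: float = 0.3,
) -> np.ndarray:
    """Deterministic click-evoked potential: a difference-of-Gaussians with a
    dominant n1 trough flanked by smaller p1/p2 positive lobes.

    The waveform minimum is exactly ``-|n1_amp_uv|`` at ``n1_latency_s``; the
    template is zero outside ``[0, support_s)``.
    """
    if n1_latency_s <= 0:
        raise SimulationError("n1 latency must be positive")
    n = int(round(support_s * sampling_rate_hz))
    t = np.arange(n) / sampling_rate_hz
    if n1_amp_uv == 0:
        return np.zeros(n)

    def g(center, sd):
        return np.exp(-0.5 * ((t - center) / sd) ** 2)

    p1_c = max(n1_latency_s - 0.025, 0.005)
    w = 0.35 * g(p1_c, 0.006) - 1.0 * g(n1_latency_s, 0.010) \
        + 0.45 * g(n1_latency_s + 0.045, 0.015)
    w *= abs(n1_amp_uv) / abs(w.min())
    return w


def pink_noise(
    n_samples: int, alpha: float, sd_uv: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Zero-mean 1/f^alpha noise scaled to sample standard deviation sd_uv."""
    if n_samples < 2:
        raise SimulationError("need at least 2 samples")
    if alpha < 0:
        raise SimulationError("alpha must be >= 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if sd_uv == 0:
        return np.zeros(n_samples)
    x = rng.standard_normal(n_samples)
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-alpha / 2.0)
    scale[0] = 0.0  # zero mean
    y = np.fft.irfft(spec * scale, n=n_samples)
    y -= y.mean()
    return y * (sd_uv / y.std())


def band_limited_noise(
    n_samples: int, sampling_rate_hz: float, band_hz: tuple[float, float],
    sd_uv: float, rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Gaussian noise band-passed to ``band_hz`` and scaled to sd_uv."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if sd_uv == 0:
        return np.zeros(n_samples)
    sos = sps.butter(4, band_hz, btype="bandpass", fs=sampling_rate_hz, output="sos")
    y = sps.sosfiltfilt(sos, rng.standard_normal(n_samples))
    return y * (sd_uv / y.std())


def _draw_phases(rng: np.random.Generator, kappa: float, n: int) -> np.ndarray:
    if not np.isfinite(kappa) or kappa > 1e6:
        return np.zeros(n)
    if kappa == 0:
        return rng.uniform(-np.pi, np.pi, n)
    return rng.vonmises(0.0, kappa, n)


def synth_continuous(
    protocol: StimulusProtocol,
    events: pd.DataFrame,
    params: ConditionParams,
    channels: Sequence[str] = ("AC", "mPFC"),
    seed: int | None = None,
    sampling_rate_hz: float = 1000.0,
    pad_s: float = 3.0,
) -> Recording:
    """Simulate a continuous multichannel recording for one session.

    The recording starts ``pad_s`` seconds before the first event so that
    pre-stimulus baselines of the first trial are in range. Channels carry
    independent noise and independent trial phases but share the event
    structure and ground-truth parameters.
    """
    if (events["onset_s"] < 0).any():
        raise SimulationError("event onsets must be non-negative")
    fs = sampling_rate_hz
    t_end = float(events["onset_s"].max()) + (protocol.train_dur_s or 0.0) + pad_s
    start = -pad_s
    n = int(round((t_end - start) * fs))
    if float(events["onset_s"].max()) > start + n / fs:
        raise SimulationError("event outside session span")
    rng = np.random.default_rng(seed)
    child = rng.spawn(len(channels))

    stim_events = events[events.event_type.isin(["click1", "click2", "train_start"])]
    train_rows = stim_events[stim_events.event_type == "train_start"]
    data = np.empty((len(channels), n))
    truth = {"params": params, "sampling_rate_hz": fs, "phases": {}}
    for ci, (label, crng) in enumerate(zip(channels, child)):
        trace = pink_noise(n, params.noise_alpha, params.noise_sd_uv, crng)
        gamma = band_limited_noise(n, fs, (30.0, 80.0), params.basal_gamma_sd_uv, crng)
        # light-on trials: scale basal gamma over the light interval
        if params.opto_gamma_factor != 1.0:
            for _, row in train_rows[train_rows.opto].iterrows():
                i0 = max(0, int(round((row.onset_s - params.opto_lead_s - start) * fs)))
                i1 = min(n, int(round(
                    (row.onset_s + protocol.train_dur_s + params.opto_lag_s - start) * fs)))
                gamma[i0:i1] *= params.opto_gamma_factor
        trace += gamma
        # click-evoked templates
        tmpl = erp_template(params.n1_amp_uv, params.n1_latency_s, fs)
        for _, row in stim_events.iterrows():
            scale = params.gating_g if row.event_type == "click2" else 1.0
            i0 = int(round((row.onset_s - start) * fs))
            seg = tmpl[: n - i0] * scale
            trace[i0 : i0 + len(seg)] += seg
        # steady-state entrainment per train
        phases = np.empty(len(train_rows))
        if len(train_rows):
            dur = protocol.train_dur_s
            f0 = protocol.click_rate_hz
            m = int(round(dur * fs))
            tt = np.arange(m) / fs
            env = np.full(m, params.assr_amp_uv)
            env[tt < params.initial_boost_dur_s] *= params.initial_boost
            for k, (_, row) in enumerate(train_rows.iterrows()):
                kap = params.assr_kappa
                if row.opto:
                    kap *= params.opto_kappa_factor
                ph = _draw_phases(crng, kap, 1)[0]
                phases[k] = ph
                i0 = int(round((row.onset_s - start) * fs))
                seg = env * np.sin(2 * np.pi * f0 * tt + ph)
                trace[i0 : i0 + m] += seg[: n - i0]
        data[ci] = trace
        truth["phases"][label] = phases
    return Recording(list(channels), fs, data, start_time_s=start, ground_truth=truth)


def synth_spike_trains(
    protocol: StimulusProtocol,
    events: pd.DataFrame,
    opto_flags: Sequence[bool] | None,
    params: ConditionParams,
    seed: int | None = None,
    pad_s: float = 3.0,
) -> SpikeData:
    """Simulate a population of single units for one steady-state session.

    Each unit is an inhomogeneous Poisson process realised by thinning:
    lambda(t) = lambda_base * m_stim(t) * m_opto(t). ``m_stim`` is ``in_gain``
    in the first 50 ms of a train, ``mp_gain`` (40 Hz-modulated at depth
    ``mp_mod_depth``) from 50 ms to train end, 1 otherwise. ``m_opto`` is the
    PV suppression factor (PV units) or the disinhibition factor (others)
    during the light interval of flagged trials. Timestamps are reported on a
    40 kHz clock.
    """
    rng = np.random.default_rng(seed)
    onsets = np.sort(
        events.loc[events.event_type == "train_start", "onset_s"].to_numpy()
    )
    if opto_flags is None:
        opto_flags = np.zeros(len(onsets), dtype=bool)
    opto_flags = np.asarray(opto_flags, dtype=bool)
    if len(opto_flags) != len(onsets):
        raise SimulationError("opto_flags length must equal trial count")
    dur = protocol.train_dur_s or 0.0
    t_end = (onsets.max() if len(onsets) else 0.0) + dur + pad_s
    n_units = params.n_units
    n_pv = int(round(params.pv_fraction * n_units))
    pv_flags = np.zeros(n_units, dtype=bool)
    pv_flags[rng.permutation(n_units)[:n_pv]] = True

    base = np.exp(rng.normal(np.log(params.rate_median_hz), params.rate_sigma, n_units))
    if params.ly_tightening < 1.0:
        base = base.mean() + params.ly_tightening * (base - base.mean())

    in_dur = 0.05
    units = []
    for i in range(n_units):
        lam0 = base[i]
        m_opto = params.opto_suppression if pv_flags[i] else params.disinhibition
        lam_max = lam0 * max(1.0, params.in_gain,
                             params.mp_gain * (1 + params.mp_mod_depth)) \
            * max(1.0, m_opto)
        n_cand = rng.poisson(lam_max * t_end)
        cand = np.sort(rng.uniform(0.0, t_end, n_cand))
        lam = np.full(n_cand, lam0)
        if len(onsets):
            idx = np.searchsorted(onsets, cand, side="right") - 1
            rel = np.where(idx >= 0, cand - onsets[np.clip(idx, 0, None)], np.inf)
            m_stim = np.ones(n_cand)
            m_stim[(rel >= 0) & (rel < in_dur)] = params.in_gain
            mp = (rel >= in_dur) & (rel < dur)
            m_stim[mp] = params.mp_gain * (
                1 + params.mp_mod_depth
                * np.sin(2 * np.pi * (protocol.click_rate_hz or 40.0) * rel[mp])
            )
            lam = lam * m_stim
            lit = (idx >= 0) & opto_flags[np.clip(idx, 0, None)] \
                & (rel >= -params.opto_lead_s) & (rel < dur + params.opto_lag_s)
            # light may also lead the train: check the previous inter-train gap
            nxt = np.clip(idx + 1, 0, len(onsets) - 1)
            pre = opto_flags[nxt] & (cand >= onsets[nxt] - params.opto_lead_s) \
                & (cand < onsets[nxt])
            lam = np.where(lit | pre, lam * m_opto, lam)
        if np.any(lam < 0):
            raise SimulationError("negative rate encountered")
        keep = rng.uniform(0.0, 1.0, n_cand) < lam / lam_max
        times = np.unique(np.round(cand[keep] / SPIKE_DT) * SPIKE_DT)
        units.append(SpikeUnit(f"u{i:03d}", times, bool(pv_flags[i]), float(lam0)))
    return SpikeData(units)
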