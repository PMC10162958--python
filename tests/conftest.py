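import numpy as np
import pytest

import assrlab as al
from assrlab.erp import EpochSet


@pytest.fixture(scope="session")
def assr_freqs():
    return np.arange(35.0, 46.0)


def eeg_session_metrics(treatment: str, seed: int, n_trials: int = 30) -> dict:
    """Scaled-down double-click + steady-state pair of sessions for one
    condition; returns the headline metrics used by direction tests."""
    params = al.condition_params(treatment)
    proto, events = al.build_erp_protocol(n_trials, 3.5, 0.5)
    rec = al.synth_continuous(proto, events, params, channels=["AC"], seed=seed)
    ep1 = al.extract_epochs(rec, events, "click1", 0.5, 0.5)
    ep2 = al.extract_epochs(rec, events, "click2", 0.5, 0.5)
    m = al.erp_metrics(ep1, ep2)
    ep_bl = al.extract_epochs(rec, events, "click1", 1.6, 0.0)
    bg = al.basal_gamma(ep_bl)
    proto_a, ev_a = al.build_assr_protocol(n_trials, 40, 2, 4)
    rec_a = al.synth_continuous(proto_a, ev_a, params, channels=["AC"],
                                seed=seed + 1)
    ep_t = al.extract_epochs(rec_a, ev_a, "train_start", 2.0, 2.5)
    am = al.assr_metrics(al.morlet_tf(ep_t, np.arange(35.0, 46.0)))
    return {
        "n1": m.n1_amp_s1_uv,
        "gating": m.gating_ratio,
        "basal_gamma": bg,
        "itc40": am.itc40_mp,
        "power40": am.power40_mp,
    }


def tetrode_session_metrics(seed: int, treatment: str = "saline",
                            n_trials: int = 40) -> dict:
    """One light-interleaved steady-state session; metrics split by light."""
    params = al.condition_params(treatment, opto_model=True)
    proto, events = al.build_assr_protocol(n_trials, 40, 2, 5)
    flags = al.assign_opto_flags(n_trials, 0.5, 4, seed)
    events = al.apply_opto_flags(events, flags)
    rec = al.synth_continuous(proto, events, params, channels=["e1"], seed=seed)
    ep = al.extract_epochs(rec, events, "train_start", 2.0, 2.5)
    ep_bl = al.extract_epochs(rec, events, "train_start", 1.6, 0.0)
    out = {}
    for opto in (False, True):
        sel = ep.metadata.opto.to_numpy() == opto
        am = al.assr_metrics(al.morlet_tf(
            ep.data[sel], np.arange(35.0, 46.0),
            sampling_rate_hz=ep.sampling_rate_hz, times_s=ep.times))
        bsel = ep_bl.metadata.opto.to_numpy() == opto
        bg = al.basal_gamma(EpochSet(ep_bl.data[bsel], ep_bl.times,
                                     ep_bl.sampling_rate_hz, "train_start"))
        out[opto] = {"itc40": am.itc40_mp, "basal_gamma": bg,
                     "power40": am.power40_mp}
    spikes = al.synth_spike_trains(proto, events, flags, params, seed=seed + 1)
    onsets = np.sort(
        events.loc[events.event_type == "train_start", "onset_s"].to_numpy())
    for opto in (False, True):
        rates = [al.phase_rates(u.spike_times_s, onsets[flags == opto]).bl_hz
                 for u in spikes.units]
        out[opto]["rate_sd"] = float(np.std(rates, ddof=1))
    return out
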