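"""Single-unit metrics around light-interleaved 40 Hz trains.

Simulates a cortical population in which parvalbumin-positive (PV+)
interneurons are silenced on light-on trials while the rest of the
population disinhibits, then recovers the PV label from the firing-rate
drop (suppression index < -0.5) and summarises baseline/initial/maintenance
firing.
"""

import numpy as np

import assrlab as al

proto, events = al.build_assr_protocol(n_trials=80, click_rate_hz=40.0,
                                       train_dur_s=2.0, iti_s=5.0)
flags = al.assign_opto_flags(80, fraction=0.5, max_run=4, seed=5)
events = al.apply_opto_flags(events, flags)
params = al.condition_params("saline", opto_model=True)
spikes = al.synth_spike_trains(proto, events, flags, params, seed=5)
onsets = np.sort(events.loc[events.event_type == "train_start",
                            "onset_s"].to_numpy())

hits = 0
for u in spikes.units:
    off = al.phase_rates(u.spike_times_s, onsets[~flags])
    on = al.phase_rates(u.spike_times_s, onsets[flags])
    cls = al.classify_opto_suppressed(off.mp_hz, on.mp_hz, unit_id=u.unit_id)
    hits += cls.opto_suppressed == u.pv
    if u.pv:
        print(f"{u.unit_id} (PV+): BL {off.bl_hz:5.1f} Hz, In/BL "
              f"{off.ratio_in_bl:4.1f}, light-on MP {on.mp_hz:5.1f} Hz, "
              f"suppression index {cls.suppression_index:+.2f}")
print(f"PV classification agrees with ground truth for "
      f"{hits}/{len(spikes.units)} units")

busy = max(spikes.units, key=lambda u: u.baseline_rate_hz)
p = al.psth(busy.spike_times_s, onsets[~flags])
peak_bin = p.bin_centers_s[p.rates_hz.argmax()]
print(f"PSTH of {busy.unit_id}: peak {p.rates_hz.max():.0f} Hz "
      f"at {peak_bin * 1e3:+.0f} ms (20 ms bins, light-off trials)")
# The initial 50 ms of each train drives the strongest firing; PV+ units are
# identifiable purely from their rate collapse under light.
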