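"""Build the two auditory stimulation protocols and a cross-over design.

Prints the session geometry: a paired-click ERP session (300 pairs, 8 s
apart) and a 40 Hz steady-state session (300 trains of 80 clicks), plus a
light-on/light-off trial interleaving and a randomized treatment order.
"""

import assrlab as al

erp_proto, erp_events = al.build_erp_protocol(n_trials=300, iti_s=8.0,
                                              pair_gap_s=0.5)
print(f"ERP session: {erp_proto.n_trials} click pairs, "
      f"span {erp_proto.session_dur_s:.1f} s, "
      f"{len(erp_events)} events")

assr_proto, assr_events = al.build_assr_protocol(n_trials=300,
                                                 click_rate_hz=40.0,
                                                 train_dur_s=2.0, iti_s=10.0)
print(f"ASSR session: {assr_proto.n_trials} trains x "
      f"{assr_proto.clicks_per_train} clicks at "
      f"{assr_proto.click_rate_hz:.0f} Hz")

flags = al.assign_opto_flags(600, fraction=0.5, max_run=4, seed=0)
print(f"Tetrode opto assignment: {flags.sum()}/600 light-on trials, "
      "pseudorandom with runs capped at 4")

design = al.build_crossover_design(
    [f"m{i:02d}" for i in range(19)],
    ["vehicle", "MK801", "MK801+LY@1", "MK801+LY@3"], seed=0)
print(f"Cross-over design: {len(design)} sessions, "
      f"{design.subject_id.nunique()} mice x "
      f"{design.treatment.nunique()} treatments")
print(design.head(4).to_string(index=False))
# Every mouse receives every treatment once, in seeded random order, so each
# animal serves as its own control.
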