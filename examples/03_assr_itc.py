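"""40 Hz steady-state entrainment: power and inter-trial coherence.

Epochs are decomposed with complex Morlet wavelets; the ITC (mean resultant
length of per-trial phase, 1 = perfect locking) and the evoked power at the
40 Hz drive are summarised separately for the initial (first 50 ms) and
maintenance (50-2000 ms) response phases.
"""

import numpy as np

import assrlab as al

proto, events = al.build_assr_protocol(n_trials=50, click_rate_hz=40.0,
                                       train_dur_s=2.0, iti_s=5.0)
freqs = np.arange(35.0, 46.0)

for treatment in ("vehicle", "MK801", "MK801+LY@3"):
    params = al.condition_params(treatment)
    rec = al.synth_continuous(proto, events, params, channels=["AC"], seed=11)
    ep = al.extract_epochs(rec, events, "train_start", pre_s=2.0, post_s=2.5)
    am = al.assr_metrics(al.morlet_tf(ep, freqs))
    bg = al.basal_gamma(al.extract_epochs(rec, events, "train_start",
                                          pre_s=1.6, post_s=0.0))
    print(f"{treatment:12s} ITC(mp) {am.itc40_mp:.2f} | power40(mp) "
          f"{am.power40_mp:6.2f} µV² | basal gamma {bg:5.2f} µV²")
# The antagonist collapses phase locking (low ITC) and 40 Hz power while
# raising spontaneous gamma; the agonist restores the coherence but not the
# 40 Hz power — the dissociation this analysis is designed to expose.
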