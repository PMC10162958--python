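# assrlab

Simulation and analysis of auditory evoked brain oscillations in rodent
EEG/LFP recordings: paired-click event-related potentials, 40 Hz auditory
steady-state responses (ASSR), and single-unit firing around click trains.

The package is aimed at preclinical electrophysiologists studying
excitation/inhibition balance — for example the classic two-model setting in
which cortical oscillations are disturbed either globally (systemic NMDA
receptor antagonism with MK-801) or locally (optogenetic silencing of
parvalbumin-positive interneurons in medial prefrontal cortex), and a
candidate compound (an mGluR2/3 agonist) is tested for rescue. Because raw
recordings from such studies are rarely public, a first-class synthetic
session generator with known ground truth is part of the package: every
analysis stage is testable end to end without any data download.

## What it computes

**Evoked potentials** (`assrlab.erp`). Epochs are cut around click events,
baseline-corrected and averaged; the n1 component is the minimum of the
average in a 10–100 ms search window, and sensory gating is the S2/S1 ratio
of n1 amplitudes in the double-click paradigm,

    gating = n1(S2) / n1(S1),

with a difference score n1(S1) − n1(S2) also reported.

**Time–frequency metrics** (`assrlab.spectral`). Complex Morlet
decomposition (default 6 cycles), amplitude-calibrated so a sinusoid of
amplitude *A* µV reads power *A*² at its own frequency. Inter-trial
coherence is the mean resultant length of per-trial phase,

    ITC(f, t) = | (1/N) Σₖ exp(i φₖ(f, t)) |  ∈ [0, 1],

and band power comes in *total* (trial-mean of per-trial power) and *evoked*
(power of the trial average) modes, with evoked ≤ total guaranteed.
Steady-state metrics are summarised at the 40 Hz drive separately for the
initial (0–50 ms) and maintenance (50–2000 ms) response phases, plus basal
gamma power (30–80 Hz) in a pre-stimulus window.

**Single units** (`assrlab.units`). PSTHs (20 ms bins, spikes pooled over
trains), baseline/initial/maintenance firing rates and ratios, across-unit
rate-spread statistics, and classification of putative PV+ interneurons from
the firing-rate drop under light (suppression index below −0.5).

**Inference** (`assrlab.stats`). Within-subject cross-over contrasts from a
fixed-effects subject + treatment linear model (adjusted means equal raw
condition means in balanced designs; Wald t tests), and a two-way
light × drug ANOVA with interaction for electrode-replicate data.

**Simulation** (`assrlab.simulate`). Continuous traces are 1/f noise +
band-limited basal gamma + deterministic click-evoked templates + a 40 Hz
sinusoid per train with von Mises trial phase; spike trains are thinned
inhomogeneous Poisson processes with stimulus and light gains. Condition
presets encode the qualitative direction of each treatment effect.

## Worked example

```python
import numpy as np
import assrlab as al

proto, events = al.build_assr_protocol(n_trials=50, click_rate_hz=40.0,
                                       train_dur_s=2.0, iti_s=5.0)
for treatment in ("vehicle", "MK801", "MK801+LY@3"):
    rec = al.synth_continuous(proto, events, al.condition_params(treatment),
                              channels=["AC"], seed=11)
    ep = al.extract_epochs(rec, events, "train_start", pre_s=2.0, post_s=2.5)
    am = al.assr_metrics(al.morlet_tf(ep, np.arange(35.0, 46.0)))
    print(treatment, round(am.itc40_mp, 2), round(am.power40_mp, 2))
```

prints

```
vehicle 0.8 14.29
MK801 0.25 1.29
MK801+LY@3 0.52 3.67
```

— maintenance-phase ITC and 40 Hz evoked power (µV²). The antagonist
collapses phase locking and power; the agonist co-treatment restores the
coherence but not the power, the dissociation this analysis chain is built
to expose. The `examples/` directory holds one short script per capability
(protocols, ERP/gating, ASSR/ITC, unit PSTHs, cross-over statistics, and the
full `run_pipeline` report bundle).

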