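# Methods

## Scope and data model

The package analyses two preparations common in mouse auditory
electrophysiology: supradural screw EEG over auditory cortex (AC) and medial
prefrontal cortex (mPFC), and intracortical tetrodes in mPFC with sorted
single units plus local field potential. Continuous traces are represented
in µV at 1 kHz (`Recording`), spike timestamps on a 40 kHz clock
(`SpikeData`), events as tidy tables of onsets (`onset_s`, `event_type`,
`trial_id`, `opto`), and treatment assignment as a cross-over design table.
Protocols are described in continuous seconds; alignment to samples happens
only when epochs are cut (onsets rounded to the nearest sample).

Two stimulation paradigms are built in:

* **double-click ERP** — 300 click pairs, onsets 8 s apart. The intra-pair
  interval is not a fixed property of the paradigm; the package defaults to
  0.5 s, the common double-click gating convention, and makes it
  configurable.
* **40 Hz ASSR** — 2-s trains of 80 clicks at 40 clicks/s, 10 s apart
  (300 trains in the EEG variant; 600 trains with 50 % light-on trials in
  the tetrode variant). Light-on/light-off interleaving is pseudorandom with
  the exact flagged count `round(fraction × n_trials)` and runs of identical
  flags capped (default 4), generated by a constructive sampler that checks
  remainder feasibility at every step, so any feasible (fraction, cap)
  combination succeeds for every seed.

## Synthetic sessions

The generator is deliberately phenomenological: it produces signals with
exactly the statistical structure the downstream metrics measure, with every
parameter recorded as ground truth.

**Continuous traces** are a sum of four components per channel:

1. background 1/f^α noise (FFT-filtered Gaussian noise, α = 1, scaled to
   10 µV sample SD);
2. band-limited "basal gamma" — 30–80 Hz Butterworth-filtered noise
   (vehicle scale 2 µV SD), present throughout the session. On light-on
   trials of the optogenetic model this component is scaled by a factor
   (default 1.8) over the light interval (2.1 s before train onset to 0.1 s
   after train end), so the pre-stimulus baseline window of flagged trials
   is affected;
3. a deterministic click-evoked template per click: a difference-of-
   Gaussians with a dominant n1 trough (exactly −n1_amp at the nominal
   latency, default 30 µV at 40 ms) and smaller p1/p2 positive lobes,
   support limited to 300 ms so the S1 and S2 responses never overlap at the
   0.5 s pair gap. The second click's template is scaled by the gating
   factor g ∈ [0, 1]. In steady-state sessions the template is placed at
   train onset (an onset response); individual clicks within a train are not
   convolved separately;
4. a 40 Hz sinusoid per train whose phase is drawn once per trial from a
   von Mises distribution with concentration κ — the single knob controlling
   inter-trial coherence (sample-level jitter is not modelled). Amplitude is
   `assr_amp × initial_boost` during the first 50 ms, `assr_amp` afterwards.

**Spike trains** are inhomogeneous Poisson processes realised by thinning:
λ(t) = λ_base · m_stim(t) · m_opto(t), with m_stim = in_gain (default 3)
during the first 50 ms of a train, mp_gain (default 1.5) with a 40 Hz
sinusoidal modulation (depth 0.5) during the rest of the train, and 1
elsewhere; m_opto applies during the light interval of flagged trials:
suppression s ∈ [0, 1] (default 0.1) for PV-flagged units, disinhibition
d ≥ 1 (default 1.5) for the rest. Baseline rates are lognormal (median
5 Hz, σ = 0.7); the agonist's population effect is modelled as linear
shrinkage of rates toward their mean (`ly_tightening`, so a factor of 0.5
halves the across-unit SD exactly). A fraction of units (default 0.15,
consistent with the 10–20 % inhibitory share of cortex) is flagged PV.

**Condition presets** encode the direction of the reported treatment
effects; the magnitudes are package defaults because the source figures
print no numeric effect sizes. Vehicle: n1 30 µV, g 0.5, basal gamma 2 µV,
assr amplitude 4 µV, κ 8. MK-801: n1 15 µV, g 0.8 (weaker gating), basal
gamma 3.6 µV, assr amplitude 2 µV, κ 1.5. Agonist co-treatment at dose D
moves n1, g, basal gamma and κ back toward vehicle by the fraction
D/(D+1) — dose-monotone — but leaves the 40 Hz amplitude at the MK-801
level, reproducing the power/ITC dissociation (coherence rescued, power
not). Agonist alone: κ 10, basal gamma 1.5 µV (below control), tighter unit
rates, larger initial gain. The optogenetic overlay multiplies basal gamma
by 1.8 and κ by 0.4 on light-on trials and engages s and d for units; the
40 Hz amplitude is untouched (power at the drive is unaffected by PV
silencing). The κ modulation is an essential part of the light overlay: PV
silencing degrades phase locking without touching entrained power, and only
a concentration knob can produce that dissociation in this generative model.

What the generator does **not** emulate: volume conduction and channel
covariance (channels are independent), spike waveforms, bursting and
refractoriness, non-stationary drift, movement or line artifacts, and any
biophysics of the photocurrent. Passing recovery tests therefore shows the
analysis chain is correct and well-calibrated on signals with the assumed
structure — not that the presets quantitatively match any real animal.

## Analysis conventions

* **Epoching**: `[onset − pre, onset + post)`, per-trial baseline correction
  subtracting the mean over −100–0 ms by default; artifact rejection by
  absolute threshold (500 µV convention; off for synthetic data), edge and
  amplitude rejections logged per trial.
* **n1**: minimum of the trial-averaged waveform in a 10–100 ms search
  window (measurement on the average, matching how grand-average traces are
  presented); ties resolve to the earliest sample. Gating is reported
  primarily as the S2/S1 ratio, with the S1 − S2 difference alongside.
* **Morlet transform**: `mne.time_frequency.tfr_array_morlet` (complex
  output, zero-mean wavelets), default 6 cycles, grid 1–100 Hz at 1 Hz for
  full maps (narrow grids around 40 Hz for steady-state metrics).
  Coefficients are divided by √(fs·σ_t·√π), σ_t = n_cycles/(2πf), so a
  sinusoid of amplitude A reads |coef| = A; power is in µV² (no dB
  conversion). Samples within one wavelet half-width (n_cycles/(2f) s) of an
  epoch edge are flagged and excluded from all window averages.
* **ITC**: mean resultant length of per-trial phase. Zero-magnitude
  coefficients have no phase and are excluded pointwise with a logged count.
  Under uniform phases the expected value is √π/(2√N) (Rayleigh), which the
  tests verify at N = 10, 100, 300.
* **Band power**: evoked mode uses the linearity of the transform (power of
  the trial-mean coefficients equals the transform of the trial-mean
  signal). Evoked gamma rectangle: 30–80 Hz × 0–100 ms post-click. Basal
  gamma: total-mode 30–80 Hz power in −1.5 to −0.5 s, inside the baseline
  but clear of edge effects.
* **Phase windows**: baseline −2–0 s, initial 0–50 ms, maintenance
  50–2000 ms relative to train onset, configurable. Note the 50 ms initial
  window is shorter than the 40 Hz wavelet half-width (75 ms at 6 cycles),
  so initial-phase estimates at 40 Hz unavoidably mix in early maintenance
  signal; the amplitude-ratio recovery test therefore uses a longer boost
  segment with interior windows, while the defaults stay at the standard
  BL/In/MP definitions.
* **Units**: PSTH window −2 to +3 s, 20 ms bins; rates = pooled counts /
  (n_trains × bin width), so counts are conserved exactly. Units with
  baseline rate < 0.1 Hz are flagged and their ratios reported as NaN
  rather than inflated. PV classification threshold −0.5 on the symmetric
  suppression index (rate_on − rate_off)/(rate_on + rate_off); the index is
  always reported so other cutoffs can be applied.
* **Inference**: the cross-over analysis fits `value ~ subject + treatment`
  by OLS with Wald t contrasts — for balanced complete designs this
  reproduces adjusted (least-squares) means exactly and is equivalent to a
  paired t test for two conditions; random-effects machinery is deliberately
  avoided. Only subject and condition are modelled (no session-order
  covariate). The tetrode analysis treats the electrode as the replicate
  unit and fits a two-way fixed-effects ANOVA (type II) with interaction.
  No multiplicity correction by default; Holm adjustment by flag.
  Significance stars at 0.05/0.01/0.001.

## Problem sizes in the test suite

Unit and acceptance tests run on scaled-down sessions chosen so each check
retains comfortable statistical margin: direction-of-effect comparisons use
20-trial sessions (the preset effect sizes are several times the
trial-averaged noise at that size), parameter-recovery runs use 15–40 trials
across 100 seeds, and inference calibration uses 400–1000 null simulations.
The generator defaults remain the full protocols (300/600 trials); nothing
in the analysis depends on trial count beyond the usual √N precision.

## Known limitations

* Absolute power calibration of the source figures is unknown; only
  relative and directional claims are testable, and preset magnitudes are
  explicit package choices.
* Whether published "power at 40 Hz" is evoked- or total-mode is ambiguous;
  evoked mode is primary here (the ASSR convention) and total mode is
  always emitted alongside.
* The EDF writer is minimal (16-bit, one data record per second, equal
  rates across channels); it round-trips against mne's reader but does not
  aim at full EDF+ annotation support.
* Unit populations are treated as independent across sessions; no attempt
  is made to track the same unit across recording days.
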