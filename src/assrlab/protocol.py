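"""Stimulus protocols, event timelines and cross-over designs.

Two auditory paradigms are supported:

* the double-click (paired-click) ERP paradigm: pairs of white-noise clicks,
  used to measure the n1 component and sensory gating (S2/S1 attenuation);
* the 40 Hz auditory steady-state (ASSR) paradigm: 2-s click trains at
  40 clicks/s, used to probe gamma-band entrainment.

Protocols are described in continuous seconds; alignment to samples happens
downstream when epochs are cut from a recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StimulusProtocol",
    "ProtocolError",
    "AssignmentError",
    "DesignError",
    "build_erp_protocol",
    "build_assr_protocol",
    "assign_opto_flags",
    "build_crossover_design",
]


class ProtocolError(ValueError):
    """Raised for protocol parameters that describe an impossible session."""


class AssignmentError(ValueError):
    """Raised when a pseudorandom opto assignment is infeasible."""


class DesignError(ValueError):
    """Raised for invalid cross-over designs (e.g. duplicate treatments)."""


@dataclass(frozen=True)
class StimulusProtocol:
    """Parameters of one auditory stimulation session.

    ``level_db`` is metadata only: the simulator models the neural response,
    not the acoustic waveform.
    """

    kind: Literal["erp_pair", "assr_train"]
    n_trials: int
    iti_s: float
    pair_gap_s: float | None = None
    train_dur_s: float | None = None
    click_rate_hz: float | None = None
    level_db: float = 85.0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ProtocolError("n_trials must be >= 1")
        if self.iti_s <= 0:
            raise ProtocolError("iti_s must be positive")
        if self.kind == "erp_pair":
            if self.pair_gap_s is None or not 0 < self.pair_gap_s < self.iti_s:
                raise ProtocolError("need 0 < pair_gap_s < iti_s for erp_pair")
        elif self.kind == "assr_train":
            if self.train_dur_s is None or self.click_rate_hz is None:
                raise ProtocolError("assr_train needs train_dur_s and click_rate_hz")
            if self.iti_s <= self.train_dur_s:
                raise ProtocolError("iti_s must exceed train_dur_s (no overlap)")
            n_clicks = self.click_rate_hz * self.train_dur_s
            if abs(n_clicks - round(n_clicks)) > 1e-9:
                raise ProtocolError("click_rate_hz * train_dur_s must be integral")

    @property
    def clicks_per_train(self) -> int:
        if self.kind != "assr_train":
            raise ProtocolError("clicks_per_train defined only for assr_train")
        return int(round(self.click_rate_hz * self.train_dur_s))

    @property
    def session_dur_s(self) -> float:
        """Time from the first onset to the end of the last trial's footprint."""
        last_onset = (self.n_trials - 1) * self.iti_s
        tail = self.pair_gap_s if self.kind == "erp_pair" else self.train_dur_s
        return last_onset + tail


def build_erp_protocol(
    n_trials: int = 300, iti_s: float = 8.0, pair_gap_s: float = 0.5
) -> tuple[StimulusProtocol, pd.DataFrame]:
    """Build a paired-click session: ``n_trials`` click pairs, onsets ``iti_s``
    apart, second click ``pair_gap_s`` after the first.

    Returns the protocol and an event table with one ``click1`` and one
    ``click2`` row per trial (columns onset_s, event_type, trial_id, opto).
    """
    proto = StimulusProtocol(
        kind="erp_pair", n_trials=n_trials, iti_s=iti_s, pair_gap_s=pair_gap_s
    )
    onsets1 = np.arange(n_trials) * iti_s
    rows = []
    for tid, o1 in enumerate(onsets1):
        rows.append((o1, "click1", tid, False))
        rows.append((o1 + pair_gap_s, "click2", tid, False))
    events = pd.DataFrame(rows, columns=["onset_s", "event_type", "trial_id", "opto"])
    return proto, events.sort_values("onset_s", ignore_index=True)


def build_assr_protocol(
    n_trials: int = 300,
    click_rate_hz: float = 40.0,
    train_dur_s: float = 2.0,
    iti_s: float = 10.0,
) -> tuple[StimulusProtocol, pd.DataFrame]:
    """Build a steady-state session of click trains.

    The default is the screw-EEG ASSR protocol: 300 trains of 2 s at
    40 clicks/s (80 clicks per train), 10 s apart. The event table holds one
    ``train_start`` row per trial plus a ``click`` row per click.
    """
    proto = StimulusProtocol(
        kind="assr_train",
        n_trials=n_trials,
        iti_s=iti_s,
        train_dur_s=train_dur_s,
        click_rate_hz=click_rate_hz,
    )
    n_clicks = proto.clicks_per_train
    rows = []
    for tid in range(n_trials):
        t0 = tid * iti_s
        rows.append((t0, "train_start", tid, False))
        for k in range(n_clicks):
            rows.append((t0 + k / click_rate_hz, "click", tid, False))
    events = pd.DataFrame(rows, columns=["onset_s", "event_type", "trial_id", "opto"])
    return proto, events.sort_values(
        ["onset_s", "event_type"], ignore_index=True, kind="stable"
    )


def assign_opto_flags(
    n_trials: int, fraction: float, max_run: int = 4, seed: int | None = None
) -> np.ndarray:
    """Pseudorandom boolean trial flags with an exact count and bounded runs.

    Exactly ``round(fraction * n_trials)`` trials are flagged True, in a
    seeded random order constrained so that no run of identical flags exceeds
    ``max_run`` — the usual constraint when interleaving opto and control
    trials so neither accumulates in long blocks.
    """
    if not 0.0 <= fraction <= 1.0:
        raise AssignmentError("fraction must be in [0, 1]")
    if max_run < 1:
        raise AssignmentError("max_run must be >= 1")
    n_true = int(round(fraction * n_trials))
    n_false = n_trials - n_true
    if n_true == 0 or n_false == 0:
        # single-class sequence: nothing to interleave, run bound is vacuous
        return np.full(n_trials, n_true > 0, dtype=bool)
    # feasibility: k items in runs <= max_run need at least ceil(k/max_run)-1
    # separators from the other class
    if n_true and -(-n_true // max_run) - 1 > n_false:
        raise AssignmentError("cannot bound True runs with so few False trials")
    if n_false and -(-n_false // max_run) - 1 > n_true:
        raise AssignmentError("cannot bound False runs with so few True trials")
    rng = np.random.default_rng(seed)
    remaining = {True: n_true, False: n_false}
    flags = np.zeros(n_trials, dtype=bool)
    last, run = None, 0
    for i in range(n_trials):
        cands = []
        for c in (True, False):
            if remaining[c] == 0:
                continue
            new_run = run + 1 if c == last else 1
            if new_run > max_run:
                continue
            # can the remainder still be arranged within the run bound?
            n_same, n_other = remaining[c] - 1, remaining[not c]
            if n_same > (max_run - new_run) + n_other * max_run:
                continue
            if n_other > (n_same + 1) * max_run:
                continue
            cands.append(c)
        if not cands:  # pragma: no cover - excluded by the feasibility check
            raise AssignmentError("dead end in run-bounded assignment")
        w = np.array([remaining[c] for c in cands], dtype=float)
        c = cands[rng.choice(len(cands), p=w / w.sum())]
        flags[i] = c
        remaining[c] -= 1
        run = run + 1 if c == last else 1
        last = c
    return flags


def _longest_run(flags: np.ndarray) -> int:
    best = run = 1
    for a, b in zip(flags[:-1], flags[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def apply_opto_flags(events: pd.DataFrame, flags: Sequence[bool]) -> pd.DataFrame:
    """Mark events of opto-flagged trials and add opto_on/opto_off brackets."""
    events = events.copy()
    flags = np.asarray(flags, dtype=bool)
    events["opto"] = flags[events["trial_id"].to_numpy()]
    extra = []
    for tid in np.flatnonzero(flags):
        trial = events[(events.trial_id == tid) & (events.event_type != "click")]
        t0 = trial.onset_s.min()
        t1 = events[events.trial_id == tid].onset_s.max()
        extra.append((t0 - 0.0, "opto_on", tid, True))
        extra.append((t1 + 0.025, "opto_off", tid, True))
    if extra:
        extra_df = pd.DataFrame(
            extra, columns=["onset_s", "event_type", "trial_id", "opto"]
        )
        events = pd.concat([events, extra_df], ignore_index=True)
    return events.sort_values(
        ["onset_s", "event_type"], ignore_index=True, kind="stable"
    )


def build_crossover_design(
    subject_ids: Sequence, treatments: Sequence[str], seed: int | None = None
) -> pd.DataFrame:
    """Randomized cross-over design: every subject receives every treatment
    once, in a per-subject seeded random order.

    Treatment labels of the form ``"MK801+LY@3"`` carry the dose (mg/kg) after
    the ``@``; it is parsed into the ``dose_mg_kg`` column.
    """
    if len(subject_ids) < 1 or len(treatments) < 2:
        raise DesignError("need >= 1 subject and >= 2 treatments")
    if len(set(treatments)) != len(treatments):
        raise DesignError("duplicate treatment labels")
    rng = np.random.default_rng(seed)
    rows = []
    for sid in subject_ids:
        order = rng.permutation(len(treatments))
        for sess, ti in enumerate(order):
            label = treatments[ti]
            dose = float(label.split("@")[1]) if "@" in label else np.nan
            rows.append((sid, sess, label, dose))
    return pd.DataFrame(
        rows, columns=["subject_id", "session_index", "treatment", "dose_mg_kg"]
    )
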