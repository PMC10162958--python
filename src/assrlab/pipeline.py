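"""End-to-end study pipelines: simulate -> analyze -> infer -> report.

Two study layouts mirror the two recording preparations:

* ``study: eeg`` — screw-EEG cross-over: every subject receives every
  treatment; paired-click ERP and 40 Hz steady-state sessions are simulated
  per (subject, treatment), summarised into a tidy metric table, and
  condition contrasts are estimated with the within-subject linear model.
* ``study: tetrode`` — local PV-silencing cross-over (saline vs agonist),
  with 50% light-on trials per session; steady-state metrics per electrode
  and light condition feed a two-way light x drug ANOVA, and simulated units
  are summarised with PSTH/phase-rate metrics.

Outputs are tidy CSVs, a JSON run manifest and a handful of figures; the
whole bundle is a deterministic function of the config and its seed.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .erp import EpochSet, average_erp, erp_metrics, extract_epochs
from .protocol import (
    apply_opto_flags,
    assign_opto_flags,
    build_assr_protocol,
    build_crossover_design,
    build_erp_protocol,
)
from .simulate import condition_params, synth_continuous, synth_spike_trains
from .spectral import PhaseWindows, assr_metrics, band_power, basal_gamma, morlet_tf
from .stats import lsmeans_contrasts, twoway_opto_drug
from .units import classify_opto_suppressed, phase_rates, psth, rate_distribution_stats

__all__ = ["ConfigError", "default_config", "run_pipeline"]


class ConfigError(ValueError):
    pass


def default_config(study: str = "eeg") -> dict:
    """Reference configs for the two study layouts (full-size protocols)."""
    if study == "eeg":
        return {
            "study": "eeg",
            "seed": 0,
            "subjects": 19,
            "treatments": ["vehicle", "MK801", "MK801+LY@1", "MK801+LY@3"],
            "channels": ["AC", "mPFC"],
            "erp": {"n_trials": 300, "iti_s": 8.0, "pair_gap_s": 0.5},
            "assr": {"n_trials": 300, "iti_s": 10.0,
                     "click_rate_hz": 40.0, "train_dur_s": 2.0},
        }
    if study == "tetrode":
        return {
            "study": "tetrode",
            "seed": 0,
            "subjects": 8,
            "treatments": ["saline", "LY@3"],
            "n_electrodes": 3,
            "opto_fraction": 0.5,
            "max_run": 4,
            "assr": {"n_trials": 600, "iti_s": 10.0,
                     "click_rate_hz": 40.0, "train_dur_s": 2.0},
        }
    raise ConfigError(f"study: unknown study kind {study!r}")


def _validate(cfg: dict) -> dict:
    def need(path: str, cond: bool) -> None:
        if not cond:
            raise ConfigError(f"{path}: invalid or missing")

    need("study", cfg.get("study") in ("eeg", "tetrode"))
    need("seed", isinstance(cfg.get("seed"), int))
    need("subjects", isinstance(cfg.get("subjects"), int) and cfg["subjects"] >= 1)
    need("treatments", isinstance(cfg.get("treatments"), list)
         and len(cfg["treatments"]) >= 2)
    assr = cfg.get("assr", {})
    for key in ("n_trials", "iti_s", "click_rate_hz", "train_dur_s"):
        need(f"assr.{key}", key in assr and assr[key] > 0)
    if cfg["study"] == "eeg":
        erp = cfg.get("erp", {})
        for key in ("n_trials", "iti_s", "pair_gap_s"):
            need(f"erp.{key}", key in erp and erp[key] > 0)
        need("channels", bool(cfg.get("channels")))
    else:
        need("n_electrodes", cfg.get("n_electrodes", 0) >= 1)
        need("opto_fraction", 0 < cfg.get("opto_fraction", 0) < 1)
    return cfg


def _session_seed(base: int, *parts) -> int:
    tag = "|".join(str(p) for p in parts)
    return (base * 1_000_003 + zlib.crc32(tag.encode())) % (2**31 - 1)


_ASSR_FREQS = np.arange(35.0, 46.0)
_GAMMA_FREQS_BAND = (30.0, 80.0)


def _eeg_session_metrics(cfg: dict, subject: str, treatment: str,
                         extras: dict | None = None) -> list[dict]:
    params = condition_params(treatment)
    seed_e = _session_seed(cfg["seed"], subject, treatment, "erp")
    seed_a = _session_seed(cfg["seed"], subject, treatment, "assr")
    rows = []

    proto_e, ev_e = build_erp_protocol(**cfg["erp"])
    rec_e = synth_continuous(proto_e, ev_e, params, channels=cfg["channels"],
                             seed=seed_e)
    proto_a, ev_a = build_assr_protocol(**cfg["assr"])
    rec_a = synth_continuous(proto_a, ev_a, params, channels=cfg["channels"],
                             seed=seed_a)
    for ch in cfg["channels"]:
        ep1 = extract_epochs(rec_e, ev_e, "click1", 0.5, 0.5, channel=ch)
        ep2 = extract_epochs(rec_e, ev_e, "click2", 0.5, 0.5, channel=ch)
        m = erp_metrics(ep1, ep2)
        if extras is not None and ch == cfg["channels"][0]:
            extras.setdefault("erp_traces", {})[treatment] = (
                ep1.times, average_erp(ep1))
        tf_click = morlet_tf(ep1, np.arange(30.0, 81.0, 2.0))
        evoked_gamma = band_power(tf_click, _GAMMA_FREQS_BAND, (0.0, 0.1),
                                  mode="evoked")
        ep_bl = extract_epochs(rec_e, ev_e, "click1", 1.6, 0.0, channel=ch)
        bg = basal_gamma(ep_bl)
        ep_tr = extract_epochs(rec_a, ev_a, "train_start", 2.0, 2.5, channel=ch)
        am = assr_metrics(morlet_tf(ep_tr, _ASSR_FREQS))
        vals = {
            "n1_s1": m.n1_amp_s1_uv, "n1_s2": m.n1_amp_s2_uv,
            "latency_s1": m.n1_latency_s1_s, "latency_s2": m.n1_latency_s2_s,
            "gating_ratio": m.gating_ratio, "gating_diff": m.gating_diff_uv,
            "evoked_gamma": evoked_gamma, "basal_gamma": bg,
            "power40_in": am.power40_in, "power40_mp": am.power40_mp,
            "itc40_in": am.itc40_in, "itc40_mp": am.itc40_mp,
            "n_trials_used": m.n_trials_used,
        }
        rows += [{"subject_id": subject, "channel": ch, "treatment": treatment,
                  "opto": False, "metric": k, "value": v}
                 for k, v in vals.items()]
    return rows


def _tetrode_session(cfg: dict, subject: str, treatment: str,
                     extras: dict | None = None
                     ) -> tuple[list[dict], list[dict]]:
    params = condition_params(treatment, opto_model=True)
    seed = _session_seed(cfg["seed"], subject, treatment, "tetrode")
    proto, events = build_assr_protocol(**cfg["assr"])
    flags = assign_opto_flags(proto.n_trials, cfg["opto_fraction"],
                              cfg.get("max_run", 4), seed=seed)
    events = apply_opto_flags(events, flags)
    electrodes = [f"e{i + 1}" for i in range(cfg["n_electrodes"])]
    rec = synth_continuous(proto, events, params, channels=electrodes, seed=seed)
    lfp_rows, unit_rows = [], []
    for ch in electrodes:
        ep = extract_epochs(rec, events, "train_start", 2.0, 2.5, channel=ch)
        ep_bl = extract_epochs(rec, events, "train_start", 1.6, 0.0, channel=ch)
        for opto in (False, True):
            sel = ep.metadata.opto.to_numpy() == opto
            sub = morlet_tf(ep.data[sel], _ASSR_FREQS,
                            sampling_rate_hz=ep.sampling_rate_hz,
                            times_s=ep.times)
            am = assr_metrics(sub)
            bg_sel = ep_bl.metadata.opto.to_numpy() == opto
            bg = basal_gamma(EpochSet(ep_bl.data[bg_sel], ep_bl.times,
                                      ep_bl.sampling_rate_hz, "train_start"))
            vals = {"power40_in": am.power40_in, "power40_mp": am.power40_mp,
                    "itc40_in": am.itc40_in, "itc40_mp": am.itc40_mp,
                    "basal_gamma": bg}
            lfp_rows += [{"subject_id": subject, "electrode": f"{subject}:{ch}",
                          "treatment": treatment, "opto": opto,
                          "metric": k, "value": v} for k, v in vals.items()]
    spikes = synth_spike_trains(proto, events, flags, params, seed=seed + 1)
    onsets = np.sort(
        events.loc[events.event_type == "train_start", "onset_s"].to_numpy())
    on_opto, on_ctrl = onsets[flags], onsets[~flags]
    if extras is not None and "psth_grid" not in extras:
        extras["psth_grid"] = [
            (u.unit_id, psth(u.spike_times_s, on_ctrl, label="light off"),
             psth(u.spike_times_s, on_opto, label="light on"))
            for u in spikes.units[:4]
        ]
    for u in spikes.units:
        pr = {True: phase_rates(u.spike_times_s, on_opto),
              False: phase_rates(u.spike_times_s, on_ctrl)}
        cls = classify_opto_suppressed(pr[False].mp_hz, pr[True].mp_hz,
                                       unit_id=u.unit_id)
        for opto, p in pr.items():
            unit_rows.append({
                "subject_id": subject, "unit_id": f"{subject}:{u.unit_id}",
                "treatment": treatment, "opto": opto,
                "bl_hz": p.bl_hz, "in_hz": p.in_hz, "mp_hz": p.mp_hz,
                "ratio_in_bl": p.ratio_in_bl, "ratio_mp_bl": p.ratio_mp_bl,
                "low_rate": p.low_rate,
                "suppression_index": cls.suppression_index,
                "opto_suppressed": cls.opto_suppressed,
                "pv_true": u.pv,
            })
    return lfp_rows, unit_rows


def _figures(cfg: dict, out: Path, metrics: pd.DataFrame,
             extras: dict) -> list[str]:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    made = []
    if "erp_traces" in extras:
        fig, ax = plt.subplots(figsize=(5, 3))
        for trt, (times, wave) in extras["erp_traces"].items():
            ax.plot(times * 1e3, wave, label=trt, lw=1)
        ax.set_xlabel("time from click (ms)")
        ax.set_ylabel("µV")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "erp_traces.png", dpi=100)
        plt.close(fig)
        made.append("erp_traces.png")
    if "psth_grid" in extras:
        grid = extras["psth_grid"]
        fig, axes = plt.subplots(len(grid), 2, figsize=(6, 2 * len(grid)),
                                 sharex=True, squeeze=False)
        for row, (uid, p_off, p_on) in zip(axes, grid):
            for ax, p in zip(row, (p_off, p_on)):
                ax.bar(p.bin_centers_s, p.rates_hz,
                       width=p.bin_edges_s[1] - p.bin_edges_s[0])
                ax.set_title(f"{uid} {p.label}", fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "psth_grid.png", dpi=100)
        plt.close(fig)
        made.append("psth_grid.png")
    bar_metrics = [m for m in ("n1_s1", "gating_ratio", "basal_gamma",
                               "itc40_mp", "power40_mp")
                   if m in set(metrics.metric)]
    if bar_metrics:
        fig, axes = plt.subplots(1, len(bar_metrics),
                                 figsize=(3 * len(bar_metrics), 3))
        for ax, m in zip(np.atleast_1d(axes), bar_metrics):
            sub = metrics[metrics.metric == m]
            grp = sub.groupby("treatment")["value"]
            mean, sem = grp.mean(), grp.sem()
            ax.bar(range(len(mean)), mean.values, yerr=sem.values, capsize=3)
            ax.set_xticks(range(len(mean)))
            ax.set_xticklabels(mean.index, rotation=45, ha="right", fontsize=7)
            ax.set_title(m, fontsize=9)
        fig.tight_layout()
        fig.savefig(out / "condition_bars.png", dpi=100)
        plt.close(fig)
        made.append("condition_bars.png")
    return made


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Run a full study from a config dict or YAML path; write the report
    bundle into ``out_dir`` and return a manifest dict."""
    if isinstance(config, (str, Path)):
        cfg = yaml.safe_load(Path(config).read_text())
    else:
        cfg = dict(config)
    cfg = _validate(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    subjects = [f"m{i + 1:02d}" for i in range(cfg["subjects"])]
    design = build_crossover_design(subjects, cfg["treatments"],
                                    seed=cfg["seed"])
    design.to_csv(out / "design.csv", index=False)

    files = ["design.csv"]
    extras: dict = {}
    if cfg["study"] == "eeg":
        rows = []
        for sid in subjects:
            for trt in cfg["treatments"]:
                rows += _eeg_session_metrics(
                    cfg, sid, trt, extras if sid == subjects[0] else None)
        metrics = pd.DataFrame(rows)
        metrics.to_csv(out / "metrics.csv", index=False)
        files.append("metrics.csv")
        refs = [t for t in cfg["treatments"] if t == "MK801"]
        con_rows = []
        for (m, ch), _ in metrics.groupby(["metric", "channel"]):
            sub = metrics[(metrics.metric == m) & (metrics.channel == ch)]
            if m == "n_trials_used":
                continue
            for c in lsmeans_contrasts(sub, baseline_label="vehicle",
                                       reference_labels=refs):
                con_rows.append({"metric": m, "channel": ch,
                                 "comparison": c.comparison,
                                 "estimate": c.estimate, "se": c.se,
                                 "t": c.t, "p": c.p, "n": c.n})
        pd.DataFrame(con_rows).to_csv(out / "contrasts.csv", index=False)
        files.append("contrasts.csv")
    else:
        lfp_rows, unit_rows = [], []
        for sid in subjects:
            for trt in cfg["treatments"]:
                lr, ur = _tetrode_session(cfg, sid, trt, extras)
                lfp_rows += lr
                unit_rows += ur
        metrics = pd.DataFrame(lfp_rows)
        metrics.to_csv(out / "metrics.csv", index=False)
        units_df = pd.DataFrame(unit_rows)
        units_df.to_csv(out / "unit_metrics.csv", index=False)
        files += ["metrics.csv", "unit_metrics.csv"]
        aov_rows = []
        for m in sorted(set(metrics.metric)):
            for eff in twoway_opto_drug(metrics[metrics.metric == m]):
                aov_rows.append({"metric": m, "effect": eff.effect,
                                 "F": eff.F, "df_num": eff.df_num,
                                 "df_den": eff.df_den, "p": eff.p})
        pd.DataFrame(aov_rows).to_csv(out / "anova.csv", index=False)
        files.append("anova.csv")
        spread = []
        for (trt, opto), g in units_df.groupby(["treatment", "opto"]):
            for phase in ("bl_hz", "mp_hz"):
                s = rate_distribution_stats(g[phase].to_numpy())
                spread.append({"treatment": trt, "opto": opto,
                               "phase": phase, **s})
        pd.DataFrame(spread).to_csv(out / "rate_spread.csv", index=False)
        files.append("rate_spread.csv")

    files += _figures(cfg, out, metrics, extras)
    manifest = {
        "assrlab_version": __version__,
        "seed": cfg["seed"],
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
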