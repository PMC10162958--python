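"""Condition-level inference for cross-over designs.

The within-subject cross-over (every mouse receives every treatment) is
analysed with a fixed-effects linear model ``value ~ subject + treatment``;
adjusted (least-squares) condition means and pairwise Wald t contrasts come
from the OLS fit. For balanced complete designs the adjusted means coincide
with raw condition means. The tetrode study's 2 x 2 crossing (light x drug,
electrode as replicate) is analysed with a two-way fixed-effects ANOVA with
interaction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContrastResult",
    "EffectTest",
    "lsmeans_contrasts",
    "twoway_opto_drug",
    "adjusted_means",
    "significance_stars",
]


@dataclass(frozen=True)
class ContrastResult:
    metric: str
    comparison: str  # e.g. "MK801 vs vehicle"
    estimate: float
    se: float
    t: float
    p: float
    df: float
    n: int


@dataclass(frozen=True)
class EffectTest:
    metric: str
    effect: str  # "opto", "drug" or "opto:drug"
    F: float
    df_num: float
    df_den: float
    p: float


def significance_stars(p: float) -> str:
    """Figure-caption star rendering: * <0.05, ** <0.01, *** <0.001."""
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def _term_name(level, levels_sorted) -> str | None:
    # patsy drops the alphabetically first level as reference
    return None if level == levels_sorted[0] else f"C(treatment)[T.{level}]"


def _fit_subject_treatment(table: pd.DataFrame) -> sm.regression.linear_model.RegressionResultsWrapper:
    return smf.ols("value ~ C(subject_id) + C(treatment)", data=table).fit()


def adjusted_means(table: pd.DataFrame, metric: str | None = None) -> pd.Series:
    """Least-squares condition means from the subject + treatment model
    (equal weight on every subject)."""
    df = _prep(table, metric)
    res = _fit_subject_treatment(df)
    levels = sorted(df.treatment.unique())
    base = res.params["Intercept"] + np.mean(
        [0.0] + [res.params[f"C(subject_id)[T.{s}]"]
                 for s in sorted(df.subject_id.unique())[1:]]
    )
    out = {}
    for lev in levels:
        term = _term_name(lev, levels)
        out[lev] = base + (res.params[term] if term else 0.0)
    return pd.Series(out)


def _prep(table: pd.DataFrame, metric: str | None) -> pd.DataFrame:
    df = table.copy()
    if metric is not None and "metric" in df.columns:
        df = df[df.metric == metric]
    if df.empty:
        raise ValueError("no rows for requested metric")
    df["subject_id"] = df["subject_id"].astype(str)
    df["treatment"] = df["treatment"].astype(str)
    return df


def lsmeans_contrasts(
    table: pd.DataFrame,
    metric: str | None = None,
    baseline_label: str = "vehicle",
    reference_labels: Sequence[str] = (),
    holm: bool = False,
) -> list[ContrastResult]:
    """Pairwise treatment contrasts from the within-subject linear model.

    Every treatment is contrasted against ``baseline_label`` and against each
    additional label in ``reference_labels`` (e.g. the challenge condition, to
    test rescue). Wald t tests use the OLS residual degrees of freedom.
    Conditions observed only once are skipped with a warning column rather
    than an error. ``holm=True`` applies a Holm step-down adjustment across
    the emitted contrasts.
    """
    df = _prep(table, metric)
    counts = df.treatment.value_counts()
    usable = set(counts[counts >= 2].index)
    res = _fit_subject_treatment(df)
    levels = sorted(df.treatment.unique())
    results = []
    refs = [baseline_label] + [r for r in reference_labels if r != baseline_label]
    for ref in refs:
        if ref not in usable:
            continue
        label_map = {baseline_label: "vs-vehicle"}
        for lev in levels:
            if lev == ref or lev not in usable:
                continue
            terms = []
            t_lev, t_ref = _term_name(lev, levels), _term_name(ref, levels)
            if t_lev:
                terms.append(t_lev)
            if t_ref:
                terms.append(f"- {t_ref}" if terms else f"-{t_ref}")
            tt = res.t_test(" + ".join(terms).replace("+ -", "-") + " = 0")
            results.append(ContrastResult(
                metric=metric or "value",
                comparison=f"{lev} vs {ref}",
                estimate=float(np.squeeze(tt.effect)),
                se=float(np.squeeze(tt.sd)),
                t=float(np.squeeze(tt.tvalue)),
                p=float(np.squeeze(tt.pvalue)),
                df=float(res.df_resid),
                n=int(counts[lev]),
            ))
    if holm and results:
        adj = multipletests([r.p for r in results], method="holm")[1]
        results = [ContrastResult(r.metric, r.comparison, r.estimate, r.se,
                                  r.t, float(p), r.df, r.n)
                   for r, p in zip(results, adj)]
    return results


def twoway_opto_drug(table: pd.DataFrame, metric: str | None = None) -> list[EffectTest]:
    """Two-way fixed-effects ANOVA (light x drug, with interaction) on an
    electrode-replicate table with columns opto (bool), treatment, value."""
    df = table.copy()
    if metric is not None and "metric" in df.columns:
        df = df[df.metric == metric]
    if df.empty:
        raise ValueError("no rows for requested metric")
    cells = df.groupby(["opto", "treatment"]).size()
    if len(cells) < 4 or (cells == 0).any():
        raise ValueError("need all four opto x drug cells populated")
    df = df.assign(opto=df.opto.astype(bool))
    if np.ptp(df.value.to_numpy()) == 0:  # constant data: every SS is zero
        return [EffectTest(metric or "value", e, 0.0, np.nan, np.nan, 1.0)
                for e in ("opto", "drug", "opto:drug")]
    res = smf.ols("value ~ C(opto) * C(treatment)", data=df).fit()
    tab = anova_lm(res, typ=2)
    out = []
    name_map = {"C(opto)": "opto", "C(treatment)": "drug",
                "C(opto):C(treatment)": "opto:drug"}
    for row_name, effect in name_map.items():
        row = tab.loc[row_name]
        F = float(row["F"])
        p = float(row["PR(>F)"])
        if np.isnan(F):  # all-equal data: zero SS everywhere -> F = 0/0
            F, p = 0.0, 1.0
        elif np.isinf(F):  # perfect fit with a real effect
            p = 0.0
        out.append(EffectTest(
            metric=metric or "value", effect=effect, F=F,
            df_num=float(row["df"]), df_den=float(tab.loc["Residual", "df"]),
            p=p,
        ))
    return out
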