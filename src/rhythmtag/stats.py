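"""Group-level statistics: paired t with Bonferroni correction, mixed
(between x within) ANOVA with Greenhouse-Geisser correction, Pearson
correlation, and assembly of the tabular report.

The mixed ANOVA is delegated to :func:`pingouin.mixed_anova`; the
Greenhouse-Geisser epsilon it estimates is applied to the within and
interaction degrees of freedom and the corrected p-values recomputed from
the F distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "MixedAnovaResult",
    "paired_t_bonferroni",
    "mixed_anova_gg",
    "pearson_r",
    "build_report",
]


@dataclass
class TTestResult:
    t: float
    df: int
    p_raw: float
    p_adjusted: float


@dataclass
class AnovaEffect:
    F: float
    df1: float
    df2: float
    p: float


@dataclass
class MixedAnovaResult:
    between: AnovaEffect
    within: AnovaEffect
    interaction: AnovaEffect
    gg_epsilon: float


def paired_t_bonferroni(values_a, values_b, m_comparisons: int = 1) -> TTestResult:
    """Two-sided paired t-test with Bonferroni adjustment over a family of
    ``m_comparisons`` tests."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    if m_comparisons < 1:
        raise ValueError("m_comparisons must be >= 1")
    res = sps.ttest_rel(a, b)
    t = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(t):  # zero variance of differences (identical vectors)
        t, p = 0.0, 1.0
    return TTestResult(t=t, df=len(a) - 1, p_raw=p, p_adjusted=min(1.0, m_comparisons * p))


def mixed_anova_gg(
    table: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    between: str,
) -> MixedAnovaResult:
    """Mixed-design ANOVA (one between-subject, one repeated factor) with
    Greenhouse-Geisser-corrected within/interaction tests.

    ``table`` is long-format with one row per subject x within-level.
    Epsilon is 1 exactly when the repeated factor has two levels.
    """
    k = table[within].nunique()
    if k < 2 or table[between].nunique() < 2:
        raise ValueError("need >= 2 within levels and >= 2 groups")
    aov = pg.mixed_anova(
        data=table, dv=dv, within=within, subject=subject, between=between,
        correction=False,
    )
    aov = aov.set_index("Source")
    wide = table.pivot(index=subject, columns=within, values=dv)
    eps = 1.0 if k == 2 else float(pg.epsilon(wide, correction="gg"))
    eps = min(max(eps, 1.0 / (k - 1)), 1.0)

    def effect(row, corrected: bool) -> AnovaEffect:
        F = float(aov.loc[row, "F"])
        df1 = float(aov.loc[row, "DF1"])
        df2 = float(aov.loc[row, "DF2"])
        if corrected:
            df1, df2 = df1 * eps, df2 * eps
        return AnovaEffect(F=F, df1=df1, df2=df2, p=float(sps.f.sf(F, df1, df2)))

    return MixedAnovaResult(
        between=effect(between, corrected=False),
        within=effect(within, corrected=True),
        interaction=effect("Interaction", corrected=True),
        gg_epsilon=eps,
    )


def pearson_r(x, y):
    """Sample Pearson correlation with two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def build_report(
    cohort: pd.DataFrame,
    out_dir,
    tagged_hz,
    related_hz,
    unrelated_hz,
    group_col: str = "group",
    posthoc_alpha: float = 0.10,
) -> dict:
    """Assemble the group-level comparison tables from a cohort table.

    ``cohort`` needs one row per subject with columns ``subject_id``,
    ``group_col``, ``included``, ``noise_floor``, ``amp_<f>`` for each
    tagged frequency and (optionally) ``auc_left``/``auc_right``.

    Writes CSV tables plus a plain-text exclusion log under ``out_dir`` and
    returns the tables in a dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    required = {"subject_id", group_col, "included", "noise_floor"} | {
        f"amp_{f}" for f in tagged_hz
    }
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    d = cohort[cohort["included"]].reset_index(drop=True)
    tables = {}

    # 1. Each tagged frequency vs the noise floor (Bonferroni family).
    rows = []
    for f in tagged_hz:
        res = paired_t_bonferroni(d[f"amp_{f}"], d["noise_floor"], len(tagged_hz))
        rows.append(
            {"frequency_hz": f, "t": res.t, "df": res.df,
             "p_raw": res.p_raw, "p_bonferroni": res.p_adjusted}
        )
    tables["ssep_vs_noise_floor"] = pd.DataFrame(rows)

    # 2. Beat/meter-related vs unrelated contrast.
    rel = d[[f"amp_{f}" for f in related_hz]].mean(axis=1)
    unrel = d[[f"amp_{f}" for f in unrelated_hz]].mean(axis=1)
    c = paired_t_bonferroni(rel, unrel, 1)
    tables["related_vs_unrelated"] = pd.DataFrame(
        [{"t": c.t, "df": c.df, "p": c.p_raw,
          "mean_related": rel.mean(), "mean_unrelated": unrel.mean()}]
    )

    # 3. Group x frequency mixed ANOVA plus per-frequency post-hoc t-tests.
    long = d.melt(
        id_vars=["subject_id", group_col],
        value_vars=[f"amp_{f}" for f in tagged_hz],
        var_name="frequency", value_name="amplitude",
    )
    aov = mixed_anova_gg(long, "amplitude", "frequency", "subject_id", group_col)
    tables["group_by_frequency_anova"] = pd.DataFrame(
        [
            {"effect": "group", "F": aov.between.F, "df1": aov.between.df1,
             "df2": aov.between.df2, "p": aov.between.p, "gg_epsilon": np.nan},
            {"effect": "frequency", "F": aov.within.F, "df1": aov.within.df1,
             "df2": aov.within.df2, "p": aov.within.p, "gg_epsilon": aov.gg_epsilon},
            {"effect": "interaction", "F": aov.interaction.F,
             "df1": aov.interaction.df1, "df2": aov.interaction.df2,
             "p": aov.interaction.p, "gg_epsilon": aov.gg_epsilon},
        ]
    )
    groups = sorted(d[group_col].unique())
    rows = []
    for f in tagged_hz:
        a = d.loc[d[group_col] == groups[0], f"amp_{f}"]
        b = d.loc[d[group_col] == groups[1], f"amp_{f}"]
        t, p = sps.ttest_ind(a, b)
        p_adj = min(1.0, len(tagged_hz) * p)
        rows.append(
            {"frequency_hz": f, "t": float(t), "df": len(a) + len(b) - 2,
             "p_raw": float(p), "p_bonferroni": p_adj,
             "significant": p_adj < posthoc_alpha}
        )
    tables["posthoc_group_by_frequency"] = pd.DataFrame(rows)

    # 4. ERP: group x hemisphere ANOVA (2 within levels -> epsilon 1).
    if {"auc_left", "auc_right"} <= set(d.columns):
        erp_long = d.melt(
            id_vars=["subject_id", group_col],
            value_vars=["auc_left", "auc_right"],
            var_name="hemisphere", value_name="auc",
        )
        e = mixed_anova_gg(erp_long, "auc", "hemisphere", "subject_id", group_col)
        tables["erp_anova"] = pd.DataFrame(
            [
                {"effect": "group", "F": e.between.F, "df1": e.between.df1,
                 "df2": e.between.df2, "p": e.between.p},
                {"effect": "hemisphere", "F": e.within.F, "df1": e.within.df1,
                 "df2": e.within.df2, "p": e.within.p},
                {"effect": "interaction", "F": e.interaction.F,
                 "df1": e.interaction.df1, "df2": e.interaction.df2,
                 "p": e.interaction.p},
            ]
        )

    # 5. Correlations with music-background measures.
    rows = []
    if {"auc_left", "auc_right", "parent_training_years"} <= set(d.columns):
        erp_mag = (d["auc_left"] + d["auc_right"]) / 2.0
        r, p = pearson_r(d["parent_training_years"], erp_mag)
        rows.append({"x": "parent_training_years", "y": "erp_auc_mean", "r": r, "p": p})
    if "listening_hours" in d.columns:
        for f in tagged_hz:
            r, p = pearson_r(d["listening_hours"], d[f"amp_{f}"])
            rows.append({"x": "listening_hours", "y": f"amp_{f}", "r": r, "p": p})
    if rows:
        tables["correlations"] = pd.DataFrame(rows)

    for name, tab in tables.items():
        tab.to_csv(out_dir / f"{name}.csv", index=False)
    excluded = cohort.loc[~cohort["included"], "subject_id"].tolist()
    with open(out_dir / "exclusions.txt", "w") as fh:
        if excluded:
            fh.write("excluded subjects (|z| > cutoff):\n")
            fh.writelines(f"  {s}\n" for s in excluded)
        else:
            fh.write("no subjects excluded\n")
    return tables
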