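"""Statistical comparisons for shared-word scores and response lengths.

Two-sample Welch contrasts, a same/other x dataset factorial analysis,
Pearson correlation, contingency-table tests, and linear mixed models with
participant and clip as *fully crossed* random factors.

Crossed random effects are fitted with statsmodels' ``MixedLM`` by placing
all observations in one super-group and declaring participant and clip as
variance components — the standard construction for non-nested grouping
factors.  Estimation is REML by default (ML available for nested-model
comparisons); fixed-effect p-values are Wald tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .scoring import SharedWordResult

__all__ = [
    "EffectEstimate",
    "FactorialResult",
    "welch_t",
    "same_other_factorial",
    "pearson_r",
    "contingency_test",
    "demographic_effects",
]


@dataclass(frozen=True)
class EffectEstimate:
    """One fixed-effect estimate from a demographic model."""

    term: str
    coefficient: float
    standard_error: float
    p_value: float
    conf_low: float = math.nan
    conf_high: float = math.nan
    metadata: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class FactorialResult:
    """Two-way fixed-effects analysis of scores: comparison x dataset."""

    f_comparison: float
    p_comparison: float
    f_dataset: float
    p_dataset: float
    f_interaction: float
    p_interaction: float
    df_num: int
    df_den: int
    cell_means: pd.DataFrame


def welch_t(
    sample_x: Sequence[float], sample_y: Sequence[float]
) -> tuple[float, float, float]:
    """Welch's unequal-variance t test with Satterthwaite df; two-sided p."""
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least two values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        raise ValueError("both samples have zero variance; t is undefined")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def pearson_r(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Product-moment correlation with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least three paired values")
    if x.var() == 0.0 or y.var() == 0.0:
        raise ValueError("correlation undefined for a constant input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def contingency_test(
    table: Sequence[Sequence[int]], method: str = "chi2"
) -> tuple[float, int, float]:
    """Test of independence on an r x c count table.

    ``chi2`` (default) is Pearson's chi-square *without* continuity
    correction; ``fisher`` gives Fisher's exact test (2x2 only, statistic is
    the odds ratio, df reported as 1).  Rows/columns that are entirely zero
    are dropped; a warning is raised when any expected cell count is below 5.
    """
    arr = np.asarray(table, dtype=float)
    if np.any(arr < 0) or np.any(arr != np.floor(arr)):
        raise ValueError("table must contain nonnegative integer counts")
    arr = arr[arr.sum(axis=1) > 0][:, arr.sum(axis=0) > 0]
    if arr.size == 0:
        raise ValueError("table has no counts")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need at least two non-empty rows and columns")
    if method == "fisher":
        if arr.shape != (2, 2):
            raise ValueError("Fisher's exact test requires a 2x2 table")
        odds, p = stats.fisher_exact(arr)
        return float(odds), 1, float(p)
    if method != "chi2":
        raise ValueError(f"unknown method {method!r}")
    res = stats.chi2_contingency(arr, correction=False)
    if np.any(res.expected_freq < 5):
        warnings.warn(
            "expected cell count below 5; chi-square approximation may be poor",
            stacklevel=2,
        )
    return float(res.statistic), int(res.dof), float(res.pvalue)


def _long_scores(results: Sequence[SharedWordResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        if not math.isnan(r.mean_same):
            rows.append((r.response_id, r.dataset_label, "same", r.mean_same))
        if not math.isnan(r.mean_other):
            rows.append((r.response_id, r.dataset_label, "other", r.mean_other))
    return pd.DataFrame(
        rows, columns=["response_id", "dataset", "comparison", "score"]
    )


def same_other_factorial(
    results: Sequence[SharedWordResult], paired: bool = False
) -> FactorialResult:
    """Factorial analysis of shared-word scores: same/other x dataset.

    Each response contributes two observations — its same-clip and other-clip
    mean scores — crossed with its dataset label; a two-way fixed-effects
    model with interaction is fitted on the long-format scores.  With
    ``paired`` on, or when only one dataset is present, the analysis reduces
    to a paired same-vs-other contrast (reported as F = t^2 on 1 df).
    """
    long = _long_scores(results)
    if long.empty or long["score"].var() == 0.0:
        raise ValueError("scores are constant; no variance to analyse")
    datasets = long["dataset"].unique()
    cell_means = (
        long.groupby(["dataset", "comparison"], sort=True)["score"]
        .mean()
        .reset_index()
    )
    if paired or len(datasets) < 2:
        if len(datasets) < 2:
            warnings.warn(
                "single dataset: reducing to a paired same/other contrast",
                stacklevel=2,
            )
        wide = long.pivot(index="response_id", columns="comparison", values="score")
        wide = wide.dropna()
        res = stats.ttest_rel(wide["same"], wide["other"])
        f = float(res.statistic) ** 2
        df_den = len(wide) - 1
        p = float(res.pvalue)
        return FactorialResult(
            f_comparison=f,
            p_comparison=p,
            f_dataset=math.nan,
            p_dataset=math.nan,
            f_interaction=math.nan,
            p_interaction=math.nan,
            df_num=1,
            df_den=df_den,
            cell_means=cell_means,
        )
    model = smf.ols("score ~ C(comparison) * C(dataset)", data=long).fit()
    table = anova_lm(model, typ=2)
    f_comp = table.loc["C(comparison)"]
    f_ds = table.loc["C(dataset)"]
    f_int = table.loc["C(comparison):C(dataset)"]
    return FactorialResult(
        f_comparison=float(f_comp["F"]),
        p_comparison=float(f_comp["PR(>F)"]),
        f_dataset=float(f_ds["F"]),
        p_dataset=float(f_ds["PR(>F)"]),
        f_interaction=float(f_int["F"]),
        p_interaction=float(f_int["PR(>F)"]),
        df_num=1,
        df_den=int(table.loc["Residual", "df"]),
        cell_means=cell_means,
    )


def demographic_effects(
    data: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str] = ("age", "gender", "education"),
    participant_col: str = "participant_id",
    clip_col: str = "clip_id",
    reml: bool = True,
    center_age: bool = True,
) -> list[EffectEstimate]:
    """Fixed demographic effects with participant and clip crossed random factors.

    ``data`` holds one row per response with the outcome (e.g. ``mean_same``
    or ``word_count``), the demographic predictors, and participant/clip
    identifiers.  Gender is coded with female as the reference level (the
    returned term is ``male``); education enters as an ordinal integer; age in
    years, centered by default.  Returns one :class:`EffectEstimate` per fixed
    effect (intercept included), each carrying model metadata (method,
    variance components).

    Raises on rank-deficient fixed-effect designs, naming the collinear
    terms.
    """
    df = data.copy()
    needed = {outcome, participant_col, clip_col, *predictors}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = df.dropna(subset=[outcome])
    if df.empty:
        raise ValueError("no rows with a defined outcome")

    terms: list[str] = []
    for p in predictors:
        if p == "gender":
            vals = df["gender"].astype(str).str.lower()
            df["male"] = (vals.str[0] == "m").astype(float)
            terms.append("male")
        elif p == "age" and center_age:
            df["age_c"] = df["age"] - df["age"].mean()
            terms.append("age_c")
        elif p == "dataset":
            levels = sorted(df["dataset"].astype(str).unique())
            if len(levels) > 1:
                ref = levels[0]
                for lv in levels[1:]:
                    col = f"dataset_{lv}"
                    df[col] = (df["dataset"].astype(str) == lv).astype(float)
                    terms.append(col)
        else:
            df[p] = df[p].astype(float)
            terms.append(p)

    X = np.column_stack([np.ones(len(df))] + [df[t].to_numpy(float) for t in terms])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the offending columns: those whose removal restores full rank
        bad = []
        for j, t in enumerate(terms, start=1):
            Xr = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(Xr) == Xr.shape[1]:
                bad.append(t)
        raise ValueError(
            f"rank-deficient fixed-effect design; collinear terms: {bad or terms}"
        )

    if df[outcome].var() == 0.0:
        # degenerate but well-defined: a constant outcome has no effects
        const = float(df[outcome].iloc[0])
        meta = {"method": "REML" if reml else "ML", "degenerate": True,
                "n_obs": int(len(df))}
        return [
            EffectEstimate("intercept", const, 0.0, math.nan, const, const, meta)
        ] + [
            EffectEstimate({"age_c": "age"}.get(t, t), 0.0, 0.0, 1.0, 0.0, 0.0, meta)
            for t in terms
        ]

    df["_group"] = 1
    df["_participant"] = df[participant_col].astype(str)
    df["_clip"] = df[clip_col].astype(str)
    formula = f"{outcome} ~ " + " + ".join(terms)
    vc = {
        "participant": "0 + C(_participant)",
        "clip": "0 + C(_clip)",
    }
    model = smf.mixedlm(formula, df, groups="_group", vc_formula=vc, re_formula="0")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=reml, method="lbfgs", maxiter=200)
    meta = {
        "method": "REML" if reml else "ML",
        "converged": bool(fit.converged),
        "vc_participant": float(fit.vcomp[0]) if len(fit.vcomp) > 0 else math.nan,
        "vc_clip": float(fit.vcomp[1]) if len(fit.vcomp) > 1 else math.nan,
        "resid_var": float(fit.scale),
        "n_obs": int(len(df)),
    }
    out = []
    zcrit = stats.norm.ppf(0.975)
    for name in fit.fe_params.index:
        coef = float(fit.fe_params[name])
        se = float(fit.bse_fe[name])
        z = coef / se if se > 0 else math.inf
        p = float(2.0 * stats.norm.sf(abs(z)))
        out.append(
            EffectEstimate(
                term={"Intercept": "intercept", "age_c": "age"}.get(name, name),
                coefficient=coef,
                standard_error=se,
                p_value=p,
                conf_low=coef - zcrit * se,
                conf_high=coef + zcrit * se,
                metadata=meta,
            )
        )
    return out
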