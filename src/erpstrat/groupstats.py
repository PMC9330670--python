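"""Group-level inference on ERP contrasts.

Split-plot (repeated-measures) ANOVA with a 2-level within-subject factor
(condition) and a 3-level between-subject factor (outcome group), optional
extra between factor (cohort), covariate adjustment, and Welch post-hoc
t-tests with pooled-SD Cohen's d and Sidak correction.

With exactly two within-subject levels the design decomposes exactly:
between-subject effects are a one-way ANOVA on subject means, and the
condition effect and all condition-by-group interactions are an ANOVA on
per-subject difference scores (sphericity is vacuous with two levels).
Both parts use Type-III sums of squares with sum-coded factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm


@dataclass
class AnovaResult:
    effect: str
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float


def _anova_results(df: pd.DataFrame, response: str, rhs: str, label_map: dict,
                   prefix: str = "") -> list:
    y = df[response].to_numpy(dtype=float)
    if y.var() < 1e-24 * (1.0 + abs(y.mean())) ** 2:
        # constant response: every effect is null by convention
        df_resid = len(df) - 1
        return [AnovaResult(prefix + label, 0.0, 1, df_resid, 1.0, 0.0)
                for label in label_map.values()]
    model = smf.ols(f"{response} ~ {rhs}", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tab = anova_lm(model, typ=3)
    ss_resid = float(tab.loc["Residual", "sum_sq"])
    df_resid = int(tab.loc["Residual", "df"])
    out = []
    for term, label in label_map.items():
        if term not in tab.index:
            continue
        ss = float(tab.loc[term, "sum_sq"])
        F = float(tab.loc[term, "F"])
        p = float(tab.loc[term, "PR(>F)"])
        if not np.isfinite(F):  # degenerate data (e.g. all values identical)
            F, p = 0.0, 1.0
        eta = ss / (ss + ss_resid) if (ss + ss_resid) > 0 else 0.0
        out.append(AnovaResult(prefix + label, F, int(tab.loc[term, "df"]),
                               df_resid, p, eta))
    return out


def _prep(values, group, extra_between):
    V = np.asarray(values, dtype=float)
    if V.ndim != 2 or V.shape[1] != 2:
        raise ValueError("values must be n x 2 (two within-subject conditions)")
    group = np.asarray(group)
    keep = ~np.isnan(V).any(axis=1)
    if (~keep).any():
        warnings.warn(f"dropping {int((~keep).sum())} subjects with a missing condition value")
    df = pd.DataFrame({
        "m": V[keep].mean(axis=1),
        "d": V[keep, 1] - V[keep, 0],
        "group": group[keep],
    })
    if extra_between is not None:
        df["cohort"] = np.asarray(extra_between)[keep]
    for g, sub in df.groupby("group"):
        if len(sub) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 complete subjects")
    return df


def splitplot_anova(values, group, extra_between=None) -> list:
    """Split-plot ANOVA: condition (2 within) x group (+ optional cohort).

    ``values`` is n x 2 (condition order fixed by the caller); returns the
    between-group test(s), the condition main effect, and the
    condition-by-group interaction(s).  The interaction F equals the one-way
    ANOVA F on difference scores by construction.
    """
    df = _prep(values, group, extra_between)
    if extra_between is None:
        rhs = "C(group, Sum)"
        between = {"C(group, Sum)": "group"}
        within = {"Intercept": "condition", "C(group, Sum)": "condition:group"}
    else:
        rhs = "C(group, Sum) * C(cohort, Sum)"
        between = {"C(group, Sum)": "group", "C(cohort, Sum)": "cohort",
                   "C(group, Sum):C(cohort, Sum)": "group:cohort"}
        within = {"Intercept": "condition", "C(group, Sum)": "condition:group",
                  "C(cohort, Sum)": "condition:cohort",
                  "C(group, Sum):C(cohort, Sum)": "condition:group:cohort"}
    results = _anova_results(df, "m", rhs, between)
    results += _anova_results(df, "d", rhs, within)
    return results


def ancova_adjust(values, group, covariates, extra_between=None) -> list:
    """Same split-plot tests with covariates entered into both submodels.

    ``covariates`` is an n x q array (complete, post-imputation); constant
    or collinear covariate columns are dropped with a warning.
    """
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != np.asarray(values).shape[0]:
        C = C.T
    keep_cols = []
    for j in range(C.shape[1]):
        col = C[:, j]
        if np.nanstd(col) < 1e-12:
            warnings.warn(f"covariate {j} is constant; dropped")
            continue
        cand = C[:, keep_cols + [j]]
        if np.linalg.matrix_rank(cand - cand.mean(axis=0)) < len(keep_cols) + 1:
            warnings.warn(f"covariate {j} is collinear; dropped")
            continue
        keep_cols.append(j)
    df = _prep(values, group, extra_between)
    V = np.asarray(values, dtype=float)
    mask = ~np.isnan(V).any(axis=1)
    cov_terms = []
    for idx, j in enumerate(keep_cols):
        name = f"cov{idx}"
        df[name] = C[mask, j]
        cov_terms.append(name)
    cov_rhs = ("" if not cov_terms else " + ".join(cov_terms) + " + ")
    if extra_between is None:
        rhs = cov_rhs + "C(group, Sum)"
        between = {"C(group, Sum)": "group"}
        within = {"Intercept": "condition", "C(group, Sum)": "condition:group"}
    else:
        rhs = cov_rhs + "C(group, Sum) * C(cohort, Sum)"
        between = {"C(group, Sum)": "group", "C(cohort, Sum)": "cohort",
                   "C(group, Sum):C(cohort, Sum)": "group:cohort"}
        within = {"Intercept": "condition", "C(group, Sum)": "condition:group",
                  "C(cohort, Sum)": "condition:cohort",
                  "C(group, Sum):C(cohort, Sum)": "condition:group:cohort"}
    results = _anova_results(df, "m", rhs, between)
    results += _anova_results(df, "d", rhs, within)
    return results


def cohens_d(a, b) -> float:
    """Pooled-SD standardized mean difference (positive when mean(a) > mean(b))."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 <= 0:
        return np.nan  # d undefined: zero variance in both groups
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def sidak(p: float, m: int) -> float:
    """Sidak family adjustment: p_adj = 1 - (1 - p)^m, clipped to [p, 1]."""
    if m < 1:
        raise ValueError("family size must be >= 1")
    return float(min(1.0, max(p, 1.0 - (1.0 - p) ** m)))


def posthoc_d(a, b, family_m: int = 1) -> dict:
    """Welch t-test plus pooled-SD Cohen's d and Sidak-adjusted p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    d = cohens_d(a, b)
    return {"t": float(t), "p": float(p), "p_sidak": sidak(float(p), family_m),
            "d": d}


def pairwise_posthoc(values_by_group: dict) -> pd.DataFrame:
    """All pairwise group contrasts; the Sidak family is the set of pairs."""
    names = list(values_by_group)
    pairs = [(i, j) for i in range(len(names)) for j in range(i + 1, len(names))]
    rows = []
    for i, j in pairs:
        res = posthoc_d(values_by_group[names[i]], values_by_group[names[j]],
                        family_m=len(pairs))
        rows.append({"group_a": names[i], "group_b": names[j], **res})
    return pd.DataFrame(rows)
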