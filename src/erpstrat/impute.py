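"""Eligibility filtering and EM imputation of missing ERP features.

Subjects qualify for the individual-level analyses when at least 70% of
their ERP feature cells are observed.  Remaining missing entries are
imputed by maximum-likelihood expectation-maximization under a single
multivariate Gaussian over the ERP features (gender/age and metadata are
excluded from the imputation model and used only for the missing-at-random
diagnostics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synth import averaged_feature_names, erp_feature_names, recompute_contrasts


@dataclass
class ImputationModel:
    """Fitted Gaussian (mean, covariance) with the EM log-likelihood trace."""

    mean: np.ndarray
    cov: np.ndarray
    loglik_trace: list = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    feature_cols: list = field(default_factory=list)


def _erp_cols(table: pd.DataFrame, feature_cols=None) -> list:
    if feature_cols is not None:
        return list(feature_cols)
    inv = set(erp_feature_names())
    return [c for c in table.columns if c in inv]


def eligibility_filter(table: pd.DataFrame, min_fraction: float = 0.70,
                       feature_cols=None) -> pd.DataFrame:
    """Keep rows with an observed ERP-feature fraction >= ``min_fraction``.

    The boundary is inclusive; metadata columns never enter the denominator.
    """
    cols = _erp_cols(table, feature_cols)
    frac = table[cols].notna().mean(axis=1)
    return table.loc[frac >= min_fraction - 1e-12].copy()


def _pattern_groups(M: np.ndarray):
    """Group row indices by missingness pattern."""
    keys = {}
    for i, row in enumerate(M):
        keys.setdefault(row.tobytes(), []).append(i)
    patterns = []
    for key, rows in keys.items():
        patterns.append((np.frombuffer(key, dtype=bool).copy(), np.array(rows)))
    return patterns


def _safe_cho(S: np.ndarray):
    """Cholesky with ridge fallback (1e-8 * trace/p) for singular blocks."""
    from scipy.linalg import cho_factor

    try:
        return cho_factor(S, lower=True), 0.0
    except np.linalg.LinAlgError:
        pass
    ridge = 1e-8 * np.trace(S) / max(S.shape[0], 1)
    ridge = ridge if ridge > 0 else 1e-10
    warnings.warn("singular observed-block covariance; ridge-regularized inverse")
    return cho_factor(S + ridge * np.eye(S.shape[0]), lower=True), ridge


def em_impute(table: pd.DataFrame, tol: float = 1e-6, max_iter: int = 500,
              feature_cols=None) -> tuple:
    """EM imputation under a multivariate Gaussian over the ERP features.

    E-step fills missing cells with conditional expectations given the
    observed cells under the current (mu, Sigma) and accumulates the
    conditional-covariance correction; M-step re-estimates (mu, Sigma).
    Iterates until the relative observed-data log-likelihood change drops
    below ``tol``.  The returned table carries conditional means at
    convergence; a decreasing log-likelihood raises (implementation-bug
    signal).

    The Gaussian covers the averaged condition features only: differential
    features are exact parent differences (a singular direction for a
    covariance model), so they are recomputed from the imputed parents
    afterwards.
    """
    from scipy.linalg import cho_solve

    if feature_cols is None:
        avg = set(averaged_feature_names())
        feature_cols = [c for c in table.columns if c in avg] or None
    cols = _erp_cols(table, feature_cols)
    X = table[cols].to_numpy(dtype=float)
    n, p = X.shape
    M = np.isnan(X)
    for j in range(p):
        if (~M[:, j]).sum() < 2:
            raise ValueError(f"feature {cols[j]!r} observed in fewer than 2 rows")
    # init: column means / covariance of mean-filled data
    mu = np.nanmean(X, axis=0)
    X0 = np.where(M, mu, X)
    Sigma = np.cov(X0, rowvar=False, bias=True) + 1e-6 * np.eye(p)
    patterns = _pattern_groups(M)
    trace = []
    converged = False
    Ximp = X0
    it = 0
    for it in range(1, max_iter + 1):
        Ximp = np.where(M, 0.0, X)
        Ccorr = np.zeros((p, p))
        ll = 0.0
        for miss, rows in patterns:
            obs = ~miss
            o = np.where(obs)[0]
            m = np.where(miss)[0]
            Xo = X[np.ix_(rows, o)]
            dev = Xo - mu[o]
            (cf, _r) = _safe_cho(Sigma[np.ix_(o, o)])
            # observed-data log-likelihood for this pattern
            solved = cho_solve(cf, dev.T)
            logdet = 2.0 * np.log(np.diag(cf[0])).sum()
            ll += (-0.5 * (dev.T * solved).sum()
                   - 0.5 * rows.size * (logdet + o.size * np.log(2 * np.pi)))
            Ximp[np.ix_(rows, o)] = Xo
            if m.size:
                B = cho_solve(cf, Sigma[np.ix_(o, m)])  # (|o|, |m|)
                cond_mean = mu[m] + dev @ B
                Ximp[np.ix_(rows, m)] = cond_mean
                cond_cov = Sigma[np.ix_(m, m)] - Sigma[np.ix_(m, o)] @ B
                Ccorr[np.ix_(m, m)] += rows.size * cond_cov
        trace.append(ll)
        if len(trace) > 1:
            if ll < trace[-2] - 1e-8 * (1.0 + abs(trace[-2])):
                raise RuntimeError("EM log-likelihood decreased (implementation bug)")
            if abs(ll - trace[-2]) < tol * (1.0 + abs(ll)):
                converged = True
                break
        if not M.any():
            converged = True
            break
        mu = Ximp.mean(axis=0)
        dev_full = Ximp - mu
        Sigma = (dev_full.T @ dev_full + Ccorr) / n
    model = ImputationModel(mean=mu.copy(), cov=Sigma.copy(), loglik_trace=trace,
                            converged=converged, n_iter=it, feature_cols=cols)
    out = table.copy()
    out[cols] = Ximp
    recompute_contrasts(out)
    return out, model


def apply_imputation(model: ImputationModel, table: pd.DataFrame) -> pd.DataFrame:
    """Impute a (holdout) table with previously fitted parameters only."""
    from scipy.linalg import cho_solve

    cols = model.feature_cols
    X = table[cols].to_numpy(dtype=float)
    M = np.isnan(X)
    mu, Sigma = model.mean, model.cov
    for miss, rows in _pattern_groups(M):
        m = np.where(miss)[0]
        if not m.size:
            continue
        o = np.where(~miss)[0]
        if o.size == 0:
            X[np.ix_(rows, m)] = mu[m]
            continue
        (cf, _r) = _safe_cho(Sigma[np.ix_(o, o)])
        B = cho_solve(cf, Sigma[np.ix_(o, m)])
        X[np.ix_(rows, m)] = mu[m] + (X[np.ix_(rows, o)] - mu[o]) @ B
    out = table.copy()
    out[cols] = X
    recompute_contrasts(out)
    return out


def mar_diagnostics(table: pd.DataFrame, continuous=("age", "outcome"),
                    categorical=("gender", "diagnosis"),
                    feature_cols=None) -> pd.DataFrame:
    """Compare complete vs incomplete rows on covariates.

    Welch t-tests for continuous covariates and chi-square tests for
    categorical ones; a covariate whose contingency degenerates (single
    level, or fewer than 2 rows on a side) is flagged not-computable.
    """
    cols = _erp_cols(table, feature_cols)
    complete = table[cols].notna().all(axis=1)
    rows = []
    too_small = complete.sum() < 2 or (~complete).sum() < 2
    for cov in continuous:
        if cov not in table.columns:
            continue
        if too_small:
            rows.append({"covariate": cov, "kind": "continuous", "stat": np.nan,
                         "df": np.nan, "p": np.nan, "flag": "not-computable"})
            continue
        a = table.loc[complete, cov].dropna()
        b = table.loc[~complete, cov].dropna()
        res = stats.ttest_ind(a, b, equal_var=False)
        df = res.df if hasattr(res, "df") else np.nan
        rows.append({"covariate": cov, "kind": "continuous",
                     "stat": float(res.statistic), "df": float(df),
                     "p": float(res.pvalue), "flag": "ok"})
    for cov in categorical:
        if cov not in table.columns:
            continue
        if too_small:
            rows.append({"covariate": cov, "kind": "categorical", "stat": np.nan,
                         "df": np.nan, "p": np.nan, "flag": "not-computable"})
            continue
        ct = pd.crosstab(complete, table[cov])
        if ct.shape[1] < 2 or ct.shape[0] < 2:
            rows.append({"covariate": cov, "kind": "categorical", "stat": np.nan,
                         "df": np.nan, "p": np.nan, "flag": "not-computable"})
            continue
        chi2, pval, df, _ = stats.chi2_contingency(ct)
        rows.append({"covariate": cov, "kind": "categorical", "stat": float(chi2),
                     "df": float(df), "p": float(pval), "flag": "ok"})
    return pd.DataFrame(rows)
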