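"""Elastic-net prediction of a continuous social-functioning outcome.

Objective (standard units, X standardized):

    (1/2n) * ||y - b0 - X b||^2 + lam * (alpha * ||b||_1 + (1-alpha)/2 * ||b||_2^2)

with the penalty weight lam selected per outer fold by repeated inner
k-fold cross-validation minimizing RMSE, leave-one-out outer
cross-validation for the honest performance estimate, and feature relevance
read off as the coefficients selected (nonzero) in every outer fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet, enet_path
from sklearn.model_selection import RepeatedKFold

from .synth import derive_seed

DEFAULT_ALPHA_GRID = (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)


@dataclass
class ElasticNetFit:
    coef: np.ndarray
    intercept: float
    lam: float
    alpha: float
    objective: float
    converged: bool = True


@dataclass
class PredictionReport:
    rmse: float
    rmse_ci: tuple
    relative_error: float
    pearson_r: float
    slope: float
    slope_t: float
    slope_p: float
    shapiro_p: float
    breusch_pagan_p: float
    shuffle_p: float | None
    predictions: np.ndarray
    observed: np.ndarray
    coef_matrix: pd.DataFrame
    chosen_params: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(X: pd.DataFrame, skew_threshold: float = 0.7):
    """Skew check, optional log transform, and standardization.

    Predictors with |sample skewness| >= ``skew_threshold`` are shifted to
    positive support and log1p-transformed; all predictors are then
    standardized to mean 0, SD 1.  Zero-variance predictors are dropped
    with a warning.  Returns (standardized table, info dict with the fitted
    transform parameters so the identical transform can be applied to new
    rows).
    """
    X = pd.DataFrame(X).copy()
    info = {"skew": {}, "transformed": [], "dropped": [], "shift": {},
            "mean": {}, "sd": {}}
    for col in list(X.columns):
        v = X[col].to_numpy(dtype=float)
        if np.nanstd(v) < 1e-12:
            warnings.warn(f"zero-variance predictor {col!r} dropped")
            info["dropped"].append(col)
            X = X.drop(columns=[col])
            continue
        sk = float(stats.skew(v, nan_policy="omit"))
        info["skew"][col] = sk
        if abs(sk) >= skew_threshold:
            shift = float(np.nanmin(v))
            v = np.log1p(v - shift)
            info["transformed"].append(col)
            info["shift"][col] = shift
            X[col] = v
        info["mean"][col] = float(np.nanmean(X[col]))
        info["sd"][col] = float(np.nanstd(X[col]))
        X[col] = (X[col] - info["mean"][col]) / info["sd"][col]
    return X, info


def apply_preprocess(X: pd.DataFrame, info: dict) -> pd.DataFrame:
    """Apply a fitted preprocess transform to new rows (no leakage)."""
    X = pd.DataFrame(X).copy().drop(columns=info["dropped"], errors="ignore")
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        if col in info["shift"]:
            v = np.log1p(np.maximum(v - info["shift"][col], 0.0))
        X[col] = (v - info["mean"][col]) / info["sd"][col]
    return X


# ---------------------------------------------------------------------------
# single fits
# ---------------------------------------------------------------------------

def objective_value(X, y, coef, intercept, lam, alpha) -> float:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    resid = y - intercept - X @ coef
    pen = lam * (alpha * np.abs(coef).sum() + 0.5 * (1 - alpha) * (coef ** 2).sum())
    return float(0.5 * np.mean(resid ** 2) + pen)


def fit_elastic_net(X, y, lam: float, alpha: float, tol: float = 1e-8,
                    max_iter: int = 100000) -> ElasticNetFit:
    """Coordinate-descent minimization of the elastic-net objective.

    ``lam = 0`` reduces exactly to ordinary least squares (solved by
    normal equations); non-convergence at ``max_iter`` warns and flags.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    if lam == 0.0:
        A = np.column_stack([np.ones(X.shape[0]), X])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        fit = ElasticNetFit(beta[1:], float(beta[0]), 0.0, alpha,
                            objective_value(X, y, beta[1:], beta[0], 0.0, alpha))
        return fit
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = ElasticNet(alpha=lam, l1_ratio=alpha, tol=tol, max_iter=max_iter)
        model.fit(X, y)
        if any("onverge" in str(w.message) for w in caught):
            warnings.warn("elastic net did not converge at max_iter")
            converged = False
    return ElasticNetFit(model.coef_.copy(), float(model.intercept_), lam, alpha,
                         objective_value(X, y, model.coef_, model.intercept_,
                                         lam, alpha),
                         converged)


def kkt_residual(fit: ElasticNetFit, X, y) -> float:
    """Max violation of the elastic-net stationarity conditions (0 at optimum)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    resid = y - fit.intercept - X @ fit.coef
    grad = -X.T @ resid / n + fit.lam * (1 - fit.alpha) * fit.coef
    viol = np.where(
        fit.coef != 0,
        np.abs(grad + fit.lam * fit.alpha * np.sign(fit.coef)),
        np.maximum(np.abs(grad) - fit.lam * fit.alpha, 0.0),
    )
    viol = np.append(viol, abs(resid.mean()))
    return float(viol.max())


def lambda_grid(X, y, alpha: float, n_lambda: int = 50, decades: float = 4.0) -> np.ndarray:
    """Log-spaced grid from lam_max (all coefficients zero) down ``decades``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    a = max(alpha, 1e-3)
    lam_max = np.abs(X.T @ (y - y.mean())).max() / (n * a)
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - decades, n_lambda)


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------

def _inner_select(X, y, alpha_grid, n_lambda, inner_k, inner_reps, seed):
    """Repeated k-fold CV over the (alpha, lambda) grid; returns the minimizer."""
    n = y.size
    best = (np.inf, None, None)
    rkf = RepeatedKFold(n_splits=inner_k, n_repeats=inner_reps, random_state=seed)
    splits = list(rkf.split(X))
    for alpha in alpha_grid:
        grid = lambda_grid(X, y, alpha, n_lambda)
        sq_err = np.zeros(grid.size)
        cnt = 0
        for tr, te in splits:
            if np.std(y[tr]) < 1e-12:
                continue  # degenerate inner fold; skip (re-randomization analogue)
            mu = X[tr].mean(axis=0)
            sd = X[tr].std(axis=0)
            sd[sd < 1e-12] = 1.0
            Xtr = (X[tr] - mu) / sd
            Xte = (X[te] - mu) / sd
            with warnings.catch_warnings():
                # small-lambda path segments may stop at max_iter; harmless
                # for grid search, the KKT check guards the final fit
                warnings.simplefilter("ignore")
                _, coefs, _ = enet_path(Xtr, y[tr] - y[tr].mean(),
                                        l1_ratio=alpha, alphas=grid)
            pred = Xte @ coefs + y[tr].mean()
            sq_err += ((pred - y[te][:, None]) ** 2).sum(axis=0)
            cnt += te.size
        rmse = np.sqrt(sq_err / max(cnt, 1))
        j = int(np.argmin(rmse))
        if rmse[j] < best[0]:
            best = (float(rmse[j]), alpha, float(grid[j]))
    return best[1], best[2]


def nested_cv(X, y, alpha_grid=DEFAULT_ALPHA_GRID, n_lambda: int = 50,
              inner_k: int = 10, inner_reps: int = 10, seed: int = 0,
              n_boot: int = 1000, n_perm: int = 0,
              skew_threshold: float = 0.7) -> PredictionReport:
    """Leave-one-out outer CV with nested repeated k-fold parameter tuning.

    For each left-out subject the inner CV on the remaining n-1 picks
    (alpha, lam) minimizing mean RMSE; the model refit on the n-1 predicts
    the held-out subject.  Preprocessing (skew check + standardization) is
    fitted inside each outer training fold.  Pooled predictions give RMSE,
    the relative error RMSE / range(y), the Pearson correlation and the
    slope test of observed on predicted, residual normality
    (Shapiro-Wilk) and heteroscedasticity (Breusch-Pagan) checks, a
    percentile bootstrap CI on RMSE, and optionally a label-shuffle p-value
    for RMSE (``n_perm`` > 0; each permutation re-runs the outer loop).
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if y.size < 20:
        raise ValueError("need n >= 20 for nested cross-validation")

    def loo_predict(y_vec, collect=None):
        preds = np.empty(y_vec.size)
        for i in range(y_vec.size):
            tr = np.delete(np.arange(y_vec.size), i)
            Xtr_raw = X.iloc[tr]
            Xp, info = preprocess(Xtr_raw, skew_threshold)
            Xte = apply_preprocess(X.iloc[[i]], info)
            alpha, lam = _inner_select(Xp.to_numpy(), y_vec[tr], alpha_grid,
                                       n_lambda, inner_k, inner_reps,
                                       derive_seed(seed, f"inner-{i}"))
            fit = fit_elastic_net(Xp.to_numpy(), y_vec[tr], lam, alpha)
            preds[i] = fit.intercept + Xte.to_numpy()[0] @ fit.coef
            if collect is not None:
                row = pd.Series(0.0, index=X.columns)
                row[Xp.columns] = fit.coef
                collect["coefs"].append(row)
                collect["params"].append((alpha, lam))
        return preds

    collect = {"coefs": [], "params": []}
    preds = loo_predict(y, collect)
    resid = y - preds
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    rel = relative_error(rmse, y)
    lr = stats.linregress(preds, y) if np.std(preds) > 1e-12 else None
    if lr is None:
        slope = slope_t = np.nan
        slope_p = np.nan
        r = 0.0
    else:
        slope, r = float(lr.slope), float(lr.rvalue)
        slope_t = (float(lr.slope / lr.stderr) if lr.stderr > 0 else np.nan)
        slope_p = float(lr.pvalue)
    shapiro_p = float(stats.shapiro(resid).pvalue) if resid.size >= 3 else np.nan
    try:
        import statsmodels.api as sm
        from statsmodels.stats.diagnostic import het_breuschpagan

        bp_p = float(het_breuschpagan(resid, sm.add_constant(preds))[1])
    except Exception:
        bp_p = np.nan
    rng = np.random.default_rng(derive_seed(seed, "rmse-boot"))
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(y.size, size=y.size)
        boot[b] = np.sqrt(np.mean((y[idx] - preds[idx]) ** 2))
    rmse_ci = tuple(np.percentile(boot, [2.5, 97.5]))
    shuffle_p = None
    if n_perm > 0:
        prng = np.random.default_rng(derive_seed(seed, "rmse-shuffle"))
        count = 0
        for _ in range(n_perm):
            yp = prng.permutation(y)
            pp = loo_predict(yp)
            if np.sqrt(np.mean((yp - pp) ** 2)) <= rmse:
                count += 1
        shuffle_p = (1.0 + count) / (n_perm + 1.0)
    coef_matrix = pd.DataFrame(collect["coefs"]).reset_index(drop=True)
    return PredictionReport(
        rmse=rmse, rmse_ci=rmse_ci, relative_error=rel, pearson_r=r,
        slope=slope, slope_t=slope_t, slope_p=slope_p, shapiro_p=shapiro_p,
        breusch_pagan_p=bp_p, shuffle_p=shuffle_p, predictions=preds,
        observed=y, coef_matrix=coef_matrix, chosen_params=collect["params"])


def relative_error(rmse: float, y) -> float:
    """RMSE divided by the observed outcome range."""
    y = np.asarray(y, dtype=float)
    rng_y = float(y.max() - y.min())
    if rng_y <= 0:
        return np.inf if rmse > 0 else 0.0
    return float(rmse / rng_y)


def selection_stability(coef_matrix: pd.DataFrame) -> pd.DataFrame:
    """Features with a nonzero coefficient in 100% of the outer fits.

    Reports mean and SD of their coefficients in standard units.
    """
    if coef_matrix.shape[0] < 2:
        raise ValueError("need at least 2 outer fits")
    nonzero = coef_matrix != 0.0
    always = nonzero.all(axis=0)
    sel = coef_matrix.loc[:, always]
    return pd.DataFrame({
        "mean_coef": sel.mean(axis=0),
        "sd_coef": sel.std(axis=0, ddof=1),
    })
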