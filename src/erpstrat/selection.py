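"""GA-driven feature selection and linear-SVM classification of outcome.

The classification arm: a stratified 70/30 main/holdout split, a linear
soft-margin SVM scored by 10-fold cross-validated AUC, a binary-chromosome
genetic algorithm (tournament selection, single-point crossover, per-bit
mutation, elitism) searching feature masks against that fitness, incidence
aggregation over repeated evolutions ("optimal" and "highest incidence"
sets), manually defined top-down feature sets, holdout evaluation with
bootstrap confidence intervals, and label-shuffle permutation tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .synth import (COMPONENTS, CONDITIONS, CONTRAST_PARENTS, MEASURES,
                    build_feature_inventory, derive_seed)

try:
    import numba as _numba
except ImportError:  # pragma: no cover - numba is a hard dependency
    _numba = None


def _dcd_kernel(X, y, C, max_iter, tol):
    """Dual coordinate descent for the L1-hinge linear SVM (liblinear's
    algorithm; bias handled as an augmented constant feature).

    Solves min_w 0.5||w||^2 + C sum_i max(0, 1 - y_i w.x_i) via its dual,
    one alpha at a time with projected Newton steps, deterministic
    per-epoch permutations, and the projected-gradient stopping rule.
    """
    n, p = X.shape
    alpha = np.zeros(n)
    w = np.zeros(p)
    Qd = np.empty(n)
    for i in range(n):
        s = 0.0
        for j in range(p):
            s += X[i, j] * X[i, j]
        Qd[i] = s
    idx = np.arange(n)
    for it in range(max_iter):
        max_pg = 0.0
        min_pg = 0.0
        for k in range(n - 1, 0, -1):
            r = (it * 2654435761 + k * 40503) % (k + 1)
            t = idx[k]
            idx[k] = idx[r]
            idx[r] = t
        for kk in range(n):
            i = idx[kk]
            G = 0.0
            for j in range(p):
                G += w[j] * X[i, j]
            G = G * y[i] - 1.0
            pg = G
            if alpha[i] == 0.0:
                if G > 0.0:
                    pg = 0.0
            elif alpha[i] == C:
                if G < 0.0:
                    pg = 0.0
            if pg > max_pg:
                max_pg = pg
            if pg < min_pg:
                min_pg = pg
            if pg != 0.0:
                old = alpha[i]
                na = old - G / Qd[i]
                if na < 0.0:
                    na = 0.0
                elif na > C:
                    na = C
                alpha[i] = na
                d = (na - old) * y[i]
                for j in range(p):
                    w[j] += d * X[i, j]
        if max_pg - min_pg < tol:
            break
    return w


if _numba is not None:
    _dcd_kernel = _numba.njit(fastmath=True)(_dcd_kernel)


def linear_svm_decision(X_train, y_train, X_test, C: float = 1.0,
                        max_iter: int = 200, tol: float = 0.05):
    """Decision values of a soft-margin linear SVM (dual coordinate descent).

    Numerically equivalent to libsvm's linear-kernel SVC up to the bias
    regularization convention; used as the fast fitness path inside the
    genetic algorithm.
    """
    n = X_train.shape[0]
    Xa = np.column_stack([X_train, np.ones(n)])
    ys = 2.0 * np.asarray(y_train, dtype=float) - 1.0
    w = _dcd_kernel(Xa, ys, C, max_iter, tol)
    return np.column_stack([X_test, np.ones(X_test.shape[0])]) @ w


@dataclass
class FeatureMask:
    """Binary chromosome over the feature inventory with its CV-AUC fitness."""

    mask: np.ndarray
    fitness: float | None = None

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_features(self) -> int:
        return int(self.mask.sum())


@dataclass
class EvolutionArchive:
    """Best mask + fitness per repeated evolution."""

    masks: list = field(default_factory=list)
    fitnesses: list = field(default_factory=list)

    def append(self, best: FeatureMask):
        self.masks.append(best.mask.copy())
        self.fitnesses.append(float(best.fitness))

    def __len__(self):
        return len(self.masks)


@dataclass
class ClassifierReport:
    """Holdout metrics, each as (point, ci_lo, ci_hi); plus decision scores."""

    metrics: dict
    scores: np.ndarray
    labels: np.ndarray
    threshold: float
    flags: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.metrics[key]


# ---------------------------------------------------------------------------
# splitting and AUC
# ---------------------------------------------------------------------------

def stratified_split(table: pd.DataFrame, train_fraction: float = 0.70,
                     seed: int = 0, label_col: str = "diagnosis") -> tuple:
    """Split positives and negatives independently at ``train_fraction``.

    Per class, round(n * fraction) subjects go to the main sample and the
    remainder to the holdout, so the class ratio differs between splits by
    at most one subject per class.  144 subjects with 33 positives at 0.70
    yield main n = 101 and holdout n = 43.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    y = table[label_col].to_numpy()
    rng = np.random.default_rng(seed)
    main_idx, hold_idx = [], []
    for cls in np.unique(y):
        idx = np.where(y == cls)[0]
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
        n_tr = int(np.floor(train_fraction * idx.size + 0.5))
        n_tr = min(max(n_tr, 1), idx.size - 1)  # both splits keep every class
        perm = rng.permutation(idx)
        main_idx.extend(perm[:n_tr])
        hold_idx.extend(perm[n_tr:])
    return table.iloc[np.sort(main_idx)], table.iloc[np.sort(hold_idx)]


def auc(scores, labels) -> float:
    """ROC AUC (Mann-Whitney formulation; ties count one half)."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("both classes required to compute AUC")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _standardize(train: np.ndarray, other: np.ndarray | None = None):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd < 1e-12] = 1.0
    if other is None:
        return (train - mu) / sd
    return (train - mu) / sd, (other - mu) / sd


def cv_auc(X: np.ndarray, y: np.ndarray, mask=None, k: int = 10,
           seed: int = 0, C: float = 1.0, solver: str = "svc") -> float:
    """Pooled stratified k-fold AUC of a linear SVM on the masked features.

    Standardization parameters come from each training fold only; held-out
    decision values are pooled into a single AUC.  A fold whose training
    part collapses to one class triggers re-randomization (up to 10 times).
    ``solver`` selects libsvm ("svc") or the fast dual-coordinate-descent
    path ("dcd") used inside the genetic algorithm.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if mask is not None:
        m = mask.mask if isinstance(mask, FeatureMask) else np.asarray(mask, dtype=bool)
        if not m.any():
            raise ValueError("empty feature mask")
        X = X[:, m]
    if X.shape[0] < k:
        raise ValueError("need at least k subjects")
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=(seed + attempt) % (2**31))
        pooled = np.empty(y.size)
        ok = True
        for tr, te in skf.split(X, y):
            if np.unique(y[tr]).size < 2:
                ok = False
                break
            Xtr, Xte = _standardize(X[tr], X[te])
            if solver == "dcd":
                pooled[te] = linear_svm_decision(Xtr, y[tr], Xte, C)
            else:
                clf = SVC(kernel="linear", C=C)
                clf.fit(Xtr, y[tr])
                pooled[te] = clf.decision_function(Xte)
        if ok:
            return auc(pooled, y)
    raise ValueError("could not build folds containing both classes")


# ---------------------------------------------------------------------------
# genetic algorithm
# ---------------------------------------------------------------------------

def ga_evolve(X: np.ndarray, y: np.ndarray, seed: int = 0, pop_size: int = 50,
              generations: int = 100, p_crossover: float = 0.8,
              p_mutation: float | None = None, elitism: int = 1,
              tournament: int = 3, init_p: float = 0.2, k: int = 10,
              C: float = 1.0, solver: str = "dcd") -> FeatureMask:
    """Evolve a binary feature mask maximizing cross-validated SVM AUC.

    Tournament selection, single-point crossover, per-bit mutation
    (default rate 1/p) and elitism of ``elitism``.  Fitness uses one fixed
    fold randomization per evolution, so the elite's fitness is comparable
    across generations and the returned mask is never worse than the best
    initial chromosome.  All-zero chromosomes are repaired by setting one
    random bit.  Initial masks include each feature with probability
    ``init_p`` (sparse initialization).
    """
    if pop_size < 4:
        raise ValueError("pop_size must be >= 4")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    p = X.shape[1]
    pm = (1.0 / p) if p_mutation is None else p_mutation
    rng = np.random.default_rng(seed)
    fold_seed = derive_seed(seed, "folds")
    cache: dict = {}

    def fitness(mask: np.ndarray) -> float:
        key = mask.tobytes()
        if key not in cache:
            cache[key] = cv_auc(X, y, mask, k=k, seed=fold_seed, C=C,
                                solver=solver)
        return cache[key]

    def repair(mask: np.ndarray) -> np.ndarray:
        if not mask.any():
            mask = mask.copy()
            mask[rng.integers(p)] = True
        return mask

    pop = [repair(rng.random(p) < init_p) for _ in range(pop_size)]
    fits = np.array([fitness(m) for m in pop])
    best_i = int(np.argmax(fits))
    best = FeatureMask(pop[best_i].copy(), float(fits[best_i]))
    for _gen in range(generations):
        order = np.argsort(-fits)
        new_pop = [pop[i].copy() for i in order[:elitism]]
        while len(new_pop) < pop_size:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                contenders = rng.integers(pop_size, size=tournament)
                parents.append(pop[contenders[np.argmax(fits[contenders])]])
            a, b = parents[0].copy(), parents[1].copy()
            if rng.random() < p_crossover and p > 1:
                cut = int(rng.integers(1, p))
                a[cut:], b[cut:] = b[cut:].copy(), a[cut:].copy()
            for child in (a, b):
                flip = rng.random(p) < pm
                child ^= flip
                new_pop.append(repair(child))
                if len(new_pop) >= pop_size:
                    break
        pop = new_pop
        fits = np.array([fitness(m) for m in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best.fitness:
            best = FeatureMask(pop[gen_best].copy(), float(fits[gen_best]))
    return best


def run_evolutions(X: np.ndarray, y: np.ndarray, n_runs: int = 100,
                   seed: int = 0, **ga_kwargs) -> EvolutionArchive:
    """Repeat the evolution ``n_runs`` times with independent seeds."""
    archive = EvolutionArchive()
    for r in range(n_runs):
        best = ga_evolve(X, y, seed=derive_seed(seed, f"evolution-{r}"), **ga_kwargs)
        archive.append(best)
    return archive


def optimal_mask(archive: EvolutionArchive) -> FeatureMask:
    """Single best-fitness mask across evolutions.

    Ties break to the mask with fewest features, then lexicographically.
    """
    if not len(archive):
        raise ValueError("empty archive")
    keyed = sorted(
        range(len(archive)),
        key=lambda i: (-archive.fitnesses[i], int(archive.masks[i].sum()),
                       tuple(archive.masks[i].astype(int))),
    )
    i = keyed[0]
    return FeatureMask(archive.masks[i].copy(), archive.fitnesses[i])


def aggregate_incidence(archive: EvolutionArchive, auc_floor: float = 0.85,
                        incidence_floor: float = 0.80):
    """"Highest incidence" set: features in > ``incidence_floor`` of the
    best masks whose fitness exceeds ``auc_floor`` (both strict).

    Returns (FeatureMask, per-feature incidence, n_qualifying); with no
    qualifying runs the mask is empty and incidence all-NaN.
    """
    if not len(archive):
        raise ValueError("empty archive")
    fits = np.asarray(archive.fitnesses)
    qual = fits > auc_floor
    p = archive.masks[0].size
    if not qual.any():
        return FeatureMask(np.zeros(p, dtype=bool)), np.full(p, np.nan), 0
    stack = np.stack([m for m, q in zip(archive.masks, qual) if q])
    incidence = stack.mean(axis=0)
    return (FeatureMask(incidence > incidence_floor), incidence,
            int(qual.sum()))


def topdown_sets(inventory=None) -> dict:
    """Manually defined masks: per stimulus, per contrast, per measure, per component."""
    inventory = list(inventory) if inventory is not None else build_feature_inventory()
    masks = {}

    def mask_for(predicate):
        return np.array([predicate(name) for name in inventory], dtype=bool)

    for cond in CONDITIONS:
        masks[f"condition:{cond}"] = mask_for(lambda n, c=cond: n.endswith("_" + c))
    for contrast in CONTRAST_PARENTS:
        masks[f"contrast:{contrast}"] = mask_for(lambda n, c=contrast: n.endswith("_" + c))
    for meas in MEASURES:
        masks[f"measure:{meas}"] = mask_for(lambda n, m=meas: f"_{m}_" in n)
    for comp in COMPONENTS:
        masks[f"component:{comp}"] = mask_for(lambda n, c=comp: n.startswith(c + "_"))
    return masks


# ---------------------------------------------------------------------------
# holdout evaluation and permutation inference
# ---------------------------------------------------------------------------

def _confusion_metrics(pred: np.ndarray, ytrue: np.ndarray) -> dict:
    tp = int(((pred == 1) & (ytrue == 1)).sum())
    fn = int(((pred == 0) & (ytrue == 1)).sum())
    tn = int(((pred == 0) & (ytrue == 0)).sum())
    fp = int(((pred == 1) & (ytrue == 0)).sum())

    def ratio(a, b):
        return a / b if b else np.nan

    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "accuracy": ratio(tp + tn, tp + fn + tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Decision threshold maximizing sensitivity + specificity - 1."""
    fpr, tpr, thr = roc_curve(labels, scores)
    return float(thr[np.argmax(tpr - fpr)])


def evaluate_holdout(X_main, y_main, X_hold, y_hold, mask,
                     n_boot: int = 10000, seed: int = 0,
                     C: float = 1.0) -> ClassifierReport:
    """Train on the full main sample and score the untouched holdout.

    Standardization parameters and the Youden-optimal decision threshold
    come from the main sample only.  AUC, sensitivity, specificity,
    accuracy, PPV and NPV carry percentile bootstrap 95% CIs over holdout
    resamples.  If the holdout lacks a class, only threshold metrics that
    remain defined are reported and the rest are flagged.
    """
    m = mask.mask if isinstance(mask, FeatureMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty feature mask")
    Xm = np.asarray(X_main, dtype=float)[:, m]
    Xh = np.asarray(X_hold, dtype=float)[:, m]
    y_main = np.asarray(y_main)
    y_hold = np.asarray(y_hold)
    Xm_s, Xh_s = _standardize(Xm, Xh)
    clf = SVC(kernel="linear", C=C)
    clf.fit(Xm_s, y_main)
    main_scores = clf.decision_function(Xm_s)
    thr = youden_threshold(main_scores, y_main)
    scores = clf.decision_function(Xh_s)
    pred = (scores >= thr).astype(int)
    point = _confusion_metrics(pred, y_hold)
    flags = {}
    if np.unique(y_hold).size < 2:
        point["auc"] = np.nan
        flags["auc"] = "holdout lacks a class"
    else:
        point["auc"] = auc(scores, y_hold)
    rng = np.random.default_rng(seed)
    boot: dict = {k: [] for k in point}
    nh = y_hold.size
    for _ in range(n_boot):
        idx = rng.integers(nh, size=nh)
        yb = y_hold[idx]
        bm = _confusion_metrics(pred[idx], yb)
        bm["auc"] = auc(scores[idx], yb) if np.unique(yb).size == 2 else np.nan
        for k2, v in bm.items():
            boot[k2].append(v)
    metrics = {}
    for k2, v in point.items():
        draws = np.asarray(boot[k2], dtype=float)
        draws = draws[np.isfinite(draws)]
        if np.isfinite(v) and draws.size:
            lo, hi = np.percentile(draws, [2.5, 97.5])
        else:
            lo = hi = np.nan
        metrics[k2] = (float(v), float(lo), float(hi))
    return ClassifierReport(metrics=metrics, scores=scores, labels=y_hold,
                            threshold=thr, flags=flags)


def shuffle_test(evaluator, labels, n_perm: int = 10000, seed: int = 0) -> dict:
    """Permutation test of a performance statistic against chance.

    ``evaluator(permuted_labels)`` returns the statistic (e.g. an AUC
    computed by re-running the evaluation pipeline under permuted outcome
    labels).  p = (1 + #{stat_perm >= stat_obs}) / (n_perm + 1).  A failing
    permutation is re-drawn up to 3 times.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    observed = float(evaluator(labels))
    perm_stats = np.empty(n_perm)
    for i in range(n_perm):
        for attempt in range(4):
            try:
                perm_stats[i] = evaluator(rng.permutation(labels))
                break
            except Exception:
                if attempt == 3:
                    raise
    p = (1.0 + np.sum(perm_stats >= observed)) / (n_perm + 1.0)
    return {"p": float(p), "observed": observed, "perm_stats": perm_stats}


def compare_classifiers(scores_a, scores_b, labels, n_perm: int = 10000,
                        seed: int = 0) -> dict:
    """Paired permutation test on |AUC_a - AUC_b| over the same holdout.

    Each permutation swaps the two classifiers' scores within random
    subjects; both score vectors must cover the same subjects.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if a.shape != b.shape or a.shape[0] != labels.shape[0]:
        raise ValueError("classifier scores must cover the same subjects")
    obs = abs(auc(a, labels) - auc(b, labels))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        swap = rng.random(a.size) < 0.5
        ap = np.where(swap, b, a)
        bp = np.where(swap, a, b)
        if abs(auc(ap, labels) - auc(bp, labels)) >= obs:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return {"p": float(p), "observed": float(obs)}
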