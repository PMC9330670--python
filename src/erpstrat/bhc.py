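"""Bayesian hierarchical clustering of averaged ERP features.

Greedy model-based agglomeration: starting from singleton leaves, the pair
of subtrees whose merged-hypothesis posterior probability r is highest is
merged at each step.  The merged hypothesis compares the marginal
likelihood of the pooled data under one component against the product of
the subtree likelihoods, with prior weights given by the Dirichlet-process
recursion of Heller & Ghahramani:

    d_k  = a0 * Gamma(n_k) + d_i * d_j
    pi_k = a0 * Gamma(n_k) / d_k
    p(D_k | T_k) = pi_k * ML(D_k) + (1 - pi_k) * p(D_i|T_i) * p(D_j|T_j)
    r_k  = pi_k * ML(D_k) / p(D_k | T_k)

The per-cluster likelihood is an independent Normal-Gamma model per
dimension (diagonal covariance), whose marginal likelihood is available in
closed form from the prior/posterior normalizing-constant ratio.  All
arithmetic is in log space.  Cutting the tree at r > 0.5 yields a flat
partition whose cluster count emerges from the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln


@dataclass(frozen=True)
class BHCHyperparams:
    """DP concentration and per-dimension Normal-Gamma prior.

    Defaults are calibrated to standardized features: with m0 = 0,
    kappa0 = 1, a0 = 2, b0 = 1 the prior predictive variance is
    b0*(kappa0+1)/(a0*kappa0) = 1 (each feature has unit marginal variance
    by construction) and the expected within-component precision is
    a0/b0 = 2, i.e. cluster structure is expected to explain about half of
    the marginal variance.  An overly vague location prior (kappa0 << 1)
    makes any merge beat two independent draws and collapses the tree into
    a single cluster.
    """

    crp_alpha: float = 1.0   # DP concentration
    m0: float = 0.0
    kappa0: float = 1.0
    a0: float = 2.0          # Gamma shape of the precision prior
    b0: float = 1.0          # Gamma rate

    def __post_init__(self):
        for name in ("crp_alpha", "kappa0", "a0", "b0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class BHCNode:
    members: np.ndarray
    log_ml: float
    log_tree: float
    log_d: float
    r: float
    children: tuple | None = None
    index: int = 0

    @property
    def size(self) -> int:
        return self.members.size


def _log_ml_stats(n, s1, s2, hyper: BHCHyperparams):
    """Log marginal likelihood of data blocks from sufficient statistics.

    ``n`` broadcasts against leading axes of ``s1``/``s2`` (…, p): per
    dimension sum and sum of squares.  Vectorized over any leading shape.
    """
    n = np.asarray(n, dtype=float)
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    nn = n[..., None] if s1.ndim > n.ndim else n
    mean = s1 / nn
    ss = s2 - nn * mean ** 2
    kappa_n = hyper.kappa0 + nn
    a_n = hyper.a0 + nn / 2.0
    b_n = (hyper.b0 + 0.5 * ss
           + hyper.kappa0 * nn * (mean - hyper.m0) ** 2 / (2.0 * kappa_n))
    per_dim = (-0.5 * nn * np.log(2.0 * np.pi)
               + 0.5 * (np.log(hyper.kappa0) - np.log(kappa_n))
               + gammaln(a_n) - gammaln(hyper.a0)
               + hyper.a0 * np.log(hyper.b0) - a_n * np.log(b_n))
    return per_dim.sum(axis=-1)


def marginal_likelihood(X, hyper: BHCHyperparams | None = None) -> float:
    """Closed-form log marginal likelihood of an n x p block under one component."""
    hyper = hyper or BHCHyperparams()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite data")
    if X.shape[0] < 1:
        raise ValueError("need n >= 1")
    return float(_log_ml_stats(np.array(X.shape[0]), X.sum(axis=0),
                               (X ** 2).sum(axis=0), hyper))


def _merge_terms(ni, nj, log_di, log_dj, log_mli_tree, log_mlj_tree,
                 s1, s2, hyper):
    """Vectorized DP-recursion terms for candidate merges (arrays over pairs)."""
    nk = ni + nj
    log_a_gamma = np.log(hyper.crp_alpha) + gammaln(nk)
    log_dk = np.logaddexp(log_a_gamma, log_di + log_dj)
    log_pi = log_a_gamma - log_dk
    # 1 - pi = d_i * d_j / d_k exactly; avoids cancellation when pi -> 1
    log_one_minus_pi = log_di + log_dj - log_dk
    log_ml = _log_ml_stats(nk, s1, s2, hyper)
    term_merge = log_pi + log_ml
    term_split = log_one_minus_pi + log_mli_tree + log_mlj_tree
    log_tree = np.logaddexp(term_merge, term_split)
    r = np.exp(term_merge - log_tree)
    return log_dk, log_pi, log_ml, log_tree, r, term_merge, term_split


def build_tree(X, hyper: BHCHyperparams | None = None) -> BHCNode:
    """Greedy bottom-up merge of the pair with the highest merge posterior.

    Ties break to the candidate whose (smaller creation index, larger
    creation index) pair is lexicographically smallest.  Raises on numerical
    breakdown (the tree likelihood must dominate both mixture terms).
    """
    hyper = hyper or BHCHyperparams()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need an n x p matrix with n >= 2")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite data")
    n, p = X.shape
    log_alpha = np.log(hyper.crp_alpha)
    nodes: list[BHCNode] = []
    S1 = {}
    S2 = {}
    for i in range(n):
        ml = float(_log_ml_stats(np.array(1.0), X[i], X[i] ** 2, hyper))
        nodes.append(BHCNode(members=np.array([i]), log_ml=ml, log_tree=ml,
                             log_d=log_alpha, r=1.0, index=i))
        S1[i] = X[i].copy()
        S2[i] = X[i] ** 2
    active = list(range(n))
    cand: dict = {}

    def add_candidates(new: int, others: list):
        if not others:
            return
        arr = np.array(others)
        ni = np.array([nodes[a].size for a in arr], dtype=float)
        s1 = np.stack([S1[a] for a in arr]) + S1[new]
        s2 = np.stack([S2[a] for a in arr]) + S2[new]
        log_di = np.array([nodes[a].log_d for a in arr])
        log_ti = np.array([nodes[a].log_tree for a in arr])
        nj = float(nodes[new].size)
        res = _merge_terms(ni, nj, log_di, nodes[new].log_d, log_ti,
                           nodes[new].log_tree, s1, s2, hyper)
        log_dk, log_pi, log_ml, log_tree, r, t_m, t_s = res
        for idx, a in enumerate(arr):
            key = (min(a, new), max(a, new))
            cand[key] = (float(r[idx]), float(log_dk[idx]), float(log_ml[idx]),
                         float(log_tree[idx]), float(t_m[idx]), float(t_s[idx]))

    for pos, i in enumerate(active):
        add_candidates(i, active[pos + 1:])
    next_index = n
    while len(active) > 1:
        best_key = max(cand, key=lambda k: (cand[k][0], -k[0], -k[1]))
        r, log_dk, log_ml, log_tree, t_m, t_s = cand[best_key]
        if not np.isfinite(log_tree):
            raise FloatingPointError("numerical underflow in tree likelihood")
        if log_tree < max(t_m, t_s) - 1e-6:
            raise FloatingPointError("mixture bound violated (bug signal)")
        i, j = best_key
        node = BHCNode(
            members=np.sort(np.concatenate([nodes[i].members, nodes[j].members])),
            log_ml=log_ml, log_tree=log_tree, log_d=log_dk, r=r,
            children=(nodes[i], nodes[j]), index=next_index)
        nodes.append(node)
        S1[next_index] = S1[i] + S1[j]
        S2[next_index] = S2[i] + S2[j]
        active = [a for a in active if a not in (i, j)]
        cand = {k: v for k, v in cand.items() if i not in k and j not in k}
        add_candidates(next_index, active)
        active.append(next_index)
        next_index += 1
    return nodes[active[0]]


def cut_tree(root: BHCNode) -> np.ndarray:
    """Flat partition: maximal subtrees with merge posterior r > 0.5.

    Traverses from the root splitting any node with r <= 0.5; leaves carry
    r = 1 by convention, so every subject is labeled.  Labels are contiguous
    1..K in order of each cluster's smallest subject index.
    """
    clusters = []

    def descend(node: BHCNode):
        if node.children is None or node.r > 0.5:
            clusters.append(node.members)
        else:
            for child in node.children:
                descend(child)

    descend(root)
    n = root.size
    labels = np.zeros(n, dtype=int)
    clusters.sort(key=lambda m: int(m.min()))
    for lab, members in enumerate(clusters, start=1):
        labels[members] = lab
    return labels


def partition(X, hyper: BHCHyperparams | None = None) -> np.ndarray:
    """Convenience: build and cut in one call."""
    return cut_tree(build_tree(X, hyper))


def loo_stability(X, hyper: BHCHyperparams | None = None) -> dict:
    """Leave-one-out stability of the flat partition.

    Rebuilds the tree without each subject and compares the resulting
    partition with the full-data partition restricted to the same subjects
    via the adjusted Rand index.  Returns mean, min and the per-subject
    distribution.
    """
    from sklearn.metrics import adjusted_rand_score

    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need n >= 3")
    full = partition(X, hyper)
    aris = np.empty(n)
    for i in range(n):
        keep = np.delete(np.arange(n), i)
        sub = partition(X[keep], hyper)
        aris[i] = adjusted_rand_score(full[keep], sub)
    return {"mean_ari": float(aris.mean()), "min_ari": float(aris.min()),
            "aris": aris}


def characterize_clusters(labels, features: pd.DataFrame,
                          outcomes: pd.DataFrame | None = None,
                          alpha: float = 0.05) -> dict:
    """One-way ANOVAs across clusters with Holm correction per family.

    ERP features and outcome variables form separate Holm families; Tukey
    HSD pairwise comparisons are reported for measures surviving
    correction.  Size-1 clusters are excluded with a warning.
    """
    from statsmodels.stats.multitest import multipletests
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    labels = np.asarray(labels)
    sizes = pd.Series(labels).value_counts()
    small = sizes[sizes < 2].index.to_numpy()
    if small.size:
        warnings.warn(f"excluding size-1 clusters {small.tolist()} from ANOVA")
    keep = ~np.isin(labels, small)
    labs = labels[keep]
    if np.unique(labs).size < 2:
        raise ValueError("need at least 2 clusters of size >= 2")

    def family(table: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for col in table.columns:
            v = table[col].to_numpy(dtype=float)[keep]
            groups = [v[labs == g] for g in np.unique(labs)]
            ok = ~np.isnan(v)
            groups = [g[~np.isnan(g)] for g in groups]
            if any(g.size < 2 for g in groups):
                rows.append({"measure": col, "F": np.nan, "df1": np.nan,
                             "df2": np.nan, "p": np.nan})
                continue
            F, pval = stats.f_oneway(*groups)
            rows.append({"measure": col, "F": float(F),
                         "df1": len(groups) - 1,
                         "df2": int(ok.sum()) - len(groups), "p": float(pval)})
        out = pd.DataFrame(rows).set_index("measure")
        mask = out["p"].notna()
        adj = np.full(len(out), np.nan)
        sig = np.zeros(len(out), dtype=bool)
        if mask.any():
            rej, p_holm, _, _ = multipletests(out.loc[mask, "p"], alpha=alpha,
                                              method="holm")
            adj[mask.to_numpy()] = p_holm
            sig[mask.to_numpy()] = rej
        out["p_holm"] = adj
        out["significant"] = sig
        return out

    report = {"erp": family(features)}
    if outcomes is not None and len(outcomes.columns):
        report["outcome"] = family(outcomes)
    tukey = {}
    for fam_name, fam_table in (("erp", features),
                                ("outcome", outcomes if outcomes is not None else pd.DataFrame())):
        if fam_name not in report:
            continue
        for col in report[fam_name].index[report[fam_name]["significant"]]:
            v = fam_table[col].to_numpy(dtype=float)[keep]
            ok = ~np.isnan(v)
            res = pairwise_tukeyhsd(v[ok], labs[ok], alpha=alpha)
            tukey[col] = pd.DataFrame(res.summary().data[1:],
                                      columns=res.summary().data[0])
    report["tukey"] = tukey
    return report


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvals, dtype=float), method="holm")[1]


def to_newick(root: BHCNode, names=None) -> str:
    """Serialize the merge tree with per-node merge posteriors."""

    def fmt(node: BHCNode) -> str:
        if node.children is None:
            i = int(node.members[0])
            return str(names[i]) if names is not None else f"s{i}"
        a, b = node.children
        return f"({fmt(a)},{fmt(b)})r={node.r:.4f}"

    return fmt(root) + ";"
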