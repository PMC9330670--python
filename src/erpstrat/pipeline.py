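"""End-to-end orchestration of the analysis arms and the summary matrix.

Runs synth (or a user-supplied feature table) through imputation and the
four analysis arms — group comparison, GA/SVM classification, elastic-net
trait prediction, Bayesian hierarchical stratification — under one root
seed, writing per-stage tables and one cross-arm summary of which ERP
features each arm flags.  Features flagged by three or more arms are
marked convergent.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import bhc, enet, groupstats, impute, selection, synth

logger = logging.getLogger("erpstrat")

#: reduced-replication profiles for desk-scale runs; 'study' keeps the
#: full-scale permutation/bootstrap counts.
PROFILES = {
    "study": {"n_perm": 10000, "n_boot": 10000, "rmse_boot": 1000,
              "ga_runs": 100, "ga_pop": 50, "ga_generations": 100, "cv_k": 10,
              "inner_k": 10, "inner_reps": 10, "n_lambda": 50},
    "test": {"n_perm": 200, "n_boot": 200, "rmse_boot": 200,
             "ga_runs": 10, "ga_pop": 12, "ga_generations": 6, "cv_k": 5,
             "inner_k": 10, "inner_reps": 2, "n_lambda": 25},
    "smoke": {"n_perm": 100, "n_boot": 50, "rmse_boot": 50,
              "ga_runs": 3, "ga_pop": 8, "ga_generations": 3, "cv_k": 5,
              "inner_k": 5, "inner_reps": 1, "n_lambda": 10},
}


def default_config(seed: int = 0, profile: str = "test") -> dict:
    return {
        "mode": "synthetic",
        "seed": int(seed),
        "profile": profile,
        "stages": {"groupstats": True, "select": True, "enet": True, "bhc": True},
        "synth": {"miss_rate": 0.05, "miss_mechanism": "MAR-on-age",
                  "cluster_spec": {"n_clusters": 5, "separation": 3.0}},
        "impute": {"min_fraction": 0.70},
        "select": {"train_fraction": 0.70},
        "enet": {"alpha_grid": [0.1, 0.5, 1.0]},
        "bhc": {},
    }


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str)
                          .encode()).hexdigest()[:12]


def _log_stage(name: str, seed: int, config: dict, out: Path):
    entry = {"stage": name, "seed": seed, "config_hash": _config_hash(config)}
    logger.info("stage %s seed=%d", name, seed)
    with open(out / "pipeline.log.jsonl", "a") as fh:
        fh.write(json.dumps(entry) + "\n")


def _fmt_float(df: pd.DataFrame) -> pd.DataFrame:
    return df.round(10)


def run_pipeline(config: dict, out_dir) -> Path:
    """Execute enabled stages in dependency order; one arm failing does not
    abort the others.  Outputs are deterministic under a fixed seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    profile = PROFILES[config.get("profile", "test")]
    stages = config.get("stages", {})
    # ---- cohort ------------------------------------------------------
    if config.get("mode", "synthetic") == "synthetic":
        synth_cfg = dict(config.get("synth", {}))
        cspec = synth_cfg.pop("cluster_spec", None)
        if isinstance(cspec, dict):
            cspec = synth.ClusterSpec(**cspec)
        gcfg = synth.GeneratorConfig(seed=synth.derive_seed(seed, "synth"),
                                     cluster_spec=cspec, **synth_cfg)
        cohort = (synth.plant_clusters(gcfg) if cspec is not None
                  else synth.generate_feature_table(gcfg))
        table = cohort.feature_table
        _log_stage("synth", gcfg.seed, config, out)
    else:
        path = config.get("features_path")
        if not path or not Path(path).exists():
            raise FileNotFoundError("user-data mode requires an existing features_path")
        table = synth.load_feature_table(path)
        cohort = synth.SyntheticCohort(table, truth={})
    synth.cohort_summary(table).to_csv(out / "cohort_summary.tsv", sep="\t")
    table.to_csv(out / "features_raw.tsv", sep="\t")
    # ---- eligibility + imputation ------------------------------------
    table = impute.eligibility_filter(table, **config.get("impute", {}))
    diag = impute.mar_diagnostics(cohort.feature_table)
    diag.to_csv(out / "mar_diagnostics.tsv", sep="\t", index=False)
    table, model = impute.em_impute(table)
    _fmt_float(table).to_csv(out / "features_imputed.tsv", sep="\t")
    _log_stage("impute", seed, config, out)
    inventory = synth.build_feature_inventory()
    erp_cols = synth.erp_feature_names()
    flags: dict = {}
    # ---- group comparison --------------------------------------------
    if stages.get("groupstats", True):
        try:
            flags["groupstats"] = _run_groupstats(table, out)
            _log_stage("groupstats", seed, config, out)
        except Exception:
            logger.exception("groupstats arm failed")
    # ---- classification ----------------------------------------------
    if stages.get("select", True):
        try:
            flags.update(_run_select(table, inventory, seed, profile,
                                     config.get("select", {}), out))
            _log_stage("select", seed, config, out)
        except Exception:
            logger.exception("classification arm failed")
    # ---- elastic net --------------------------------------------------
    if stages.get("enet", True):
        try:
            flags["enet"] = _run_enet(table, erp_cols, seed, profile,
                                      config.get("enet", {}), out)
            _log_stage("enet", seed, config, out)
        except Exception:
            logger.exception("elastic-net arm failed")
    # ---- stratification -----------------------------------------------
    if stages.get("bhc", True):
        try:
            flags["bhc"] = _run_bhc(table, seed, out)
            _log_stage("bhc", seed, config, out)
        except Exception:
            logger.exception("stratification arm failed")
    summary = build_summary(flags, inventory)
    summary.to_csv(out / "summary_matrix.tsv", sep="\t")
    return out


def _run_groupstats(table: pd.DataFrame, out: Path) -> set:
    """Split-plot ANOVA per component x measure x contrast; flag interactions p < .05."""
    sig = set()
    rows = []
    for comp in synth.COMPONENTS:
        for meas in synth.MEASURES:
            for contrast, (a, b) in synth.CONTRAST_PARENTS.items():
                cols = [f"{comp}_{meas}_{b}", f"{comp}_{meas}_{a}"]
                vals = table[cols].to_numpy(dtype=float)
                res = groupstats.splitplot_anova(vals, table["group"].to_numpy())
                for r in res:
                    rows.append({"measure": f"{comp}_{meas}_{contrast}",
                                 "effect": r.effect, "F": r.F, "df1": r.df1,
                                 "df2": r.df2, "p": r.p,
                                 "partial_eta_sq": r.partial_eta_sq})
                    if r.effect == "condition:group" and r.p < 0.05:
                        sig.add(f"{comp}_{meas}_{contrast}")
    pd.DataFrame(rows).to_csv(out / "groupstats.tsv", sep="\t", index=False)
    return sig


def _run_select(table: pd.DataFrame, inventory, seed, profile, cfg, out: Path) -> dict:
    el = table[table["group"] != "TL"]
    main, hold = selection.stratified_split(
        el, train_fraction=cfg.get("train_fraction", 0.70),
        seed=synth.derive_seed(seed, "split"))
    Xm = main[inventory].to_numpy(dtype=float)
    ym = main["diagnosis"].to_numpy(dtype=int)
    Xh = hold[inventory].to_numpy(dtype=float)
    yh = hold["diagnosis"].to_numpy(dtype=int)
    archive = selection.run_evolutions(
        Xm, ym, n_runs=profile["ga_runs"], seed=synth.derive_seed(seed, "ga"),
        pop_size=profile["ga_pop"], generations=profile["ga_generations"],
        k=profile["cv_k"])
    opt = selection.optimal_mask(archive)
    inc_mask, incidence, n_qual = selection.aggregate_incidence(archive)
    pd.DataFrame({"feature": inventory, "incidence": incidence}).to_csv(
        out / "ga_incidence.tsv", sep="\t", index=False)
    report = selection.evaluate_holdout(Xm, ym, Xh, yh, opt,
                                        n_boot=profile["n_boot"],
                                        seed=synth.derive_seed(seed, "boot"))
    metrics = pd.DataFrame(report.metrics, index=["point", "ci_lo", "ci_hi"]).T
    metrics.to_csv(out / "classifier_report.tsv", sep="\t")
    flags = {"select_optimal": {n for n, m in zip(inventory, opt.mask) if m}}
    if inc_mask.mask.any():
        flags["select_incidence"] = {n for n, m in zip(inventory, inc_mask.mask) if m}
    return flags


def _run_enet(table: pd.DataFrame, erp_cols, seed, profile, cfg, out: Path) -> set:
    el = table[table["group"] != "TL"]
    X = el[erp_cols + ["gender", "age"]]
    y = el["outcome"].to_numpy(dtype=float)
    report = enet.nested_cv(
        X, y, alpha_grid=tuple(cfg.get("alpha_grid", enet.DEFAULT_ALPHA_GRID)),
        n_lambda=profile["n_lambda"], inner_k=profile["inner_k"],
        inner_reps=profile["inner_reps"], seed=synth.derive_seed(seed, "enet"),
        n_boot=profile["rmse_boot"])
    stability = enet.selection_stability(report.coef_matrix)
    stability.to_csv(out / "enet_stability.tsv", sep="\t")
    summary = pd.Series({
        "rmse": report.rmse, "rmse_ci_lo": report.rmse_ci[0],
        "rmse_ci_hi": report.rmse_ci[1],
        "relative_error": report.relative_error,
        "pearson_r": report.pearson_r, "slope": report.slope,
        "slope_p": report.slope_p})
    summary.to_csv(out / "enet_report.tsv", sep="\t", header=False)
    return set(stability.index)


def _run_bhc(table: pd.DataFrame, seed, out: Path) -> set:
    el = table[table["group"] != "TL"]
    cols = synth.averaged_feature_names()
    X = el[cols].to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) < 1e-12, 1.0, X.std(axis=0))
    labels = bhc.partition(X)
    pd.DataFrame({"subject": el.index, "cluster": labels}).to_csv(
        out / "bhc_partition.tsv", sep="\t", index=False)
    if labels.max() < 2:  # single cluster: nothing to characterize
        return set()
    report = bhc.characterize_clusters(labels, el[cols], el[["outcome"]])
    report["erp"].to_csv(out / "bhc_characterization.tsv", sep="\t")
    return set(report["erp"].index[report["erp"]["significant"]])


def build_summary(arm_flags: dict, inventory) -> pd.DataFrame:
    """Cross-tabulate per-arm feature flags; >= 3 arms => convergent.

    Column order mirrors the analysis arms: group-significant, GA-optimal,
    GA-highest-incidence, elastic-net always-selected, cluster-
    discriminating.
    """
    if not arm_flags:
        raise ValueError("need at least one arm report")
    order = ["groupstats", "select_optimal", "select_incidence", "enet", "bhc"]
    cols = [c for c in order if c in arm_flags]
    inv_set = set(inventory)
    rows = {}
    for col in cols:
        for feat in arm_flags[col]:
            if feat in inv_set:
                rows.setdefault(feat, set()).add(col)
    out = pd.DataFrame(False, index=sorted(rows), columns=cols)
    for feat, hit in rows.items():
        for col in hit:
            out.loc[feat, col] = True
    # the GA sets count as one arm for convergence
    arm_of = {"select_optimal": "select", "select_incidence": "select"}
    n_arms = []
    for feat in out.index:
        arms = {arm_of.get(c, c) for c in cols if out.loc[feat, c]}
        n_arms.append(len(arms))
    out["n_arms"] = n_arms
    out["convergent"] = out["n_arms"] >= 3
    return out
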