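"""Synthetic infant face-ERP cohorts with planted effect structure.

Generates cohorts that mimic the statistical structure of a prospective
infant-sibling ERP study: three outcome groups (TL, EL-noASD, EL-ASD), six
stimulus conditions (FD direct gaze, FA averted gaze, F static face, N
visual noise, SD gaze shift toward, SA gaze shift away), three components
(P1, N290, P400) measured in peak amplitude (uV) and latency (ms), group x
condition effects of configurable standardized magnitude (Cohen's d), a
linear model for a continuous social-functioning outcome, missing data
under MCAR or MAR-on-age mechanisms, and an optional latent cluster
structure over the averaged features.  Everything planted is recorded in
``SyntheticCohort.truth`` so downstream recovery can be scored.

Feature scales
--------------
Condition-level ERP features are generated as standardized Gaussians
(mean 0, SD 1 within the reference population), so a planted Cohen's d is
simply a mean shift of d.  Differential (contrast) features are always the
arithmetic difference of their parent condition features and therefore have
SD sqrt(2) under independence; an effect planted *on a contrast* is realised
by shifting the first parent condition by d*sqrt(2), which yields exactly a
standardized shift of d on the contrast.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .erp import CONDITIONS, CONTRAST_PARENTS, EpochSet

COMPONENTS = ("P1", "N290", "P400")
MEASURES = ("amp", "lat")
GROUPS = ("TL", "EL-noASD", "EL-ASD")
METADATA_COLUMNS = ("group", "diagnosis", "outcome")


class ConfigurationError(ValueError):
    """Raised for inconsistent generator configuration."""


def derive_seed(root_seed: int, label: str) -> int:
    """Split one root seed into stable per-subsystem seeds (< 2**31)."""
    h = hashlib.sha256(f"{int(root_seed)}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# feature inventory
# ---------------------------------------------------------------------------

def build_feature_inventory() -> list:
    """The fixed, ordered 56-column feature inventory.

    36 averaged features ({P1,N290,P400} x {amp,lat} x six conditions),
    18 differential features (same components/measures x three contrasts),
    then gender and age.  Order: component-major, measure, condition.
    """
    names = [
        f"{comp}_{meas}_{cond}"
        for comp in COMPONENTS for meas in MEASURES for cond in CONDITIONS
    ]
    names += [
        f"{comp}_{meas}_{contrast}"
        for comp in COMPONENTS for meas in MEASURES for contrast in CONTRAST_PARENTS
    ]
    names += ["gender", "age"]
    return names


def averaged_feature_names() -> list:
    return build_feature_inventory()[:36]


def contrast_feature_names() -> list:
    return build_feature_inventory()[36:54]


def erp_feature_names() -> list:
    """The 54 ERP columns (inventory without gender/age)."""
    return build_feature_inventory()[:54]


def _parse_contrast(name: str):
    """Return (parent_a, parent_b) column names if ``name`` is a contrast."""
    for contrast, (a, b) in CONTRAST_PARENTS.items():
        if name.endswith("_" + contrast):
            stem = name[: -len(contrast) - 1]
            return f"{stem}_{a}", f"{stem}_{b}"
    return None


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSpec:
    """A standardized group x feature mean shift (Cohen's d)."""

    feature_name: str
    group: str
    d: float

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ConfigurationError(f"unknown group {self.group!r}")
        if not np.isfinite(self.d):
            raise ConfigurationError("effect size d must be finite")
        if self.feature_name not in build_feature_inventory():
            raise ConfigurationError(f"unknown feature {self.feature_name!r}")


@dataclass(frozen=True)
class ComponentParams:
    """Waveform-mode component shape: a Gaussian bump in time."""

    latency_ms: float
    amplitude_uv: float
    width_ms: float
    latency_sd: float = 15.0
    amplitude_sd: float = 2.0

    def __post_init__(self):
        for v in (self.width_ms, self.latency_sd, self.amplitude_sd):
            if v <= 0:
                raise ConfigurationError("widths and SDs must be positive")


def default_component_params() -> dict:
    return {
        "P1": ComponentParams(120.0, 8.0, 30.0, 12.0, 2.0),
        "N290": ComponentParams(290.0, -10.0, 45.0, 15.0, 2.5),
        "P400": ComponentParams(450.0, 7.0, 70.0, 18.0, 2.0),
    }


@dataclass(frozen=True)
class ClusterSpec:
    """Latent mixture over the 36 averaged features.

    ``separation`` is the per-feature centroid shift in within-cluster SD
    units: each cluster is displaced by ``separation`` on its own disjoint
    block of ``signature_size`` averaged features (explicit ``centroids``
    override this construction).  ``weights`` are mixing proportions.
    """

    n_clusters: int
    separation: float = 3.0
    signature_size: int = 3
    weights: tuple | None = None
    centroids: np.ndarray | None = None

    def __post_init__(self):
        if self.n_clusters < 1:
            raise ConfigurationError("n_clusters must be >= 1")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.size != self.n_clusters or np.any(w <= 0):
                raise ConfigurationError("weights must be positive, one per cluster")
            if abs(w.sum() - 1.0) > 1e-8:
                raise ConfigurationError("mixing weights must sum to 1")


def make_centroids(n_clusters: int, n_features: int, separation: float,
                   signature_size: int, rng: np.random.Generator) -> np.ndarray:
    """Signature-block centroids: disjoint feature blocks shifted by ``separation``."""
    if n_clusters * signature_size > n_features:
        raise ConfigurationError("not enough features for disjoint signatures")
    dims = rng.permutation(n_features)
    C = np.zeros((n_clusters, n_features))
    for k in range(n_clusters):
        C[k, dims[k * signature_size:(k + 1) * signature_size]] = separation
    return C


def default_effects() -> list:
    """Planted group x condition effects.

    Magnitudes follow the reported standardized group differences for the
    dynamic-gaze and face-noise contrasts (toward > away differentiation of
    P1/P400 latency and the face > noise N290 latency differentiation present
    in TL and EL-noASD but absent/reversed in EL-ASD); reversed effects whose
    magnitude is not reported default to d = -0.40.
    """
    return [
        EffectSpec("P1_lat_toward_away", "TL", 0.74),
        EffectSpec("P1_lat_toward_away", "EL-noASD", 0.43),
        EffectSpec("P1_lat_toward_away", "EL-ASD", -0.40),
        EffectSpec("P400_lat_toward_away", "TL", 0.55),
        EffectSpec("P400_lat_toward_away", "EL-noASD", 0.47),
        EffectSpec("P400_lat_toward_away", "EL-ASD", -0.40),
        EffectSpec("P400_amp_toward_away", "EL-ASD", 0.46),
        EffectSpec("P400_amp_toward_away", "EL-noASD", 0.41),
        EffectSpec("P400_amp_toward_away", "TL", -0.40),
        EffectSpec("N290_lat_face_noise", "TL", 0.61),
        EffectSpec("N290_lat_face_noise", "EL-noASD", 0.52),
    ]


def default_outcome_beta() -> dict:
    """Linear coefficients (standardized features -> standardized outcome)."""
    return {
        "N290_lat_face_noise": -0.30,
        "P1_lat_toward_away": 0.15,
        "P400_amp_F": 0.15,
        "gender": 0.25,
        "age": -0.15,
    }


@dataclass
class GeneratorConfig:
    """Everything the cohort generator needs; defaults are the study conditions.

    ``n_per_group`` defaults to the study composition (68 TL, 115 EL-noASD,
    33 EL-ASD).  The continuous outcome emulates an adaptive-social-
    functioning score: mean 100, population SD 15, linear in the
    standardized features plus Gaussian noise.
    """

    n_per_group: dict = field(default_factory=lambda: {"TL": 68, "EL-noASD": 115, "EL-ASD": 33})
    effects: list = field(default_factory=default_effects)
    outcome_beta: dict = field(default_factory=default_outcome_beta)
    outcome_noise_sd: float = 0.9
    outcome_mean: float = 100.0
    outcome_scale: float = 15.0
    #: within-subject correlation among same-measure ERP features (a shared
    #: per-subject amplitude factor and latency factor); marginal SD stays 1
    feature_corr: float = 0.30
    p_male: dict = field(default_factory=lambda: {"TL": 0.5, "EL-noASD": 0.5, "EL-ASD": 0.78})
    miss_rate: float = 0.0
    miss_mechanism: str = "MCAR"
    cluster_spec: ClusterSpec | None = None
    # waveform mode
    n_channels: int = 20
    ot_channels: tuple = (14, 15, 16, 17, 18, 19)
    sample_rate: float = 250.0
    epoch_window: tuple = (-200.0, 800.0)
    n_epochs: int = 30
    noise_sd_uv: float = 5.0
    component_params: dict = field(default_factory=default_component_params)
    seed: int = 0

    def validate(self):
        if not (0.0 <= self.miss_rate < 1.0):
            raise ConfigurationError("miss_rate must be in [0, 1)")
        if any(n < 0 for n in self.n_per_group.values()):
            raise ConfigurationError("group sizes must be non-negative")
        if set(self.n_per_group) - set(GROUPS):
            raise ConfigurationError("unknown group label in n_per_group")
        if not (self.epoch_window[0] < 0.0 < self.epoch_window[1]):
            raise ConfigurationError("epoch window must straddle stimulus onset")
        if self.outcome_noise_sd <= 0:
            raise ConfigurationError("outcome_noise_sd must be positive")
        if not (0.0 <= self.feature_corr < 1.0):
            raise ConfigurationError("feature_corr must be in [0, 1)")
        inv = set(build_feature_inventory())
        for eff in self.effects:
            if eff.feature_name not in inv:
                raise ConfigurationError(f"effect on unknown feature {eff.feature_name!r}")
        for name in self.outcome_beta:
            if name not in inv:
                raise ConfigurationError(f"outcome beta on unknown feature {name!r}")
        # component bumps must stay temporally distinct for peak round trips
        params = sorted(self.component_params.values(), key=lambda c: c.latency_ms)
        for a, b in zip(params, params[1:]):
            if b.latency_ms - a.latency_ms < (a.width_ms + b.width_ms):
                raise ConfigurationError("component windows overlap beyond tolerance")


@dataclass
class SyntheticCohort:
    """A generated cohort: feature table, optional epochs, and ground truth."""

    feature_table: pd.DataFrame
    truth: dict
    epochs: list | None = None


# ---------------------------------------------------------------------------
# feature-level generation
# ---------------------------------------------------------------------------

def _group_vector(n_per_group: dict) -> np.ndarray:
    parts = [np.repeat(g, n_per_group.get(g, 0)) for g in GROUPS]
    return np.concatenate(parts) if parts else np.array([], dtype=object)


def _effect_shift_matrix(effects, groups: np.ndarray,
                         feature_corr: float = 0.0) -> pd.DataFrame:
    """Per-subject additive shifts on the 36 condition features.

    An effect planted on a contrast is realised through the first parent
    condition, scaled by the contrast SD sqrt(2*(1-rho)) so the planted
    Cohen's d holds on the contrast itself.
    """
    avg_names = averaged_feature_names()
    contrast_sd = np.sqrt(2.0 * (1.0 - feature_corr))
    shifts = pd.DataFrame(0.0, index=range(groups.size), columns=avg_names)
    for eff in effects:
        rows = groups == eff.group
        parents = _parse_contrast(eff.feature_name)
        if parents is not None:
            a, _ = parents
            shifts.loc[rows, a] += eff.d * contrast_sd
        elif eff.feature_name in avg_names:
            shifts.loc[rows, eff.feature_name] += eff.d
        # gender/age effects are not expressible as condition shifts
    return shifts


def _condition_block(rng: np.random.Generator, n: int,
                     feature_corr: float) -> np.ndarray:
    """Standardized condition features with within-subject structure.

    Same-measure features share a per-subject factor (general amplitude
    responsiveness / overall latency) with loading sqrt(rho); marginal
    variance stays exactly 1.
    """
    Z = rng.standard_normal((n, 36))
    if feature_corr > 0:
        names = averaged_feature_names()
        factors = {m: rng.standard_normal(n) for m in MEASURES}
        load = np.sqrt(feature_corr)
        resid = np.sqrt(1.0 - feature_corr)
        for j, name in enumerate(names):
            meas = name.split("_")[1]
            Z[:, j] = resid * Z[:, j] + load * factors[meas]
    return Z


def _assemble_table(Z: np.ndarray, groups: np.ndarray, gender: np.ndarray,
                    age: np.ndarray, config: GeneratorConfig,
                    rng_outcome: np.random.Generator) -> pd.DataFrame:
    """Condition block -> contrasts -> outcome -> full table."""
    inv = build_feature_inventory()
    avg = pd.DataFrame(Z, columns=averaged_feature_names())
    for contrast, (a, b) in CONTRAST_PARENTS.items():
        for comp in COMPONENTS:
            for meas in MEASURES:
                avg[f"{comp}_{meas}_{contrast}"] = (
                    avg[f"{comp}_{meas}_{a}"] - avg[f"{comp}_{meas}_{b}"]
                )
    avg["gender"] = gender.astype(float)
    avg["age"] = age
    X = avg[inv].to_numpy()
    # standardized design for the outcome model: ERP features are standardized
    # by construction; gender is centered/scaled as a Bernoulli(1/2) code.
    Xs = X.copy()
    gcol = inv.index("gender")
    Xs[:, gcol] = (X[:, gcol] - 0.5) / 0.5
    beta = np.array([config.outcome_beta.get(name, 0.0) for name in inv])
    lin = Xs @ beta
    y = config.outcome_mean + config.outcome_scale * (
        lin + config.outcome_noise_sd * rng_outcome.standard_normal(groups.size)
    )
    table = avg.copy()
    table["group"] = groups
    table["diagnosis"] = (groups == "EL-ASD").astype(int)
    table["outcome"] = y
    table.index = [f"sub-{i + 1:03d}" for i in range(groups.size)]
    return table


def generate_feature_table(config: GeneratorConfig) -> SyntheticCohort:
    """Draw a feature-level cohort with the configured planted structure."""
    config.validate()
    groups = _group_vector(config.n_per_group)
    n = groups.size
    rng = np.random.default_rng(derive_seed(config.seed, "features"))
    Z = (_condition_block(rng, n, config.feature_corr)
         + _effect_shift_matrix(config.effects, groups,
                                config.feature_corr).to_numpy())
    p_male = np.array([config.p_male.get(g, 0.5) for g in groups])
    gender = (rng.random(n) < p_male).astype(int)
    age = rng.standard_normal(n)  # age in days, standardized
    rng_out = np.random.default_rng(derive_seed(config.seed, "outcome"))
    table = _assemble_table(Z, groups, gender, age, config, rng_out)
    truth = {
        "effects": [(e.feature_name, e.group, e.d) for e in config.effects],
        "outcome_beta": dict(config.outcome_beta),
        "outcome_noise_sd": config.outcome_noise_sd,
        "cluster_assignments": None,
        "missingness": None,
        "seed": config.seed,
    }
    cohort = SyntheticCohort(feature_table=table, truth=truth)
    if config.miss_rate > 0:
        cohort = inject_missingness(cohort, config.miss_rate, config.miss_mechanism,
                                    seed=derive_seed(config.seed, "missing"))
    return cohort


def plant_clusters(config: GeneratorConfig) -> SyntheticCohort:
    """Cohort whose averaged-feature block is drawn around K mixture centroids.

    Cluster assignments are allocated to the mixing weights with deterministic
    rounding (largest-remainder), then shuffled; unit Gaussian noise is added
    around the assigned centroid.  Group effects and the outcome model apply
    on top, and the assignment vector is recorded in ``truth``.
    """
    config.validate()
    spec = config.cluster_spec
    if spec is None:
        raise ConfigurationError("cluster_spec required for plant_clusters")
    groups = _group_vector(config.n_per_group)
    n = groups.size
    if spec.n_clusters > n:
        raise ConfigurationError("more clusters than subjects")
    rng = np.random.default_rng(derive_seed(config.seed, "clusters"))
    C = spec.centroids
    if C is None:
        C = make_centroids(spec.n_clusters, 36, spec.separation,
                           spec.signature_size, rng)
    C = np.asarray(C, dtype=float)
    w = (np.full(spec.n_clusters, 1.0 / spec.n_clusters)
         if spec.weights is None else np.asarray(spec.weights, dtype=float))
    counts = np.floor(w * n).astype(int)
    rem = w * n - counts
    for k in np.argsort(-rem)[: n - counts.sum()]:
        counts[k] += 1
    z = np.repeat(np.arange(spec.n_clusters), counts)
    rng.shuffle(z)
    Z = C[z] + rng.standard_normal((n, C.shape[1]))
    Z += _effect_shift_matrix(config.effects, groups).to_numpy()
    p_male = np.array([config.p_male.get(g, 0.5) for g in groups])
    gender = (rng.random(n) < p_male).astype(int)
    age = rng.standard_normal(n)
    rng_out = np.random.default_rng(derive_seed(config.seed, "outcome"))
    table = _assemble_table(Z, groups, gender, age, config, rng_out)
    truth = {
        "effects": [(e.feature_name, e.group, e.d) for e in config.effects],
        "outcome_beta": dict(config.outcome_beta),
        "outcome_noise_sd": config.outcome_noise_sd,
        "cluster_assignments": z.tolist(),
        "centroids": C.tolist(),
        "missingness": None,
        "seed": config.seed,
    }
    cohort = SyntheticCohort(feature_table=table, truth=truth)
    if config.miss_rate > 0:
        cohort = inject_missingness(cohort, config.miss_rate, config.miss_mechanism,
                                    seed=derive_seed(config.seed, "missing"))
    return cohort


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

def inject_missingness(cohort: SyntheticCohort, miss_rate: float,
                       mechanism: str = "MCAR", seed: int | None = None) -> SyntheticCohort:
    """Mask condition-feature cells at the expected rate (MCAR or MAR-on-age).

    Masking applies to the 36 averaged condition features; the differential
    features are recomputed as parent differences afterwards, so a contrast
    is missing exactly when one of its parents is (mirroring how contrasts
    propagate missingness during peak extraction).  MAR-on-age makes the
    per-cell masking probability a logistic function of (standardized) age
    only: p_i = expit(a + age_i), with the offset ``a`` solved so the
    expected masked fraction equals ``miss_rate``.  Metadata and gender/age
    are never masked.
    """
    if not (0.0 <= miss_rate < 1.0):
        raise ValueError("miss_rate must be in [0, 1)")
    table = cohort.feature_table.copy()
    cols = [c for c in averaged_feature_names() if c in table.columns]
    truth = dict(cohort.truth)
    truth["missingness"] = {"rate": miss_rate, "mechanism": mechanism}
    if miss_rate == 0.0:
        return SyntheticCohort(table, truth, cohort.epochs)
    rng = np.random.default_rng(derive_seed(truth.get("seed", 0), "missing")
                                if seed is None else seed)
    n = table.shape[0]
    if mechanism == "MCAR":
        p_row = np.full(n, miss_rate)
    elif mechanism == "MAR-on-age":
        age = table["age"].to_numpy(dtype=float)

        def mean_rate(a):
            return expit(a + age).mean() - miss_rate

        offset = brentq(mean_rate, -30.0, 30.0)
        p_row = expit(offset + age)
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    mask = rng.random((n, len(cols))) < p_row[:, None]
    vals = table[cols].to_numpy(dtype=float)
    vals[mask] = np.nan
    table[cols] = vals
    recompute_contrasts(table)
    return SyntheticCohort(table, truth, cohort.epochs)


def recompute_contrasts(table: pd.DataFrame) -> pd.DataFrame:
    """Refresh differential columns as parent differences (NaN-propagating)."""
    for contrast, (a, b) in CONTRAST_PARENTS.items():
        for comp in COMPONENTS:
            for meas in MEASURES:
                name = f"{comp}_{meas}_{contrast}"
                pa, pb = f"{comp}_{meas}_{a}", f"{comp}_{meas}_{b}"
                if name in table.columns and pa in table.columns and pb in table.columns:
                    table[name] = table[pa] - table[pb]
    return table


# ---------------------------------------------------------------------------
# waveform-level generation
# ---------------------------------------------------------------------------

def generate_waveforms(config: GeneratorConfig) -> SyntheticCohort:
    """Per subject x condition epochs: baseline noise + three Gaussian bumps.

    Each subject/condition draws component latencies and amplitudes around
    the configured means (between-subject SDs; effect shifts applied in SD
    units on the matching component/measure/condition), places the bumps on
    the occipito-temporal channels and adds white noise everywhere.  The
    planted peak parameters per subject/condition/component are recorded in
    ``truth['waveform_params']``.
    """
    config.validate()
    groups = _group_vector(config.n_per_group)
    n = groups.size
    rng = np.random.default_rng(derive_seed(config.seed, "waveforms"))
    step = 1000.0 / config.sample_rate
    times = np.arange(config.epoch_window[0], config.epoch_window[1] + step / 2, step)
    ot = np.asarray(config.ot_channels, dtype=int)
    eff_by_key: dict = {}
    for eff in config.effects:
        parents = _parse_contrast(eff.feature_name)
        if parents is not None:
            comp, meas, _ = parents[0].split("_", 2)
            key = (comp, meas, parents[0].rsplit("_", 1)[-1], eff.group)
            eff_by_key[key] = eff_by_key.get(key, 0.0) + eff.d * np.sqrt(2.0)
        else:
            parts = eff.feature_name.split("_")
            if len(parts) == 3:
                comp, meas, cond = parts
                eff_by_key[(comp, meas, cond, eff.group)] = (
                    eff_by_key.get((comp, meas, cond, eff.group), 0.0) + eff.d)
    epoch_sets = []
    planted: dict = {}
    for i in range(n):
        subject = f"sub-{i + 1:03d}"
        for cond in CONDITIONS:
            data = config.noise_sd_uv * rng.standard_normal(
                (config.n_epochs, config.n_channels, times.size))
            for comp, cp in config.component_params.items():
                lat = cp.latency_ms + cp.latency_sd * (
                    rng.standard_normal()
                    + eff_by_key.get((comp, "lat", cond, groups[i]), 0.0))
                amp = cp.amplitude_uv + cp.amplitude_sd * (
                    rng.standard_normal()
                    + eff_by_key.get((comp, "amp", cond, groups[i]), 0.0))
                bump = amp * np.exp(-0.5 * ((times - lat) / cp.width_ms) ** 2)
                data[:, ot, :] += bump[None, None, :]
                planted[(subject, cond, comp)] = {"latency": float(lat),
                                                  "amplitude": float(amp)}
            epoch_sets.append(EpochSet(subject, cond, data, times,
                                       tuple(int(c) for c in ot)))
    base = generate_feature_table(config)
    truth = dict(base.truth)
    truth["waveform_params"] = planted
    return SyntheticCohort(base.feature_table, truth, epochs=epoch_sets)


# ---------------------------------------------------------------------------
# summaries and I/O
# ---------------------------------------------------------------------------

def cohort_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Group counts, EL-relative percentages, and diagnosis rate.

    The percentage column is computed within the elevated-likelihood (EL)
    subset, mirroring how outcome rates are reported for sibling cohorts.
    """
    counts = table["group"].value_counts()
    n_el = int(counts.get("EL-noASD", 0) + counts.get("EL-ASD", 0))
    rows = []
    for g in GROUPS:
        c = int(counts.get(g, 0))
        pct = 100.0 * c / n_el if (g.startswith("EL") and n_el) else np.nan
        rows.append({"group": g, "n": c, "percent_of_EL": pct})
    return pd.DataFrame(rows).set_index("group")


def save_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write the feature table (TSV) and truth (JSON) side by side."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.feature_table.to_csv(out / "features.tsv", sep="\t")
    with open(out / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=2, default=str)


def load_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
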