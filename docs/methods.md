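# Methods

This note documents the statistical models implemented in `erpstrat`, the
assumptions behind them, what the synthetic cohort generator does and does
not emulate, and the numerical and design choices a maintainer would want
to know. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Feature space

The analysis operates on a fixed, ordered 56-column inventory:
{P1, N290, P400} × {amplitude (µV), latency (ms)} × the six stimulus
conditions (FD, FA, F, N, SD, SA) — 36 averaged features — plus the same
component/measure grid over the three contrasts face−noise (F−N),
direct−averted (FD−FA), toward−away (SD−SA) — 18 differential features —
and gender (0 female / 1 male) and age (days, standardized). The printed
record of the source study never states the predictor count; this is the
smallest inventory consistent with every analysis, and it is flagged as a
reconstruction. Differential features are **by construction** the exact
arithmetic difference of their parent condition features, everywhere in
the package: in the generator, after peak extraction, and after
imputation. Consequences of this algebra matter downstream (see
*Wrapper selection* below).

## Synthetic cohort generator (`synth`)

The generator is first-class, tested code: it defines the study
conditions under which every recovery property is evaluated.

Condition features are standardized Gaussians (mean 0, SD 1 in the
reference population), with a within-subject correlation structure: all
amplitude features share a per-subject "general responsiveness" factor
and all latency features a "general latency" factor, each with loading
√ρ, ρ = 0.30 by default. Real infant ERP amplitudes correlate strongly
across conditions within a subject; ρ = 0.30 is a deliberately moderate
value that leaves each feature's marginal variance exactly 1, so a
planted Cohen's *d* is simply a mean shift of *d*. The correlation is
also what gives model-based (EM) imputation its advantage over
column-mean filling — with independent features the two coincide.

**Planted effects.** An `EffectSpec(feature, group, d)` shifts that
group's mean. Effects on contrasts are realised through the first parent
condition, scaled by the contrast SD √(2(1−ρ)), so the planted *d* holds
exactly on the contrast. Defaults reproduce the reported group-level
pattern: toward>away differentiation of P1 latency (d = .74 typical-
likelihood, .43 EL-no-ASD), P400 latency (.55/.47) and P400 amplitude
(.46 EL-ASD/.41 EL-no-ASD), and face>noise N290 latency differentiation
(.61/.52) absent in EL-ASD; reversed effects with no printed magnitude
default to d = −0.40.

**Outcome model.** The continuous outcome emulates an adaptive-social-
functioning score: y = 100 + 15·(Xβ + ε), with β in standardized units
(defaults: N290 latency face−noise −0.30, gender +0.25, age −0.15, two
smaller ERP terms) and ε ~ N(0, 0.9). Group sizes default to the study
composition (68 TL / 115 EL-no-ASD / 33 EL-ASD), with the ASD group
male-enriched (P(male) = 0.78 vs 0.5).

**Missingness** is planted on the 36 condition features; contrasts
inherit it as NaN-propagating parent differences, exactly as contrasts
behave after peak extraction. MCAR masks cells at a constant rate; MAR-
on-age makes the cell-masking probability a logistic function of
standardized age alone, with the offset solved numerically so the
expected masked fraction equals the nominal rate.

**Clusters.** `plant_clusters` assigns subjects to K mixture components
(largest-remainder allocation to the mixing weights, then shuffled) and
draws the averaged-feature block as centroid + unit Gaussian noise.
Default centroids give each cluster its own disjoint block of 3
"signature" features shifted by `separation` within-cluster SDs — the
pattern the study's clusters show, each distinguished by a handful of
component/condition measures. A literal "pairwise centroid distance =
separation" geometry was rejected at design time: in 36 dimensions it is
unrecoverable by any method at 3 SD (nearest-centroid assignment with
the true centroids stays near ARI 0.5).

**Waveform mode** synthesizes epochs as white noise plus three Gaussian
bumps (P1 positive, N290 negative, P400 positive) on 6 designated
occipito-temporal channels of a generic 20-channel layout, 250 Hz, with
per-subject/condition latencies and amplitudes drawn around configurable
means and recorded in the ground truth. It does **not** model 1/f EEG
spectra, volume conduction, realistic montages, or ocular artifacts —
passing round-trip tests demonstrates the extraction code is correct,
not that it is robust to real EEG nuisance structure.

## Peak extraction (`erp`)

Artifact rejection is a simplified absolute-amplitude rule (default
200 µV on any designated channel) with a minimum surviving-epoch count
(default 10); the source protocol's full artifact pipeline is out of
scope and this deviation is deliberate. Averages are baseline-corrected
by the mean of the −200..0 ms segment per channel. The component peak is
the polarity-appropriate extremum of the *channel-group mean* inside a
closed window — defaults P1 [70, 170] ms (+), N290 [200, 350] ms (−),
P400 [350, 600] ms (+), standard infant face-ERP windows, fully
configurable. Ties break to the earliest sample; an extremum on a window
edge is a monotone run, not a peak, and is flagged; flagged conditions
propagate missing values into every dependent feature (never silent
zeros).

## Imputation (`impute`)

Subjects with <70 % of ERP cells observed are excluded (boundary
inclusive). The remaining missingness is imputed by maximum-likelihood EM
under a single multivariate Gaussian over the **36 condition features**
(contrasts are exact linear combinations — a singular direction no
covariance model should contain — and are recomputed from imputed
parents; gender/age are excluded from the model and used only in
diagnostics). The E-step fills conditional means and accumulates the
conditional-covariance correction; the M-step re-estimates (µ, Σ).
Convergence: relative observed-data log-likelihood change < 1e-6, max
500 iterations; singular observed blocks get a ridge of
1e-8·trace(Σ)/p with a warning; a decreasing log-likelihood raises,
since monotonicity is a theorem for EM and its violation signals a bug.
`apply_imputation` imputes new (holdout) rows with training parameters
only, avoiding leakage; whether the source study imputed before or after
splitting is unstated, and split-first is the package default.

## Group statistics (`groupstats`)

With a 2-level within-subject factor the split-plot design decomposes
exactly: between-subject effects are an ANOVA on subject means, and the
condition effect plus all condition-by-group interactions are an ANOVA on
per-subject difference scores (sphericity is vacuous). Both parts use
Type-III sums of squares with sum-coded factors via OLS; the identity
"interaction F ≡ one-way F on difference scores" is enforced by
construction and cross-checked in tests against an independent
mixed-ANOVA implementation. Covariates enter both submodels as
regressors (classical ANCOVA); constant or collinear covariates are
dropped with warnings. Post-hoc contrasts use Welch *t* (no
equal-variance assumption) but report pooled-SD Cohen's *d* for
comparability with printed effect sizes; the Sidak family is the three
pairwise group contrasts per measure, and both raw and adjusted *p* are
reported because the source prose is ambiguous about which is printed.

## Wrapper selection and classification (`selection`)

The binary outcome arm: positives and negatives are split independently
at the train fraction (nearest-integer rounding, remainder to holdout),
so 144 subjects with 33 positives at 0.70 give exactly 101/43. The
classifier is a soft-margin linear SVM, C = 1 on features standardized
with training-fold parameters only; no internal C tuning. Fitness of a
feature mask is the pooled held-out decision-value AUC over stratified
k-folds (k = 10 default). AUC is the Mann–Whitney statistic with ties
counting ½, computed by scikit-learn and verified in tests against
brute-force pair enumeration.

Two SVM solvers back the same objective: libsvm (via scikit-learn) for
holdout evaluation, and a numba dual-coordinate-descent solver (the
liblinear algorithm, bias as an augmented penalized feature) for the GA's
inner loop, where millions of small fits dominate runtime; the two agree
to decision-value correlation > 0.999 and are cross-checked in tests.

The genetic algorithm uses tournament selection (size 3), single-point
crossover (p = 0.8), per-bit mutation (default 1/p), elitism 1, sparse
initialization (each bit set with probability 0.2 by default), all-zero
chromosomes repaired by setting one random bit, and one fixed fold
randomization per evolution so the elite's fitness is comparable across
generations (the returned mask is provably never worse than the best
initial chromosome). Defaults are pop 50 / 100 generations — plausible
study-scale settings, flagged as assumptions since the original
hyperparameters are unpublished.

Aggregation over repeated evolutions follows the printed rules with
strict inequalities: the "optimal" set is the single best-fitness mask
(ties → fewest features, then lexicographic); the "highest incidence"
set contains features present in >80 % of best masks whose fitness
exceeds 0.85 AUC. Holdout metrics (AUC, sensitivity, specificity,
accuracy, PPV, NPV) use the Youden-optimal threshold estimated on the
main sample (the source's thresholding rule is unstated) and percentile
bootstrap 95 % CIs over holdout resamples (default 10000). The shuffle
test permutes outcome labels and re-runs the supplied evaluator,
p = (1 + #{stat ≥ observed})/(n_perm + 1); classifier comparison swaps
the two classifiers' scores within subjects.

**A structural caveat the algebra imposes.** Because every contrast is an
exact linear combination of two condition features, a linear classifier
can substitute {contrast + one parent} for the other parent: feature
*sets* are identifiable only up to the span they generate. Recovery
experiments for the wrapper machinery therefore use design matrices with
independent columns; on the real inventory, incidence should be read at
the level of feature *families* (a component/measure/condition
neighbourhood), not single columns. Relatedly, at n ≈ 300 a null feature
can draw an in-sample effect of |d| ≈ 0.3–0.5; such a feature genuinely
improves in-sample cross-validated AUC and any faithful AUC-maximizing
wrapper will rank it highly. This is selection bias of wrapper methods
at moderate n — a property of the statistic, not of the optimizer.

## Elastic net (`enet`)

Objective (1/2n)·RSS + λ(α‖β‖₁ + (1−α)/2·‖β‖₂²), solved by coordinate
descent (scikit-learn's solver; λ = 0 falls back to exact least squares).
Correctness is pinned by closed forms: OLS at λ = 0, soft-thresholding
under centered orthonormal designs, and a KKT stationarity residual
checked at optima. Predictors with |skewness| ≥ 0.7 are shifted to
positive support and log1p-transformed, then everything is standardized;
both steps are fitted inside each outer training fold and applied to the
held-out subject (the source describes them globally; the leakage-free
variant is the default and the transform object makes either order
possible). The λ-grid holds 50 log-spaced values spanning 4 decades down
from λ_max (the smallest λ zeroing all coefficients; α floored at 1e-3
in that formula, glmnet's convention); the α-grid is
{0.1, 0.3, 0.5, 0.7, 0.9, 1.0}, tuned jointly with λ — the source does
not state whether α was fixed. Outer validation is leave-one-out; the
inner selector is repeated k-fold (10×10 default) minimizing RMSE along
warm-started paths. Reported: RMSE with percentile bootstrap CI
(default 1000), relative error = RMSE/range(y), Pearson r and the slope
test of observed on predicted, Shapiro–Wilk residual normality and
Breusch–Pagan heteroscedasticity checks (the source says only "checked
residuals"; these are the named defaults), an optional permutation p for
RMSE, and the "always selected" list — features with nonzero
coefficients in 100 % of outer fits (strict), with mean ± SD coefficients
in standard units.

## Bayesian hierarchical clustering (`bhc`)

Greedy bottom-up merging scored by the merged-hypothesis posterior under
the Dirichlet-process recursion: d_k = α·Γ(n_k) + d_i·d_j,
π_k = α·Γ(n_k)/d_k, p(D|T_k) = π_k·ML(D_k) + (1−π_k)·p(D_i|T_i)·p(D_j|T_j),
r_k = π_k·ML(D_k)/p(D|T_k); the pair with the highest r merges, ties
break to the smaller creation-index pair. All arithmetic is in log
space; 1−π_k is computed exactly as d_i·d_j/d_k (the naive
log(1−exp(log π)) cancels catastrophically once Γ(n_k) dominates, which
silently inverts every high-level merge decision). The per-cluster
likelihood is an independent Normal–Gamma model per dimension (diagonal
covariance — at p = 36 and n = 144 a full Normal–inverse-Wishart would
be poorly conditioned; the likelihood is an isolated function, so a full
model is a plug-in). The tree-wide mixture bound
log p(D|T) ≥ max(mixture terms) is asserted at every merge.

**Hyperparameters** (on standardized features): m₀ = 0, κ₀ = 1, a₀ = 2,
b₀ = 1, DP concentration 1. These are calibrated so the prior-predictive
variance b₀(κ₀+1)/(a₀κ₀) equals 1 — the marginal variance the input is
standardized to — and the expected within-component precision a₀/b₀ = 2,
i.e. cluster structure is expected to explain about half the variance. A
much vaguer location prior (κ₀ ≪ 1) is a known failure mode: every
candidate merge then dominates two independent draws from the nearly
flat prior, r saturates at 1 and the tree collapses into one cluster. A
sensitivity note: with κ₀ = 1, a₀ = 1 the five-cluster recovery below
degrades but does not collapse; with κ₀ ≤ 0.1 it fails entirely.

The flat partition takes maximal subtrees with r > 0.5 (r = 0.5 splits);
K emerges from the data. Leave-one-out stability rebuilds the tree
without each subject and compares partitions restricted to shared
subjects by adjusted Rand index (the stability metric is unnamed in the
source; ARI is the package's choice). Clustering runs on the 36
standardized averaged features. Cluster characterization runs one-way
ANOVAs per measure with Holm–Bonferroni applied separately to the ERP
and outcome families and Tukey HSD for survivors; size-1 clusters are
excluded with a warning.

## Pipeline, profiles, and problem sizes

Replication counts default to study scale (10000 permutations, 10000
bootstrap, 1000 RMSE bootstrap, 100 evolutions); the shipped `test` and
`smoke` profiles run reduced counts (200/200/200 and smaller GA
settings) for desk-scale work. Each stage derives its seed from the root
seed through labeled SHA-256 splitting, so stages are independently
reproducible and any rerun is bit-identical.

The recovery protocols in the test suite use these desk-scale sizes:
five-cluster recovery at n = 144 over 10 seeds; elastic-net support/sign
recovery at n = 144, SNR 4, over 10 seeds with α ∈ {0.5, 1} and a
30-point λ path; shuffle-test calibration over 500 replications of 200
permutations; Holm family-wise error over 400 null-cluster replications
(checked against the one-sided binomial 95 % bound for a rate of .05,
the appropriate empirical reading of an FWER guarantee); and the wrapper
recovery protocol — 4 planted d = 1 features among 56 independent
columns, n = 300 balanced, 20 experiments × 20 evolutions with a
diversity-heavy GA profile (pop 40, 8 generations, sparse init 0.10,
k = 3). That profile is chosen so that planted bits (ΔAUC ≈ 0.03) are
selected reliably while near-neutral pseudo-informative null bits
(ΔAUC ≈ 0.002, within fold noise) do not systematically enrich; a
longer, fully converging GA drives such bits toward fixation — see the
caveat under *Wrapper selection*.

## Known limitations

- The generator's Gaussian features with a two-factor correlation
  structure do not reproduce real ERP covariance (component-specific
  factors, age trends, cohort effects); recovery results validate the
  code, not field performance.
- The EM model ignores gender/age as predictors of ERP features, so MAR
  mechanisms driven by covariates other than the modeled block reduce to
  MCAR from the model's perspective (diagnostics still flag them).
- BHC is exact greedy agglomeration, O(n²) candidate evaluations per
  build; n in the low hundreds is comfortable, tens of thousands is not.
- The split-plot machinery is specialized to 2-level within-subject
  factors (where it is exact); >2 levels would need sphericity handling
  it deliberately does not implement.
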