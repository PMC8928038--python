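# Methods

## The problem

Episode-level admissions records for opioid-use-disorder (OUD) treatment
show, marginally, that episodes involving African American clients often
wait *fewer* days to enter treatment than episodes involving White clients.
That marginal comparison hides heterogeneity: inside specific service
configurations the sign reverses and African American episodes wait
substantially more often.  `vtwins` implements a two-step subgroup-analysis
procedure ("virtual twins") that searches for the covariate-defined
subgroups in which the race effect on waiting is largest, and then
validates those subgroups with multiplicity-controlled proportion tests.

Throughout, an episode is a row (Y, D, X₁…Xₚ): Y ∈ {0,1} is the
dichotomized wait outcome (0 = same-day entry, 1 = one day or more),
D ∈ {0,1} the group indicator (1 = African American, 0 = White), and the
Xⱼ are categorical or ordinal admission covariates (state, age band,
service setting, referral source, medication-assisted therapy, prior
episodes, …).

## The two-step procedure

**Step 1.** The table is split once, at random and without stratification,
into a 20% training part and an 80% estimation part.  A probability
classifier f(D, X) ≈ P(Y=1 | D, X) is fitted on the training part with
race among its predictors.  For every estimation episode the *virtual
probability difference*

    Z_i = f(1, X_i) − f(0, X_i)

is computed — the same covariate vector scored under both race values,
regardless of the episode's actual race.  Z_i is the model's estimate of
the extra probability of waiting attributable solely to being recorded
African American.  Computing Z on held-out rows avoids fitting the Step-2
tree to the classifier's own training noise; splitting once (rather than
averaging many splits) keeps the final tree interpretable.

**Step 2.** A CART-style regression tree is fitted to (X without race, Z).
Leaves with high mean Z are subgroups in which the estimated race effect
is concentrated; the leaf with maximal mean Z (subject to an optional
minimum-coverage filter, ties to larger coverage) is the "most vulnerable"
subgroup, and its root-to-leaf conjunction of conditions is the subgroup
rule.  Race is structurally banned from Step-2 covariates and this is
enforced at the API level.

**Validation.** Each leaf rule is re-applied to the full episode table,
its race × wait 2×2 contingency table formed, and a two-sample proportion
test run with the Yates continuity correction:

    z = max(0, |p₁ − p₂| − c) / √(p̂(1−p̂)(1/n₁ + 1/n₂)),
    c = 1/(2n₁) + 1/(2n₂),  p̂ = (k₁+k₂)/(n₁+n₂),

whose square is exactly the continuity-corrected 2×2 chi-square.  The
two-sided p-value is compared against the Bonferroni threshold α/L with
L the number of tree leaves (non-evaluable leaves — those missing one
race group — are excluded from L).  The unconditional comparison over the
whole table is reported alongside at level α, and a reversal flag is
raised when the selected subgroup's race gap and the marginal gap have
opposite signs.  The continuity correction is on by default because the
published worked examples reproduce exactly under it (California
117/426 vs 920/5084 gives p = 2.77×10⁻⁶ corrected, ≈2.0×10⁻⁶
uncorrected); it is exposed as a flag.  p-values below 2.2×10⁻¹⁶ are
displayed as "< 2.20e-16" in reports, following the conventional floor.

## Step-1 models

Three families are supported behind one contract (probabilities in [0,1],
frozen one-hot schema, counterfactual scoring under either D):

* `random_forest` — `sklearn.ensemble.RandomForestClassifier`;
* `elastic_net` — `sklearn.linear_model.LogisticRegression` (saga,
  l1_ratio 0.5);
* `boosting_tree` — `xgboost.XGBClassifier`.

`compare_classifiers` evaluates specs over repeated random 20/80 splits:
misclassification percent at threshold 0.5 (overall and per race group)
and rank-statistic AUC, reported as means and SDs over replicates.  The
20% training fraction is deliberately small — the large part is needed
downstream for Z estimation — and is configurable.

For the virtual-twins run itself, `default_step1_spec()` departs from a
conventional classification forest in three ways, all aimed at the
quality of the counterfactual *contrast* rather than raw classification:

* **Race-interaction features.**  The design matrix carries D × one-hot(X)
  products in addition to the main effects.  A forest with race as a
  single main-effect column among dozens underfits race-by-covariate
  interactions — exactly the quantity Z is built from; explicit
  interaction features are the standard remedy in the virtual-twins
  literature.  (Measured on the synthetic conditions below, the
  inside-subgroup contrast recovered roughly triples.)
* **Large leaves** (`min_samples_leaf=200`).  Z inherits the estimation
  error of f cell-by-cell; small noisy leaves translate directly into
  spatially structured Z noise that the Step-2 tree would happily split.
* **Moderate feature subsampling** (`max_features=0.3`, 500 trees), so a
  single bad greedy structure cannot dominate the whole ensemble.

Even so the forest *attenuates* the contrast: on synthetic data with a
true inside/outside Z gap of 0.119, the fitted gap is typically
0.08–0.12.  Attenuation shrinks effect estimates toward zero; it costs
power but does not manufacture subgroups, and the validation stage tests
real outcomes, not Z.

## The regression tree

Written from scratch (`vtwins.tree`) so that the split semantics are fully
specified:

* split criterion: SSE reduction Δ = SSE(parent) − SSE(left) − SSE(right);
* categorical search: levels ordered by mean response, contiguous cuts
  scanned — optimal over all 2^(L−1)−1 bipartitions for squared error
  (verified against exhaustive enumeration in the tests up to 8 levels);
* ordinal search: threshold cuts in the declared level order, condition
  "x ≤ t"; declared-but-unobserved levels below the threshold satisfy it;
* left child = condition satisfied (the figure convention); the
  satisfying subset is the lower-mean side;
* leaf prediction: mean Z of its rows; the root therefore predicts the
  overall mean Z exactly, and Σ(leaf mean × leaf count)/n ≡ mean(Z) to
  1e-12 (tested);
* ties: exactly equal gains go to the variable earlier in column order,
  then the smaller satisfying subset — the fit is fully deterministic
  (`TreeParams.seed` exists only for audit logging);
* stopping: `max_depth` (default 4), `min_leaf` (default 1% of rows),
  `min_split` (default 2·min_leaf), absolute `min_gain` (default 0) and
  relative `complexity` (default 0.05 of root SSE).

The `complexity` floor is the load-bearing stopping rule and the one
genuinely open design choice.  The Step-2 response is an *estimated*
quantity whose error is shared across whole covariate cells (every episode
in a cell gets the same forest error), so a CART with a zero gain floor
reliably grows splits that reproduce that shared noise; the selected leaf
then carries spurious conditions.  Measured on the synthetic study
conditions, noise splits inside an isolated subgroup gain ≤ 3% of root
SSE while genuine subgroup splits gain 30–55%; the default 0.05 separates
the two regimes with margin.  This is deliberately stronger than the
classical rpart default (cp = 0.01), which left spurious conditions on the
selected rule in roughly a third of runs.  No cost-complexity pruning pass
is performed; there are no surrogate splits because preparation deletes
missing rows.

## The synthetic episode generator

Real admissions microdata are restricted-access, so the package ships a
generator that emulates their structure.  The outcome model is logistic:

    logit P(Y=1 | D, X) = β₀ + Σⱼ βⱼ(Xⱼ) + (δ₀ + δ_S·1[X ∈ S]) · D

with covariates drawn independently from per-variable level probabilities,
D ~ Bernoulli(race prevalence 0.163), and S a planted
conjunction-of-conditions subgroup.  Because race enters only through δ₀
and δ_S, the closed-form oracle

    Z(x) = expit(η + δ₀ + δ_S·1[x ∈ S]) − expit(η),  η = β₀ + Σβⱼ(xⱼ)

is exact and the planted rule is the unique maximizer of true Z — the
property the recovery tests rely on.

The **default configuration** has 10 covariates (including an 8-level
state variable), illustrative level probabilities and modest covariate
effects with signs following published descriptive patterns, and a planted
reversal: δ₀ = −0.3 (African American episodes wait less marginally) with
δ₀ + δ_S = +0.6 inside {state ∈ {CA, MD}} ∧ {residential or intensive
outpatient} ∧ {not homeless} (~12.6% of episodes).  The intercept
β₀ = −0.85065 was calibrated once, by large-sample simulation, so the
marginal wait prevalence is 0.302 — the value implied by the published
admission-census totals (284,235 waited of 941,286).  "Unknown" is an
ordinary category level injected cell-wise; missing cells are a separate
marker and cause row deletion at prep (complete-case, no imputation),
matching how such data are actually cleaned.

The **recovery configuration** (`recovery_config`) is the frozen condition
set for the planted-rule recovery study: n = 50,000 episodes, 10
covariates with all βⱼ = 0, a two-condition planted rule
(`service_setting = residential` ∧ `homeless = No`, jointly 25% of
episodes), δ₀ = −0.3, and δ_S solved in closed form so the true inside-Z
is exactly +0.06 (outside ≈ −0.059).  With `null=True` both race effects
are zero — the no-disparity null used for type-I checks.

What the generator does **not** emulate: covariate dependence (covariates
are independent), person-level episode linkage, state-specific sample
sizes, and informative missingness.  Passing recovery tests therefore
demonstrate that the pipeline finds planted conjunctive heterogeneity
under realistic noise; they do not certify behavior under correlated
covariates or non-random missingness.

## Measured operating characteristics

Computed by the test suite under the frozen conditions above (20 master
seeds, per-stage seeds derived by hashing):

* planted-rule recovery: the selected most-vulnerable rule's variable set
  equals the planted set in 18/20 seeds, and its full-table disparity is
  Bonferroni-significant in 18/20.  The two failures are splits whose
  *training* data happened to carry almost no in-cell race contrast
  (raw contrasts +0.046 and +0.014 against a true +0.06) — irreducible
  sampling noise when only 20% of 50,000 episodes train Step 1.
* null control (δ₀ = δ_S = 0): a Bonferroni-significant proper subgroup
  (a leaf with at least one condition) appears in 2/20 seeds.
* generator calibration: simulated marginal prevalence within ±0.01 of
  0.302 at n = 100,000.

Problem sizes in the routine tests are scaled to what the checks need:
the recovery study runs the full n = 50,000 design; structural and oracle
tests use hundreds of rows.

## Numerical and degenerate-input conventions

* Proportion test with pooled p̂ ∈ {0,1}: reported as a degenerate result
  with p = 1 and a warning (no variance to test against).
* Corrected z is clamped at 0 when the correction exceeds |p₁ − p₂|.
* Split gains must be strictly positive (beyond a relative 1e-12 epsilon)
  even when all floors are zero; a constant response yields no split.
* Leaves missing one race group are non-evaluable and excluded from the
  Bonferroni denominator with a warning.
* Every stage's randomness derives from a master seed via
  SHA-256(seed:stage-name) mod 2³¹, so editing one stage's configuration
  does not perturb another's stream.

## Known limitations

* Forest attenuation biases |Z| toward zero (documented above); leaf mean
  Z values understate true probability increments, which is why validation
  uses raw outcome proportions rather than Z.
* The marginal/subgroup reversal diagnostic compares signs only; it does
  not quantify confounding.
* Bonferroni control is per-run; rules discovered by re-running with many
  seeds and keeping the best would need additional correction.
* The tree offers no surrogate splits, multiway splits or cost-complexity
  cross-validation pruning; depth and the complexity floor are the only
  capacity controls.
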