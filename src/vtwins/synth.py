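"""Synthetic TEDS-like episode generator with a planted disparity subgroup.

Real treatment-admission microdata with race and wait-time outcomes are
restricted-access, so the pipeline ships a fully specified generating model
that emulates their structure: multi-level categorical covariates (including
a many-level state variable), "Unknown" category codes, row-level
missingness, a marginal wait prevalence near 0.30, and — crucially — a race
effect on waiting that is negative (or null) marginally but strongly
positive inside a planted conjunction-of-conditions subgroup.  That last
feature reproduces the Simpson-style reversal seen in real admissions data,
where African American episodes wait *less* overall yet wait substantially
*more* inside specific service configurations.

The outcome model is logistic:

    logit P(Y = 1 | D, X) = beta0 + sum_j beta_j(X_j)
                            + (delta0 + deltaS * 1[X in S]) * D

where ``D`` is the group indicator (1 = African American, 0 = White), ``S``
is the planted subgroup (a conjunction of level conditions), ``delta0`` is
the baseline race effect and ``deltaS`` the extra race effect inside S.
Because race enters only through ``delta0``/``deltaS``, the planted rule is
the unique maximizer of the true counterfactual difference

    Z(x) = expit(eta(x) + delta0 + deltaS * 1[x in S]) - expit(eta(x)),

for which :func:`true_virtual_difference` is the exact closed-form oracle.
Covariates are sampled independently; the generator makes no attempt to
model covariate dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .table import GROUP, OUTCOME, EpisodeTable, SchemaError

MISSING = np.nan
UNKNOWN = "Unknown"

#: Marginal wait prevalence the default configuration is calibrated to:
#: 284,235 waited episodes out of 941,286 admissions.
TARGET_PREVALENCE = 284235 / 941286

#: Fraction of episodes involving African American clients in the same
#: admissions census (153,448 / 941,286).
DEFAULT_RACE_PREVALENCE = 0.163


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Variable:
    name: str
    kind: str                    # "categorical" | "ordinal"
    levels: tuple
    probs: tuple

    def __post_init__(self):
        if self.kind not in ("categorical", "ordinal"):
            raise ConfigError(f"variable {self.name!r}: kind must be "
                              f"'categorical' or 'ordinal', got {self.kind!r}")
        if len(self.levels) < 2:
            raise ConfigError(f"variable {self.name!r}: needs >= 2 levels")
        if len(self.levels) != len(set(self.levels)):
            raise ConfigError(f"variable {self.name!r}: duplicate levels")
        p = np.asarray(self.probs, dtype=float)
        if len(p) != len(self.levels):
            raise ConfigError(f"variable {self.name!r}: probs length mismatch")
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigError(f"variable {self.name!r}: level probabilities "
                              "must be nonnegative and sum to 1")


@dataclass(frozen=True)
class CovariateSchema:
    variables: tuple

    def __post_init__(self):
        names = [v.name for v in self.variables]
        if len(names) != len(set(names)):
            raise ConfigError("schema: duplicate variable names")
        for reserved in (GROUP, OUTCOME):
            if reserved in names:
                raise ConfigError(f"schema: {reserved!r} is reserved and may "
                                  "not appear as a covariate")

    @property
    def names(self) -> list:
        return [v.name for v in self.variables]

    def __getitem__(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise SchemaError(f"unknown variable {name!r}")

    def levels_dict(self) -> dict:
        return {v.name: list(v.levels) for v in self.variables}

    def ordinal_names(self) -> frozenset:
        return frozenset(v.name for v in self.variables if v.kind == "ordinal")


@dataclass(frozen=True)
class PlantedSubgroup:
    """Conjunction of level conditions with an amplified race effect."""
    conditions: tuple            # ((variable, frozenset(levels)), ...)
    delta0: float = 0.0          # baseline race log-odds effect
    deltaS: float = 0.0          # extra race log-odds effect inside S

    def check(self, schema: CovariateSchema) -> None:
        for var, allowed in self.conditions:
            v = schema[var]
            allowed = frozenset(allowed)
            if not allowed or not allowed < set(v.levels):
                raise ConfigError(
                    f"planted condition on {var!r}: allowed level subset must "
                    "be nonempty and proper")

    def variables(self) -> frozenset:
        return frozenset(var for var, _ in self.conditions)


@dataclass(frozen=True)
class GeneratorConfig:
    schema: CovariateSchema
    n_episodes: int
    race_prevalence: float
    intercept: float
    beta: Mapping[str, Mapping] = field(default_factory=dict)
    planted: PlantedSubgroup = PlantedSubgroup(conditions=())
    missing_rate: float = 0.0
    unknown_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_episodes < 1:
            raise ConfigError("n_episodes: must be >= 1")
        for name in ("race_prevalence", "missing_rate", "unknown_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}: must be in [0, 1], got {v}")
        for var in self.beta:
            self.schema[var]  # raises SchemaError if absent
        self.planted.check(self.schema)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _eta(config: GeneratorConfig, X: pd.DataFrame) -> np.ndarray:
    """Linear predictor without the race terms: beta0 + sum_j beta_j(x_j)."""
    eta = np.full(len(X), config.intercept, dtype=float)
    for var, coefs in config.beta.items():
        col = X[var]
        eta += col.map(lambda lv: coefs.get(lv, 0.0)).to_numpy(dtype=float)
    return eta


def in_planted_subgroup(planted: PlantedSubgroup, X: pd.DataFrame) -> np.ndarray:
    """Boolean membership vector for the planted conjunction."""
    mask = np.ones(len(X), dtype=bool)
    for var, allowed in planted.conditions:
        mask &= X[var].isin(list(allowed)).to_numpy()
    return mask


def generate_episodes(config: GeneratorConfig) -> EpisodeTable:
    """Draw an episode table from the configured logistic model.

    Deterministic for a fixed config and seed.  No missingness is injected
    here; see :func:`inject_missing_and_unknowns`.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_episodes
    cols = {}
    for v in config.schema.variables:
        codes = rng.choice(len(v.levels), size=n, p=np.asarray(v.probs, float))
        cols[v.name] = pd.Categorical.from_codes(
            codes, categories=[str(l) for l in v.levels]).astype(str)
    X = pd.DataFrame(cols)
    d = (rng.random(n) < config.race_prevalence).astype(int)
    eta = _eta(config, X)
    s = in_planted_subgroup(config.planted, X)
    p = expit(eta + (config.planted.delta0 + config.planted.deltaS * s) * d)
    y = (rng.random(n) < p).astype(int)
    df = pd.DataFrame({OUTCOME: y, GROUP: d})
    df = pd.concat([df, X], axis=1)
    return EpisodeTable.from_dataframe(
        df, levels=config.schema.levels_dict(),
        ordinal=config.schema.ordinal_names())


def true_virtual_difference(config: GeneratorConfig, covariates) -> np.ndarray | float:
    """Exact counterfactual race effect on the probability scale.

    Returns ``expit(eta + delta0 + deltaS*1[x in S]) - expit(eta)`` where
    ``eta = beta0 + sum_j beta_j(x_j)``; no sampling is involved.  Accepts a
    single mapping of covariate values or a DataFrame of rows (a scalar or
    vector is returned accordingly).
    """
    scalar = isinstance(covariates, Mapping)
    X = pd.DataFrame([covariates]) if scalar else pd.DataFrame(covariates)
    for v in config.schema.variables:
        if v.name not in X.columns:
            raise SchemaError(f"covariate {v.name!r} missing from probe")
        bad = set(X[v.name].unique()) - set(str(l) for l in v.levels)
        if bad:
            raise SchemaError(
                f"variable {v.name!r}: unknown level(s) {sorted(bad, key=str)!r}")
    eta = _eta(config, X)
    s = in_planted_subgroup(config.planted, X)
    z = expit(eta + config.planted.delta0 + config.planted.deltaS * s) - expit(eta)
    return float(z[0]) if scalar else z


def inject_missing_and_unknowns(table: EpisodeTable, missing_rate: float,
                                unknown_rate: float, seed: int = 0) -> EpisodeTable:
    """Independently blank or "Unknown"-code covariate cells.

    Each covariate cell is replaced by the missing marker with probability
    ``missing_rate`` and, failing that, by the variable's ``"Unknown"``
    level with probability ``unknown_rate``.  Outcome and group columns are
    never altered.  "Unknown" is an ordinary category level (it survives
    data prep); missing cells cause row deletion during prep.
    """
    for name, rate in (("missing_rate", missing_rate), ("unknown_rate", unknown_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ConfigError(f"{name}: must be in [0, 1], got {rate}")
    if missing_rate == 0 and unknown_rate == 0:
        return table
    rng = np.random.default_rng(seed)
    df = table.data.copy()
    levels = {k: list(v) for k, v in table.levels.items()}
    for c in table.covariates:
        u = rng.random(len(df))
        df[c] = df[c].astype(object)
        df.loc[u < missing_rate, c] = MISSING
        unk = (u >= missing_rate) & (u < missing_rate + (1 - missing_rate) * unknown_rate)
        if unk.any():
            df.loc[unk, c] = UNKNOWN
            if UNKNOWN not in levels.get(c, []):
                levels[c] = levels.get(c, []) + [UNKNOWN]
    return replace(table, data=df, levels=levels)


# ---------------------------------------------------------------------------
# shipped configurations
# ---------------------------------------------------------------------------

def config_to_dict(config: GeneratorConfig) -> dict:
    """Plain-dict form of a generator config, for YAML/JSON run logs."""
    return {
        "n_episodes": config.n_episodes,
        "race_prevalence": config.race_prevalence,
        "intercept": config.intercept,
        "beta": {v: dict(c) for v, c in config.beta.items()},
        "planted": {
            "conditions": [[var, sorted(map(str, allowed))]
                           for var, allowed in config.planted.conditions],
            "delta0": config.planted.delta0,
            "deltaS": config.planted.deltaS,
        },
        "missing_rate": config.missing_rate,
        "unknown_rate": config.unknown_rate,
        "seed": config.seed,
        "schema": [{"name": v.name, "kind": v.kind,
                    "levels": [str(l) for l in v.levels],
                    "probs": list(map(float, v.probs))}
                   for v in config.schema.variables],
    }


def default_schema() -> CovariateSchema:
    """Ten-covariate schema echoing the major admission-record variables.

    Level probabilities are illustrative, loosely guided by published
    admission-census marginals; they are not estimates.  The 8-level
    ``state`` variable dominates the planted heterogeneity, mirroring the
    finding that state is by far the most important predictor of waiting.
    """
    V = Variable
    return CovariateSchema(variables=(
        V("state", "categorical",
          ("CA", "MD", "NY", "TX", "FL", "OH", "PA", "WA"),
          (0.22, 0.18, 0.14, 0.12, 0.10, 0.09, 0.08, 0.07)),
        V("age_group", "ordinal",
          ("18-24", "25-34", "35-44", "45-54", "55+"),
          (0.15, 0.40, 0.25, 0.13, 0.07)),
        V("gender", "categorical", ("Male", "Female"), (0.60, 0.40)),
        V("homeless", "categorical", ("No", "Yes"), (0.90, 0.10)),
        V("service_setting", "categorical",
          ("outpatient", "intensive_outpatient", "residential", "detox"),
          (0.50, 0.15, 0.20, 0.15)),
        V("referral_source", "categorical",
          ("self", "provider", "criminal_justice", "community"),
          (0.55, 0.15, 0.20, 0.10)),
        V("mat", "categorical", ("Yes", "No"), (0.40, 0.60)),
        V("prior_episodes", "ordinal", ("0", "1", "2", "3+"),
          (0.35, 0.25, 0.20, 0.20)),
        V("primary_drug", "categorical", ("heroin", "other_opioid"),
          (0.78, 0.22)),
        V("use_frequency", "ordinal", ("none", "some", "daily"),
          (0.22, 0.17, 0.61)),
    ))


#: Covariate log-odds effects for the default configuration (levels not
#: listed carry 0).  Signs follow the descriptive patterns of admission
#: data: residential settings and criminal-justice referrals wait more;
#: detox, medication-assisted therapy, homelessness and repeat episodes
#: wait less.
DEFAULT_BETA = {
    "state": {"CA": 0.25, "MD": 0.15, "TX": -0.10, "OH": -0.20,
              "FL": 0.05, "PA": 0.10, "WA": -0.05},
    "age_group": {"18-24": 0.15, "25-34": 0.10, "45-54": -0.10, "55+": -0.20},
    "gender": {"Female": -0.05},
    "homeless": {"Yes": -0.40},
    "service_setting": {"residential": 0.50, "intensive_outpatient": 0.20,
                        "detox": -0.60},
    "referral_source": {"criminal_justice": 0.30, "provider": 0.15},
    "mat": {"Yes": -0.35},
    "prior_episodes": {"1": -0.10, "2": -0.20, "3+": -0.30},
    "primary_drug": {"other_opioid": -0.10},
    "use_frequency": {"daily": 0.20},
}

#: Intercept calibrated (by large-sample simulation under the default
#: schema, betas and planted effects) so that the marginal wait prevalence
#: is 0.302, matching the 2015-2017 admissions census.
DEFAULT_INTERCEPT = -0.85065


def default_planted() -> PlantedSubgroup:
    """Default planted subgroup: a reversal configuration.

    Marginally the race effect is negative (delta0 = -0.3: African American
    episodes wait less overall), but inside the conjunction it flips to
    +0.6 on the log-odds scale (delta0 + deltaS).  Conditioning on ``state``
    makes the subgroup race effect heterogeneous by state.
    """
    return PlantedSubgroup(
        conditions=(
            ("state", frozenset({"CA", "MD"})),
            ("service_setting", frozenset({"residential", "intensive_outpatient"})),
            ("homeless", frozenset({"No"})),
        ),
        delta0=-0.3,
        deltaS=0.9,
    )


def default_config(n_episodes: int = 50_000, seed: int = 0, *,
                   missing_rate: float = 0.0, unknown_rate: float = 0.0) -> GeneratorConfig:
    """The shipped study conditions: calibrated prevalence, planted reversal."""
    return GeneratorConfig(
        schema=default_schema(),
        n_episodes=n_episodes,
        race_prevalence=DEFAULT_RACE_PREVALENCE,
        intercept=DEFAULT_INTERCEPT,
        beta=DEFAULT_BETA,
        planted=default_planted(),
        missing_rate=missing_rate,
        unknown_rate=unknown_rate,
        seed=seed,
    )


def recovery_schema() -> CovariateSchema:
    """Ten covariates for the planted-rule recovery study: two balanced
    binary condition variables plus eight pure-noise variables (including
    an 8-level state)."""
    V = Variable
    base = default_schema()
    vs = [
        V("service_setting", "categorical", ("residential", "outpatient"), (0.5, 0.5)),
        V("homeless", "categorical", ("No", "Yes"), (0.5, 0.5)),
    ]
    for v in base.variables:
        if v.name not in ("service_setting", "homeless"):
            vs.append(v)
    return CovariateSchema(variables=tuple(vs))


def recovery_config(n_episodes: int = 50_000, seed: int = 0, *,
                    inside_z: float = 0.06, delta0: float = -0.3,
                    null: bool = False) -> GeneratorConfig:
    """Study conditions for subgroup recovery.

    A two-condition subgroup (``service_setting = residential`` and
    ``homeless = No``, jointly 25% of episodes) carries a race effect lifting
    the true counterfactual difference to exactly ``inside_z`` (default
    +0.06); all covariate betas are zero so the planted rule is the only
    signal.  With ``null=True`` both race effects are switched off
    (delta0 = deltaS = 0), the no-disparity null for type-I checks.
    """
    beta0 = float(logit(0.30))
    if null:
        planted = PlantedSubgroup(conditions=(
            ("service_setting", frozenset({"residential"})),
            ("homeless", frozenset({"No"})),
        ), delta0=0.0, deltaS=0.0)
    else:
        # solve expit(beta0 + delta0 + deltaS) = expit(beta0) + inside_z
        deltaS = float(logit(expit(beta0) + inside_z)) - beta0 - delta0
        planted = PlantedSubgroup(conditions=(
            ("service_setting", frozenset({"residential"})),
            ("homeless", frozenset({"No"})),
        ), delta0=delta0, deltaS=deltaS)
    return GeneratorConfig(
        schema=recovery_schema(),
        n_episodes=n_episodes,
        race_prevalence=DEFAULT_RACE_PREVALENCE,
        intercept=beta0,
        beta={},
        planted=planted,
        seed=seed,
    )
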