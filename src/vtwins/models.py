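"""Step-1 probability classifiers: P(wait >= 1 day | race, covariates).

Three classifier families are supported — random forest, elastic net and
boosting tree — behind a common fitted-model contract: a probability
prediction P(Y=1 | D, X) in [0, 1] for any covariate vector matching the
training schema, scoreable under *either* value of the group indicator D
(counterfactual scoring is the whole point of the virtual-twins method).

Categorical covariates are one-hot encoded against the category dictionary
frozen on the analytic table, so training, testing and counterfactual
scoring all share one schema; a fingerprint of that schema guards against
mismatched probes.

:func:`compare_classifiers` is the repeated-split evaluation harness:
each replicate draws one random train/test split (by default 20% train —
deliberately small, as the estimation subset downstream is the large
part), fits every candidate spec on the training part and scores the rest,
reporting misclassification percent (overall and per group, threshold 0.5)
and the rank-statistic AUC.
"""

from __future__ import annotations

import hashlib
import logging
import pickle
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import OneHotEncoder

from ._util import derive_seed
from .table import GROUP, EpisodeTable, SchemaError

logger = logging.getLogger(__name__)


class FitError(ValueError):
    pass


class CapabilityError(ValueError):
    pass


#: Conventional default hyperparameters per family (none are reported for
#: the original analysis, so each family uses its customary settings).
DEFAULT_PARAMS = {
    "random_forest": {"n_estimators": 500, "max_features": "sqrt"},
    "elastic_net": {"C": 1.0, "l1_ratio": 0.5, "max_iter": 5000},
    "boosting_tree": {"n_estimators": 100, "max_depth": 6, "learning_rate": 0.3},
}


@dataclass(frozen=True)
class ClassifierSpec:
    method: str = "random_forest"
    params: Mapping = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.method not in DEFAULT_PARAMS:
            raise ValueError(f"unknown classifier family {self.method!r}; "
                             f"choose from {sorted(DEFAULT_PARAMS)}")

    def resolved_params(self) -> dict:
        out = dict(DEFAULT_PARAMS[self.method])
        out.update(self.params)
        return out

    def build(self):
        p = self.resolved_params()
        if self.method == "random_forest":
            return RandomForestClassifier(random_state=self.seed, n_jobs=1, **p)
        if self.method == "elastic_net":
            return LogisticRegression(solver="saga", random_state=self.seed, **p)
        # boosting tree via xgboost, the library conventionally used for it
        from xgboost import XGBClassifier
        return XGBClassifier(random_state=self.seed, n_jobs=1, verbosity=0, **p)


class _Codec:
    """Frozen one-hot encoding of the covariates plus the race indicator.

    With ``race_interactions=True`` the design also carries the products of
    the race indicator with every one-hot column.  Tree ensembles underfit
    group-by-covariate interactions when the group enters only as a single
    main-effect column; explicit interaction features are the standard
    remedy in the virtual-twins literature and sharpen the counterfactual
    contrast f(1, X) - f(0, X) considerably.
    """

    def __init__(self, covariates: Sequence, levels: Mapping,
                 use_race: bool = True, race_interactions: bool = False):
        self.covariates = list(covariates)
        self.levels = {c: [str(l) for l in levels[c]] for c in self.covariates}
        self.use_race = use_race
        self.race_interactions = race_interactions and use_race
        self._enc = OneHotEncoder(
            categories=[self.levels[c] for c in self.covariates],
            handle_unknown="error", sparse_output=False, dtype=float)
        self._enc.fit(pd.DataFrame({c: [self.levels[c][0]] for c in self.covariates}))
        onehot_vars = []
        for c in self.covariates:
            onehot_vars += [c] * len(self.levels[c])
        self.feature_vars = list(onehot_vars)
        if use_race:
            self.feature_vars.append(GROUP)
        if self.race_interactions:
            self.feature_vars += list(onehot_vars)

    @property
    def fingerprint(self) -> str:
        blob = repr(sorted((c, tuple(self.levels[c])) for c in self.covariates))
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def transform(self, X: pd.DataFrame, d) -> np.ndarray:
        missing = [c for c in self.covariates if c not in X.columns]
        if missing:
            raise SchemaError(f"probe lacks covariate(s) {missing!r}")
        Xs = X[self.covariates].astype(str)
        for c in self.covariates:
            bad = set(Xs[c].unique()) - set(self.levels[c])
            if bad:
                raise SchemaError(f"variable {c!r}: unseen level(s) "
                                  f"{sorted(bad)!r}")
        M = self._enc.transform(Xs)
        if self.use_race:
            dcol = np.asarray(d, dtype=float)
            if dcol.ndim == 0:
                dcol = np.full(len(X), float(dcol))
            if dcol.shape[0] != len(X):
                raise SchemaError("group vector length mismatch")
            dcol = dcol.reshape(-1, 1)
            parts = [M, dcol]
            if self.race_interactions:
                parts.append(M * dcol)
            M = np.hstack(parts)
        return M


@dataclass
class FittedWaitModel:
    """Opaque fitted classifier honoring P(Y=1 | D, X) in [0, 1]."""
    estimator: object
    codec: _Codec
    spec: ClassifierSpec
    feature_scale: Optional[np.ndarray] = None   # train-column SDs (elastic net)

    @property
    def fingerprint(self) -> str:
        return self.codec.fingerprint

    def predict_proba_df(self, X: pd.DataFrame, d) -> np.ndarray:
        M = self.codec.transform(X, d)
        p = self.estimator.predict_proba(M)[:, 1]
        return np.clip(p, 0.0, 1.0)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "FittedWaitModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def fit_wait_model(train: EpisodeTable, spec: ClassifierSpec = ClassifierSpec(),
                   use_race: bool = True,
                   race_interactions: bool = False) -> FittedWaitModel:
    """Fit one Step-1 classifier on a prepared training table."""
    train.validate_binary()
    y = train.y
    if len(np.unique(y)) < 2:
        raise FitError("training data contain a single outcome class")
    codec = _Codec(train.covariates, train.levels, use_race=use_race,
                   race_interactions=race_interactions)
    M = codec.transform(train.X, train.d)
    est = spec.build()
    est.fit(M, y)
    scale = M.std(axis=0)
    logger.info("fit %s on %d rows, %d features (params %r)",
                spec.method, len(y), M.shape[1], spec.resolved_params())
    return FittedWaitModel(est, codec, spec, feature_scale=scale)


def predict_wait_probability(model: FittedWaitModel, d, X) -> np.ndarray:
    """P(Y=1 | D=d, X) for a DataFrame of covariate rows; d may differ from
    the episodes' actual group — counterfactual scoring is supported."""
    X = pd.DataFrame(X)
    return model.predict_proba_df(X, d)


def variable_importance(model: FittedWaitModel) -> list:
    """Per-variable importance, descending.

    Tree families aggregate impurity-decrease importances over a variable's
    one-hot columns; the elastic net aggregates absolute standardized
    coefficients.  Scores are nonnegative; one entry per input variable
    (including race when it was a predictor).
    """
    est = model.estimator
    if hasattr(est, "feature_importances_"):
        raw = np.asarray(est.feature_importances_, dtype=float)
    elif hasattr(est, "coef_"):
        scale = (model.feature_scale if model.feature_scale is not None
                 else np.ones(est.coef_.shape[1]))
        raw = np.abs(est.coef_.ravel()) * scale
    else:
        raise CapabilityError(
            f"{model.spec.method!r} does not expose variable importance")
    agg = {}
    for var, score in zip(model.codec.feature_vars, raw):
        agg[var] = agg.get(var, 0.0) + float(abs(score))
    return sorted(agg.items(), key=lambda kv: (-kv[1], kv[0]))


# ---------------------------------------------------------------------------
# repeated-split comparison harness
# ---------------------------------------------------------------------------

def misclassification_pct(y_true: np.ndarray, scores: np.ndarray,
                          threshold: float = 0.5) -> float:
    """100 x (FP + FN) / n with scores dichotomized at ``threshold``.

    Ties at the threshold go to class 0.
    """
    pred = (np.asarray(scores) > threshold).astype(int)
    return 100.0 * float((pred != np.asarray(y_true)).mean())


def auc_score(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Rank-statistic (Mann-Whitney) area under the ROC curve."""
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        return float("nan")
    return float(roc_auc_score(y_true, scores))


@dataclass(frozen=True)
class ModelComparisonReport:
    table: pd.DataFrame          # per method: mean/sd of metrics
    n_reps: int
    train_frac: float
    replicates: pd.DataFrame     # per (method, rep) raw metrics

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compare_classifiers(table: EpisodeTable, specs: Sequence,
                        n_reps: int = 100, train_frac: float = 0.2,
                        seed: int = 0) -> ModelComparisonReport:
    """Repeated random-split evaluation of candidate Step-1 classifiers."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    table.validate_binary()
    n = table.n
    n_train = max(1, int(round(train_frac * n)))
    if n_train >= n:
        raise ValueError("train fraction leaves no test rows")
    rows = []
    for rep in range(n_reps):
        rng = np.random.default_rng(derive_seed(seed, f"compare-rep-{rep}"))
        for attempt in range(100):
            perm = rng.permutation(n)
            tr_idx, te_idx = perm[:n_train], perm[n_train:]
            if len(np.unique(table.y[tr_idx])) == 2:
                break
            logger.warning("replicate %d: single-class training split, "
                           "resampling", rep)
        else:
            raise FitError("could not draw a two-class training split")
        train = table.subset(table.data.index[tr_idx])
        test = table.subset(table.data.index[te_idx])
        for spec in specs:
            rep_spec = ClassifierSpec(spec.method, spec.params,
                                      seed=derive_seed(spec.seed, f"rep-{rep}"))
            model = fit_wait_model(train, rep_spec)
            scores = model.predict_proba_df(test.X, test.d)
            yte, dte = test.y, test.d
            rows.append({
                "method": spec.method, "rep": rep,
                "misclass_overall": misclassification_pct(yte, scores),
                "misclass_group1": (misclassification_pct(yte[dte == 1], scores[dte == 1])
                                    if (dte == 1).any() else float("nan")),
                "misclass_group0": (misclassification_pct(yte[dte == 0], scores[dte == 0])
                                    if (dte == 0).any() else float("nan")),
                "auc": auc_score(yte, scores),
            })
    reps = pd.DataFrame(rows)
    metrics = ["misclass_overall", "misclass_group1", "misclass_group0", "auc"]
    summary = reps.groupby("method", sort=False)[metrics].agg(["mean", "std"])
    summary.columns = [f"{m}_{s}" for m, s in summary.columns]
    summary = summary.reset_index()
    return ModelComparisonReport(summary, n_reps, train_frac, reps)
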