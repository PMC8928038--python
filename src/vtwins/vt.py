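"""Virtual-twins orchestration: split once, fit, score counterfactually,
grow the subgroup tree.

The two-step procedure:

* **Step 1** — split the analytic table once into a small training part
  (default 20%) and a large estimation part; fit the wait classifier
  f(D, X) on the training part only.
* **Step 2** — for every episode in the estimation part, compute the
  virtual probability difference Z_i = f(1, X_i) - f(0, X_i) (scored under
  both races regardless of the episode's actual race), then fit a
  regression tree to Z on all covariates *except* race.  Leaves with high
  mean Z are the subgroups most vulnerable to the racial disparity.

The split happens exactly once (an interpretable single tree is the
deliverable; replicate-based evaluation lives in the comparison harness),
and Z is computed only on rows the classifier never saw, so the tree is
not fit to its own training noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._util import derive_seed
from .models import ClassifierSpec, FittedWaitModel, fit_wait_model
from .table import EpisodeTable, SchemaError
from .tree import (RegressionTree, SubgroupRule, TreeParams,
                   extract_subgroup_rules, fit_regression_tree,
                   select_most_vulnerable)

logger = logging.getLogger(__name__)


class SplitError(ValueError):
    pass


def default_step1_spec() -> ClassifierSpec:
    """Step-1 forest configuration used for counterfactual scoring.

    Compared with a plain classification forest, leaves are kept large
    (``min_samples_leaf=200``): per-episode counterfactual contrasts
    average over leaf cells, so small noisy leaves translate directly into
    noisy Z values.  A moderate feature subsample (``max_features=0.3``)
    decorrelates the trees without starving the race column of chances to
    split, and 500 trees keep the ensemble average stable.
    """
    return ClassifierSpec("random_forest",
                          {"n_estimators": 500, "min_samples_leaf": 200,
                           "max_features": 0.3})


class DegenerateTreeError(ValueError):
    pass


@dataclass(frozen=True)
class VirtualDifferenceVector:
    """Per-episode Z_i aligned to the estimation subset's row order."""
    values: np.ndarray
    model_fingerprint: str
    split_seed: int

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.isfinite(v).all():
            raise ValueError("non-finite virtual differences")
        if (np.abs(v) > 1.0 + 1e-12).any():
            raise ValueError("virtual differences must lie in [-1, 1]")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class VTResult:
    model: FittedWaitModel
    train: EpisodeTable
    estimation: EpisodeTable
    z: VirtualDifferenceVector
    tree: RegressionTree
    rules: list
    selected: SubgroupRule
    seed: int


def split_once(table: EpisodeTable, train_frac: float = 0.2,
               seed: int = 0):
    """Disjoint, exhaustive two-part random partition (unstratified)."""
    if not 0.0 < train_frac < 1.0:
        raise SplitError("train_frac must be in (0, 1)")
    n = table.n
    if n < 2:
        raise SplitError("need at least 2 rows to split")
    n_train = int(round(train_frac * n))
    if n_train == 0 or n_train == n:
        raise SplitError("split produces an empty partition")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    idx = table.data.index
    train = table.subset(idx[perm[:n_train]])
    estimation = table.subset(idx[perm[n_train:]])
    return train, estimation


def compute_virtual_differences(model: FittedWaitModel,
                                estimation: EpisodeTable,
                                split_seed: int = 0) -> VirtualDifferenceVector:
    """Z_i = f(1, X_i) - f(0, X_i) for every estimation row, in row order."""
    p1 = model.predict_proba_df(estimation.X, 1)
    p0 = model.predict_proba_df(estimation.X, 0)
    return VirtualDifferenceVector(values=p1 - p0,
                                   model_fingerprint=model.fingerprint,
                                   split_seed=split_seed)


def run_virtual_twins(table: EpisodeTable,
                      spec: Optional[ClassifierSpec] = None,
                      tree_params: TreeParams = TreeParams(),
                      train_frac: float = 0.2,
                      seed: int = 0,
                      min_coverage: float = 0.0,
                      race_interactions: bool = True,
                      require_split: bool = False) -> VTResult:
    """End-to-end two-step run; deterministic for a fixed seed.

    Step-1 defaults to :func:`default_step1_spec` with explicit
    race-interaction features (see :class:`~vtwins.models.ClassifierSpec`
    and the codec notes in :mod:`vtwins.models`).
    """
    table.validate_binary()
    if spec is None:
        spec = default_step1_spec()
    split_seed = derive_seed(seed, "vt-split")
    train, estimation = split_once(table, train_frac, seed=split_seed)
    model_spec = ClassifierSpec(spec.method, spec.params,
                                seed=derive_seed(seed, "vt-model"))
    model = fit_wait_model(train, model_spec,
                           race_interactions=race_interactions)
    z = compute_virtual_differences(model, estimation, split_seed=split_seed)
    X = estimation.X
    if estimation.group in X.columns:   # defensive; X already excludes it
        raise SchemaError("race column leaked into Step-2 covariates")
    tree = fit_regression_tree(
        X, z.values, params=tree_params,
        ordinal=frozenset(o for o in estimation.ordinal if o in X.columns),
        level_orders={v: list(estimation.levels[v]) for v in X.columns
                      if v in estimation.levels})
    if require_split and tree.root.is_leaf:
        raise DegenerateTreeError("tree degenerated to a single leaf")
    rules = extract_subgroup_rules(tree)
    selected = select_most_vulnerable(rules, min_coverage=min_coverage)
    logger.info("virtual twins: split %d/%d, %d leaves, selected rule "
                "mean Z=%.4f coverage=%.1f%% [%s]",
                train.n, estimation.n, len(rules), selected.mean_z,
                100 * selected.coverage, selected.describe())
    return VTResult(model=model, train=train, estimation=estimation, z=z,
                    tree=tree, rules=rules, selected=selected, seed=seed)
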