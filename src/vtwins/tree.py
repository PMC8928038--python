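"""CART-style regression tree on the virtual probability difference.

This is the Step-2 engine of the virtual-twins procedure, written from
scratch so the split search, stopping rules and rule extraction are fully
specified:

* split criterion: reduction in within-node sum of squared errors (SSE),
  the classical regression-tree criterion;
* categorical variables: levels are ordered by their mean response and
  contiguous cut points are scanned — for squared-error loss this attains
  the optimum over all 2^(L-1) - 1 bipartitions;
* ordinal variables: thresholds scanned in the declared level order,
  condition "level <= threshold";
* child order: the LEFT child always holds the rows *satisfying* the split
  condition (the lower-mean side), matching the figure convention that the
  left branch means the condition is met;
* leaf prediction: the mean response of the leaf's rows.

Stopping is controlled by ``max_depth``, ``min_split``/``min_leaf`` row
counts, an absolute gain floor ``min_gain``, and a relative complexity
floor ``complexity`` (a split must reduce SSE by at least ``complexity``
times the root SSE — the rpart ``cp`` convention).  The complexity floor
is what keeps the trees shallow and interpretable: the Step-2 response is
a model-estimated counterfactual contrast whose sampling noise is spatially
structured (whole covariate cells share one estimation error), so splits
with small relative gains are overwhelmingly fits to that shared noise
rather than to real effect heterogeneity; the default of 0.05 prunes them
while retaining splits that explain a material share of the Z variance.  Exact gain ties are broken toward the
variable earlier in column order, then the smaller satisfying subset; the
procedure is deterministic.

A root-to-leaf path is a :class:`SubgroupRule`: a conjunction of satisfied
or violated split conditions, carrying the leaf's mean response and its
coverage of the estimation rows.  The leaf with maximal mean defines the
subgroup most vulnerable to the disparity under study.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .table import GROUP, SchemaError


class ContractViolation(ValueError):
    """The race/group column reached the Step-2 tree."""


class DataError(ValueError):
    pass


@dataclass(frozen=True)
class TreeParams:
    max_depth: int = 4
    min_split: Optional[int] = None      # default: 2 * min_leaf
    min_leaf: Optional[int] = None       # default: max(1, round(0.01 * n))
    min_gain: float = 0.0                # absolute SSE-reduction floor
    complexity: float = 0.05             # relative floor: fraction of root SSE
    seed: int = 0                        # audit only; fitting is deterministic

    def __post_init__(self):
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.min_leaf is not None and self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if (self.min_split is not None and self.min_leaf is not None
                and self.min_split < 2 * self.min_leaf):
            raise ValueError("min_split must be >= 2 * min_leaf")
        if self.min_gain < 0 or self.complexity < 0:
            raise ValueError("gain floors must be >= 0")

    def resolve(self, n: int) -> "TreeParams":
        min_leaf = self.min_leaf if self.min_leaf is not None else max(1, round(0.01 * n))
        min_split = self.min_split if self.min_split is not None else 2 * min_leaf
        return TreeParams(self.max_depth, min_split, min_leaf,
                          self.min_gain, self.complexity, self.seed)


@dataclass(frozen=True)
class SplitCondition:
    """Satisfied iff the variable's value lies in ``levels``.

    For ordinal variables the satisfying set is the prefix of the declared
    level order up to ``threshold`` (condition "x <= threshold"); for
    categorical variables it is an arbitrary subset.
    """
    variable: str
    levels: frozenset
    kind: str = "categorical"
    threshold: Optional[object] = None    # last satisfying level, ordinal only

    def evaluate(self, df: pd.DataFrame) -> np.ndarray:
        if self.variable not in df.columns:
            raise SchemaError(f"unknown variable {self.variable!r}")
        return df[self.variable].isin(list(self.levels)).to_numpy()

    def describe(self, negated: bool = False) -> str:
        if self.kind == "ordinal" and self.threshold is not None:
            op = ">" if negated else "<="
            return f"{self.variable} {op} {self.threshold}"
        op = "not in" if negated else "in"
        lv = ", ".join(sorted(map(str, self.levels)))
        return f"{self.variable} {op} {{{lv}}}"


@dataclass
class Node:
    n: int
    mean: float
    coverage: float
    condition: Optional[SplitCondition] = None
    left: Optional["Node"] = None         # condition satisfied
    right: Optional["Node"] = None        # condition violated

    @property
    def is_leaf(self) -> bool:
        return self.condition is None


@dataclass(frozen=True)
class SubgroupRule:
    """Conjunction of (condition, negated) pairs along a root-to-leaf path."""
    conditions: tuple                     # ((SplitCondition, negated), ...)
    mean_z: float
    n: int
    coverage: float
    leaf_index: int = 0

    def variables(self) -> frozenset:
        return frozenset(c.variable for c, _ in self.conditions)

    def mask(self, df: pd.DataFrame) -> np.ndarray:
        m = np.ones(len(df), dtype=bool)
        for cond, negated in self.conditions:
            sat = cond.evaluate(df)
            m &= ~sat if negated else sat
        return m

    def describe(self) -> str:
        if not self.conditions:
            return "(all episodes)"
        return " AND ".join(c.describe(neg) for c, neg in self.conditions)


@dataclass
class RegressionTree:
    root: Node
    n: int
    params: TreeParams
    variables: list

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        out = np.empty(len(df), dtype=float)
        idx = np.arange(len(df))

        def recurse(node: Node, rows: np.ndarray) -> None:
            if node.is_leaf:
                out[rows] = node.mean
                return
            sat = node.condition.evaluate(df.iloc[rows])
            recurse(node.left, rows[sat])
            recurse(node.right, rows[~sat])

        recurse(self.root, idx)
        return out

    def leaves(self) -> list:
        acc = []

        def walk(node):
            if node.is_leaf:
                acc.append(node)
            else:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return acc

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())


# ---------------------------------------------------------------------------
# split search
# ---------------------------------------------------------------------------

_EPS = 1e-12


def _scan(order_levels: Sequence, counts: np.ndarray, sums: np.ndarray,
          min_leaf: int):
    """Best contiguous prefix cut over levels already in scan order.

    Returns (gain, cut_index) with the satisfied side = prefix; the SSE
    reduction is computed from the sufficient statistics
    gain = S_L^2/n_L + S_R^2/n_R - S^2/n.
    """
    n_tot = counts.sum()
    s_tot = sums.sum()
    base = s_tot * s_tot / n_tot
    n_l = np.cumsum(counts)[:-1]
    s_l = np.cumsum(sums)[:-1]
    n_r = n_tot - n_l
    s_r = s_tot - s_l
    ok = (n_l >= min_leaf) & (n_r >= min_leaf)
    if not ok.any():
        return None
    gains = np.where(ok, s_l * s_l / np.maximum(n_l, 1)
                     + s_r * s_r / np.maximum(n_r, 1) - base, -np.inf)
    k = int(np.argmax(gains))   # first maximum -> smallest satisfying prefix
    return float(gains[k]), k


def best_split(values: pd.Series, z: np.ndarray, params: TreeParams,
               kind: str = "categorical", level_order: Optional[Sequence] = None):
    """Best SSE-reducing split of one covariate; ``None`` if inadmissible.

    ``params`` must already be resolved (integer min_split/min_leaf).  The
    relative ``complexity`` floor is applied by the tree fitter against the
    root SSE; this routine enforces only ``min_gain`` and the structural
    admissibility rules (min_leaf children, strictly positive gain).
    """
    z = np.asarray(z, dtype=float)
    if not np.isfinite(z).all():
        raise DataError("non-finite response values")
    if len(values) != len(z):
        raise DataError("covariate and response lengths differ")
    if len(z) < params.min_split:
        return None

    if kind == "ordinal":
        order = [l for l in (level_order or sorted(values.unique(), key=str))]
        order = [l for l in order if (values == l).any()]
    else:
        grouped = pd.Series(z).groupby(values.to_numpy(), sort=False).mean()
        order = list(grouped.sort_values(kind="stable").index)
    if len(order) < 2:
        return None
    code = {l: i for i, l in enumerate(order)}
    codes = values.map(code).to_numpy(dtype=int)
    counts = np.bincount(codes, minlength=len(order)).astype(float)
    sums = np.bincount(codes, weights=z, minlength=len(order))

    res = _scan(order, counts, sums, params.min_leaf)
    if res is None:
        return None
    gain, k = res
    scale = max(1.0, float(np.abs(z).max()) ** 2 * len(z))
    if gain <= _EPS * scale or gain < params.min_gain:
        return None
    satisfied = order[:k + 1]
    if kind == "ordinal":
        threshold = satisfied[-1]
        if level_order is not None:
            # the condition is "x <= threshold" over the declared order, so
            # declared levels below the threshold satisfy it even if they
            # were unobserved at this node
            full = list(level_order)
            satisfied = full[:full.index(threshold) + 1]
        cond = SplitCondition(values.name, frozenset(satisfied), "ordinal",
                              threshold=threshold)
    else:
        cond = SplitCondition(values.name, frozenset(satisfied), "categorical")
    return cond, gain


# ---------------------------------------------------------------------------
# tree fitting
# ---------------------------------------------------------------------------

def fit_regression_tree(X: pd.DataFrame, z, params: TreeParams = TreeParams(),
                        ordinal: frozenset = frozenset(),
                        level_orders: Optional[dict] = None) -> RegressionTree:
    """Greedy recursive partitioning of the covariates on response ``z``.

    ``X`` must not contain the race/group column — the Step-2 tree is
    defined on all covariates *except* race, and that contract is enforced
    structurally here.
    """
    if GROUP in X.columns:
        raise ContractViolation(
            f"column {GROUP!r} must not be offered to the subgroup tree")
    z = np.asarray(z, dtype=float)
    if len(X) != len(z):
        raise DataError("X and z lengths differ")
    if not np.isfinite(z).all():
        raise DataError("non-finite response values")
    p = params.resolve(len(z))
    level_orders = level_orders or {}
    n_root = len(z)
    sse_root = float(((z - z.mean()) ** 2).sum())
    gain_floor = max(p.min_gain, p.complexity * sse_root)

    def build(rows: np.ndarray, depth: int) -> Node:
        zr = z[rows]
        node = Node(n=len(rows), mean=float(zr.mean()),
                    coverage=len(rows) / n_root)
        if depth >= p.max_depth or len(rows) < p.min_split:
            return node
        best = None   # (gain, col_index, condition, sat_mask)
        sub = X.iloc[rows]
        for j, col in enumerate(X.columns):
            kind = "ordinal" if col in ordinal else "categorical"
            res = best_split(sub[col], zr, p, kind=kind,
                             level_order=level_orders.get(col))
            if res is None:
                continue
            cond, gain = res
            if gain < gain_floor:
                continue
            # strict improvement required: on an exact tie the earlier
            # variable wins (within a variable, the scan already prefers
            # the smaller satisfying subset)
            if best is None or gain > best[0] + _EPS * max(1.0, abs(best[0])):
                best = (gain, j, cond)
        if best is None:
            return node
        _, _, cond = best
        sat = cond.evaluate(sub)
        node.condition = cond
        node.left = build(rows[sat], depth + 1)
        node.right = build(rows[~sat], depth + 1)
        return node

    root = build(np.arange(n_root), 0)
    return RegressionTree(root=root, n=n_root, params=p,
                          variables=list(X.columns))


# ---------------------------------------------------------------------------
# rules
# ---------------------------------------------------------------------------

def extract_subgroup_rules(tree: RegressionTree) -> list:
    """One rule per leaf, in left-to-right leaf order.

    Rules are mutually exclusive and exhaustive: every covariate vector
    satisfies exactly one of them.
    """
    rules = []

    def walk(node: Node, path: tuple) -> None:
        if node.is_leaf:
            rules.append(SubgroupRule(conditions=path, mean_z=node.mean,
                                      n=node.n, coverage=node.coverage,
                                      leaf_index=len(rules)))
            return
        walk(node.left, path + ((node.condition, False),))
        walk(node.right, path + ((node.condition, True),))

    walk(tree.root, ())
    return rules


class SelectionError(ValueError):
    pass


def select_most_vulnerable(rules: Sequence, min_coverage: float = 0.0) -> SubgroupRule:
    """The rule with maximal leaf mean among those with adequate coverage.

    Ties go to the larger coverage, then to the earlier leaf in path order.
    """
    if not rules:
        raise SelectionError("empty rule list")
    admissible = [r for r in rules if r.coverage >= min_coverage]
    if not admissible:
        raise SelectionError(
            f"no rule reaches min_coverage={min_coverage}")
    return max(admissible, key=lambda r: (r.mean_z, r.coverage, -r.leaf_index))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_tree(tree: RegressionTree, fmt: str = "text") -> str:
    """Figure-style rendering: left branch = condition satisfied; each node
    shows its mean response (4 decimals) and coverage percent."""
    if fmt == "text":
        lines = []

        def walk(node: Node, indent: str, tag: str) -> None:
            label = f"mean Z = {node.mean:.4f}, {round(100 * node.coverage)}%"
            if node.is_leaf:
                lines.append(f"{indent}{tag}leaf: {label}")
            else:
                lines.append(f"{indent}{tag}[{node.condition.describe()}] {label}")
                walk(node.left, indent + "  ", "yes: ")
                walk(node.right, indent + "  ", "no:  ")

        walk(tree.root, "", "")
        return "\n".join(lines) + "\n"
    if fmt == "dot":
        lines = ["digraph subgroup_tree {", "  node [shape=box];"]
        counter = [0]

        def walk(node: Node) -> int:
            nid = counter[0]
            counter[0] += 1
            label = f"{node.mean:.4f}\\n{round(100 * node.coverage)}%"
            if node.is_leaf:
                lines.append(f'  n{nid} [label="{label}", style=filled, '
                             'fillcolor=lightgray];')
            else:
                cond = node.condition.describe().replace('"', "'")
                lines.append(f'  n{nid} [label="{cond}\\n{label}"];')
                lid = walk(node.left)
                rid = walk(node.right)
                lines.append(f'  n{nid} -> n{lid} [label="yes"];')
                lines.append(f'  n{nid} -> n{rid} [label="no"];')
            return nid

        walk(tree.root)
        lines.append("}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown rendering format {fmt!r}")
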