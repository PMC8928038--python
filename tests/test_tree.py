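"""Regression tree: split search optimality, fitting, rules, rendering."""

import numpy as np
import pandas as pd
import pytest

from oracles import (exhaustive_best_bipartition, exhaustive_best_split_all,
                     sse)
from vtwins.tree import (ContractViolation, DataError, SelectionError,
                         SplitCondition, SubgroupRule, TreeParams, best_split,
                         extract_subgroup_rules, fit_regression_tree,
                         render_tree, select_most_vulnerable)

FREE = TreeParams(max_depth=4, min_split=2, min_leaf=1, complexity=0.0)


def _random_X(rng, n, spec):
    return pd.DataFrame({name: rng.choice(levels, size=n)
                         for name, levels in spec.items()})


class TestBestSplit:
    def test_constant_response_gives_none(self):
        v = pd.Series(["A"] * 10 + ["B"] * 10, name="v")
        assert best_split(v, np.zeros(20), FREE) is None

    def test_hand_sse_arithmetic(self):
        # z = 0.2 on level A (10 rows), 0.0 on level B (10 rows):
        # parent SSE = 20 * Var = 0.2, children are pure, gain = 0.2
        v = pd.Series(["A"] * 10 + ["B"] * 10, name="v")
        z = np.array([0.2] * 10 + [0.0] * 10)
        cond, gain = best_split(v, z, FREE)
        assert gain == pytest.approx(0.2, abs=1e-12)
        assert cond.levels in (frozenset({"A"}), frozenset({"B"}))

    @pytest.mark.parametrize("n_levels", [4, 6, 8])
    def test_mean_ordering_attains_exhaustive_bipartition_optimum(self, n_levels):
        rng = np.random.default_rng(777 + n_levels)
        for _ in range(50):
            n = 200
            v = pd.Series(rng.choice([f"L{i}" for i in range(n_levels)], size=n),
                          name="v")
            z = rng.normal(size=n)
            got = best_split(v, z, FREE)
            want = exhaustive_best_bipartition(v, z, min_leaf=1)
            assert got is not None and want is not None
            assert got[1] == pytest.approx(want[0], abs=1e-9)

    def test_min_leaf_respected(self):
        v = pd.Series(["A"] * 2 + ["B"] * 18, name="v")
        z = np.array([5.0] * 2 + [0.0] * 18)
        res = best_split(v, z, TreeParams(min_split=10, min_leaf=5, complexity=0.0))
        assert res is None   # only admissible cut would strand 2 rows

    def test_non_finite_response_rejected(self):
        v = pd.Series(["A", "B"], name="v")
        with pytest.raises(DataError):
            best_split(v, np.array([np.nan, 1.0]), FREE)


class TestFitRegressionTree:
    def test_depth1_equals_exhaustive_search(self):
        rng = np.random.default_rng(2024)
        spec = {"u": ["u1", "u2", "u3"], "v": ["v1", "v2", "v3", "v4"],
                "w": ["w1", "w2"]}
        for _ in range(50):
            X = _random_X(rng, 120, spec)
            z = rng.normal(size=120)
            t = fit_regression_tree(X, z, TreeParams(max_depth=1, min_split=2,
                                                     min_leaf=1, complexity=0.0))
            want = exhaustive_best_split_all(X, z, min_leaf=1)
            assert not t.root.is_leaf
            got_gain = (sse(z) - sse(z[t.root.condition.evaluate(X)])
                        - sse(z[~t.root.condition.evaluate(X)]))
            assert got_gain == pytest.approx(want[0], abs=1e-9)

    def test_single_signal_covariate_found(self):
        rng = np.random.default_rng(5)
        X = _random_X(rng, 400, {"sig": ["s1", "s2"], "noise": ["n1", "n2"]})
        z = np.where(X["sig"] == "s1", 0.3, 0.0) + rng.normal(0, 0.01, 400)
        t = fit_regression_tree(X, z, TreeParams(max_depth=1, complexity=0.0,
                                                 min_split=2, min_leaf=1))
        assert t.root.condition.variable == "sig"

    def test_constant_response_single_leaf(self):
        X = pd.DataFrame({"v": ["A", "B"] * 10})
        t = fit_regression_tree(X, np.full(20, 0.7), FREE)
        assert t.root.is_leaf
        assert t.root.mean == pytest.approx(0.7)

    def test_max_depth_zero_disallowed(self):
        with pytest.raises(ValueError):
            TreeParams(max_depth=0)

    def test_weighted_leaf_mean_conservation(self):
        rng = np.random.default_rng(8)
        X = _random_X(rng, 500, {"u": list("abcd"), "v": list("xy"),
                                 "w": list("pqr")})
        z = rng.normal(size=500)
        t = fit_regression_tree(X, z, FREE)
        leaves = t.leaves()
        total = sum(l.mean * l.n for l in leaves) / t.n
        assert total == pytest.approx(float(z.mean()), abs=1e-12)
        assert sum(l.coverage for l in leaves) == pytest.approx(1.0, abs=1e-12)

    def test_sse_monotone_in_depth(self):
        rng = np.random.default_rng(9)
        X = _random_X(rng, 400, {"u": list("abcd"), "v": list("xy")})
        z = rng.normal(size=400)
        prev = np.inf
        for depth in (1, 2, 3, 4):
            t = fit_regression_tree(X, z, TreeParams(max_depth=depth,
                                                     min_split=2, min_leaf=1,
                                                     complexity=0.0))
            pred = t.predict(X)
            total = float(((z - pred) ** 2).sum())
            assert total <= prev + 1e-9
            prev = total

    def test_race_column_rejected(self):
        X = pd.DataFrame({"race": [0, 1] * 5, "v": ["A", "B"] * 5})
        with pytest.raises(ContractViolation):
            fit_regression_tree(X, np.zeros(10), FREE)

    def test_ordinal_threshold_in_declared_order(self):
        order = ["low", "mid", "high"]
        X = pd.DataFrame({"o": ["low"] * 10 + ["mid"] * 10 + ["high"] * 10})
        z = np.array([0.0] * 20 + [1.0] * 10)
        t = fit_regression_tree(X, z, FREE, ordinal=frozenset({"o"}),
                                level_orders={"o": order})
        cond = t.root.condition
        assert cond.kind == "ordinal"
        assert cond.threshold == "mid"
        assert cond.levels == frozenset({"low", "mid"})


class TestRules:
    def test_single_leaf_vacuous_rule(self):
        X = pd.DataFrame({"v": ["A", "B"] * 5})
        t = fit_regression_tree(X, np.zeros(10), FREE)
        rules = extract_subgroup_rules(t)
        assert len(rules) == 1
        assert rules[0].conditions == ()
        assert rules[0].coverage == pytest.approx(1.0)

    def test_rules_partition_rows(self):
        rng = np.random.default_rng(12)
        X = _random_X(rng, 300, {"u": list("abcd"), "v": list("xy"),
                                 "w": list("pq")})
        z = rng.normal(size=300)
        t = fit_regression_tree(X, z, TreeParams(max_depth=2, min_split=2,
                                                 min_leaf=1, complexity=0.0))
        rules = extract_subgroup_rules(t)
        hits = np.zeros(len(X), dtype=int)
        for r in rules:
            m = r.mask(X)
            hits += m
            assert int(m.sum()) == r.n   # rule reproduces its leaf exactly
        assert (hits == 1).all()

    def test_select_most_vulnerable(self):
        def rule(mean, cov, idx):
            return SubgroupRule(conditions=(), mean_z=mean, n=10,
                                coverage=cov, leaf_index=idx)
        rules = [rule(0.01, 0.3, 0), rule(0.059, 0.2, 1), rule(-0.067, 0.5, 2)]
        assert select_most_vulnerable(rules).mean_z == pytest.approx(0.059)
        tie = [rule(0.05, 0.03, 0), rule(0.05, 0.12, 1)]
        assert select_most_vulnerable(tie).coverage == pytest.approx(0.12)
        assert select_most_vulnerable([rules[0]]) is rules[0]
        with pytest.raises(SelectionError):
            select_most_vulnerable(rules, min_coverage=0.9)


class TestRenderTree:
    def test_single_leaf_text(self):
        X = pd.DataFrame({"v": ["A", "B"] * 5})
        t = fit_regression_tree(X, np.full(10, 0.25), FREE)
        out = render_tree(t, "text")
        assert "0.2500" in out and "100%" in out

    def test_coverage_labels_sum_to_100(self):
        rng = np.random.default_rng(3)
        X = _random_X(rng, 300, {"u": list("abcd"), "v": list("xy")})
        z = rng.normal(size=300)
        t = fit_regression_tree(X, z, TreeParams(max_depth=3, min_split=2,
                                                 min_leaf=1, complexity=0.0))
        import re
        out = render_tree(t, "text")
        leaf_pcts = [int(m) for m in re.findall(r"leaf: .*?, (\d+)%", out)]
        assert abs(sum(leaf_pcts) - 100) <= len(leaf_pcts)  # rounding slack

    def test_dot_output_well_formed(self):
        rng = np.random.default_rng(4)
        X = _random_X(rng, 200, {"u": list("ab"), "v": list("xy")})
        z = np.where(X["u"] == "a", 1.0, 0.0) + np.where(X["v"] == "x", 0.5, 0.0)
        t = fit_regression_tree(X, z, TreeParams(max_depth=2, min_split=2,
                                                 min_leaf=1, complexity=0.0))
        dot = render_tree(t, "dot")
        assert dot.startswith("digraph")
        assert dot.rstrip().endswith("}")
        assert dot.count("{") == dot.count("}")
        import re
        n_leaves = t.n_leaves
        n_nodes = 2 * n_leaves - 1
        node_defs = re.findall(r"^\s*n\d+ \[label=", dot, flags=re.M)
        assert len(node_defs) == n_nodes
        assert dot.count("->") == n_nodes - 1

    def test_unknown_format_rejected(self):
        X = pd.DataFrame({"v": ["A", "B"]})
        t = fit_regression_tree(X, np.zeros(2), FREE)
        with pytest.raises(ValueError):
            render_tree(t, "svg")
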