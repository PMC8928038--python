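"""Step-1 classifiers: contracts, metrics, harness, importance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import StubModel
from oracles import pair_count_auc
from vtwins import synth
from vtwins.models import (CapabilityError, ClassifierSpec, FitError,
                           auc_score, compare_classifiers, fit_wait_model,
                           misclassification_pct, predict_wait_probability,
                           variable_importance)
from vtwins.table import EpisodeTable, SchemaError

ALL_METHODS = ["random_forest", "elastic_net", "boosting_tree"]
FAST = {"random_forest": {"n_estimators": 50},
        "elastic_net": {},
        "boosting_tree": {"n_estimators": 30}}


def _separable_table(n=300, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.choice(["hi", "lo"], size=n)
    df = pd.DataFrame({"wait_binary": (x == "hi").astype(int),
                       "race": rng.integers(0, 2, n), "x": x,
                       "noise": rng.choice(["a", "b"], size=n)})
    return EpisodeTable.from_dataframe(df)


class TestMetrics:
    def test_constant_half_scorer(self):
        y = np.array([0, 1] * 50)
        scores = np.full(100, 0.5)
        # ties at the threshold go to class 0
        assert misclassification_pct(y, scores) == pytest.approx(50.0)
        assert auc_score(y, scores) == pytest.approx(0.5)

    def test_auc_equals_pair_count(self):
        y = np.array([1, 1, 0, 1, 0, 0])
        s = np.array([0.9, 0.8, 0.4, 0.2, 0.4, 0.1])
        assert auc_score(y, s) == pytest.approx(pair_count_auc(y, s), abs=1e-12)

    def test_misclassification_equals_confusion_recount(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 500)
        s = rng.random(500)
        pred = (s > 0.5).astype(int)
        fp = int(((pred == 1) & (y == 0)).sum())
        fn = int(((pred == 0) & (y == 1)).sum())
        assert misclassification_pct(y, s) == pytest.approx(100 * (fp + fn) / 500)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_auc_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, 60)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        s = rng.random(60)
        base = auc_score(y, s)
        for f in (lambda v: 2 * v + 1, np.exp, lambda v: v ** 3):
            assert auc_score(y, f(s)) == pytest.approx(base, abs=1e-12)


class TestFitAndPredict:
    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_separable_data_learned_perfectly(self, method):
        t = _separable_table()
        model = fit_wait_model(t, ClassifierSpec(method, FAST[method], seed=1))
        s = model.predict_proba_df(t.X, t.d)
        assert misclassification_pct(t.y, s) == pytest.approx(0.0)
        assert auc_score(t.y, s) == pytest.approx(1.0)

    def test_refit_determinism(self, small_table):
        probes = small_table.X.head(50)
        preds = []
        for _ in range(2):
            m = fit_wait_model(small_table,
                               ClassifierSpec("random_forest",
                                              {"n_estimators": 50}, seed=9))
            preds.append(m.predict_proba_df(probes, 1))
        np.testing.assert_array_equal(preds[0], preds[1])

    def test_single_class_training_rejected(self):
        df = pd.DataFrame({"wait_binary": [0] * 10, "race": [0, 1] * 5,
                           "x": ["a", "b"] * 5})
        with pytest.raises(FitError):
            fit_wait_model(EpisodeTable.from_dataframe(df))

    def test_probabilities_bounded(self, small_table):
        m = fit_wait_model(small_table, ClassifierSpec("random_forest",
                                                       {"n_estimators": 50}))
        for d in (0, 1):
            p = predict_wait_probability(m, d, small_table.X)
            assert np.all((p >= 0) & (p <= 1))

    def test_counterfactual_scoring_both_groups(self, small_table):
        m = fit_wait_model(small_table, ClassifierSpec("random_forest",
                                                       {"n_estimators": 50}))
        p1 = predict_wait_probability(m, 1, small_table.X)
        p0 = predict_wait_probability(m, 0, small_table.X)
        assert p1.shape == p0.shape == (small_table.n,)

    def test_race_excluded_model_is_counterfactually_flat(self, small_table):
        m = fit_wait_model(small_table,
                           ClassifierSpec("random_forest", {"n_estimators": 50}),
                           use_race=False)
        p1 = m.predict_proba_df(small_table.X, 1)
        p0 = m.predict_proba_df(small_table.X, 0)
        np.testing.assert_array_equal(p1, p0)

    def test_unseen_level_rejected_with_names(self, small_table):
        m = fit_wait_model(small_table, ClassifierSpec("random_forest",
                                                       {"n_estimators": 10}))
        probe = small_table.X.head(3).copy()
        probe.loc[probe.index[0], "state"] = "XX"
        with pytest.raises(SchemaError, match="state"):
            m.predict_proba_df(probe, 1)

    def test_null_data_auc_near_half(self):
        rng = np.random.default_rng(44)
        n = 5000
        df = pd.DataFrame({
            "wait_binary": rng.integers(0, 2, n),
            "race": rng.integers(0, 2, n),
            "x1": rng.choice(list("abcd"), n),
            "x2": rng.choice(list("pq"), n),
        })
        t = EpisodeTable.from_dataframe(df)
        tr = t.subset(t.data.index[:2500])
        te = t.subset(t.data.index[2500:])
        m = fit_wait_model(tr, ClassifierSpec("random_forest",
                                              {"n_estimators": 100}, seed=5))
        a = auc_score(te.y, m.predict_proba_df(te.X, te.d))
        assert 0.45 <= a <= 0.55

    def test_model_auc_close_to_bayes_scorer(self):
        # the generating model is logistic in main effects plus one planted
        # interaction, so a well-fit elastic net approaches the Bayes scorer
        cfg = synth.default_config(n_episodes=20_000, seed=21)
        t = synth.generate_episodes(cfg)
        tr = t.subset(t.data.index[:10_000])
        te = t.subset(t.data.index[10_000:])
        m = fit_wait_model(tr, ClassifierSpec("elastic_net", seed=3))
        model_auc = auc_score(te.y, m.predict_proba_df(te.X, te.d))
        # the generating model's own probabilities are the Bayes scorer
        from scipy.special import expit
        from vtwins.synth import _eta, in_planted_subgroup
        eta = _eta(cfg, te.X)
        s = in_planted_subgroup(cfg.planted, te.X)
        p = expit(eta + (cfg.planted.delta0 + cfg.planted.deltaS * s) * te.d)
        bayes_auc = auc_score(te.y, p)
        assert abs(model_auc - bayes_auc) <= 0.03


class TestVariableImportance:
    def test_planted_signal_ranked_first(self):
        hits = 0
        trials = 10
        for seed in range(trials):
            rng = np.random.default_rng(1000 + seed)
            n = 20_000
            x_sig = rng.choice(["s1", "s2"], n)
            df = pd.DataFrame({
                "race": rng.integers(0, 2, n),
                "signal": x_sig,
                "noise1": rng.choice(list("abcd"), n),
                "noise2": rng.choice(list("pq"), n),
            })
            logits = np.where(x_sig == "s1", 1.0, -1.0)
            df["wait_binary"] = (rng.random(n) <
                                 1 / (1 + np.exp(-logits))).astype(int)
            t = EpisodeTable.from_dataframe(df)
            m = fit_wait_model(t, ClassifierSpec("random_forest",
                                                 {"n_estimators": 100},
                                                 seed=seed))
            ranking = variable_importance(m)
            scores = dict(ranking)
            if ranking[0][0] == "signal":
                hits += 1
            assert scores["noise1"] <= scores["signal"]
        assert hits >= trials - 1

    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_one_score_per_predictor(self, method, small_table):
        m = fit_wait_model(small_table, ClassifierSpec(method, FAST[method]))
        ranking = variable_importance(m)
        assert len(ranking) == len(small_table.covariates) + 1  # + race
        assert all(score >= 0 for _, score in ranking)
        assert [s for _, s in ranking] == sorted((s for _, s in ranking),
                                                 reverse=True)

    def test_stub_without_importance_rejected(self):
        from vtwins.models import FittedWaitModel, _Codec
        codec = _Codec(["x"], {"x": ["a", "b"]})
        m = FittedWaitModel(object(), codec, ClassifierSpec("random_forest"))
        with pytest.raises(CapabilityError):
            variable_importance(m)


class TestCompareClassifiers:
    def test_report_structure_and_determinism(self, small_table):
        specs = [ClassifierSpec(m, FAST[m]) for m in ALL_METHODS]
        reps = []
        for _ in range(2):
            r = compare_classifiers(small_table, specs, n_reps=3,
                                    train_frac=0.2, seed=11)
            reps.append(r)
        pd.testing.assert_frame_equal(reps[0].table, reps[1].table)
        assert set(reps[0].table["method"]) == set(ALL_METHODS)
        assert len(reps[0].replicates) == 3 * len(ALL_METHODS)
        assert reps[0].replicates.misclass_overall.between(0, 100).all()
        assert reps[0].replicates.auc.between(0, 1).all()

    def test_groupwise_misclassification_averages_to_overall(self):
        rng = np.random.default_rng(17)
        y = rng.integers(0, 2, 400)
        s = rng.random(400)
        d = rng.integers(0, 2, 400)
        overall = misclassification_pct(y, s)
        m1 = misclassification_pct(y[d == 1], s[d == 1])
        m0 = misclassification_pct(y[d == 0], s[d == 0])
        n1, n0 = int((d == 1).sum()), int((d == 0).sum())
        assert overall == pytest.approx((n1 * m1 + n0 * m0) / 400, abs=1e-9)

    def test_perfectly_separable_all_methods(self):
        t = _separable_table(n=400, seed=2)
        specs = [ClassifierSpec(m, FAST[m]) for m in ALL_METHODS]
        r = compare_classifiers(t, specs, n_reps=2, train_frac=0.5, seed=7)
        assert (r.replicates.misclass_overall == 0).all()
        assert (r.replicates.auc == 1.0).all()

    def test_invalid_args(self, small_table):
        with pytest.raises(ValueError):
            compare_classifiers(small_table, [], n_reps=0)
        with pytest.raises(ValueError):
            compare_classifiers(small_table, [], n_reps=1, train_frac=1.5)
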