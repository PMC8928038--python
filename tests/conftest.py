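import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from vtwins import synth
from vtwins.table import EpisodeTable


@pytest.fixture
def two_binary_config():
    """Small generating model with a planted rule on two binary covariates."""
    schema = synth.CovariateSchema(variables=(
        synth.Variable("a", "categorical", ("a1", "a2"), (0.5, 0.5)),
        synth.Variable("b", "categorical", ("b1", "b2"), (0.5, 0.5)),
        synth.Variable("c", "categorical", ("c1", "c2", "c3"), (0.5, 0.3, 0.2)),
    ))
    planted = synth.PlantedSubgroup(
        conditions=(("a", frozenset({"a1"})), ("b", frozenset({"b1"}))),
        delta0=-0.3, deltaS=1.2)
    return synth.GeneratorConfig(schema=schema, n_episodes=50_000,
                                 race_prevalence=0.5, intercept=-2.0,
                                 planted=planted, seed=42)


@pytest.fixture
def small_table():
    """A prepared 400-row analytic table with real outcome signal."""
    cfg = synth.recovery_config(n_episodes=400, seed=7)
    return synth.generate_episodes(cfg)


def make_table(df: pd.DataFrame, **kw) -> EpisodeTable:
    return EpisodeTable.from_dataframe(df, **kw)


class StubModel:
    """Lookup-table wait model: constant probabilities per race value."""

    def __init__(self, p1: float, p0: float):
        self.p1, self.p0 = p1, p0
        self.fingerprint = "stub"

    def predict_proba_df(self, X, d):
        d = np.asarray(d)
        if d.ndim == 0:
            d = np.full(len(X), int(d))
        return np.where(d == 1, self.p1, self.p0).astype(float)
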