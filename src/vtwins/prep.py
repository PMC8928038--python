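"""Raw episode tables -> analytic tables, plus descriptive comparisons.

Preparation mirrors the standard admissions-data cleaning sequence:

1. drop episodes whose wait-time band is unknown (the outcome cannot be
   dichotomized);
2. restrict to exactly two race groups and code them 1/0;
3. drop episodes with any missing covariate cell (complete-case analysis;
   no imputation);
4. dichotomize the wait outcome: band "0" (same-day entry) -> 0, any
   positive band -> 1;
5. optionally collapse over-fine category levels.

Each dropped row is counted in exactly one bucket, in the precedence
unknown-wait, then race, then missing, so the drop counts always sum with
the surviving rows to the input row count.

:func:`descriptive_summary` produces a "client characteristics by wait
time" style report: per-level counts and within-class percentages, with a
chi-square test of independence for categorical covariates and a
two-sample t-test on integer level scores for ordinal ones.  No
multiplicity correction is applied at this descriptive stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .table import GROUP, OUTCOME, EpisodeTable, SchemaError

logger = logging.getLogger(__name__)


class EmptyTableError(ValueError):
    """No rows survived preparation."""


@dataclass(frozen=True)
class PrepConfig:
    """How to turn a raw table into the analytic table.

    ``no_wait_levels`` are the raw wait-band levels mapped to outcome 0;
    ``unknown_wait_levels`` are dropped; every other band maps to 1.
    ``group1_level``/``group0_level`` are the two retained race levels
    (coded 1 and 0); all other race levels are dropped.
    """
    wait_variable: str = OUTCOME
    no_wait_levels: frozenset = frozenset({"0", 0})
    unknown_wait_levels: frozenset = frozenset({"unknown", "Unknown"})
    race_variable: str = GROUP
    group1_level: object = 1
    group0_level: object = 0
    collapse: Mapping = field(default_factory=dict)   # var -> {old: new}
    drop_missing: bool = True


@dataclass(frozen=True)
class PrepResult:
    table: EpisodeTable
    rows_in: int
    dropped_unknown_wait: int
    dropped_race: int
    dropped_missing: int

    @property
    def rows_out(self) -> int:
        return self.table.n


def prepare_analytic_table(raw, prep: PrepConfig = PrepConfig()) -> PrepResult:
    """Apply the cleaning sequence; idempotent on already-prepared tables."""
    df = raw.data.copy() if isinstance(raw, EpisodeTable) else pd.DataFrame(raw).copy()
    levels = dict(raw.levels) if isinstance(raw, EpisodeTable) else {}
    ordinal = raw.ordinal if isinstance(raw, EpisodeTable) else frozenset()

    for col in (prep.wait_variable, prep.race_variable):
        if col not in df.columns:
            raise SchemaError(f"configured variable {col!r} absent from table")
    rows_in = len(df)

    wait = df[prep.wait_variable]
    unknown_mask = wait.isin(list(prep.unknown_wait_levels)) | wait.isna()
    df = df[~unknown_mask]

    race = df[prep.race_variable]
    race_mask = ~race.isin([prep.group1_level, prep.group0_level])
    n_race = int(race_mask.sum())
    df = df[~race_mask]

    covars = [c for c in df.columns if c not in (prep.wait_variable, prep.race_variable)]
    if prep.drop_missing and covars:
        miss_mask = df[covars].isna().any(axis=1)
        n_missing = int(miss_mask.sum())
        df = df[~miss_mask]
    else:
        n_missing = 0

    if len(df) == 0:
        raise EmptyTableError("no rows survived preparation")

    y = (~df[prep.wait_variable].isin(list(prep.no_wait_levels))).astype(int)
    d = (df[prep.race_variable] == prep.group1_level).astype(int)
    out = df[covars].copy()
    for var, mapping in prep.collapse.items():
        if var not in out.columns:
            raise SchemaError(f"collapse map names unknown variable {var!r}")
        out[var] = out[var].replace(dict(mapping))
        if var in levels:
            new = [mapping.get(l, l) for l in levels[var]]
            levels[var] = list(dict.fromkeys(new))
    out.insert(0, GROUP, d.to_numpy())
    out.insert(0, OUTCOME, y.to_numpy())

    n_unknown = int(unknown_mask.sum())
    logger.info("prep: %d rows in, %d unknown-wait, %d race, %d missing, %d out",
                rows_in, n_unknown, n_race, n_missing, len(out))
    table = EpisodeTable.from_dataframe(
        out, levels={k: v for k, v in levels.items() if k in covars},
        ordinal=frozenset(o for o in ordinal if o in covars))
    table.validate_binary()
    return PrepResult(table, rows_in, n_unknown, n_race, n_missing)


# ---------------------------------------------------------------------------
# descriptive report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DescriptiveReport:
    """Per-variable counts/percentages by outcome class plus a test."""
    counts: pd.DataFrame    # variable, level, n_no_wait, pct_no_wait, n_wait, pct_wait
    tests: pd.DataFrame     # variable, test, statistic, p_value

    def to_csv(self, counts_path, tests_path) -> None:
        self.counts.to_csv(counts_path, index=False)
        self.tests.to_csv(tests_path, index=False)


def _chi_square(table2xk: np.ndarray):
    """Pearson chi-square of independence, uncorrected (descriptive use)."""
    obs = np.asarray(table2xk, dtype=float)
    obs = obs[:, obs.sum(axis=0) > 0]
    if obs.shape[1] < 2:
        return None
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row @ col / obs.sum()
    stat = float(((obs - exp) ** 2 / exp).sum())
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return stat, float(stats.chi2.sf(stat, dof))


def descriptive_summary(table: EpisodeTable) -> DescriptiveReport:
    table.validate_binary()
    y = table.y
    rows, tests = [], []
    class_n = {0: int((y == 0).sum()), 1: int((y == 1).sum())}
    for var in table.covariates:
        col = table.data[var]
        lvls = [l for l in table.levels.get(var, []) if (col == l).any()]
        counts = {}
        for cls in (0, 1):
            vc = col[y == cls].value_counts()
            counts[cls] = [int(vc.get(l, 0)) for l in lvls]
        for i, l in enumerate(lvls):
            rows.append({
                "variable": var, "level": l,
                "n_no_wait": counts[0][i],
                "pct_no_wait": 100.0 * counts[0][i] / max(class_n[0], 1),
                "n_wait": counts[1][i],
                "pct_wait": 100.0 * counts[1][i] / max(class_n[1], 1),
            })
        if len(lvls) < 2:
            logger.warning("descriptive: %r has a single observed level; "
                           "test skipped", var)
            continue
        if var in table.ordinal:
            order = {l: i for i, l in enumerate(table.levels[var])}
            scores = col.map(order).to_numpy(dtype=float)
            t, p = stats.ttest_ind(scores[y == 1], scores[y == 0], equal_var=False)
            tests.append({"variable": var, "test": "t",
                          "statistic": float(t), "p_value": float(p)})
        else:
            res = _chi_square(np.array([counts[0], counts[1]]))
            if res is not None:
                tests.append({"variable": var, "test": "chi2",
                              "statistic": res[0], "p_value": res[1]})
    return DescriptiveReport(pd.DataFrame(rows), pd.DataFrame(tests))
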