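"""Subgroup validation: contingency counts, corrected proportion tests,
Bonferroni control, and the marginal-reversal check.

Tree-derived subgroups are hypotheses, not findings; this module re-tests
them on a full episode table.  For each subgroup rule it forms the
race-by-wait 2x2 table and runs a two-sample proportion test with the
Yates continuity correction,

    z = max(0, |p1 - p2| - c) / sqrt(phat (1 - phat) (1/n1 + 1/n2)),
    c = 1/(2 n1) + 1/(2 n2),    phat = (k1 + k2) / (n1 + n2),

whose square is exactly the continuity-corrected 2x2 chi-square.  The
two-sided p-value is compared against a Bonferroni threshold alpha / L
with L the number of tree leaves.  The unconditional (whole-table)
comparison is reported alongside, and a reversal flag is raised when the
selected subgroup's race gap and the marginal race gap have opposite
signs — the Simpson-style pattern in which one group waits less overall
yet waits substantially more inside the identified subgroup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._util import format_p
from .table import EpisodeTable
from .tree import SubgroupRule

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyCounts:
    k1: int   # waited, group D=1
    n1: int
    k2: int   # waited, group D=0
    n2: int

    def __post_init__(self):
        if not (0 <= self.k1 <= self.n1 and 0 <= self.k2 <= self.n2):
            raise ValueError("counts must satisfy 0 <= k <= n")


@dataclass(frozen=True)
class ProportionTestResult:
    counts: ContingencyCounts
    p1: float
    p2: float
    z: float
    chi2: float
    p_value: float
    continuity_correction: bool
    degenerate: bool = False

    @property
    def p_display(self) -> str:
        return format_p(self.p_value)


@dataclass(frozen=True)
class DisparityTestResult:
    rule: Optional[SubgroupRule]
    test: Optional[ProportionTestResult]
    threshold: float
    evaluable: bool = True
    label: str = ""

    @property
    def significant(self) -> bool:
        return self.evaluable and self.test.p_value < self.threshold


def two_proportion_test(counts: ContingencyCounts,
                        continuity_correction: bool = True) -> ProportionTestResult:
    """Two-sided pooled two-sample proportion test (optionally corrected)."""
    k1, n1, k2, n2 = counts.k1, counts.n1, counts.k2, counts.n2
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups need at least one observation")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        logger.warning("degenerate contingency table (pooled proportion %g); "
                       "p set to 1", pooled)
        return ProportionTestResult(counts, p1, p2, 0.0, 0.0, 1.0,
                                    continuity_correction, degenerate=True)
    c = (1.0 / (2 * n1) + 1.0 / (2 * n2)) if continuity_correction else 0.0
    se = np.sqrt(pooled * (1 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = max(0.0, abs(p1 - p2) - c) / se
    p = 2.0 * float(norm.sf(z))
    return ProportionTestResult(counts, p1, p2, float(z), float(z * z),
                                min(p, 1.0), continuity_correction)


def bonferroni_threshold(alpha: float, n_leaves: int) -> float:
    """alpha / L, with L the number of leaves in the fitted tree."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_leaves < 1:
        raise ValueError("n_leaves must be >= 1")
    return alpha / n_leaves


def apply_rule(rule: SubgroupRule, table: EpisodeTable) -> EpisodeTable:
    """Rows satisfying every condition of the rule (empty rule = all)."""
    for cond, _ in rule.conditions:
        from .table import check_levels
        check_levels(table, cond.variable, cond.levels)
    mask = rule.mask(table.data)
    sub = table.subset(mask)
    logger.info("rule [%s]: %d of %d episodes", rule.describe(), sub.n, table.n)
    return sub


def contingency_from_table(table: EpisodeTable) -> ContingencyCounts:
    y, d = table.y, table.d
    return ContingencyCounts(
        k1=int(y[d == 1].sum()), n1=int((d == 1).sum()),
        k2=int(y[d == 0].sum()), n2=int((d == 0).sum()))


@dataclass(frozen=True)
class ValidationReport:
    results: tuple               # one DisparityTestResult per evaluable rule
    marginal: DisparityTestResult
    selected: Optional[DisparityTestResult]
    reversal: bool
    alpha: float
    n_rules: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in list(self.results) + [self.marginal]:
            t = r.test
            rows.append({
                "rule": r.label,
                "conditions": r.rule.describe() if r.rule is not None else "(marginal)",
                "mean_z": r.rule.mean_z if r.rule is not None else float("nan"),
                "k1": t.counts.k1 if t else 0, "n1": t.counts.n1 if t else 0,
                "p1": t.p1 if t else float("nan"),
                "k2": t.counts.k2 if t else 0, "n2": t.counts.n2 if t else 0,
                "p2": t.p2 if t else float("nan"),
                "chi2": t.chi2 if t else float("nan"),
                "p_value": t.p_value if t else float("nan"),
                "p_display": t.p_display if t else "",
                "threshold": r.threshold,
                "significant": r.significant,
                "evaluable": r.evaluable,
            })
        df = pd.DataFrame(rows)
        df.attrs["reversal"] = self.reversal
        return df


def validate_subgroups(rules: Sequence, full_table: EpisodeTable,
                       alpha: float = 0.05,
                       continuity_correction: bool = True,
                       selected: Optional[SubgroupRule] = None) -> ValidationReport:
    """Test every subgroup rule on the full table, Bonferroni-controlled.

    ``selected`` names the most-vulnerable rule for the reversal check; by
    default it is the evaluable rule with maximal leaf mean Z.  Rules whose
    subgroup lacks one of the race groups are reported as non-evaluable and
    excluded from the Bonferroni denominator.
    """
    if not rules:
        raise ValueError("need at least one rule")
    full_table.validate_binary()
    prelim = []
    for i, rule in enumerate(rules):
        sub = apply_rule(rule, full_table)
        y, d = sub.y, sub.d
        n1, n2 = int((d == 1).sum()), int((d == 0).sum())
        if n1 == 0 or n2 == 0:
            logger.warning("rule %d [%s]: one race group empty; excluded "
                           "from Bonferroni count", i, rule.describe())
            prelim.append((rule, None))
        else:
            prelim.append((rule, contingency_from_table(sub)))
    n_eval = sum(1 for _, c in prelim if c is not None)
    threshold = bonferroni_threshold(alpha, max(n_eval, 1))
    results = []
    for i, (rule, counts) in enumerate(prelim):
        if counts is None:
            results.append(DisparityTestResult(rule, None, threshold,
                                               evaluable=False, label=f"leaf_{i}"))
        else:
            t = two_proportion_test(counts, continuity_correction)
            results.append(DisparityTestResult(rule, t, threshold,
                                               label=f"leaf_{i}"))

    marg_t = two_proportion_test(contingency_from_table(full_table),
                                 continuity_correction)
    marginal = DisparityTestResult(None, marg_t, alpha, label="marginal")

    sel_res = None
    if selected is not None:
        for r in results:
            if r.rule is selected or r.rule == selected:
                sel_res = r
                break
        if sel_res is None:
            sub = apply_rule(selected, full_table)
            d = sub.d
            if (d == 1).any() and (d == 0).any():
                t = two_proportion_test(contingency_from_table(sub),
                                        continuity_correction)
                sel_res = DisparityTestResult(selected, t, threshold,
                                              label="selected")
    else:
        evaluable = [r for r in results if r.evaluable]
        if evaluable:
            sel_res = max(evaluable, key=lambda r: r.rule.mean_z)

    reversal = False
    if sel_res is not None and sel_res.evaluable:
        gap_sub = sel_res.test.p1 - sel_res.test.p2
        gap_marg = marg_t.p1 - marg_t.p2
        reversal = bool(gap_sub * gap_marg < 0)
    return ValidationReport(tuple(results), marginal, sel_res, reversal,
                            alpha, len(rules))
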