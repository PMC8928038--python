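"""End-to-end run orchestration producing a reproducible run directory.

A run executes (optionally) simulate -> prep -> compare-models -> virtual
twins -> validate, writing every artifact needed to audit or re-execute
it: the episode snapshot, the prep drop counts, the model-comparison
table, the subgroup tree (text and DOT), the validation table and a YAML
run log capturing every seed and resolved default.  Identical configs
produce byte-identical outputs; every stage's randomness derives from the
master seed via a named per-stage schedule.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from ._util import derive_seed
from . import synth
from .models import ClassifierSpec, compare_classifiers
from .prep import PrepConfig, PrepResult, descriptive_summary, prepare_analytic_table
from .table import read_episodes, write_episodes
from .tree import TreeParams, render_tree
from .validate import ValidationReport, validate_subgroups
from .vt import VTResult, run_virtual_twins

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of ``input_path`` (a delimited-text episode table) or
    ``generator`` (synthetic study conditions) must be set.
    """
    outdir: str
    input_path: Optional[str] = None
    generator: Optional[synth.GeneratorConfig] = None
    prep: PrepConfig = PrepConfig()
    classifier: Optional[ClassifierSpec] = None   # None -> VT step-1 default
    compare_specs: Optional[tuple] = None     # None -> skip comparison stage
    n_reps: int = 20
    tree_params: TreeParams = TreeParams()
    train_frac: float = 0.2
    alpha: float = 0.05
    continuity_correction: bool = True
    min_coverage: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if (self.input_path is None) == (self.generator is None):
            raise ValueError("set exactly one of input_path or generator")


@dataclass
class RunResult:
    outdir: Path
    prep: PrepResult
    vt: VTResult
    validation: ValidationReport
    comparison: Optional[object] = None


def run_pipeline(config: RunConfig) -> RunResult:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "stages": {}}
    try:
        # -- simulate / load ------------------------------------------
        if config.generator is not None:
            gen = dataclasses.replace(
                config.generator, seed=derive_seed(config.seed, "simulate"))
            raw = synth.generate_episodes(gen)
            if gen.missing_rate or gen.unknown_rate:
                raw = synth.inject_missing_and_unknowns(
                    raw, gen.missing_rate, gen.unknown_rate,
                    seed=derive_seed(config.seed, "inject"))
            log["stages"]["simulate"] = {"n": raw.n, "seed": gen.seed,
                                         "generator": synth.config_to_dict(gen)}
        else:
            raw = read_episodes(config.input_path)
            log["stages"]["load"] = {"path": str(config.input_path), "n": raw.n}
        write_episodes(raw, out / "episodes_raw.csv")

        # -- prep ------------------------------------------------------
        prep_res = prepare_analytic_table(raw, config.prep)
        table = prep_res.table
        write_episodes(table, out / "episodes_analytic.csv")
        log["stages"]["prep"] = {
            "rows_in": prep_res.rows_in, "rows_out": prep_res.rows_out,
            "dropped_unknown_wait": prep_res.dropped_unknown_wait,
            "dropped_race": prep_res.dropped_race,
            "dropped_missing": prep_res.dropped_missing,
        }
        desc = descriptive_summary(table)
        desc.to_csv(out / "descriptive_counts.csv", out / "descriptive_tests.csv")

        # -- optional model comparison --------------------------------
        comparison = None
        if config.compare_specs:
            comparison = compare_classifiers(
                table, list(config.compare_specs), n_reps=config.n_reps,
                train_frac=config.train_frac,
                seed=derive_seed(config.seed, "compare"))
            comparison.to_csv(out / "model_comparison.csv")
            log["stages"]["compare"] = {
                "n_reps": config.n_reps, "train_frac": config.train_frac,
                "methods": [s.method for s in config.compare_specs]}

        # -- virtual twins --------------------------------------------
        from .vt import default_step1_spec
        step1 = config.classifier if config.classifier is not None else default_step1_spec()
        vt_res = run_virtual_twins(
            table, spec=step1, tree_params=config.tree_params,
            train_frac=config.train_frac, seed=derive_seed(config.seed, "vt"),
            min_coverage=config.min_coverage)
        (out / "tree.txt").write_text(render_tree(vt_res.tree, "text"))
        (out / "tree.dot").write_text(render_tree(vt_res.tree, "dot"))
        zv = vt_res.z.values
        log["stages"]["virtual_twins"] = {
            "classifier": step1.method,
            "classifier_params": step1.resolved_params(),
            "train_rows": vt_res.train.n, "estimation_rows": vt_res.estimation.n,
            "n_leaves": vt_res.tree.n_leaves,
            "z_mean": float(zv.mean()), "z_min": float(zv.min()),
            "z_max": float(zv.max()),
            "selected_rule": vt_res.selected.describe(),
            "selected_mean_z": float(vt_res.selected.mean_z),
            "tree_params": dataclasses.asdict(vt_res.tree.params),
        }

        # -- validation ------------------------------------------------
        report = validate_subgroups(
            vt_res.rules, table, alpha=config.alpha,
            continuity_correction=config.continuity_correction,
            selected=vt_res.selected)
        frame = report.to_frame()
        frame.to_csv(out / "validation.csv", index=False)
        log["stages"]["validate"] = {
            "alpha": config.alpha, "n_leaves": vt_res.tree.n_leaves,
            "bonferroni_threshold": report.results[0].threshold,
            "reversal": report.reversal,
            "continuity_correction": config.continuity_correction,
        }
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
    return RunResult(out, prep_res, vt_res, report, comparison)
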