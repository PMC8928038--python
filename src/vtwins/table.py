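"""Episode tables: the tabular exchange object used throughout the pipeline.

An :class:`EpisodeTable` is a thin, immutable wrapper around a pandas
``DataFrame`` holding one row per treatment admission episode with

* an outcome column (default ``"wait_binary"``): 1 if the client waited one
  day or more to enter treatment, 0 for same-day entry;
* a group column (default ``"race"``): 1 for African American, 0 for White;
* any number of categorical/ordinal covariate columns.

The wrapper carries the category dictionary (``levels``) and the set of
covariates that carry an ordinal level order (``ordinal``), so that model
encoding and tree splitting share one frozen schema.  Missing covariate
cells are ``NaN``; the on-disk representation is a plain CSV with empty
fields for missing values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

OUTCOME = "wait_binary"
GROUP = "race"


class SchemaError(ValueError):
    """A table, rule or probe does not match the declared schema."""


@dataclass(frozen=True)
class EpisodeTable:
    data: pd.DataFrame
    levels: Mapping[str, list] = field(default_factory=dict)
    ordinal: frozenset = frozenset()
    outcome: str = OUTCOME
    group: str = GROUP

    def __post_init__(self):
        if self.outcome not in self.data.columns:
            raise SchemaError(f"outcome column {self.outcome!r} absent")
        if self.group not in self.data.columns:
            raise SchemaError(f"group column {self.group!r} absent")
        # fill level dictionary from observed data for covariates it omits
        lv = dict(self.levels)
        for c in self.covariates:
            if c not in lv:
                obs = self.data[c].dropna().unique().tolist()
                lv[c] = sorted(obs, key=str)
        object.__setattr__(self, "levels", lv)

    # -- basic views --------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def covariates(self) -> list:
        return [c for c in self.data.columns if c not in (self.outcome, self.group)]

    @property
    def y(self) -> np.ndarray:
        return self.data[self.outcome].to_numpy(dtype=int)

    @property
    def d(self) -> np.ndarray:
        return self.data[self.group].to_numpy(dtype=int)

    @property
    def X(self) -> pd.DataFrame:
        """Covariate block (no outcome, no group)."""
        return self.data[self.covariates]

    def subset(self, mask) -> "EpisodeTable":
        return replace(self, data=self.data.loc[mask])

    def validate_binary(self) -> None:
        """Check the analytic-table invariants (binary Y and D)."""
        for col in (self.outcome, self.group):
            vals = set(self.data[col].dropna().unique().tolist())
            if not vals <= {0, 1}:
                raise SchemaError(f"column {col!r} is not binary: {sorted(vals)!r}")

    # -- I/O -----------------------------------------------------------
    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, na_rep="")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, levels=None, ordinal=(), **kw):
        return cls(df.reset_index(drop=True), levels=levels or {},
                   ordinal=frozenset(ordinal), **kw)


def read_episodes(path, levels=None, ordinal=(), outcome=OUTCOME, group=GROUP) -> EpisodeTable:
    """Read an episode table from a delimited text file."""
    df = pd.read_csv(Path(path), dtype={outcome: "Int64", group: "Int64"},
                     keep_default_na=True, na_values=[""])
    # covariates come back as object/str; normalize whole-number floats
    for c in df.columns:
        if c in (outcome, group):
            df[c] = df[c].astype(int)
    return EpisodeTable.from_dataframe(df, levels=levels, ordinal=ordinal,
                                       outcome=outcome, group=group)


def write_episodes(table: EpisodeTable, path) -> None:
    table.to_csv(path)


def check_levels(table: EpisodeTable, variable: str, wanted: Iterable) -> None:
    """Raise :class:`SchemaError` if any wanted level is undeclared."""
    if variable not in table.covariates:
        raise SchemaError(f"unknown variable {variable!r}")
    declared = set(table.levels.get(variable, []))
    extra = set(wanted) - declared
    if extra:
        raise SchemaError(
            f"variable {variable!r}: unknown level(s) {sorted(extra, key=str)!r}")
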