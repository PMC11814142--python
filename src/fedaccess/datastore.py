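"""Toy encounter-level datastore standing in for a local clinical warehouse.

One table of emergency-department encounter rows with a handful of typed
columns — enough for the mini query language to filter and aggregate.
"""

from __future__ import annotations

from datetime import datetime, timedelta, timezone
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["LocalDatastore", "make_toy_datastore", "ENCOUNTER_COLUMNS"]

ENCOUNTER_COLUMNS = (
    "encounter_id",
    "timestamp",
    "age_group",
    "triage_level",
    "diagnosis_code",
    "disposition",
)

_AGE_GROUPS = ("child", "adult", "elderly")
_DIAGNOSES = ("J06", "I21", "S93", "R10", "J44", "T78")
_DISPOSITIONS = ("discharged", "admitted", "transferred")


class LocalDatastore:
    """Named tables of typed columns; encounter ids unique per table."""

    def __init__(self, tables: Optional[dict[str, pd.DataFrame]] = None):
        self.tables: dict[str, pd.DataFrame] = {}
        for name, df in (tables or {}).items():
            self.add_table(name, df)

    def add_table(self, name: str, df: pd.DataFrame) -> None:
        if "encounter_id" in df.columns and df["encounter_id"].duplicated().any():
            raise ValueError(f"table {name!r}: encounter_id not unique")
        self.tables[name] = df.reset_index(drop=True)

    def get(self, name: str) -> pd.DataFrame:
        return self.tables[name]

    def __contains__(self, name: str) -> bool:
        return name in self.tables


def make_toy_datastore(
    rng: np.random.Generator,
    n_rows: int = 200,
    start: Optional[datetime] = None,
    period_days: int = 365,
    table: str = "encounters",
) -> LocalDatastore:
    """Random but reproducible encounter table for demos and simulation."""
    if start is None:
        start = datetime(2020, 1, 1, tzinfo=timezone.utc)
    offsets = rng.integers(0, period_days * 86400, size=n_rows)
    df = pd.DataFrame(
        {
            "encounter_id": [f"E{i:06d}" for i in range(n_rows)],
            "timestamp": [
                (start + timedelta(seconds=int(s))).strftime("%Y-%m-%dT%H:%M:%SZ")
                for s in sorted(offsets)
            ],
            "age_group": rng.choice(_AGE_GROUPS, size=n_rows, p=[0.2, 0.6, 0.2]),
            "triage_level": rng.integers(1, 6, size=n_rows),
            "diagnosis_code": rng.choice(_DIAGNOSES, size=n_rows),
            "disposition": rng.choice(_DISPOSITIONS, size=n_rows, p=[0.6, 0.3, 0.1]),
        }
    )
    return LocalDatastore({table: df})
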