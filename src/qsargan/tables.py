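"""Descriptor-table conventions.

Every tabular stage of the pipeline exchanges pandas DataFrames with a
``compound_id`` column, continuous descriptor columns, and (for labelled
data) a ``label`` column holding ``"active"`` or ``"inactive"``.  CSV is the
on-disk form: UTF-8, header row, ``compound_id`` first, descriptors next,
``label`` last when present.  Missing descriptor values are empty CSV fields
(NaN in memory).
"""

from __future__ import annotations

import pandas as pd

from .errors import SchemaError

ID_COL = "compound_id"
LABEL_COL = "label"
LABELS = ("active", "inactive")
SYNTHETIC_PREFIX = "SYN-"


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Descriptor column names, i.e. everything except id and label."""
    return [c for c in table.columns if c not in (ID_COL, LABEL_COL)]


def require_columns(table: pd.DataFrame, columns: list[str]) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")


def is_synthetic_id(compound_id: str) -> bool:
    return str(compound_id).startswith(SYNTHETIC_PREFIX)


def write_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    require_columns(table, [ID_COL])
    return table
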