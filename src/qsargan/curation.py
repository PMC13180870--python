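"""Training-set curation: activity labelling and dataset assembly.

Activity records (compound id + IC50 in nM) are reduced to a set of active
compound ids by an inclusive potency threshold; compounds above the
threshold are discarded outright, not treated as inactives — the negative
class comes from a separate decoy table.  Actives and decoys are then
concatenated, deduplicated (first by compound id, then by exact
descriptor-vector equality), stripped of rows with missing descriptors, and
labelled.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd

from .errors import SchemaError, ValidationError
from .tables import ID_COL, LABEL_COL, feature_columns

log = logging.getLogger(__name__)

DEFAULT_IC50_THRESHOLD_NM = 10_000.0


@dataclass(frozen=True)
class ActivityRecord:
    """One potency measurement: IC50 in nM (None when not measured)."""

    compound_id: str
    ic50: float | None
    source: str = ""

    def __post_init__(self) -> None:
        if self.ic50 is not None and not self.ic50 > 0:
            raise ValidationError(f"ic50 must be positive, got {self.ic50}")


def label_actives(
    records: list[ActivityRecord], threshold: float = DEFAULT_IC50_THRESHOLD_NM
) -> set[str]:
    """Ids of compounds with IC50 ≤ threshold (inclusive boundary).

    Records without an IC50 and records above the threshold are discarded;
    neither contributes an inactive label.
    """
    if not threshold > 0:
        raise ValidationError("threshold must be positive")
    return {r.compound_id for r in records if r.ic50 is not None and r.ic50 <= threshold}


def read_activity_records(path) -> list[ActivityRecord]:
    """CSV columns: compound_id, ic50_nM, source (optional)."""
    df = pd.read_csv(path)
    if ID_COL not in df.columns or "ic50_nM" not in df.columns:
        raise SchemaError("activity CSV needs columns compound_id, ic50_nM")
    out = []
    for _, row in df.iterrows():
        ic50 = row["ic50_nM"]
        out.append(
            ActivityRecord(
                str(row[ID_COL]),
                None if pd.isna(ic50) else float(ic50),
                str(row.get("source", "")),
            )
        )
    return out


def assemble_dataset(actives: pd.DataFrame, decoys: pd.DataFrame) -> pd.DataFrame:
    """Concatenate actives and decoys into one labelled, deduplicated table.

    Duplicate policy: the first occurrence of a compound_id wins; after id
    dedup, rows whose full descriptor vector exactly equals an earlier row
    are also dropped.  Rows with any missing descriptor are dropped with a
    logged count.  Descriptor columns are canonicalised to sorted order.
    Assembling a table with itself is idempotent.
    """
    a_feats, d_feats = set(feature_columns(actives)), set(feature_columns(decoys))
    if len(decoys) and a_feats != d_feats:
        raise SchemaError(
            f"descriptor columns differ: only-actives={sorted(a_feats - d_feats)}, "
            f"only-decoys={sorted(d_feats - a_feats)}"
        )
    if not len(decoys):
        warnings.warn("empty decoy table: assembled dataset is all-active", stacklevel=2)

    feats = sorted(a_feats)
    actives = actives.assign(**{LABEL_COL: "active"})
    decoys = decoys.assign(**{LABEL_COL: "inactive"}) if len(decoys) else decoys
    combined = pd.concat([actives, decoys], ignore_index=True)[[ID_COL] + feats + [LABEL_COL]]

    n0 = len(combined)
    combined = combined.drop_duplicates(subset=ID_COL, keep="first")
    combined = combined.drop_duplicates(subset=feats, keep="first")
    n_dup = n0 - len(combined)

    incomplete = combined[feats].isna().any(axis=1)
    n_missing = int(incomplete.sum())
    combined = combined[~incomplete]
    if n_dup or n_missing:
        log.info("curation dropped %d duplicate and %d incomplete rows", n_dup, n_missing)
    return combined.reset_index(drop=True)
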