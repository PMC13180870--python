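"""Virtual screening: score an external unlabelled descriptor library.

Library compounds are scaled with the *training* scaler stored in the
classifier bundle (never refit), scored, thresholded (predicted active when
probability ≥ threshold), and ranked by descending probability with ties
broken by compound id.  Compounds with any missing required descriptor are
dropped and logged rather than imputed, mirroring the attrition that occurs
when descriptor generation fails for part of a library.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import ClassifierResults
from .errors import SchemaError
from .tables import ID_COL

DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class ScreeningResult:
    """Ranked predictions plus the dropped-compound log."""

    scored: pd.DataFrame  # compound_id, probability, predicted_class, rank
    dropped: pd.DataFrame  # compound_id, reason
    threshold: float

    @property
    def n_scored(self) -> int:
        return len(self.scored)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)

    @property
    def n_predicted_active(self) -> int:
        return int((self.scored["predicted_class"] == "active").sum())

    def summary(self) -> str:
        return (
            f"Screening: {self.n_scored + self.n_dropped} compounds in, "
            f"{self.n_dropped} dropped (incomplete descriptors), "
            f"{self.n_scored} scored, {self.n_predicted_active} predicted active "
            f"at threshold {self.threshold}"
        )


def screen(
    bundle: ClassifierResults,
    library: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
) -> ScreeningResult:
    """Apply a trained bundle to a descriptor library.

    The library must contain every feature the bundle was trained on
    (missing columns are a schema error); extra columns are ignored with a
    warning.  The bundle is never mutated.
    """
    required = bundle.feature_names
    missing_cols = [c for c in required if c not in library.columns]
    if missing_cols:
        raise SchemaError(f"library lacks required descriptor column(s): {missing_cols}")
    extra = [c for c in library.columns if c not in required and c != ID_COL]
    if extra:
        warnings.warn(f"ignoring {len(extra)} extra library column(s): {extra[:5]}", stacklevel=2)

    values = library[required]
    incomplete = values.isna().any(axis=1)
    dropped_rows = []
    for _, row in library[incomplete].iterrows():
        bad = [c for c in required if pd.isna(row[c])]
        dropped_rows.append({ID_COL: row[ID_COL], "reason": f"missing descriptor: {bad[0]}"})
    dropped = pd.DataFrame(dropped_rows, columns=[ID_COL, "reason"])

    usable = library[~incomplete][[ID_COL] + required].reset_index(drop=True)
    if len(usable):
        probs = bundle.predict_proba(usable)
    else:
        probs = np.empty(0)
    scored = pd.DataFrame(
        {
            ID_COL: usable[ID_COL],
            "probability": probs,
            "predicted_class": np.where(probs >= threshold, "active", "inactive"),
        }
    )
    scored = scored.sort_values(
        ["probability", ID_COL], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    scored["rank"] = np.arange(1, len(scored) + 1)
    return ScreeningResult(scored, dropped, threshold)
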