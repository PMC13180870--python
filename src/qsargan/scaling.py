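"""Fitted, reusable, invertible per-feature scalers.

Two kinds are provided: ``minmax`` (maps each feature's training range onto
[0, 1]; used in front of the GAN so descriptors match its sigmoid output
range) and ``zscore`` (sample-sd standardisation; used in front of the
boosted-tree classifier).  A scaler is fit once on training rows and then
applied, unchanged, to any later table — screening compounds outside the
training range map outside [0, 1] by the same affine rule and are never
clipped, and applying a scaler never consults statistics of the new data.

Degenerate (constant) features transform to 0 for both kinds; their inverse
returns the constant.  Parameters round-trip through JSON so a pipeline can
persist them next to a model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .tables import feature_columns

KINDS = ("minmax", "zscore")


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature affine statistics: ``(x - loc) / scale`` with scale>0.

    For ``minmax`` loc/scale are min and (max-min); for ``zscore`` they are
    mean and sample sd (ddof=1).  Constant features store scale 0 and are
    transformed with an effective scale of 1, so they map to exactly 0.
    """

    kind: str
    features: tuple[str, ...]
    loc: tuple[float, ...]
    scale: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(f"unknown scaler kind {self.kind!r}")
        if not self.features:
            raise ValidationError("feature list must be non-empty")
        if len(set(self.features)) != len(self.features):
            raise ValidationError("feature names must be unique")
        if any(s < 0 for s in self.scale):
            raise ValidationError("negative scale")

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "features": list(self.features),
                "loc": list(self.loc),
                "scale": list(self.scale),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ScalerParams":
        d = json.loads(text)
        return cls(d["kind"], tuple(d["features"]), tuple(d["loc"]), tuple(d["scale"]))


def fit(table: pd.DataFrame, kind: str) -> ScalerParams:
    """Fit per-feature statistics on the provided rows only."""
    if kind not in KINDS:
        raise ValidationError(f"unknown scaler kind {kind!r}")
    features = feature_columns(table)
    if not features:
        raise ValidationError("table has no descriptor columns")
    if len(table) < 2:
        raise ValidationError("need at least 2 rows to fit a scaler")
    values = table[features].to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValidationError("non-finite descriptor values in scaler fit")
    if kind == "minmax":
        lo = values.min(axis=0)
        hi = values.max(axis=0)
        loc, scale = lo, hi - lo
    else:
        loc = values.mean(axis=0)
        scale = values.std(axis=0, ddof=1)
    return ScalerParams(kind, tuple(features), tuple(map(float, loc)), tuple(map(float, scale)))


def _effective_scale(params: ScalerParams) -> np.ndarray:
    scale = np.asarray(params.scale, dtype=float)
    return np.where(scale == 0.0, 1.0, scale)


def transform(table: pd.DataFrame, params: ScalerParams) -> pd.DataFrame:
    """Apply the fitted affine map; never refits, never clips."""
    _check_schema(table, params)
    out = table.copy()
    values = out[list(params.features)].to_numpy(dtype=float)
    out[list(params.features)] = (values - np.asarray(params.loc)) / _effective_scale(params)
    return out


def inverse_transform(table: pd.DataFrame, params: ScalerParams) -> pd.DataFrame:
    _check_schema(table, params)
    out = table.copy()
    values = out[list(params.features)].to_numpy(dtype=float)
    out[list(params.features)] = values * _effective_scale(params) + np.asarray(params.loc)
    return out


def _check_schema(table: pd.DataFrame, params: ScalerParams) -> None:
    missing = [c for c in params.features if c not in table.columns]
    if missing:
        raise SchemaError(f"table lacks feature column(s): {missing}")
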