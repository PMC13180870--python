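"""Fidelity diagnostics for generated descriptor tables.

Visual checks (PCA and t-SNE overlays of real vs synthetic rows, descriptor
histograms) are complemented by machine-checkable statistics: per-descriptor
two-sample Kolmogorov–Smirnov distances and moment deltas, a cross-validated
real-vs-synthetic discriminability score (0.5 = indistinguishable), and a
mode-collapse ratio (mean pairwise distance among synthetic rows over the
same among real rows, on jointly z-scored features; a generator stuck on a
few modes drives this toward 0).

Thresholds — collapse flagged strictly below 0.2, discriminability warned
above 0.85 — are engineering defaults, labelled as such in the report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import ks_2samp
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.manifold import TSNE
from sklearn.model_selection import StratifiedKFold

from .errors import ValidationError
from .tables import LABEL_COL, feature_columns

COLLAPSE_THRESHOLD = 0.2
DISCRIMINABILITY_WARN = 0.85


def _matched_features(real: pd.DataFrame, synthetic: pd.DataFrame) -> list[str]:
    feats = feature_columns(real)
    if set(feats) != set(feature_columns(synthetic)):
        raise ValidationError("real and synthetic tables must share descriptor columns")
    return feats


def _joint_zscore(real: np.ndarray, synthetic: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    both = np.vstack([real, synthetic])
    mean = both.mean(axis=0)
    sd = both.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (real - mean) / sd, (synthetic - mean) / sd


def pca_overlay(
    real: pd.DataFrame, synthetic: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Project jointly standardised rows onto principal axes.

    Returns (coordinates tagged real/synthetic, explained-variance ratios).
    """
    feats = _matched_features(real, synthetic)
    if len(real) + len(synthetic) < n_components:
        raise ValidationError("fewer rows than requested components")
    xr, xs = _joint_zscore(
        real[feats].to_numpy(dtype=float), synthetic[feats].to_numpy(dtype=float)
    )
    both = np.vstack([xr, xs])
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(both)
    out = pd.DataFrame(coords, columns=[f"pc{i+1}" for i in range(n_components)])
    out["source"] = ["real"] * len(xr) + ["synthetic"] * len(xs)
    return out, pca.explained_variance_ratio_


def tsne_overlay(
    real: pd.DataFrame,
    synthetic: pd.DataFrame,
    perplexity: float = 30.0,
    iterations: int = 1000,
    seed: int = 42,
) -> pd.DataFrame:
    """2-D t-SNE embedding of the combined rows, deterministic given seed.

    Perplexity is auto-reduced (with a warning) when the combined table is
    too small for the requested value.
    """
    feats = _matched_features(real, synthetic)
    xr, xs = _joint_zscore(
        real[feats].to_numpy(dtype=float), synthetic[feats].to_numpy(dtype=float)
    )
    both = np.vstack([xr, xs])
    n = len(both)
    if n <= 3 * perplexity:
        new = max(1.0, (n - 1) / 3.0 - 1.0)
        warnings.warn(
            f"perplexity {perplexity} too large for {n} rows; reduced to {new}", stacklevel=2
        )
        perplexity = new
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=iterations,
        random_state=seed,
        init="pca",
    )
    coords = tsne.fit_transform(both)
    out = pd.DataFrame(coords, columns=["tsne1", "tsne2"])
    out["source"] = ["real"] * len(xr) + ["synthetic"] * len(xs)
    return out


def distribution_report(real: pd.DataFrame, synthetic: pd.DataFrame) -> pd.DataFrame:
    """Per-descriptor KS statistic and moment deltas, per class and pooled."""
    feats = _matched_features(real, synthetic)
    groups = [("pooled", real, synthetic)]
    if LABEL_COL in real.columns and LABEL_COL in synthetic.columns:
        for label in sorted(set(real[LABEL_COL]) & set(synthetic[LABEL_COL])):
            groups.append(
                (label, real[real[LABEL_COL] == label], synthetic[synthetic[LABEL_COL] == label])
            )
    rows = []
    for group, r, s in groups:
        for f in feats:
            rv = r[f].to_numpy(dtype=float)
            sv = s[f].to_numpy(dtype=float)
            ks = float(ks_2samp(rv, sv, method="asymp").statistic) if len(rv) and len(sv) else np.nan
            rows.append(
                {
                    "group": group,
                    "descriptor": f,
                    "ks": ks,
                    "mean_delta": float(sv.mean() - rv.mean()) if len(sv) and len(rv) else np.nan,
                    "sd_delta": float(sv.std(ddof=1) - rv.std(ddof=1))
                    if len(sv) > 1 and len(rv) > 1
                    else np.nan,
                }
            )
    return pd.DataFrame(rows)


def collapse_check(real: pd.DataFrame, synthetic: pd.DataFrame) -> tuple[float, str]:
    """Mode-collapse diagnostic: synthetic/real mean pairwise distance ratio.

    Verdict is "collapse-suspect" strictly below the 0.2 threshold, "ok"
    otherwise (a ratio of exactly 0.2 is not flagged).
    """
    feats = _matched_features(real, synthetic)
    if len(real) < 2 or len(synthetic) < 2:
        raise ValidationError("need at least 2 rows in each table")
    xr, xs = _joint_zscore(
        real[feats].to_numpy(dtype=float), synthetic[feats].to_numpy(dtype=float)
    )
    real_spread = pdist(xr).mean()
    synth_spread = pdist(xs).mean()
    ratio = float(synth_spread / real_spread) if real_spread > 0 else np.inf
    verdict = "collapse-suspect" if ratio < COLLAPSE_THRESHOLD else "ok"
    return ratio, verdict


def discriminability(
    real: pd.DataFrame, synthetic: pd.DataFrame, k: int = 5, seed: int = 0
) -> float:
    """Cross-validated accuracy of a linear classifier told to separate real
    from synthetic rows; 0.5 means indistinguishable.  Fold-averaged and
    floored at the majority-class fraction, so the score is ≥ 0.5."""
    feats = _matched_features(real, synthetic)
    xr, xs = _joint_zscore(
        real[feats].to_numpy(dtype=float), synthetic[feats].to_numpy(dtype=float)
    )
    x = np.vstack([xr, xs])
    y = np.r_[np.zeros(len(xr)), np.ones(len(xs))]
    k = min(k, int(min(len(xr), len(xs))))
    if k < 2:
        raise ValidationError("need at least 2 rows per table for discriminability")
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for train, test in cv.split(x, y):
        clf = LogisticRegression(max_iter=1000)
        clf.fit(x[train], y[train])
        accs.append(float((clf.predict(x[test]) == y[test]).mean()))
    majority = max(y.mean(), 1 - y.mean())
    return max(float(np.mean(accs)), float(majority))


@dataclass(frozen=True)
class FidelityReport:
    """Bundle of fidelity diagnostics for one real/synthetic pair."""

    distributions: pd.DataFrame
    pca_coordinates: pd.DataFrame
    explained_variance_ratio: tuple[float, ...]
    tsne_coordinates: pd.DataFrame
    discriminability: float
    collapse_ratio: float
    collapse_verdict: str

    def summary(self) -> dict:
        pooled = self.distributions[self.distributions.group == "pooled"]
        return {
            "median_ks_pooled": float(pooled.ks.median()),
            "max_ks_pooled": float(pooled.ks.max()),
            "discriminability": self.discriminability,
            "discriminability_warn_threshold": DISCRIMINABILITY_WARN,
            "collapse_ratio": self.collapse_ratio,
            "collapse_threshold": COLLAPSE_THRESHOLD,
            "collapse_verdict": self.collapse_verdict,
            "explained_variance_ratio": list(self.explained_variance_ratio),
        }


def fidelity_report(
    real: pd.DataFrame, synthetic: pd.DataFrame, seed: int = 42, tsne: bool = True
) -> FidelityReport:
    """Run the full diagnostic suite on a real/synthetic table pair."""
    dist = distribution_report(real, synthetic)
    pca_coords, evr = pca_overlay(real, synthetic)
    tsne_coords = (
        tsne_overlay(real, synthetic, seed=seed)
        if tsne
        else pd.DataFrame(columns=["tsne1", "tsne2", "source"])
    )
    disc = discriminability(real, synthetic, seed=seed)
    ratio, verdict = collapse_check(real, synthetic)
    return FidelityReport(dist, pca_coords, tuple(map(float, evr)), tsne_coords, disc, ratio, verdict)
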