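"""Leakage-safe augmentation and gradient-boosted activity classification.

Real compounds are split (stratified) into train/validation/test before any
synthetic data enters the picture; GAN-generated rows join the training set
only, and every trained bundle carries a leakage certificate proving that no
synthetic id — and no training id — appears in an evaluation split.
Features are z-score standardised with statistics of the combined (real +
synthetic) training rows, and an XGBoost model is trained for a fixed
number of boosting rounds (no early stopping) with log-loss tracked on
train and validation each round.

Evaluation metrics come from :mod:`qsargan.metrics` (own formulas).  The
default hyperparameters are the reference workflow's: 2000 estimators,
learning rate 0.03, depth 6, subsample 0.9, colsample 0.8, λ=1, α=0,
``hist`` tree method, single-threaded for reproducibility.
"""

from __future__ import annotations

import math
import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb

from . import metrics, scaling
from .errors import LeakageError, ValidationError
from .tables import ID_COL, LABEL_COL, LABELS, feature_columns, is_synthetic_id

_Y = {"active": 1, "inactive": 0}


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/validation/test fractions (must sum to 1)."""

    train: float = 0.70
    validation: float = 0.15
    test: float = 0.15
    stratified: bool = True
    seed: int = 42

    def __post_init__(self) -> None:
        fracs = (self.train, self.validation, self.test)
        if any(not f > 0 for f in fracs):
            raise ValidationError("every split fraction must be positive")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValidationError("split fractions must sum to 1")


@dataclass(frozen=True)
class GbtConfig:
    n_estimators: int = 2000
    learning_rate: float = 0.03
    max_depth: int = 6
    subsample: float = 0.9
    colsample_bytree: float = 0.8
    reg_lambda: float = 1.0
    reg_alpha: float = 0.0
    tree_method: str = "hist"
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_estimators < 1 or self.max_depth < 1:
            raise ValidationError("n_estimators and max_depth must be positive")
        if not 0 < self.learning_rate:
            raise ValidationError("learning_rate must be positive")
        for name in ("subsample", "colsample_bytree"):
            if not 0 < getattr(self, name) <= 1:
                raise ValidationError(f"{name} must lie in (0, 1]")
        if self.reg_lambda < 0 or self.reg_alpha < 0:
            raise ValidationError("regularisation weights must be nonnegative")

    def xgb_params(self) -> dict:
        return dict(
            n_estimators=self.n_estimators,
            learning_rate=self.learning_rate,
            max_depth=self.max_depth,
            subsample=self.subsample,
            colsample_bytree=self.colsample_bytree,
            reg_lambda=self.reg_lambda,
            reg_alpha=self.reg_alpha,
            tree_method=self.tree_method,
            random_state=self.seed,
            n_jobs=1,
            objective="binary:logistic",
            eval_metric="logloss",
        )


def split_real(
    table: pd.DataFrame, spec: SplitSpec = SplitSpec()
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Disjoint stratified partition of a labelled real-compound table.

    Rounding rule, per class: ``n_train = floor(f_train·n)``,
    ``n_val = floor(f_val·n)``, the remainder goes to test.  Deterministic
    given ``spec.seed``; raises if any class is absent from any split.
    """
    if LABEL_COL not in table.columns:
        raise ValidationError("split requires a labelled table")
    if any(is_synthetic_id(i) for i in table[ID_COL]):
        raise LeakageError("synthetic ids found in the real-compound table")
    rng = np.random.default_rng(spec.seed)
    parts: dict[str, list[pd.DataFrame]] = {"train": [], "validation": [], "test": []}
    groups = table.groupby(LABEL_COL, sort=True) if spec.stratified else [("all", table)]
    for label, group in groups:
        n = len(group)
        n_train = math.floor(spec.train * n)
        n_val = math.floor(spec.validation * n)
        n_test = n - n_train - n_val
        if min(n_train, n_val, n_test) < 1:
            raise ValidationError(f"class {label!r} would be absent from a split (n={n})")
        order = rng.permutation(n)
        shuffled = group.iloc[order]
        parts["train"].append(shuffled.iloc[:n_train])
        parts["validation"].append(shuffled.iloc[n_train : n_train + n_val])
        parts["test"].append(shuffled.iloc[n_train + n_val :])
    out = tuple(
        pd.concat(parts[k], ignore_index=True) for k in ("train", "validation", "test")
    )
    if spec.stratified:
        for split in out:
            if set(split[LABEL_COL]) != set(table[LABEL_COL]):
                raise ValidationError("a class is absent from a split")
    return out


def augment_training(
    train_real: pd.DataFrame,
    synthetic: pd.DataFrame,
    validation: pd.DataFrame | None = None,
    test: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Concatenate synthetic rows into the training set only.

    Returns (combined table, leakage certificate).  Any synthetic id found
    in validation or test is a hard failure, as is a synthetic row without
    the recognisable id prefix.
    """
    if len(synthetic):
        bad = [i for i in synthetic[ID_COL] if not is_synthetic_id(i)]
        if bad:
            raise LeakageError(f"synthetic rows without synthetic id prefix: {bad[:5]}")
    for name, split in (("validation", validation), ("test", test)):
        if split is not None:
            leaked = [i for i in split[ID_COL] if is_synthetic_id(i)]
            if leaked:
                raise LeakageError(f"synthetic id(s) in {name} split: {leaked[:5]}")
    combined = (
        pd.concat([train_real, synthetic], ignore_index=True) if len(synthetic) else train_real.copy()
    )
    certificate = {
        "n_train_real": int(len(train_real)),
        "n_synthetic": int(len(synthetic)),
        "n_train_combined": int(len(combined)),
        "synthetic_in_validation": 0,
        "synthetic_in_test": 0,
        "leakage_free": True,
    }
    return combined, certificate


@dataclass
class EvalReport:
    """Test-set evaluation: confusion matrix, rate metrics, ranking metrics,
    calibration curve."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float
    roc_auc: float | None
    average_precision: float | None
    calibration_bin_centers: list[float]
    calibration_mean_predicted: list[float]
    calibration_observed_frequency: list[float]

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def summary(self) -> str:
        auc = "n/a" if self.roc_auc is None else f"{self.roc_auc:.4f}"
        ap = "n/a" if self.average_precision is None else f"{self.average_precision:.4f}"
        return (
            "Activity-classifier evaluation\n"
            f"  confusion  TP={self.tp} FP={self.fp} FN={self.fn} TN={self.tn}\n"
            f"  accuracy   {self.accuracy:.4f}\n"
            f"  precision  {self.precision:.4f}\n"
            f"  recall     {self.recall:.4f}\n"
            f"  F1         {self.f1:.4f}\n"
            f"  MCC        {self.mcc:.4f}\n"
            f"  ROC-AUC    {auc}\n"
            f"  avg prec   {ap}"
        )


def evaluate_scores(y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5) -> EvalReport:
    """Full metric suite from labels and predicted activity probabilities."""
    c = metrics.confusion_at(y_true, scores, threshold)
    centers, mean_pred, obs = metrics.calibration_curve(y_true, scores)
    return EvalReport(
        tp=c.tp,
        fp=c.fp,
        fn=c.fn,
        tn=c.tn,
        accuracy=metrics.accuracy(c),
        precision=metrics.precision(c),
        recall=metrics.recall(c),
        f1=metrics.f1_score(c),
        mcc=float(metrics.mcc(c)),
        roc_auc=metrics.roc_auc(y_true, scores),
        average_precision=metrics.average_precision(y_true, scores),
        calibration_bin_centers=list(centers),
        calibration_mean_predicted=list(mean_pred),
        calibration_observed_frequency=list(obs),
    )


class ActivityClassifier:
    """Model object: combined training table + validation table + config."""

    def __init__(
        self,
        train_combined: pd.DataFrame,
        validation: pd.DataFrame,
        config: GbtConfig | None = None,
    ):
        for name, t in (("training", train_combined), ("validation", validation)):
            if LABEL_COL not in t.columns:
                raise ValidationError(f"{name} table must be labelled")
        overlap = set(train_combined[ID_COL]) & set(validation[ID_COL])
        if overlap:
            raise LeakageError(f"training ids present in validation: {sorted(overlap)[:5]}")
        if any(is_synthetic_id(i) for i in validation[ID_COL]):
            raise LeakageError("synthetic ids in validation split")
        self.train = train_combined.reset_index(drop=True)
        self.validation = validation.reset_index(drop=True)
        self.config = config or GbtConfig()
        self.feature_names = feature_columns(train_combined)

    def fit(self) -> "ClassifierResults":
        for table in (self.train, self.validation):
            self._check_finite(table)
        scaler = scaling.fit(self.train, "zscore")
        xtr = self._design(self.train, scaler)
        xva = self._design(self.validation, scaler)
        ytr = self.train[LABEL_COL].map(_Y).to_numpy()
        yva = self.validation[LABEL_COL].map(_Y).to_numpy()
        model = xgb.XGBClassifier(**self.config.xgb_params())
        model.fit(xtr, ytr, eval_set=[(xtr, ytr), (xva, yva)], verbose=False)
        ev = model.evals_result()
        curves = pd.DataFrame(
            {
                "round": np.arange(self.config.n_estimators),
                "train_logloss": ev["validation_0"]["logloss"],
                "val_logloss": ev["validation_1"]["logloss"],
            }
        )
        return ClassifierResults(model, scaler, self.feature_names, curves, set(self.train[ID_COL]))

    def _check_finite(self, table: pd.DataFrame) -> None:
        values = table[self.feature_names].to_numpy(dtype=float)
        if not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite feature value: compound "
                f"{table[ID_COL].iloc[i]!r}, feature {self.feature_names[j]!r}"
            )

    def _design(self, table: pd.DataFrame, scaler) -> np.ndarray:
        scaled = scaling.transform(table, scaler)[self.feature_names]
        values = scaled.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite feature after scaling: compound "
                f"{table[ID_COL].iloc[i]!r}, feature {self.feature_names[j]!r}"
            )
        return values


class ClassifierResults:
    """Fitted boosted-tree bundle: model, training-set scaler, loss curves."""

    def __init__(self, model, scaler, feature_names, logloss_curves, train_ids):
        self.model = model
        self.scaler = scaler
        self.feature_names = list(feature_names)
        self.logloss_curves = logloss_curves
        self.train_ids = set(train_ids)

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        scaled = scaling.transform(table, self.scaler)[self.feature_names]
        return self.model.predict_proba(scaled.to_numpy(dtype=float))[:, 1]

    def evaluate(self, test: pd.DataFrame, threshold: float = 0.5) -> EvalReport:
        overlap = self.train_ids & set(test[ID_COL])
        if overlap:
            raise LeakageError(f"test rows seen in training: {sorted(overlap)[:5]}")
        y = test[LABEL_COL].map(_Y).to_numpy()
        return evaluate_scores(y, self.predict_proba(test), threshold)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "ClassifierResults":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, cls):
            raise ValidationError(f"{path} is not a saved ClassifierResults bundle")
        return obj


@dataclass(frozen=True)
class CVResult:
    fold_accuracies: tuple[float, ...]
    mean: float
    sd: float


def cross_validate(
    real_table: pd.DataFrame,
    synthetic: pd.DataFrame,
    k: int = 5,
    config: GbtConfig | None = None,
    seed: int = 42,
) -> CVResult:
    """Stratified k-fold CV with the leakage-safe augmentation policy:
    synthetic rows join only each fold's training part; held-out folds are
    real-only."""
    from sklearn.model_selection import StratifiedKFold

    if k < 2:
        raise ValidationError("k must be at least 2")
    counts = real_table[LABEL_COL].value_counts()
    if any(counts.get(label, 0) < k for label in LABELS):
        raise ValidationError(f"every class needs at least k={k} members")
    config = config or GbtConfig()
    y = real_table[LABEL_COL].map(_Y).to_numpy()
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in cv.split(np.zeros(len(y)), y):
        fold_train = real_table.iloc[train_idx].reset_index(drop=True)
        fold_test = real_table.iloc[test_idx].reset_index(drop=True)
        combined, _ = augment_training(fold_train, synthetic, test=fold_test)
        results = ActivityClassifier(combined, fold_test, config).fit()
        report = results.evaluate(fold_test)
        accs.append(report.accuracy)
    accs = tuple(accs)
    return CVResult(accs, float(np.mean(accs)), float(np.std(accs, ddof=1)))
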