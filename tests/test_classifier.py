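"""Splitting, leakage-safe augmentation, boosted-tree training, CV."""

import numpy as np
import pandas as pd
import pytest

from qsargan.classifier import (
    ActivityClassifier,
    GbtConfig,
    SplitSpec,
    augment_training,
    cross_validate,
    split_real,
)
from qsargan.errors import LeakageError, ValidationError
from qsargan.synthetic import FixtureSpec, make_training_fixture
from qsargan.tables import ID_COL, LABEL_COL


class TestSplit:
    def test_stratified_sizes_follow_floor_rule(self):
        # per class: floor(0.70 n) train, floor(0.15 n) validation, rest test
        table = make_training_fixture(FixtureSpec(n_active=138, n_inactive=150, seed=0))
        train, val, test = split_real(table, SplitSpec(seed=1))
        assert (len(train), len(val), len(test)) == (201, 42, 45)
        assert len(train) + len(val) + len(test) == 288

    def test_partition_is_disjoint_and_stratified(self, small_table):
        train, val, test = split_real(small_table, SplitSpec(seed=2))
        ids = [set(s[ID_COL]) for s in (train, val, test)]
        assert not (ids[0] & ids[1] or ids[0] & ids[2] or ids[1] & ids[2])
        for split in (train, val, test):
            assert set(split[LABEL_COL]) == {"active", "inactive"}

    def test_deterministic_given_seed(self, small_table):
        a = split_real(small_table, SplitSpec(seed=3))
        b = split_real(small_table, SplitSpec(seed=3))
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_degenerate_fractions_rejected(self):
        with pytest.raises(ValidationError):
            SplitSpec(train=1.0, validation=0.0, test=0.0)
        with pytest.raises(ValidationError):
            SplitSpec(train=0.5, validation=0.2, test=0.2)

    def test_tiny_class_cannot_fill_every_split(self):
        table = make_training_fixture(
            FixtureSpec(n_active=2, n_inactive=30, n_descriptors=5, n_shifted=2,
                        latent_rank=2, seed=4)
        )
        with pytest.raises(ValidationError):
            split_real(table, SplitSpec(seed=0))


class TestAugmentation:
    def _synthetic(self, small_table, n=10):
        synth = small_table.iloc[:n].copy()
        synth[ID_COL] = [f"SYN-a-{i}" for i in range(n)]
        return synth

    def test_counts_and_certificate(self, small_table):
        train, val, test = split_real(small_table, SplitSpec(seed=5))
        synth = self._synthetic(small_table)
        combined, cert = augment_training(train, synth, val, test)
        assert len(combined) == len(train) + 10
        assert cert["leakage_free"] and cert["n_synthetic"] == 10

    def test_empty_synthetic_leaves_train_unchanged(self, small_table):
        train, val, test = split_real(small_table, SplitSpec(seed=5))
        combined, _ = augment_training(train, train.iloc[0:0], val, test)
        pd.testing.assert_frame_equal(combined, train)

    def test_injected_synthetic_row_in_test_is_hard_failure(self, small_table):
        train, val, test = split_real(small_table, SplitSpec(seed=5))
        synth = self._synthetic(small_table)
        poisoned = pd.concat([test, synth.iloc[:1]], ignore_index=True)
        with pytest.raises(LeakageError):
            augment_training(train, synth, val, poisoned)

    def test_synthetic_rows_must_carry_prefix(self, small_table):
        train, val, test = split_real(small_table, SplitSpec(seed=5))
        bogus = small_table.iloc[:3].copy()  # real-looking ids
        with pytest.raises(LeakageError):
            augment_training(train, bogus, val, test)


class TestTraining:
    def test_training_logloss_non_increasing(self, small_bundle):
        results, *_ = small_bundle
        steps = np.diff(results.logloss_curves["train_logloss"])
        assert (steps <= 1e-6).all()

    def test_validation_logloss_improves_on_separable_fixture(self):
        table = make_training_fixture(FixtureSpec(n_active=60, n_inactive=60, class_shift=3.0, seed=6))
        train, val, test = split_real(table, SplitSpec(seed=6))
        results = ActivityClassifier(train, val, GbtConfig(n_estimators=200, seed=6)).fit()
        curve = results.logloss_curves["val_logloss"]
        assert curve.iloc[-1] < curve.iloc[0]

    def test_same_seed_identical_predictions(self, small_table):
        train, val, test = split_real(small_table, SplitSpec(seed=7))
        cfg = GbtConfig(n_estimators=40, seed=7)
        p1 = ActivityClassifier(train, val, cfg).fit().predict_proba(test)
        p2 = ActivityClassifier(train, val, cfg).fit().predict_proba(test)
        np.testing.assert_array_equal(p1, p2)

    def test_nonfinite_feature_reported_with_compound_and_feature(self, small_table):
        train, val, _ = split_real(small_table, SplitSpec(seed=8))
        bad = train.copy()
        bad.iloc[0, 2] = np.inf
        with pytest.raises(ValidationError, match=bad[ID_COL].iloc[0]):
            ActivityClassifier(bad, val, GbtConfig(n_estimators=5, seed=0)).fit()

    def test_overlapping_validation_ids_rejected(self, small_table):
        train, val, _ = split_real(small_table, SplitSpec(seed=8))
        with pytest.raises(LeakageError):
            ActivityClassifier(train, train.iloc[:5], GbtConfig(seed=0))


class TestEvaluation:
    def test_full_report_on_held_out_test(self, small_bundle):
        results, train, val, test = small_bundle
        report = results.evaluate(test)
        assert report.tp + report.fp + report.fn + report.tn == len(test)
        for name in ("accuracy", "precision", "recall", "f1"):
            assert 0 <= getattr(report, name) <= 1
        assert -1 <= report.mcc <= 1

    def test_test_rows_seen_in_training_rejected(self, small_bundle):
        results, train, *_ = small_bundle
        with pytest.raises(LeakageError):
            results.evaluate(train.iloc[:4])


class TestCrossValidation:
    def test_returns_k_fold_accuracies_deterministically(self, small_table):
        cfg = GbtConfig(n_estimators=20, seed=9)
        empty = small_table.iloc[0:0]
        a = cross_validate(small_table, empty, k=5, config=cfg, seed=9)
        b = cross_validate(small_table, empty, k=5, config=cfg, seed=9)
        assert len(a.fold_accuracies) == 5
        assert a == b

    def test_small_class_rejected(self, small_table):
        tiny = small_table.iloc[:6]
        with pytest.raises(ValidationError):
            cross_validate(tiny, small_table.iloc[0:0], k=5, config=GbtConfig(n_estimators=5))

    def test_separable_fixture_scores_high(self):
        table = make_training_fixture(FixtureSpec(n_active=60, n_inactive=60, class_shift=2.0, seed=10))
        wins = 0
        for seed in (1, 2, 3):
            cv = cross_validate(table, table.iloc[0:0], k=5,
                                config=GbtConfig(n_estimators=150, seed=seed), seed=seed)
            wins += cv.mean > 0.9
        assert wins >= 2
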