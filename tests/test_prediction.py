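"""Tests of nested night-level CV, learners and evaluation metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import average_precision_score, roc_auc_score

from nighteda.config import ModelConfig
from nighteda.features import FEATURE_COLUMNS
from nighteda.prediction import (
    EvaluationResult,
    NextDayHeadacheModel,
    SingleClassError,
    average_precision,
    class_weights,
    plan_folds,
    predict_night,
    rates_to_metrics,
    roc_auc,
    tune_and_fit,
    _night_arrays,
)

from conftest import make_feature_blocks, oracle_auroc


class TestFoldPlanning:
    def test_leave_one_night_out_structure(self):
        labels = pd.Series([1, 0, 1, 0, 1], index=[f"n{i}" for i in range(5)])
        plan = plan_folds(labels)
        assert len(plan.outer) == 5
        held = [h for h, _ in plan.outer]
        assert sorted(held) == sorted(labels.index)
        for h, train in plan.outer:
            assert h not in train
            assert len(train) == 4

    def test_inner_pairs_are_exhaustive(self):
        labels = pd.Series([1] * 3 + [0] * 4 + [1], index=[f"n{i}" for i in range(8)])
        plan = plan_folds(labels)
        held, train = plan.outer[-1]  # hold out a headache night
        pairs = plan.inner_pairs[held]
        assert len(pairs) == 3 * 4  # all headache x non-headache pairs
        assert len(set(pairs)) == len(pairs)
        for pos, neg in pairs:
            assert labels[pos] == 1 and labels[neg] == 0
            assert held not in (pos, neg)

    def test_single_class_raises(self):
        with pytest.raises(SingleClassError):
            plan_folds(pd.Series([1, 1, 1], index=list("abc")))

    def test_fold_integrity_end_to_end(self, participant_blocks_40):
        cache = _night_arrays(participant_blocks_40)
        labels = pd.Series({n: lab for n, (_, lab) in cache.items()})
        plan = plan_folds(labels)
        held = [h for h, _ in plan.outer]
        assert sorted(held) == sorted(labels.index)
        for h, train in plan.outer:
            assert set(train) | {h} == set(labels.index)


class TestClassWeights:
    def test_balanced_classes_unit_weights(self):
        w = class_weights(pd.Series([1] * 20 + [0] * 20))
        assert w == {0: 1.0, 1: 1.0}

    def test_inverse_frequency_formula(self):
        w = class_weights(pd.Series([1] * 10 + [0] * 30))
        assert w[1] == pytest.approx(2.0)
        assert w[0] == pytest.approx(2 / 3, abs=1e-3)

    def test_disabled_weighting(self):
        w = class_weights(pd.Series([1] * 10 + [0] * 30), enabled=False)
        assert w == {0: 1.0, 1: 1.0}


class TestMetrics:
    def test_auroc_matches_pairwise_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(5, 30))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            s = np.round(rng.uniform(size=n), 1)  # rounding forces ties
            assert roc_auc(y, s) == pytest.approx(oracle_auroc(y, s))

    def test_auroc_matches_sklearn(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 50)
        s = rng.normal(size=50)
        assert roc_auc(y, s) == pytest.approx(roc_auc_score(y, s))

    def test_average_precision_matches_sklearn(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            y = rng.integers(0, 2, 30)
            if y.min() == y.max():
                continue
            s = np.round(rng.uniform(size=30), 1)
            assert average_precision(y, s) == pytest.approx(average_precision_score(y, s))

    def test_degenerate_scores(self):
        y = np.array([1, 0, 1, 0])
        s = np.array([0.4, 0.4, 0.4, 0.4])
        assert roc_auc(y, s) == pytest.approx(0.5)
        assert average_precision(y, s) == pytest.approx(0.5)  # prevalence
        perfect = np.array([0.9, 0.1, 0.8, 0.2])
        assert roc_auc(y, perfect) == 1.0
        assert average_precision(y, perfect) == 1.0


class TestMetricProperties:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 1), st.floats(0, 1)), min_size=4, max_size=40))
    def test_auroc_invariant_to_monotone_score_transform(self, pairs):
        y = np.array([p[0] for p in pairs])
        # probability-scale resolution: keeps the affine map tie-preserving
        s = np.round(np.array([p[1] for p in pairs]), 6)
        if y.min() == y.max():
            return
        assert roc_auc(y, s) == pytest.approx(roc_auc(y, 3.0 * s + 1.0))
        assert roc_auc(y, s) == pytest.approx(1.0 - roc_auc(1 - y, s))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(0.01, 0.99), st.floats(0.0, 1.0), st.floats(0.0, 1.0)
    )
    def test_rates_to_metrics_stay_in_unit_interval(self, p, se, sp):
        precision, accuracy = rates_to_metrics(p, se, sp)
        assert 0.0 <= accuracy <= 1.0
        assert np.isnan(precision) or 0.0 <= precision <= 1.0
        # accuracy is the prevalence-weighted mean of se and sp
        assert accuracy == pytest.approx(p * se + (1 - p) * sp)


class TestRatesToMetrics:
    def test_printed_50pct_operating_point(self):
        precision, accuracy = rates_to_metrics(0.455, 0.75, 0.75)
        assert round(precision, 2) == 0.71
        assert round(accuracy, 2) == 0.75

    def test_printed_25pct_operating_point(self):
        _, accuracy = rates_to_metrics(0.455, 0.85, 0.63)
        assert round(accuracy, 2) == 0.73

    def test_perfect_rates(self):
        assert rates_to_metrics(0.3, 1.0, 1.0) == (1.0, 1.0)

    def test_undefined_precision_flagged_as_nan(self):
        precision, _ = rates_to_metrics(0.5, 0.0, 1.0)
        assert np.isnan(precision)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rates_to_metrics(1.2, 0.5, 0.5)


class TestNightScores:
    def test_score_is_mean_block_probability(self):
        class Stub:
            def predict_proba(self, X):
                p = np.array([0.2, 0.4, 0.9])[: len(X)]
                return np.column_stack([1 - p, p])

        assert predict_night(Stub(), np.zeros((3, 2))) == pytest.approx(0.5)

    def test_single_block_night(self):
        class Stub:
            def predict_proba(self, X):
                return np.array([[0.4, 0.6]])

        assert predict_night(Stub(), np.zeros((1, 2))) == pytest.approx(0.6)

    def test_zero_blocks_rejected(self):
        with pytest.raises(ValueError):
            predict_night(None, np.zeros((0, 2)))


class TestTuneAndFit:
    def setup_method(self):
        self.blocks = make_feature_blocks([1, 0, 1, 0, 1, 0, 1, 0], signal=2.0)
        self.cache = _night_arrays(self.blocks)
        self.nights = sorted(self.cache)

    def test_singleton_grid_skips_tuning(self):
        cfg = ModelConfig(learner="elastic_net", grid=[{"l1_ratio": 0.5, "penalty": 0.1}])
        model, chosen = tune_and_fit(self.cache, self.nights, [], cfg)
        assert chosen == {"l1_ratio": 0.5, "penalty": 0.1}

    def test_no_inner_pair_falls_back_to_midpoint(self):
        cfg = ModelConfig(learner="elastic_net")
        with pytest.warns(UserWarning, match="midpoint"):
            _, chosen = tune_and_fit(self.cache, self.nights, [], cfg)
        assert chosen == cfg.grid[len(cfg.grid) // 2]

    def test_scaler_statistics_frozen_from_training_only(self):
        # leakage probe: an extreme held-out block must not move the
        # frozen standardization means
        cfg = ModelConfig(learner="elastic_net", grid=[{"l1_ratio": 0.5, "penalty": 0.1}])
        train = self.nights[:-1]
        model, _ = tune_and_fit(self.cache, train, [], cfg)
        X_train = np.vstack([self.cache[n][0] for n in train])
        np.testing.assert_allclose(
            model.named_steps["scaler"].mean_, X_train.mean(axis=0), atol=1e-12
        )
        extreme = np.full((1, len(FEATURE_COLUMNS)), 1e6)
        model.predict_proba(extreme)
        np.testing.assert_allclose(
            model.named_steps["scaler"].mean_, X_train.mean(axis=0), atol=1e-12
        )

    def test_inner_pair_cap_is_seeded_subset(self):
        labels = pd.Series({n: self.cache[n][1] for n in self.nights})
        plan = plan_folds(labels)
        held, train = plan.outer[0]
        pairs = plan.inner_pairs[held]
        cfg = ModelConfig(
            learner="elastic_net", grid=[{"l1_ratio": 0.5, "penalty": 0.1},
                                         {"l1_ratio": 0.5, "penalty": 1.0}],
            max_inner_pairs=2, seed=3,
        )
        _, chosen_a = tune_and_fit(self.cache, train, pairs, cfg, fold_seed=0)
        _, chosen_b = tune_and_fit(self.cache, train, pairs, cfg, fold_seed=0)
        assert chosen_a == chosen_b  # deterministic under the seed


class TestModelEndToEnd:
    def test_strong_signal_is_learned(self):
        labels = [1, 0] * 8
        blocks = make_feature_blocks(labels, blocks_per_night=6, signal=3.0, seed=1)
        cfg = ModelConfig(learner="elastic_net", grid=[{"l1_ratio": 0.5, "penalty": 0.1}])
        res = NextDayHeadacheModel(blocks, config=cfg).fit()
        assert res.auroc > 0.9
        assert res.clinically_informative
        assert len(res.nightly) == 16
        assert "AUROC" in res.summary()

    def test_all_learners_run_and_are_deterministic(self):
        labels = [1, 0] * 6
        blocks = make_feature_blocks(labels, blocks_per_night=4, signal=2.0, seed=2)
        grids = {
            "elastic_net": [{"l1_ratio": 0.5, "penalty": 0.1}],
            "random_forest": [{"n_estimators": 30, "max_depth": 2, "max_features": "sqrt"}],
            "gbm": [{"n_estimators": 20, "learning_rate": 0.1, "max_depth": 2}],
        }
        for learner, grid in grids.items():
            cfg = ModelConfig(learner=learner, grid=grid, seed=5)
            a = NextDayHeadacheModel(blocks, config=cfg).fit()
            b = NextDayHeadacheModel(blocks, config=cfg).fit()
            pd.testing.assert_frame_equal(a.nightly, b.nightly)
            assert 0.0 <= a.auroc <= 1.0

    def test_single_class_participant_cannot_be_modelled(self):
        blocks = make_feature_blocks([1, 1, 1, 1])
        with pytest.raises(SingleClassError):
            NextDayHeadacheModel(blocks).fit()

    def test_evaluation_thresholds_use_geq_rule(self):
        labels = np.array([1, 1, 0, 0])
        scores = np.array([0.75, 0.50, 0.25, 0.10])
        ev = EvaluationResult.from_scores(labels, scores)
        row50 = ev.threshold_table.set_index("threshold").loc[0.50]
        assert row50["sensitivity"] == pytest.approx(1.0)  # 0.50 counts as positive
        assert row50["specificity"] == pytest.approx(1.0)
        row25 = ev.threshold_table.set_index("threshold").loc[0.25]
        assert row25["specificity"] == pytest.approx(0.5)
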