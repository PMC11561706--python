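import dataclasses

import numpy as np
import pandas as pd
import pytest

from clockshift import (LinearClock, MethylationDataset, SimulationConfig,
                        apply_clock, compare_model_families, fit_lasso_clock,
                        regression_metrics, rejuvenation_delta,
                        simulate_aging_methylation, simulate_reprogramming_course,
                        split_train_test)
from clockshift.clocks import AgePrediction, FamilySpec, predictions_to_array


def _dataset_from(beta_dict, ages=None, index=None):
    beta = pd.DataFrame(beta_dict)
    beta.index = index or [f"s{i}" for i in range(len(beta))]
    age = None if ages is None else pd.Series(ages, index=beta.index)
    return MethylationDataset(beta=beta, age=age)


class TestFitLassoClock:
    def test_default_is_five_fold(self, aging_dataset):
        clock = fit_lasso_clock(aging_dataset, seed=0)
        assert clock.cv_folds == 5

    def test_noiseless_single_cpg_recovery(self):
        rng = np.random.default_rng(1)
        cg1 = rng.uniform(0.1, 0.9, size=60)
        decoys = {f"cg_d{i:02d}": rng.uniform(0.2, 0.8, size=60) for i in range(50)}
        ages = 2.0 * cg1 * 100.0 + 5.0
        data = _dataset_from({"cg1": cg1, **decoys}, ages=ages)
        clock = fit_lasso_clock(data, seed=1)
        assert "cg1" in clock.support
        assert abs(clock.coefficients["cg1"] - 200.0) / 200.0 < 0.05

    def test_constant_target_rejected(self):
        data = _dataset_from({"cg1": [0.1, 0.5, 0.9, 0.2, 0.7]}, ages=[40.0] * 5)
        with pytest.raises(ValueError, match="constant"):
            fit_lasso_clock(data)

    def test_too_few_samples_rejected(self):
        data = _dataset_from({"cg1": [0.1, 0.5, 0.9]}, ages=[10.0, 20.0, 30.0])
        with pytest.raises(ValueError, match="folds"):
            fit_lasso_clock(data, folds=5)

    def test_huge_alpha_gives_empty_support_and_mean_intercept(self, aging_dataset):
        clock = fit_lasso_clock(aging_dataset, alpha_grid=[1e6], seed=0)
        assert clock.support == []
        assert abs(clock.intercept - aging_dataset.age.mean()) < 1e-8

    def test_synthetic_recovery(self):
        cfg = SimulationConfig(seed=11)
        train = simulate_aging_methylation(cfg)
        test = simulate_aging_methylation(
            dataclasses.replace(cfg, n_samples=100), sample_seed=99
        )
        clock = fit_lasso_clock(train, seed=11)
        metrics = regression_metrics(
            test.age.to_numpy(), predictions_to_array(apply_clock(clock, test))
        )
        assert metrics.r2 > 0.9
        recovered = set(clock.support) & set(train.attrs["age_cpgs"])
        assert len(recovered) >= 35

    def test_serialization_round_trip(self, aging_dataset, tmp_path):
        clock = fit_lasso_clock(aging_dataset, seed=2)
        clock.to_files(tmp_path / "coef.tsv", tmp_path / "header.json")
        back = LinearClock.from_files(tmp_path / "coef.tsv", tmp_path / "header.json")
        assert back.coefficients == clock.coefficients
        assert back.intercept == clock.intercept and back.alpha == clock.alpha


class TestApplyClock:
    def test_zero_coefficients_return_intercept(self, tiny_dataset):
        clock = LinearClock(coefficients={}, intercept=42.0, alpha=1.0, cv_folds=5)
        mus = predictions_to_array(apply_clock(clock, tiny_dataset))
        assert (mus == 42.0).all()

    def test_dot_product_by_hand(self):
        data = _dataset_from({"cg1": [0.5]})
        clock = LinearClock(coefficients={"cg1": 10.0}, intercept=5.0, alpha=0.1,
                            cv_folds=5)
        assert apply_clock(clock, data)[0].predicted_age == pytest.approx(10.0)

    def test_missing_support_cpgs_listed(self, tiny_dataset):
        clock = LinearClock(coefficients={"cg_absent": 1.0}, intercept=0.0, alpha=0.1,
                            cv_folds=5)
        with pytest.raises(KeyError, match="cg_absent"):
            apply_clock(clock, tiny_dataset)

    def test_linearity_in_samples(self):
        rng = np.random.default_rng(3)
        x1, x2 = rng.uniform(0.1, 0.9, size=4), rng.uniform(0.1, 0.9, size=4)
        lam = 0.3
        # three samples (x1, x2, their convex mix) over four CpGs
        beta = pd.DataFrame([x1, x2, lam * x1 + (1 - lam) * x2],
                            index=["a", "b", "mix"],
                            columns=["cg1", "cg2", "cg3", "cg4"])
        data = MethylationDataset(beta=beta)
        clock = LinearClock(coefficients={"cg1": 3.0, "cg3": -2.0, "cg4": 0.5},
                            intercept=7.0, alpha=0.1, cv_folds=5)
        mus = predictions_to_array(apply_clock(clock, data))
        assert mus[2] == pytest.approx(lam * mus[0] + (1 - lam) * mus[1], abs=1e-12)


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        m = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.mae == 0.0 and m.r2 == 1.0 and m.pearson_r == pytest.approx(1.0)

    def test_mean_predictor_scores_zero_r2(self):
        y = np.array([10.0, 20.0, 30.0, 40.0])
        m = regression_metrics(y, np.full(4, y.mean()))
        assert m.r2 == pytest.approx(0.0)
        assert m.constant_prediction and np.isnan(m.pearson_r)

    def test_hand_worked_case(self):
        m = regression_metrics([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert m.mae == pytest.approx(2.0 / 3.0)
        assert m.r2 == pytest.approx(0.0)
        assert np.isnan(m.pearson_r)

    def test_agrees_with_textbook_formulas(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            y = rng.normal(50, 10, size=30)
            yhat = y + rng.normal(0, 5, size=30)
            m = regression_metrics(y, yhat)
            err = yhat - y
            assert abs(m.mae - np.abs(err).mean()) < 1e-12
            assert abs(m.medae - np.median(np.abs(err))) < 1e-12
            expected_r2 = 1 - (err**2).sum() / ((y - y.mean()) ** 2).sum()
            assert abs(m.r2 - expected_r2) < 1e-12
            cov = np.cov(y, yhat)
            assert abs(m.pearson_r - cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1])) < 1e-12


class TestRejuvenationDelta:
    def _preds(self, values, group):
        return [AgePrediction(f"s{i}", v, group=group) for i, v in enumerate(values)]

    def test_identical_groups_zero(self):
        preds = self._preds([30.0, 40.0], "t0") + self._preds([30.0, 40.0], "t1")
        assert rejuvenation_delta(preds, "t0", "t1") == 0.0

    def test_arithmetic(self):
        preds = self._preds([50.0], "d0") + self._preds([10.0], "d15")
        assert rejuvenation_delta(preds, "d0", "d15") == -40.0

    def test_missing_group_rejected(self):
        with pytest.raises(ValueError, match="d99"):
            rejuvenation_delta(self._preds([1.0], "d0"), "d0", "d99")


class TestCompareModelFamilies:
    def test_linear_families_nail_noiseless_data(self):
        cfg = SimulationConfig(n_samples=80, n_cpgs=30, n_age_cpgs=10, noise_sd=0.0,
                               seed=4)
        full = simulate_aging_methylation(cfg)
        train, test = split_train_test(full, 0.25, seed=4)
        results = compare_model_families(train, test, seed=4)
        assert results["lasso"].test_metrics.r2 > 0.999

    def test_constant_family_has_zero_delta(self):
        class ConstantRegressor:
            def fit(self, X, y):
                return self

            def predict(self, X):
                return np.zeros(len(X))

        cfg = SimulationConfig(n_samples=60, n_cpgs=30, n_age_cpgs=10, seed=6)
        full = simulate_aging_methylation(cfg)
        train, test = split_train_test(full, 0.25, seed=6)
        course = simulate_reprogramming_course(cfg, [0, 10], 0.01, seed=6, n_per_day=10)
        results = compare_model_families(
            train, test, course,
            families={"const": FamilySpec(make=ConstantRegressor, param_grid={})},
            seed=6,
        )
        assert results["const"].delta == 0.0

    def test_failing_family_recorded_not_fatal(self):
        class Exploding:
            def fit(self, X, y):
                raise RuntimeError("boom")

            def predict(self, X):  # pragma: no cover
                return np.zeros(len(X))

        cfg = SimulationConfig(n_samples=40, n_cpgs=20, n_age_cpgs=5, seed=8)
        full = simulate_aging_methylation(cfg)
        train, test = split_train_test(full, 0.25, seed=8)
        results = compare_model_families(
            train, test, families={"bad": FamilySpec(make=Exploding, param_grid={})},
            seed=8,
        )
        assert results["bad"].failed and "boom" in results["bad"].error

    def test_families_disagree_on_drift_course(self):
        """Model-choice uncertainty: deltas differ across families on a course."""
        cfg = SimulationConfig(n_samples=120, n_cpgs=100, n_age_cpgs=20, seed=9)
        full = simulate_aging_methylation(cfg)
        train, test = split_train_test(full, 0.25, seed=9)
        course = simulate_reprogramming_course(cfg, [0, 14, 28], 0.02, seed=9,
                                               n_per_day=15)
        results = compare_model_families(train, test, course, seed=9)
        deltas = [r.delta for r in results.values() if not r.failed]
        assert len(deltas) == 2 and np.std(deltas) > 0.0
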