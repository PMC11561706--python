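"""Point-estimate aging clocks and their comparison.

The de novo clock is a Lasso-penalized linear regression of age on beta
values, with the regularization strength chosen by 5-fold cross-validated
mean squared error — the construction used by most published methylation
clocks (typically ElasticNet; Lasso is its single-hyperparameter
equivalent). Beta values are not standardized before fitting: they already
share the [0, 1] scale.

`compare_model_families` exposes the model-choice component of epistemic
uncertainty: several regressor families tuned on one training set disagree
in their rejuvenation deltas on a time course even when their test metrics
look acceptable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neighbors import KNeighborsRegressor

from .dataset import MethylationDataset

ALPHA_GRID_SIZE = 100
ALPHA_GRID_DECADES = 3.0


@dataclass
class AgePrediction:
    """One sample's predicted age; ``variance`` is set only by models that
    estimate their own uncertainty (the GPR clock)."""

    sample_id: str
    predicted_age: float
    variance: float | None = None
    group: object | None = None

    def __post_init__(self) -> None:
        if self.variance is not None and self.variance < 0:
            raise ValueError("prediction variance must be >= 0")


@dataclass
class Metrics:
    """Regression performance summary: MAE, MedAE, R², Pearson r (+p)."""

    mae: float
    medae: float
    r2: float
    pearson_r: float
    pearson_p: float
    n: int
    constant_prediction: bool = False

    def to_dict(self) -> dict:
        return {
            "mae": self.mae,
            "medae": self.medae,
            "r2": self.r2,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "n": self.n,
            "constant_prediction": self.constant_prediction,
        }


@dataclass
class LinearClock:
    """Sparse linear clock: nonzero coefficients keyed by CpG id, plus the
    intercept and CV metadata."""

    coefficients: dict[str, float]
    intercept: float
    alpha: float
    cv_folds: int
    age_unit: str = "years"
    tissue: str | None = None
    n_train: int = 0
    seed: int | None = None

    @property
    def support(self) -> list[str]:
        return list(self.coefficients)

    def to_files(self, coef_path, header_path) -> None:
        table = pd.DataFrame(
            {"cpg_id": list(self.coefficients), "weight": list(self.coefficients.values())}
        )
        # %.17g round-trips IEEE doubles exactly
        table.to_csv(coef_path, sep="\t", index=False, float_format="%.17g")
        Path(header_path).write_text(json.dumps({
            "intercept": self.intercept, "alpha": self.alpha, "cv_folds": self.cv_folds,
            "age_unit": self.age_unit, "tissue": self.tissue, "n_train": self.n_train,
            "seed": self.seed,
        }, sort_keys=True))

    @classmethod
    def from_files(cls, coef_path, header_path) -> "LinearClock":
        table = pd.read_csv(coef_path, sep="\t", float_precision="round_trip")
        header = json.loads(Path(header_path).read_text())
        return cls(
            coefficients=dict(zip(table["cpg_id"].astype(str), table["weight"].astype(float))),
            intercept=float(header["intercept"]),
            alpha=float(header["alpha"]),
            cv_folds=int(header["cv_folds"]),
            age_unit=header.get("age_unit", "years"),
            tissue=header.get("tissue"),
            n_train=int(header.get("n_train", 0)),
            seed=header.get("seed"),
        )


def default_alpha_grid(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """100 log-spaced alphas from alpha_max (smallest alpha giving an empty
    support for centered data) down three decades."""
    n = X.shape[0]
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    alpha_max = np.max(np.abs(xc.T @ yc)) / n
    if alpha_max <= 0:
        alpha_max = 1.0
    return np.logspace(np.log10(alpha_max), np.log10(alpha_max) - ALPHA_GRID_DECADES,
                       ALPHA_GRID_SIZE)


def fit_lasso_clock(train: MethylationDataset, folds: int = 5, seed: int = 0,
                    alpha_grid=None, max_iter: int = 20000) -> LinearClock:
    """Fit a Lasso clock, selecting alpha by k-fold cross-validated MSE and
    refitting on the full training set at the chosen alpha."""
    ages = train.require_age()
    y = ages.to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("training ages are constant; cannot fit a clock")
    if train.n_samples < folds:
        raise ValueError(f"need at least folds={folds} samples, got {train.n_samples}")
    X = train.beta.to_numpy(dtype=float)
    if alpha_grid is None:
        alpha_grid = default_alpha_grid(X, y)
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    model = LassoCV(alphas=alpha_grid, cv=cv, max_iter=max_iter)
    model.fit(X, y)
    coef = {
        cpg: float(w)
        for cpg, w in zip(train.cpg_ids, model.coef_)
        if w != 0.0
    }
    return LinearClock(
        coefficients=coef,
        intercept=float(model.intercept_),
        alpha=float(model.alpha_),
        cv_folds=folds,
        age_unit=train.age_unit,
        tissue=train.tissue,
        n_train=train.n_samples,
        seed=seed,
    )


def apply_clock(clock: LinearClock, data: MethylationDataset) -> list[AgePrediction]:
    """μ = intercept + Σ w_i · beta_i per sample (no variance attached)."""
    missing = [c for c in clock.support if c not in data.beta.columns]
    if missing:
        raise KeyError(
            f"{len(missing)} clock CpGs absent from the dataset: {missing[:10]}"
        )
    if clock.support:
        weights = np.array([clock.coefficients[c] for c in clock.support])
        mu = clock.intercept + data.beta[clock.support].to_numpy() @ weights
    else:
        mu = np.full(data.n_samples, clock.intercept)
    groups = data.group if data.group is not None else pd.Series(
        [None] * data.n_samples, index=data.beta.index
    )
    return [
        AgePrediction(sample_id=s, predicted_age=float(m), group=groups.loc[s])
        for s, m in zip(data.sample_ids, mu)
    ]


def predictions_to_array(predictions: list[AgePrediction]) -> np.ndarray:
    return np.array([p.predicted_age for p in predictions])


def regression_metrics(y_true, y_pred) -> Metrics:
    """MAE, MedAE, R² = 1 − SS_res/SS_tot, and Pearson r with two-sided p.

    A constant prediction vector leaves Pearson r undefined: it is reported
    as NaN with ``constant_prediction=True`` while the other metrics stand.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D and equal length")
    if y_true.size < 2:
        raise ValueError("need at least two observations")
    err = y_pred - y_true
    ss_res = float((err**2).sum())
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    constant = bool(np.ptp(y_pred) == 0)
    if constant:
        r, p = np.nan, np.nan
    else:
        r, p = stats.pearsonr(y_true, y_pred)
    return Metrics(
        mae=float(np.mean(np.abs(err))),
        medae=float(np.median(np.abs(err))),
        r2=float(r2),
        pearson_r=float(r),
        pearson_p=float(p),
        n=y_true.size,
        constant_prediction=constant,
    )


def rejuvenation_delta(predictions: list[AgePrediction], t0, t1) -> float:
    """mean(predicted age | group == t1) − mean(… | group == t0); negative
    values read as rejuvenation."""
    mu0 = [p.predicted_age for p in predictions if p.group == t0]
    mu1 = [p.predicted_age for p in predictions if p.group == t1]
    if not mu0 or not mu1:
        missing = [t for t, m in ((t0, mu0), (t1, mu1)) if not m]
        raise ValueError(f"no predictions for group(s): {missing}")
    return float(np.mean(mu1) - np.mean(mu0))


# -- pluggable regressor families ----------------------------------------


@dataclass
class FamilySpec:
    """A regressor family: an estimator factory plus its grid-search space.
    Any object with fit(X, y)/predict(X) can participate."""

    make: Callable[[], object]
    param_grid: dict = field(default_factory=dict)


def builtin_families() -> dict[str, FamilySpec]:
    """The two built-in families: penalized linear and k-NN. Other families
    (forests, SVR, boosting) plug in through the same contract."""
    return {
        "lasso": FamilySpec(
            make=lambda: Lasso(max_iter=20000),
            param_grid={"alpha": np.logspace(-4, 1, 11).tolist()},
        ),
        "knn": FamilySpec(
            make=lambda: KNeighborsRegressor(),
            param_grid={"n_neighbors": [1, 2, 3, 5, 7, 10]},
        ),
    }


@dataclass
class FamilyResult:
    name: str
    test_metrics: Metrics | None = None
    delta: float | None = None
    best_params: dict | None = None
    failed: bool = False
    error: str | None = None

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "test_metrics": None if self.test_metrics is None else self.test_metrics.to_dict(),
            "delta": self.delta,
            "best_params": self.best_params,
            "failed": self.failed,
            "error": self.error,
        }


def compare_model_families(train: MethylationDataset, test: MethylationDataset,
                           course: MethylationDataset | None = None,
                           families: dict[str, FamilySpec] | None = None,
                           t0=None, t1=None, folds: int = 5,
                           seed: int = 0) -> dict[str, FamilyResult]:
    """Tune each family by grid-search CV (MSE) on ``train``, score it on
    ``test``, and — when a time course with group labels is given — report
    its rejuvenation delta between labels ``t0`` and ``t1``.

    A family that fails to fit is recorded as failed, never fatal.
    """
    families = families if families is not None else builtin_families()
    y_train = train.require_age().to_numpy(dtype=float)
    y_test = test.require_age().to_numpy(dtype=float)
    X_train = train.beta.to_numpy(dtype=float)
    X_test = test.beta[train.cpg_ids].to_numpy(dtype=float)
    X_course = None
    if course is not None:
        if course.group is None:
            raise ValueError("course dataset lacks group labels")
        X_course = course.beta[train.cpg_ids].to_numpy(dtype=float)
        labels = course.group
        if t0 is None or t1 is None:
            ordered = sorted(labels.unique())
            t0 = ordered[0] if t0 is None else t0
            t1 = ordered[-1] if t1 is None else t1
        for t in (t0, t1):
            if t not in set(labels):
                raise ValueError(f"course has no samples with group label {t!r}")

    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    results: dict[str, FamilyResult] = {}
    for name, spec in families.items():
        try:
            if spec.param_grid:
                search = GridSearchCV(spec.make(), spec.param_grid, cv=cv,
                                      scoring="neg_mean_squared_error")
                search.fit(X_train, y_train)
                best, best_params = search.best_estimator_, dict(search.best_params_)
            else:
                # plain fit/predict contract; no sklearn cloning required
                best = spec.make()
                best.fit(X_train, y_train)
                best_params = {}
            metrics = regression_metrics(y_test, best.predict(X_test))
            delta = None
            if X_course is not None:
                mu = best.predict(X_course)
                preds = [
                    AgePrediction(sample_id=s, predicted_age=float(m), group=g)
                    for s, m, g in zip(course.sample_ids, mu, labels)
                ]
                delta = rejuvenation_delta(preds, t0, t1)
            results[name] = FamilyResult(name=name, test_metrics=metrics, delta=delta,
                                         best_params=best_params)
        except Exception as exc:  # a family's failure must not kill the comparison
            results[name] = FamilyResult(name=name, failed=True, error=str(exc))
    return results
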