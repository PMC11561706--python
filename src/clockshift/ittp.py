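"""The Inverse Train-Test Procedure (ITTP).

ITTP probes whether two datasets are *interchangeable* under a model family:
model 1 is trained on the labeled training set and predicts the second
dataset; model 2 is then trained on the second dataset's features with those
predictions as targets, and asked to recover the original training ages. If
the datasets carry the same age-encoding structure, model 2 succeeds; a
large dataset shift makes the intermediary predictions uninformative and
step 2 fails.

Case 1 (verifiable): the second dataset has chronological ages, so step-1
metrics are computable too. Case 2 (unverifiable, e.g. a reprogramming
course): only step-2 metrics exist, and the verdict rests on them alone.
Both steps use the same model family — a Lasso clock with CV-chosen alpha —
which is required for the comparison to be meaningful.

The default verdict threshold is R² > 0.25 at each computable step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clocks import (LinearClock, Metrics, apply_clock, fit_lasso_clock,
                     predictions_to_array, regression_metrics)
from .dataset import MethylationDataset
from .io import intersect_cpgs

DEFAULT_R2_THRESHOLD = 0.25

INTERCHANGEABLE = "interchangeable"
NOT_INTERCHANGEABLE = "not_interchangeable"
ONE_WAY = "one_way"

#: step-1/step-2 R² differing by more than this is flagged (verdict unchanged)
DISCREPANCY_FLAG_GAP = 0.3


def derive_verdict(case: int, step1_r2: float | None, step2_r2: float | None,
                   threshold: float = DEFAULT_R2_THRESHOLD) -> str:
    """Pure verdict rule from the recorded step R² values.

    Case 1: interchangeable iff both steps exceed the threshold; ``one_way``
    when only step 2 passes (the testing dataset still carries the
    information needed to predict the training ages); otherwise not
    interchangeable — including the asymmetric step-1-pass/step-2-fail
    outcome, by strict conjunction. Case 2: step 2 alone decides.
    """
    step2_ok = step2_r2 is not None and np.isfinite(step2_r2) and step2_r2 > threshold
    if case == 2:
        return INTERCHANGEABLE if step2_ok else NOT_INTERCHANGEABLE
    step1_ok = step1_r2 is not None and np.isfinite(step1_r2) and step1_r2 > threshold
    if step1_ok and step2_ok:
        return INTERCHANGEABLE
    if step2_ok and not step1_ok:
        return ONE_WAY
    return NOT_INTERCHANGEABLE


@dataclass
class ITTPReport:
    case: int
    step1_metrics: Metrics | None
    step2_metrics: Metrics | None
    model1: LinearClock | None
    model2: LinearClock | None
    threshold: float
    verdict: str
    reason: str | None = None
    discrepancy_flag: bool = False

    def to_dict(self) -> dict:
        return {
            "case": self.case,
            "threshold": self.threshold,
            "verdict": self.verdict,
            "reason": self.reason,
            "discrepancy_flag": self.discrepancy_flag,
            "step1_metrics": None if self.step1_metrics is None else self.step1_metrics.to_dict(),
            "step2_metrics": None if self.step2_metrics is None else self.step2_metrics.to_dict(),
            "model1_support_size": None if self.model1 is None else len(self.model1.support),
            "model2_support_size": None if self.model2 is None else len(self.model2.support),
        }


def _with_targets(data: MethylationDataset, targets: np.ndarray) -> MethylationDataset:
    return MethylationDataset(
        beta=data.beta.copy(),
        age=pd.Series(targets, index=data.beta.index),
        group=None if data.group is None else data.group.copy(),
        tissue=data.tissue,
        age_unit=data.age_unit,
    )


def ittp_case1(train: MethylationDataset, test: MethylationDataset, seed: int = 0,
               threshold: float = DEFAULT_R2_THRESHOLD, folds: int = 5) -> ITTPReport:
    """Verifiable ITTP: both datasets carry chronological ages.

    Step 1: fit model 1 on (X_tr, Y_tr), predict Ŷ_te, score against Y_te.
    Step 2: fit model 2 on (X_te, Ŷ_te) — the predictions, at full floating
    precision — and score its predictions for X_tr against Y_tr.
    """
    train.require_age()
    test.require_age()
    train, test = intersect_cpgs(train, test)
    model1 = fit_lasso_clock(train, folds=folds, seed=seed)
    y_hat_te = predictions_to_array(apply_clock(model1, test))
    step1 = regression_metrics(test.age.to_numpy(dtype=float), y_hat_te)
    if np.ptp(y_hat_te) == 0:
        return ITTPReport(case=1, step1_metrics=step1, step2_metrics=None,
                          model1=model1, model2=None, threshold=threshold,
                          verdict=NOT_INTERCHANGEABLE,
                          reason="degenerate intermediary predictions")
    model2 = fit_lasso_clock(_with_targets(test, y_hat_te), folds=folds, seed=seed)
    y_hat_tr = predictions_to_array(apply_clock(model2, train))
    step2 = regression_metrics(train.age.to_numpy(dtype=float), y_hat_tr)
    verdict = derive_verdict(1, step1.r2, step2.r2, threshold)
    flag = abs(step1.r2 - step2.r2) > DISCREPANCY_FLAG_GAP
    return ITTPReport(case=1, step1_metrics=step1, step2_metrics=step2,
                      model1=model1, model2=model2, threshold=threshold,
                      verdict=verdict, discrepancy_flag=flag)


def ittp_case2(train: MethylationDataset, unlabeled: MethylationDataset, seed: int = 0,
               threshold: float = DEFAULT_R2_THRESHOLD, folds: int = 5) -> ITTPReport:
    """Unverifiable ITTP: the second dataset has no ground-truth ages.

    Step-1 metrics cannot exist; the verdict rests on whether model 2 —
    trained on (X_rep, Ŷ_rep) — recovers the training ages.
    """
    train.require_age()
    train, unlabeled = intersect_cpgs(train, unlabeled)
    model1 = fit_lasso_clock(train, folds=folds, seed=seed)
    y_hat_rep = predictions_to_array(apply_clock(model1, unlabeled))
    if np.ptp(y_hat_rep) == 0:
        return ITTPReport(case=2, step1_metrics=None, step2_metrics=None,
                          model1=model1, model2=None, threshold=threshold,
                          verdict=NOT_INTERCHANGEABLE,
                          reason="degenerate intermediary predictions")
    model2 = fit_lasso_clock(_with_targets(unlabeled, y_hat_rep), folds=folds, seed=seed)
    y_hat_tr = predictions_to_array(apply_clock(model2, train))
    step2 = regression_metrics(train.age.to_numpy(dtype=float), y_hat_tr)
    verdict = derive_verdict(2, None, step2.r2, threshold)
    return ITTPReport(case=2, step1_metrics=None, step2_metrics=step2,
                      model1=model1, model2=model2, threshold=threshold,
                      verdict=verdict)
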