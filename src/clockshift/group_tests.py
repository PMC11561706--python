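"""Significance tests for differences between prediction groups.

Uncertainty-aware clock predictions come with per-sample variances, which
these tests propagate instead of discarding:

* ``z_test_two_predictions`` — two single predictions with known variances;
* ``meta_regression_groups`` — a random-effects meta-regression of the
  predicted ages on an intercept plus a binary group indicator, weighting
  each observation by 1/(v_i + τ²) with the between-sample heterogeneity τ²
  estimated by REML (Fisher scoring, projected to τ² ≥ 0); the effect is the
  indicator coefficient with Wald (normal) inference by default, or the
  Knapp–Hartung t correction behind a flag;
* ``mann_whitney`` — the rank test used for point-estimate clocks that carry
  no variances.

Effect sign convention: group B − group A throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .clocks import AgePrediction

REML_TOL = 1e-8
REML_MAX_ITER = 100
EXACT_MWW_MAX_N = 8


@dataclass
class GroupComparison:
    """Effect (B − A), its standard error, test statistic and two-sided p."""

    effect: float
    se: float
    statistic: float
    p_value: float
    method: str  # "z" | "meta_reml" | "mww"
    tau2: float | None = None
    n_a: int = 1
    n_b: int = 1
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "effect": self.effect,
            "se": self.se,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "method": self.method,
            "tau2": self.tau2,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "degenerate": self.degenerate,
        }


def _require_variance(pred: AgePrediction) -> float:
    if pred.variance is None:
        raise ValueError(f"prediction {pred.sample_id!r} carries no variance")
    return pred.variance


def z_test_two_predictions(p1: AgePrediction, p2: AgePrediction) -> GroupComparison:
    """z = (μ2 − μ1)/sqrt(v1 + v2) with a two-sided normal p-value."""
    v1, v2 = _require_variance(p1), _require_variance(p2)
    effect = p2.predicted_age - p1.predicted_age
    pooled = v1 + v2
    if pooled == 0:
        if effect == 0:
            return GroupComparison(effect=0.0, se=0.0, statistic=0.0, p_value=1.0,
                                   method="z", degenerate=True)
        return GroupComparison(effect=effect, se=0.0, statistic=np.inf * np.sign(effect),
                               p_value=0.0, method="z", degenerate=True)
    se = float(np.sqrt(pooled))
    z = effect / se
    p = 2.0 * stats.norm.sf(abs(z))
    return GroupComparison(effect=float(effect), se=se, statistic=float(z),
                           p_value=float(p), method="z")


def _reml_tau2(y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    """REML τ² by Fisher scoring with non-negativity projection.

    Score and expected information use P = W − WX(XᵀWX)⁻¹XᵀW with
    W = diag(1/(v_i + τ²)): U = ½(yᵀP²y − tr P), I = ½ tr(P²).
    """
    tau2 = max(float(np.var(y, ddof=1) - v.mean()), 0.0)  # method-of-moments start
    step = 0.0
    for _ in range(REML_MAX_ITER):
        w = 1.0 / (v + tau2)
        W = np.diag(w)
        XtWX_inv = np.linalg.inv(X.T @ (w[:, None] * X))
        P = W - (w[:, None] * X) @ XtWX_inv @ (X.T * w[None, :])
        Py = P @ y
        score = 0.5 * (Py @ Py - np.trace(P))
        info = 0.5 * np.sum(P * P)
        if info <= 0:
            break
        step = score / info
        new = max(tau2 + step, 0.0)
        if abs(new - tau2) < REML_TOL:
            return new
        tau2 = new
    if abs(step) > 1e-3:
        raise RuntimeError(
            f"REML did not converge in {REML_MAX_ITER} iterations (last step {step:.3g})"
        )
    return tau2


def meta_regression_groups(group_a: list[AgePrediction], group_b: list[AgePrediction],
                           knapp_hartung: bool = False) -> GroupComparison:
    """Random-effects meta-regression of predicted ages on [1, 1{B}].

    Every observation contributes its own variance v_i; the heterogeneity τ²
    is REML-estimated and the group effect is the indicator coefficient.
    With one observation per group the τ² estimate is unidentified: it is
    pinned to 0 with a warning, which reduces the test exactly to
    :func:`z_test_two_predictions`.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    if len(group_a) == 1 and len(group_b) == 1:
        warnings.warn("one observation per group: tau2 pinned to 0, using the z-test",
                      stacklevel=2)
        result = z_test_two_predictions(group_a[0], group_b[0])
        return GroupComparison(effect=result.effect, se=result.se,
                               statistic=result.statistic, p_value=result.p_value,
                               method="meta_reml", tau2=0.0,
                               degenerate=result.degenerate)

    y = np.array([p.predicted_age for p in group_a + group_b], dtype=float)
    v = np.array([_require_variance(p) for p in group_a + group_b], dtype=float)
    indicator = np.array([0.0] * len(group_a) + [1.0] * len(group_b))
    X = np.column_stack([np.ones_like(indicator), indicator])

    tau2 = _reml_tau2(y, v, X)
    w = 1.0 / (v + tau2)
    XtWX_inv = np.linalg.inv(X.T @ (w[:, None] * X))
    beta = XtWX_inv @ (X.T @ (w * y))
    effect = float(beta[1])
    var_beta = XtWX_inv
    if knapp_hartung:
        resid = y - X @ beta
        k, p_dim = y.size, X.shape[1]
        scale = float((w * resid**2).sum() / (k - p_dim))
        var_beta = var_beta * max(scale, 0.0)
        se = float(np.sqrt(var_beta[1, 1]))
        t = effect / se if se > 0 else np.inf * np.sign(effect)
        p = 2.0 * stats.t.sf(abs(t), df=k - p_dim)
        stat = t
    else:
        se = float(np.sqrt(var_beta[1, 1]))
        stat = effect / se if se > 0 else np.inf * np.sign(effect)
        p = 2.0 * stats.norm.sf(abs(stat))
    return GroupComparison(effect=effect, se=se, statistic=float(stat),
                           p_value=float(p), method="meta_reml", tau2=float(tau2),
                           n_a=len(group_a), n_b=len(group_b))


def mann_whitney(group_a, group_b) -> GroupComparison:
    """Two-sided Mann–Whitney U: exact p for min(n, m) ≤ 8 without ties,
    normal approximation with tie correction otherwise."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= EXACT_MWW_MAX_N and not has_ties) else "asymptotic"
    result = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    effect = float(np.median(b) - np.median(a))
    return GroupComparison(effect=effect, se=float("nan"),
                           statistic=float(result.statistic),
                           p_value=float(result.pvalue), method="mww",
                           n_a=a.size, n_b=b.size)
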