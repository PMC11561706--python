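"""Gaussian-process aging clock with a per-prediction uncertainty estimate.

Model: ages are a latent function of the CpG beta vector plus white noise,

    y_i = f(x_i) + ε_i,   ε_i ~ N(0, σ²),   f ~ GP(0, k),

with the RBF covariance k(x_i, x_j) = s²·exp(−‖x_i − x_j‖² / (2 l²)). The
marginal of the (centered) training targets is y ~ N(0, Σ + σ²I) with
Σ_ij = k(x_i, x_j); hyperparameters (s², l, σ²) maximize this exact log
marginal likelihood via multi-start L-BFGS-B in log-parameter space. The
posterior at a query x* is Gaussian with

    μ* = k*ᵀ (Σ + σ²I)⁻¹ y,
    (σ*)² = k(x*, x*) − k*ᵀ (Σ + σ²I)⁻¹ k*,

where k* stacks k(x_i, x*). The predictive variance is *latent-only* (it
excludes σ²), so for a query far from every training point it climbs to the
ceiling (σ*)² → s² — the model's maximal admission of ignorance about an
out-of-distribution sample — while μ* falls back to the training-mean age.
Credible intervals are μ ± 2 posterior SDs.

The zero-mean GP is realized by centering targets on the training mean and
adding it back at prediction time; ages are positive, so a raw zero mean
would bias every estimate. Features are not rescaled: beta values already
share the [0, 1] scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from .clocks import AgePrediction
from .dataset import MethylationDataset

logger = logging.getLogger(__name__)

JITTER_START = 1e-10
JITTER_MAX = 1e-6

DEFAULT_BOUNDS = {
    "s2": (1e-2, 1e5),
    "length_scale": (1e-2, 1e3),
    "noise": (1e-4, 1e4),
}

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class KernelParams:
    """RBF + white-noise kernel hyperparameters, all strictly positive.

    ``s2``: signal variance (age-units²), also the OOD variance ceiling;
    ``length_scale``: RBF length scale in feature-space distance;
    ``noise``: observation-noise variance σ² (age-units²).
    """

    s2: float
    length_scale: float
    noise: float

    def __post_init__(self) -> None:
        if min(self.s2, self.length_scale, self.noise) <= 0:
            raise ValueError("kernel hyperparameters must be strictly positive")


@dataclass(frozen=True)
class CredibleInterval:
    """Per-prediction Bayesian interval: μ ± multiplier·sqrt(variance)."""

    lower: float
    upper: float
    sd_multiplier: float = 2.0

    @classmethod
    def from_moments(cls, mu: float, variance: float,
                     sd_multiplier: float = 2.0) -> "CredibleInterval":
        half = sd_multiplier * float(np.sqrt(variance))
        return cls(lower=mu - half, upper=mu + half, sd_multiplier=sd_multiplier)

    @property
    def width(self) -> float:
        return self.upper - self.lower


def rbf_kernel(xi: np.ndarray, xj: np.ndarray, params: KernelParams) -> np.ndarray:
    """Gram matrix of the RBF kernel s²·exp(−‖xi−xj‖²/(2l²)); symmetric with
    entries in (0, s²]."""
    xi = np.atleast_2d(np.asarray(xi, dtype=float))
    xj = np.atleast_2d(np.asarray(xj, dtype=float))
    if xi.shape[1] != xj.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: {xi.shape[1]} vs {xj.shape[1]}"
        )
    d2 = cdist(xi, xj, metric="sqeuclidean")
    return params.s2 * np.exp(-d2 / (2.0 * params.length_scale**2))


def _chol_with_jitter(K: np.ndarray):
    """Lower Cholesky of K, escalating diagonal jitter ×10 from 1e-10 to 1e-6."""
    jitter = 0.0
    while True:
        try:
            return cholesky(K + jitter * np.eye(K.shape[0]), lower=True), jitter
        except np.linalg.LinAlgError:
            jitter = JITTER_START if jitter == 0.0 else jitter * 10.0
            if jitter > JITTER_MAX:
                raise np.linalg.LinAlgError(
                    f"covariance not positive definite even at jitter {JITTER_MAX}"
                )


def log_marginal_likelihood(X: np.ndarray, y_centered: np.ndarray,
                            params: KernelParams) -> float:
    """log N(y_centered; 0, Σ + σ²I) via a jittered Cholesky factorization."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y_centered, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y_centered are misaligned")
    K = rbf_kernel(X, X, params) + params.noise * np.eye(X.shape[0])
    L, _ = _chol_with_jitter(K)
    alpha = cho_solve((L, True), y)
    return float(
        -0.5 * y @ alpha - np.log(np.diag(L)).sum() - 0.5 * y.size * LOG_2PI
    )


def _nll_and_grad(theta: np.ndarray, d2: np.ndarray, y: np.ndarray):
    """Negative LML and its gradient in theta = (log s², log l, log σ²)."""
    s2, ell, noise = np.exp(theta)
    n = y.size
    K_rbf = s2 * np.exp(-d2 / (2.0 * ell * ell))
    K = K_rbf + noise * np.eye(n)
    try:
        L, _ = _chol_with_jitter(K)
    except np.linalg.LinAlgError:
        return np.inf, np.zeros(3)
    alpha = cho_solve((L, True), y)
    lml = -0.5 * y @ alpha - np.log(np.diag(L)).sum() - 0.5 * n * LOG_2PI
    K_inv = cho_solve((L, True), np.eye(n))
    A = np.outer(alpha, alpha) - K_inv  # dLML/dK = A/2
    grad = np.array([
        0.5 * np.sum(A * K_rbf),                     # ∂K/∂log s² = K_rbf
        0.5 * np.sum(A * (K_rbf * d2 / ell**2)),     # ∂K/∂log l
        0.5 * noise * np.trace(A),                   # ∂K/∂log σ²
    ])
    return -float(lml), -grad


@dataclass
class GPRClock:
    """A fitted GP age clock: training features, centered targets, kernel
    hyperparameters, and the cached Cholesky solve used by every prediction."""

    X: np.ndarray
    y_centered: np.ndarray
    y_offset: float
    params: KernelParams
    age_unit: str = "years"
    cpgs: list[str] | None = None
    log_marginal_likelihood: float = 0.0
    restarts: int = 0
    seed: int | None = None
    jitter: float = field(default=0.0)
    _L: np.ndarray = field(default=None, repr=False)
    _alpha: np.ndarray = field(default=None, repr=False)
    clamped_predictions: int = field(default=0, repr=False)

    def __post_init__(self) -> None:
        if self._L is None:
            K = rbf_kernel(self.X, self.X, self.params) + self.params.noise * np.eye(
                self.X.shape[0]
            )
            self._L, self.jitter = _chol_with_jitter(K)
            self._alpha = cho_solve((self._L, True), self.y_centered)

    @classmethod
    def fit(cls, X, y, bounds: dict | None = None, restarts: int = 5,
            seed: int = 0, age_unit: str = "years",
            cpgs: list[str] | None = None) -> "GPRClock":
        """Maximize the log marginal likelihood over (s², l, σ²).

        Multi-start local optimization in log-parameter space: one heuristic
        start (s² = var(y), l = median pairwise distance, σ² = var(y)/10)
        plus ``restarts`` log-uniform draws within the bounds, seeded for
        determinism. The best converged restart is kept.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y are misaligned")
        if X.shape[0] < 3:
            raise ValueError("need at least 3 training samples")
        bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
        log_bounds = [np.log(bounds[k]) for k in ("s2", "length_scale", "noise")]
        y_offset = float(y.mean())
        yc = y - y_offset
        d2 = cdist(X, X, metric="sqeuclidean")

        var_y = max(float(yc.var()), 1e-8)
        off_diag = d2[np.triu_indices_from(d2, k=1)]
        med = float(np.sqrt(np.median(off_diag))) if off_diag.size else 1.0
        heuristic = np.log(np.array([
            np.clip(var_y, *bounds["s2"]),
            np.clip(max(med, 1e-2), *bounds["length_scale"]),
            np.clip(var_y / 10.0, *bounds["noise"]),
        ]))
        rng = np.random.default_rng(seed)
        starts = [heuristic] + [
            np.array([rng.uniform(lo, hi) for lo, hi in log_bounds])
            for _ in range(restarts)
        ]

        best = None
        failures = []
        for theta0 in starts:
            result = minimize(_nll_and_grad, theta0, args=(d2, yc), jac=True,
                              method="L-BFGS-B", bounds=log_bounds)
            if not np.isfinite(result.fun):
                failures.append(str(result.message))
                continue
            if best is None or result.fun < best.fun:
                best = result
        if best is None:
            raise RuntimeError(f"all optimizer restarts failed: {failures}")
        s2, ell, noise = np.exp(best.x)
        params = KernelParams(s2=float(s2), length_scale=float(ell), noise=float(noise))
        return cls(X=X, y_centered=yc, y_offset=y_offset, params=params,
                   age_unit=age_unit, cpgs=cpgs,
                   log_marginal_likelihood=float(-best.fun),
                   restarts=restarts, seed=seed)

    def predict(self, X_new) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean (with the training-mean offset added back) and
        latent predictive variance, clamped at ≥ 0 (clamps are counted)."""
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.X.shape[1]:
            raise ValueError(
                f"feature dimension mismatch: trained on {self.X.shape[1]}, "
                f"got {X_new.shape[1]}"
            )
        k_star = rbf_kernel(self.X, X_new, self.params)  # n_train × n_new
        mu = self.y_offset + k_star.T @ self._alpha
        v = solve_triangular(self._L, k_star, lower=True)
        var = self.params.s2 - np.einsum("ij,ij->j", v, v)
        clamped = var < 0
        if clamped.any():
            self.clamped_predictions += int(clamped.sum())
            logger.warning("clamped %d negative predictive variances", clamped.sum())
            var = np.where(clamped, 0.0, var)
        return mu, var


def fit_gpr(train: MethylationDataset, cpgs: list[str] | None = None,
            bounds: dict | None = None, restarts: int = 5,
            seed: int = 0) -> GPRClock:
    """Fit the GP clock on a methylation dataset, optionally on a CpG panel."""
    ages = train.require_age()
    data = train.select_cpgs(cpgs) if cpgs is not None else train
    return GPRClock.fit(
        data.beta.to_numpy(dtype=float), ages.to_numpy(dtype=float),
        bounds=bounds, restarts=restarts, seed=seed,
        age_unit=train.age_unit, cpgs=data.cpg_ids,
    )


def predict_gpr(clock: GPRClock, data: MethylationDataset,
                sd_multiplier: float = 2.0,
                include_noise: bool = False,
                ) -> list[tuple[AgePrediction, CredibleInterval]]:
    """Predict a dataset: per-sample posterior mean, variance and credible
    interval. ``include_noise=True`` adds σ² for observation-level intervals
    (off by default: the latent variance is the epistemic signal and its
    ceiling is s²)."""
    X = data.beta[clock.cpgs].to_numpy(dtype=float) if clock.cpgs else data.beta.to_numpy()
    mu, var = clock.predict(X)
    if include_noise:
        var = var + clock.params.noise
    groups = data.group if data.group is not None else pd.Series(
        [None] * data.n_samples, index=data.beta.index
    )
    out = []
    for sample, m, v in zip(data.sample_ids, mu, var):
        pred = AgePrediction(sample_id=sample, predicted_age=float(m),
                             variance=float(v), group=groups.loc[sample])
        out.append((pred, CredibleInterval.from_moments(float(m), float(v), sd_multiplier)))
    return out
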