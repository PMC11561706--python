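"""Covariate-shift diagnostics between two methylation datasets.

A dataset pair is compared on an age-informative CpG panel: each CpG gets a
two-sided two-sample Kolmogorov–Smirnov test of the null that its beta-value
distributions are identical across the pair, p-values are Benjamini–Hochberg
adjusted, and a CpG is flagged shifted when the adjusted p falls below
q = 0.01. The headline summary is the rejected fraction; a PCA embedding of
the merged pair visualizes the same shift geometrically.

The KS p-value uses the exact method when min(n, m) ≤ 25 and the asymptotic
distribution otherwise — the test is known to be under-powered at small n,
so PCA should be read alongside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.proportion import proportion_confint

from .dataset import MethylationDataset

EXACT_KS_MAX_N = 25


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Sort ascending, set p'_(i) = min_{j>=i} (p_(j) · m / j) capped at 1, and
    map back to the input order. Adjusted values are >= the raw ones and
    invariant to input permutation.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    np.clip(adjusted, None, 1.0, out=adjusted)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


@dataclass
class PCAEmbedding:
    """Two-dimensional PCA scores of a merged dataset pair."""

    scores: pd.DataFrame  # columns PC1..PCk plus 'dataset'
    explained_variance_ratio: np.ndarray

    def centroid_distance(self) -> float:
        pcs = [c for c in self.scores.columns if c.startswith("PC")]
        groups = self.scores.groupby("dataset")[pcs].mean()
        if len(groups) != 2:
            raise ValueError("embedding does not contain exactly two datasets")
        return float(np.linalg.norm(groups.iloc[0] - groups.iloc[1]))


@dataclass
class ShiftReport:
    """Per-CpG KS results plus the rejected-fraction summary for a pair."""

    per_cpg: pd.DataFrame  # index cpg; columns ks_statistic, p_value, adjusted_p, rejected
    q: float
    n_a: int
    n_b: int
    rejected_fraction: float = field(init=False)
    rejected_fraction_ci: tuple[float, float] = field(init=False)
    pca: PCAEmbedding | None = None

    def __post_init__(self) -> None:
        n = len(self.per_cpg)
        k = int(self.per_cpg["rejected"].sum())
        self.rejected_fraction = k / n if n else 0.0
        # Wilson interval: an added honesty measure around the bare percentage
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson") if n else (0.0, 0.0)
        self.rejected_fraction_ci = (float(lo), float(hi))

    @property
    def cpgs_tested(self) -> list[str]:
        return list(self.per_cpg.index)

    def to_dict(self) -> dict:
        return {
            "q": self.q,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "n_cpgs_tested": len(self.per_cpg),
            "rejected_fraction": self.rejected_fraction,
            "rejected_fraction_wilson95": list(self.rejected_fraction_ci),
            "per_cpg": {
                cpg: {
                    "ks_statistic": float(row.ks_statistic),
                    "p_value": float(row.p_value),
                    "adjusted_p": float(row.adjusted_p),
                    "rejected": bool(row.rejected),
                }
                for cpg, row in self.per_cpg.iterrows()
            },
        }


def select_age_correlated_cpgs(dataset: MethylationDataset, k: int) -> list[str]:
    """The k CpGs most correlated (|Pearson r|) with chronological age.

    Zero-variance CpGs are excluded before ranking; ties break by CpG id.
    This is the surrogate panel used when no published clock CpG set applies
    — any accurate age-predicting subset serves the diagnostics equally.
    """
    ages = dataset.require_age()
    if k < 1:
        raise ValueError("k must be >= 1")
    beta = dataset.beta.to_numpy()
    usable = np.ptp(beta, axis=0) > 0  # exact: constant columns excluded
    if k > int(usable.sum()):
        raise ValueError(
            f"k={k} exceeds the {int(usable.sum())} CpGs with nonzero variance"
        )
    y = ages.to_numpy(dtype=float)
    yc = y - y.mean()
    xc = beta - beta.mean(axis=0)
    denominator = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / denominator
    table = pd.DataFrame({"cpg": dataset.cpg_ids, "abs_r": np.abs(r)})[usable]
    table = table.sort_values(["abs_r", "cpg"], ascending=[False, True], kind="stable")
    return table["cpg"].head(k).tolist()


def pca_embed(a: MethylationDataset, b: MethylationDataset,
              n_components: int = 2) -> PCAEmbedding:
    """PCA of the merged, column-mean-centered pair (no variance scaling —
    beta values share one scale). Zero-variance columns are dropped first."""
    common = [c for c in a.cpg_ids if c in set(b.cpg_ids)]
    if not common:
        raise ValueError("datasets share no CpGs")
    merged = np.vstack([a.beta[common].to_numpy(), b.beta[common].to_numpy()])
    if merged.shape[0] < n_components:
        raise ValueError("fewer samples than requested components")
    merged = merged[:, np.ptp(merged, axis=0) > 0]
    if merged.shape[1] < n_components:
        raise ValueError("fewer varying CpGs than requested components")
    model = PCA(n_components=n_components)
    scores = model.fit_transform(merged - merged.mean(axis=0))
    frame = pd.DataFrame(scores, columns=[f"PC{i + 1}" for i in range(n_components)])
    frame["dataset"] = ["a"] * a.n_samples + ["b"] * b.n_samples
    frame.index = a.sample_ids + b.sample_ids
    return PCAEmbedding(scores=frame,
                        explained_variance_ratio=model.explained_variance_ratio_)


def ks_shift_test(a: MethylationDataset, b: MethylationDataset, cpgs=None,
                  q: float = 0.01, with_pca: bool = False) -> ShiftReport:
    """Per-CpG two-sided two-sample KS test with BH correction at level q.

    ``cpgs=None`` tests every CpG shared by the pair (whole-matrix mode);
    normally a selected panel (e.g. from
    :func:`select_age_correlated_cpgs`) is passed.
    """
    if a.n_samples < 3 or b.n_samples < 3:
        raise ValueError("each dataset needs at least 3 samples for the KS test")
    if cpgs is None:
        cpgs = [c for c in a.cpg_ids if c in set(b.cpg_ids)]
    else:
        cpgs = list(cpgs)
        missing = [c for c in cpgs if c not in a.beta.columns or c not in b.beta.columns]
        if missing:
            raise KeyError(f"CpGs absent from one of the datasets: {missing[:10]}")
    if not cpgs:
        raise ValueError("no CpGs to test")
    method = "exact" if min(a.n_samples, b.n_samples) <= EXACT_KS_MAX_N else "asymp"
    stats_d = np.empty(len(cpgs))
    pvals = np.empty(len(cpgs))
    xa = a.beta[cpgs].to_numpy()
    xb = b.beta[cpgs].to_numpy()
    for i in range(len(cpgs)):
        res = stats.ks_2samp(xa[:, i], xb[:, i], alternative="two-sided", method=method)
        stats_d[i], pvals[i] = res.statistic, res.pvalue
    adjusted = bh_adjust(pvals)
    per_cpg = pd.DataFrame(
        {
            "ks_statistic": stats_d,
            "p_value": pvals,
            "adjusted_p": adjusted,
            "rejected": adjusted < q,
        },
        index=pd.Index(cpgs, name="cpg"),
    )
    pca = pca_embed(a, b) if with_pca else None
    return ShiftReport(per_cpg=per_cpg, q=q, n_a=a.n_samples, n_b=b.n_samples, pca=pca)
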