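"""End-to-end orchestration of the four uncertainty diagnostics.

``run_framework`` executes, on a training aging dataset and a query dataset
(whose ages may be unknown): CpG intersection → covariate-shift diagnostics
→ clock family comparison → ITTP (case chosen by query-age availability) →
GPR predictions with credible intervals → variance-aware group tests. Every
stage's outcome lands in one JSON-serializable report; a failed stage is
recorded and its dependents are skipped, never silently filled in.

One global seed fans out to per-stage seeds through a stable hash of the
stage name, so stages are individually reproducible and never share a
stream. Reports are byte-identical across runs of the same config.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from sklearn.linear_model import LinearRegression

from . import __version__
from .clocks import apply_clock, compare_model_families, fit_lasso_clock, regression_metrics
from .dataset import MethylationDataset
from .gpr import fit_gpr, predict_gpr
from .group_tests import mann_whitney, meta_regression_groups
from .io import intersect_cpgs, read_beta_matrix, split_train_test
from .ittp import ittp_case1, ittp_case2
from .shift import ks_shift_test, pca_embed, select_age_correlated_cpgs
from .synthetic import (ShiftSpec, SimulationConfig, simulate_aging_methylation,
                        simulate_anthropometric_cohorts, simulate_reprogramming_course)

SCHEMA_VERSION = 1


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 (stable across processes)."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def _age_available(dataset: MethylationDataset) -> bool:
    return dataset.age is not None and not dataset.age.isna().any()


@dataclass
class FrameworkReport:
    sections: dict

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.sections, indent=indent, sort_keys=True)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _load_datasets(config: dict, seed: int):
    data = config.get("data", {})
    if "simulate" in data:
        sim = dict(data["simulate"])
        query_spec = dict(sim.pop("query", {"kind": "split"}))
        kind = query_spec.pop("kind", "split")
        base = SimulationConfig(**{**sim, "seed": stage_seed(seed, "simulate")})
        if kind == "split":
            full = simulate_aging_methylation(base)
            train, query = split_train_test(
                full, query_spec.get("test_frac", 0.5), seed=stage_seed(seed, "split")
            )
        elif kind == "shift":
            from .synthetic import apply_covariate_shift

            train = simulate_aging_methylation(base)
            other = SimulationConfig(**{**sim, "seed": stage_seed(seed, "simulate-query")})
            spec = ShiftSpec(**query_spec)
            query = apply_covariate_shift(simulate_aging_methylation(other), spec,
                                          seed=stage_seed(seed, "shift-gen"))
        elif kind == "course":
            train = simulate_aging_methylation(base)
            query = simulate_reprogramming_course(
                base,
                days=query_spec.get("days", [0, 7, 14, 21, 28]),
                drift_per_day=query_spec.get("drift_per_day", 0.02),
                seed=stage_seed(seed, "course"),
                n_per_day=query_spec.get("n_per_day", 20),
            )
        else:
            raise ValueError(f"unknown simulated query kind {kind!r}")
        return train, query
    train = read_beta_matrix(data["train_beta"], data.get("train_meta"),
                             age_unit=data.get("unit", "years"))
    query = read_beta_matrix(data["query_beta"], data.get("query_meta"),
                             age_unit=data.get("unit", "years"))
    return train, query


def run_framework(config: dict) -> FrameworkReport:
    """Run all four diagnostics on the configured dataset pair."""
    seed = int(config.get("seed", 0))
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "provenance": {
            "package_version": __version__,
            "seed": seed,
            "config": config,
            "stage_seeds": {},
        },
    }
    seeds = report["provenance"]["stage_seeds"]

    def record_seed(stage: str) -> int:
        s = stage_seed(seed, stage)
        seeds[stage] = s
        return s

    try:
        train, query = _load_datasets(config, seed)
        train, query = intersect_cpgs(train, query)
        report["data"] = {
            "status": "ok",
            "n_train": train.n_samples,
            "n_query": query.n_samples,
            "n_cpgs": train.n_cpgs,
            "query_has_ages": _age_available(query),
            "age_unit": train.age_unit,
        }
    except Exception as exc:
        report["data"] = {"status": f"failed: {exc}"}
        for section in ("shift", "clock_comparison", "ittp", "gpr", "tests"):
            report[section] = {"status": "skipped: no data"}
        return FrameworkReport(sections=report)

    shift_cfg = config.get("shift", {})
    k = min(int(shift_cfg.get("top_k", 50)), train.n_cpgs)
    q = float(shift_cfg.get("q", 0.01))
    panel = None
    try:
        panel = select_age_correlated_cpgs(train, k)
        shift_report = ks_shift_test(train, query, panel, q=q)
        embedding = pca_embed(train.select_cpgs(panel), query.select_cpgs(panel))
        section = shift_report.to_dict()
        section["status"] = "ok"
        section["pca_explained_variance_ratio"] = [
            float(x) for x in embedding.explained_variance_ratio
        ]
        section["pca_centroid_distance"] = embedding.centroid_distance()
        report["shift"] = section
    except Exception as exc:
        report["shift"] = {"status": f"failed: {exc}"}

    course = query if (query.group is not None and query.group.nunique() > 1) else None
    try:
        fit_set, eval_set = split_train_test(train, 0.25, seed=record_seed("clock-split"))
        families = compare_model_families(fit_set, eval_set, course=course,
                                          seed=record_seed("clock-compare"))
        report["clock_comparison"] = {
            "status": "ok",
            "families": {name: res.to_dict() for name, res in families.items()},
        }
    except Exception as exc:
        report["clock_comparison"] = {"status": f"failed: {exc}"}

    ittp_cfg = config.get("ittp", {})
    threshold = float(ittp_cfg.get("threshold", 0.25))
    try:
        if _age_available(query):
            ittp_report = ittp_case1(train, query, seed=record_seed("ittp"),
                                     threshold=threshold)
        else:
            ittp_report = ittp_case2(train, query, seed=record_seed("ittp"),
                                     threshold=threshold)
        section = ittp_report.to_dict()
        section["status"] = "ok"
        report["ittp"] = section
    except Exception as exc:
        report["ittp"] = {"status": f"failed: {exc}"}

    gpr_cfg = config.get("gpr", {})
    predictions = None
    try:
        gpr_panel = panel if panel is not None else train.cpg_ids
        clock = fit_gpr(train, cpgs=gpr_panel,
                        restarts=int(gpr_cfg.get("restarts", 3)),
                        seed=record_seed("gpr"))
        predictions = predict_gpr(clock, query)
        by_group: dict = {}
        for pred, interval in predictions:
            key = str(pred.group)
            by_group.setdefault(key, []).append((pred, interval))
        report["gpr"] = {
            "status": "ok",
            "params": {
                "s2": clock.params.s2,
                "length_scale": clock.params.length_scale,
                "noise": clock.params.noise,
            },
            "log_marginal_likelihood": clock.log_marginal_likelihood,
            "groups": {
                key: {
                    "n": len(items),
                    "mean_predicted_age": float(np.mean([p.predicted_age for p, _ in items])),
                    "mean_variance": float(np.mean([p.variance for p, _ in items])),
                    "mean_interval_width": float(np.mean([ci.width for _, ci in items])),
                }
                for key, items in sorted(by_group.items())
            },
        }
    except Exception as exc:
        report["gpr"] = {"status": f"failed: {exc}"}

    try:
        if predictions is None:
            report["tests"] = {"status": "skipped: no GPR predictions"}
        elif course is None:
            report["tests"] = {"status": "skipped: query has no group labels"}
        else:
            labels = sorted(course.group.unique())
            pairs = config.get("tests", {}).get("pairs") or [[labels[0], labels[-1]]]
            entries = {}
            for t0, t1 in pairs:
                grp_a = [p for p, _ in predictions if p.group == t0]
                grp_b = [p for p, _ in predictions if p.group == t1]
                meta = meta_regression_groups(grp_a, grp_b)
                mww = mann_whitney([p.predicted_age for p in grp_a],
                                   [p.predicted_age for p in grp_b])
                entries[f"{t0}_vs_{t1}"] = {
                    "meta_regression": meta.to_dict(),
                    "mann_whitney": mww.to_dict(),
                }
            report["tests"] = {"status": "ok", "comparisons": entries}
    except Exception as exc:
        report["tests"] = {"status": f"failed: {exc}"}

    return FrameworkReport(sections=report)


def demo_toy_clock(n_per_cohort: int = 1000, seed: int = 0, control=None,
                   shifted=None) -> dict:
    """The two-biomarker (height/weight) clock demonstration.

    A linear clock trained on the control cohort is applied to a cohort with
    systematically lower heights: its mean predicted age drops below the true
    mean — a purely technical artifact of covariate shift, flagged by KS
    tests on the covariates themselves.
    """
    from scipy.stats import ks_2samp

    cohorts = simulate_anthropometric_cohorts(control=control, shifted=shifted,
                                              n_per_cohort=n_per_cohort, seed=seed)
    control = cohorts.cohort("control")
    shifted = cohorts.cohort("shifted")
    model = LinearRegression()
    model.fit(control[["height", "weight"]], control["age"])
    pred_control = model.predict(control[["height", "weight"]])
    pred_shifted = model.predict(shifted[["height", "weight"]])
    ks_height = ks_2samp(control["height"], shifted["height"])
    ks_weight = ks_2samp(control["weight"], shifted["weight"])
    return {
        "n_per_cohort": n_per_cohort,
        "control_metrics": regression_metrics(control["age"], pred_control).to_dict(),
        "shifted_metrics": regression_metrics(shifted["age"], pred_shifted).to_dict(),
        "shifted_mean_bias": float(np.mean(pred_shifted - shifted["age"])),
        "ks_height": {"statistic": float(ks_height.statistic), "p_value": float(ks_height.pvalue)},
        "ks_weight": {"statistic": float(ks_weight.statistic), "p_value": float(ks_weight.pvalue)},
    }


def load_config(path) -> dict:
    with open(path) as handle:
        return yaml.safe_load(handle) or {}
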