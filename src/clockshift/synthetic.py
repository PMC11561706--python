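"""Synthetic methylation and anthropometric cohorts.

The generators emulate the statistical structure that aging-clock analyses
assume, so that every downstream stage (shift diagnostics, clock fitting,
ITTP, GPR uncertainty) is testable without any external download:

* an *aging* process — a subset of CpGs whose beta values depend linearly on
  age plus bounded Gaussian noise, clipped to [0, 1];
* *covariate-shifted* cohorts — a fraction of CpGs offset on the beta scale
  (optionally with an additive age bias, a response shift);
* a *reprogramming course* — time-labeled groups that drift monotonically
  toward the 0/1 beta attractors as the day index grows, mimicking the
  hyper/hypomethylation of pluripotency without modeling its biology;
* *anthropometric cohorts* — a toy height/weight clock scenario where a
  shifted cohort has systematically lower heights at every age.

Every generator is a pure function of (config, seed): identical inputs give
bit-identical outputs. True age-CpG and shifted-CpG identities are recorded
in ``attrs`` to enable support-recovery tests; real data has no such labels,
so anything reading ``attrs`` is synthetic-only tooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import MethylationDataset


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of the synthetic aging-methylation process.

    ``slope_range`` bounds the *magnitude* of the per-unit-age beta change of
    the age-linked CpGs (sign is random). Defaults resemble an adult human
    cohort measured at clock-grade CpGs: ages uniform on 20–80 years, slopes
    0.004–0.010 beta/year (0.24–0.6 beta over the age range, the magnitude of
    change seen at CpGs selected into published clocks), so each age-linked
    CpG individually carries strong age signal (|Pearson r| ≈ 0.92–0.99 at
    the default noise), and noise_sd=0.03 on the beta scale.
    """

    n_samples: int = 200
    n_cpgs: int = 500
    n_age_cpgs: int = 50
    age_range: tuple[float, float] = (20.0, 80.0)
    slope_range: tuple[float, float] = (0.004, 0.010)
    noise_sd: float = 0.03
    age_unit: str = "years"
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_cpgs < 1:
            raise ConfigurationError("n_samples and n_cpgs must be positive")
        if not 0 <= self.n_age_cpgs <= self.n_cpgs:
            raise ConfigurationError("need 0 <= n_age_cpgs <= n_cpgs")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        lo, hi = self.age_range
        if not hi > lo:
            raise ConfigurationError("age_range must be non-degenerate (hi > lo)")
        slo, shi = self.slope_range
        if slo < 0 or shi < slo:
            raise ConfigurationError("slope_range must satisfy 0 <= lo <= hi")


@dataclass(frozen=True)
class ShiftSpec:
    """Covariate/response shift applied to an existing dataset.

    ``offset`` is a fixed beta-scale shift; alternatively ``offset_sd`` draws
    a per-CpG offset from N(0, offset_sd²). ``direction="signed"`` adds the
    offset as-is; ``"toward_extremes"`` pushes each shifted CpG toward its
    nearer beta attractor (0 or 1) by |offset|. ``response_offset`` adds a
    constant to the ages (a response shift). offset 0 with response_offset 0
    is the identity.
    """

    offset: float = 0.0
    offset_sd: float | None = None
    fraction_shifted: float = 1.0
    direction: str = "signed"
    response_offset: float = 0.0

    def validate(self) -> None:
        if not 0.0 <= self.fraction_shifted <= 1.0:
            raise ConfigurationError("fraction_shifted must be in [0, 1]")
        if self.direction not in ("signed", "toward_extremes"):
            raise ConfigurationError("direction must be 'signed' or 'toward_extremes'")
        if self.offset_sd is not None and self.offset_sd < 0:
            raise ConfigurationError("offset_sd must be >= 0")


def _cpg_ids(n: int) -> list[str]:
    return [f"cg{str(i).zfill(6)}" for i in range(n)]


def _sample_ids(n: int, prefix: str = "s") -> list[str]:
    return [f"{prefix}{str(i).zfill(4)}" for i in range(n)]


def simulate_aging_methylation(config: SimulationConfig,
                               sample_seed: int | None = None) -> MethylationDataset:
    """Draw an aging cohort: ages uniform on ``age_range``; each age-linked
    CpG i follows beta = clip(b0_i + slope_i · age + ε, 0, 1) with
    ε ~ N(0, noise_sd²); the remaining CpGs are age-independent noise around
    a random baseline.

    CpG-level generating parameters (which CpGs are age-linked, their slopes,
    intercepts and baselines) are a function of ``config.seed`` alone;
    sample-level draws (ages, noise) use ``sample_seed`` when given, so a
    fresh cohort from the *same* underlying process — e.g. an independent
    held-out set — is ``simulate_aging_methylation(config, sample_seed=...)``.

    Baselines of age-CpGs are placed so the noiseless trajectory stays within
    [0.05, 0.95] across the age range, keeping clipping rare at the default
    noise level. ``attrs["age_cpgs"]`` records the truly age-linked ids,
    ``attrs["slopes"]`` / ``attrs["intercepts"]`` the generating parameters.
    """
    config.validate()
    param_rng = np.random.default_rng([config.seed, 0])
    sample_rng = np.random.default_rng(
        [config.seed if sample_seed is None else sample_seed, 1]
    )
    lo, hi = config.age_range
    mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0

    cpgs = _cpg_ids(config.n_cpgs)
    age_idx = param_rng.choice(config.n_cpgs, size=config.n_age_cpgs, replace=False)
    age_idx.sort()
    baselines = param_rng.uniform(0.05, 0.95, size=config.n_cpgs)
    slo, shi = config.slope_range
    slopes = param_rng.uniform(slo, shi, size=config.n_age_cpgs)
    slopes *= param_rng.choice([-1.0, 1.0], size=config.n_age_cpgs)
    # center so the noiseless line stays within [0.05, 0.95] over the range
    margin = 0.05 + np.abs(slopes) * half
    centers = param_rng.uniform(margin, 1.0 - margin)
    intercepts = centers - slopes * mid

    ages = sample_rng.uniform(lo, hi, size=config.n_samples)
    beta = np.empty((config.n_samples, config.n_cpgs))
    beta[:] = baselines[None, :] + sample_rng.normal(0.0, config.noise_sd, size=beta.shape)
    signal = intercepts[None, :] + slopes[None, :] * ages[:, None]
    beta[:, age_idx] = signal + sample_rng.normal(0.0, config.noise_sd, size=signal.shape)

    np.clip(beta, 0.0, 1.0, out=beta)
    samples = _sample_ids(config.n_samples)
    frame = pd.DataFrame(beta, index=samples, columns=cpgs)
    age = pd.Series(ages, index=samples, name="age")
    age_cpg_ids = [cpgs[i] for i in age_idx]
    return MethylationDataset(
        beta=frame,
        age=age,
        age_unit=config.age_unit,
        attrs={
            "age_cpgs": age_cpg_ids,
            "slopes": dict(zip(age_cpg_ids, slopes.tolist())),
            "intercepts": dict(zip(age_cpg_ids, intercepts.tolist())),
            "seed": config.seed,
        },
    )


def apply_covariate_shift(dataset: MethylationDataset, spec: ShiftSpec,
                          seed: int = 0) -> MethylationDataset:
    """Offset a random fraction of CpG columns on the beta scale (clipped),
    optionally biasing the ages by ``spec.response_offset``.

    Unshifted columns are bitwise unchanged; shifted ids are recorded in
    ``attrs["shifted_cpgs"]``. Columns driven constant by the clipping are
    permitted but flagged in ``attrs["constant_cpgs"]``.
    """
    spec.validate()
    if dataset.n_samples == 0 or dataset.n_cpgs == 0:
        raise ValueError("cannot shift an empty dataset")
    out = dataset.copy()
    rng = np.random.default_rng(seed)
    n_shift = int(round(spec.fraction_shifted * dataset.n_cpgs))
    shift_idx = np.sort(rng.choice(dataset.n_cpgs, size=n_shift, replace=False))
    shifted_ids = [dataset.cpg_ids[i] for i in shift_idx]

    identity = (
        spec.response_offset == 0.0
        and (spec.offset == 0.0 if spec.offset_sd is None else spec.offset_sd == 0.0)
    )
    if n_shift and not identity:
        block = out.beta.iloc[:, shift_idx].to_numpy()
        if spec.offset_sd is not None:
            offsets = rng.normal(0.0, spec.offset_sd, size=n_shift)
        else:
            offsets = np.full(n_shift, float(spec.offset))
        if spec.direction == "toward_extremes":
            toward = np.where(block.mean(axis=0) >= 0.5, 1.0, -1.0)
            block = block + toward[None, :] * np.abs(offsets)[None, :]
        else:
            block = block + offsets[None, :]
        np.clip(block, 0.0, 1.0, out=block)
        out.beta.iloc[:, shift_idx] = block
    if spec.response_offset != 0.0 and out.age is not None:
        object.__setattr__(out, "age", out.age + spec.response_offset)

    constant = [c for c in shifted_ids if out.beta[c].nunique() == 1]
    out.attrs["shifted_cpgs"] = shifted_ids
    out.attrs["constant_cpgs"] = constant
    return out


def simulate_reprogramming_course(base: SimulationConfig, days, drift_per_day: float,
                                  seed: int = 0, donor_age: float | None = None,
                                  n_per_day: int | None = None,
                                  drift_fraction: float = 1.0) -> MethylationDataset:
    """Simulate a reprogramming time course from a single donor age.

    Day-0 samples are drawn from the base aging process at ``donor_age``
    (default: midpoint of the base age range). Samples at later days drift
    toward the nearer of the 0/1 beta attractors by ``drift_per_day · day``
    on a ``drift_fraction`` of CpGs. Group labels are the day indices; ages
    are deliberately absent — the biological age along reprogramming is the
    unknown the framework interrogates.
    """
    base.validate()
    days = list(days)
    if sorted(days) != days:
        raise ConfigurationError("days must be sorted ascending")
    if drift_per_day < 0:
        raise ConfigurationError("drift_per_day must be >= 0")
    if not 0.0 < drift_fraction <= 1.0:
        raise ConfigurationError("drift_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    if donor_age is None:
        donor_age = (base.age_range[0] + base.age_range[1]) / 2.0
    n = n_per_day if n_per_day is not None else base.n_samples

    # generating parameters shared with the base process at this seed
    template = simulate_aging_methylation(base)
    cpgs = template.cpg_ids
    slopes = template.attrs["slopes"]
    intercepts = template.attrs["intercepts"]
    baseline = np.array(
        [
            intercepts[c] + slopes[c] * donor_age if c in slopes
            else template.beta[c].mean()
            for c in cpgs
        ]
    )
    n_drift = int(round(drift_fraction * len(cpgs)))
    drift_idx = np.sort(rng.choice(len(cpgs), size=n_drift, replace=False))
    toward = np.where(baseline[drift_idx] >= 0.5, 1.0, -1.0)

    blocks, sample_ids, groups = [], [], []
    for day in days:
        block = baseline[None, :] + rng.normal(0.0, base.noise_sd, size=(n, len(cpgs)))
        block[:, drift_idx] += toward[None, :] * drift_per_day * day
        np.clip(block, 0.0, 1.0, out=block)
        blocks.append(block)
        sample_ids.extend(_sample_ids(n, prefix=f"d{day}_"))
        groups.extend([day] * n)

    frame = pd.DataFrame(np.vstack(blocks), index=sample_ids, columns=cpgs)
    group = pd.Series(groups, index=sample_ids, name="group")
    return MethylationDataset(
        beta=frame,
        age=None,
        group=group,
        age_unit=base.age_unit,
        attrs={
            "donor_age": donor_age,
            "drift_per_day": drift_per_day,
            "drifting_cpgs": [cpgs[i] for i in drift_idx],
            "days": days,
            "seed": seed,
        },
    )


# -- anthropometric toy cohorts -----------------------------------------


@dataclass(frozen=True)
class GrowthParams:
    """Linear-in-age mean growth curves with age-growing SDs (synthetic
    stand-ins for tabulated reference growth data). Ages in months, height
    in cm, weight in kg; ``rho`` is the height–weight correlation at a
    given age."""

    height_intercept: float = 50.0
    height_slope: float = 0.45
    weight_intercept: float = 3.5
    weight_slope: float = 0.24
    height_sd_intercept: float = 2.0
    height_sd_slope: float = 0.015
    weight_sd_intercept: float = 1.0
    weight_sd_slope: float = 0.025
    rho: float = 0.6

    def validate(self) -> None:
        if self.height_sd_intercept <= 0 or self.weight_sd_intercept <= 0:
            raise ConfigurationError("SD intercepts must be positive")
        if self.height_sd_slope < 0 or self.weight_sd_slope < 0:
            raise ConfigurationError("SD slopes must be non-negative")
        if not -1.0 < self.rho < 1.0:
            raise ConfigurationError("rho must be in (-1, 1)")


#: Shifted cohort: systematically shorter at every age (adult mean ~130 cm)
#: and correspondingly lighter; emulates a skeletal-dysplasia cohort, where
#: both covariate distributions differ visibly from the control cohort.
SHIFTED_GROWTH = GrowthParams(height_intercept=47.0, height_slope=0.30,
                              weight_intercept=3.5, weight_slope=0.20)


@dataclass
class AnthropometricDataset:
    """Per-sample age (months), height (cm), weight (kg) and cohort label."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def cohort(self, name: str) -> pd.DataFrame:
        return self.table[self.table["cohort"] == name]


def simulate_anthropometric_cohorts(control: GrowthParams | None = None,
                                    shifted: GrowthParams | None = None,
                                    n_per_cohort: int = 1000, seed: int = 0,
                                    age_range: tuple[float, float] = (0.0, 276.0),
                                    ) -> AnthropometricDataset:
    """Sample two cohorts of (age, height, weight) with jointly normal
    height/weight at each age. Ages are uniform on ``age_range`` (months);
    the default is 1000 samples per cohort over 0–276 months. The shifted
    cohort has systematically lower height means, which makes a
    control-trained height/weight clock under-predict its ages.
    """
    control = control or GrowthParams()
    shifted = shifted or SHIFTED_GROWTH
    control.validate()
    shifted.validate()
    if n_per_cohort < 1:
        raise ConfigurationError("n_per_cohort must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for name, p in (("control", control), ("shifted", shifted)):
        ages = rng.uniform(age_range[0], age_range[1], size=n_per_cohort)
        mh = p.height_intercept + p.height_slope * ages
        mw = p.weight_intercept + p.weight_slope * ages
        sh = p.height_sd_intercept + p.height_sd_slope * ages
        sw = p.weight_sd_intercept + p.weight_sd_slope * ages
        z = rng.standard_normal((n_per_cohort, 2))
        zh = z[:, 0]
        zw = p.rho * z[:, 0] + np.sqrt(1 - p.rho**2) * z[:, 1]
        heights = np.maximum(mh + sh * zh, 0.5)
        weights = np.maximum(mw + sw * zw, 0.5)
        rows.append(pd.DataFrame({
            "age": ages, "height": heights, "weight": weights, "cohort": name,
        }))
    table = pd.concat(rows, ignore_index=True)
    return AnthropometricDataset(table=table)
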