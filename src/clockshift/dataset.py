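"""In-memory containers for methylation matrices and per-sample metadata.

The central object is :class:`MethylationDataset`: a samples × CpGs matrix of
beta values (fraction of methylated reads, in [0, 1]) with optional per-sample
chronological ages and categorical group labels (reprogramming day, cohort,
treatment arm, ...). Ages carry an explicit unit — human cohorts are usually
annotated in years, mouse RRBS cohorts in months — and the unit is never
converted implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

AGE_UNITS = ("years", "months")


class FormatError(ValueError):
    """Malformed input matrix or metadata."""


class MissingAgeError(ValueError):
    """An operation requiring chronological ages was invoked on an unlabeled dataset."""


@dataclass
class MethylationDataset:
    """Beta-value matrix (samples × CpGs) with per-sample metadata.

    Parameters
    ----------
    beta
        DataFrame indexed by sample id with CpG ids as columns; all values
        must be finite and within [0, 1].
    age
        Optional per-sample chronological age, aligned to ``beta.index``.
        May be absent for datasets without ground truth (e.g. a
        reprogramming course), in which case age-requiring operations
        raise :class:`MissingAgeError` when invoked.
    group
        Optional per-sample categorical label (day, cohort, ...).
    tissue
        Free-text tissue annotation.
    age_unit
        ``"years"`` or ``"months"``; carried, never converted.
    attrs
        Provenance dictionary (e.g. which CpGs are truly age-linked in a
        synthetic dataset, which CpGs were shifted).
    """

    beta: pd.DataFrame
    age: pd.Series | None = None
    group: pd.Series | None = None
    tissue: str | None = None
    age_unit: str = "years"
    attrs: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.beta, pd.DataFrame):
            raise FormatError("beta must be a pandas DataFrame (samples × CpGs)")
        if self.beta.index.has_duplicates:
            dupes = self.beta.index[self.beta.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dupes[:5]}")
        if self.beta.columns.has_duplicates:
            dupes = self.beta.columns[self.beta.columns.duplicated()].tolist()
            raise FormatError(f"duplicate CpG ids: {dupes[:5]}")
        if self.age_unit not in AGE_UNITS:
            raise FormatError(f"age_unit must be one of {AGE_UNITS}, got {self.age_unit!r}")
        values = self.beta.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise FormatError("beta matrix contains non-numeric values")
        if values.size:
            bad = ~((values >= 0.0) & (values <= 1.0))
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise FormatError(
                    f"beta value {values[i, j]!r} outside [0, 1] at sample "
                    f"{self.beta.index[i]!r}, CpG {self.beta.columns[j]!r}"
                )
        for name in ("age", "group"):
            series = getattr(self, name)
            if series is None:
                continue
            series = pd.Series(series) if not isinstance(series, pd.Series) else series
            if not series.index.equals(self.beta.index):
                series = series.reindex(self.beta.index)
                if series.isna().all():
                    raise FormatError(f"{name} index does not match sample ids")
            object.__setattr__(self, name, series)

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.beta.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.beta.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.beta.columns)

    def require_age(self) -> pd.Series:
        """Return ages, raising :class:`MissingAgeError` if absent or incomplete."""
        if self.age is None:
            raise MissingAgeError("dataset carries no chronological ages")
        if self.age.isna().any():
            missing = self.age.index[self.age.isna()].tolist()
            raise MissingAgeError(f"ages missing for samples: {missing[:5]}")
        return self.age

    # -- subsetting ------------------------------------------------------

    def select_samples(self, sample_ids) -> "MethylationDataset":
        sample_ids = list(sample_ids)
        missing = [s for s in sample_ids if s not in self.beta.index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        return MethylationDataset(
            beta=self.beta.loc[sample_ids].copy(),
            age=None if self.age is None else self.age.loc[sample_ids].copy(),
            group=None if self.group is None else self.group.loc[sample_ids].copy(),
            tissue=self.tissue,
            age_unit=self.age_unit,
            attrs=dict(self.attrs),
        )

    def select_cpgs(self, cpg_ids) -> "MethylationDataset":
        cpg_ids = list(cpg_ids)
        missing = [c for c in cpg_ids if c not in self.beta.columns]
        if missing:
            raise KeyError(f"unknown CpG ids: {missing[:5]}")
        return MethylationDataset(
            beta=self.beta.loc[:, cpg_ids].copy(),
            age=None if self.age is None else self.age.copy(),
            group=None if self.group is None else self.group.copy(),
            tissue=self.tissue,
            age_unit=self.age_unit,
            attrs=dict(self.attrs),
        )

    def copy(self) -> "MethylationDataset":
        return self.select_samples(self.sample_ids)

    def equals(self, other: "MethylationDataset") -> bool:
        """Bitwise equality of matrix, metadata and unit (attrs excluded)."""
        if not self.beta.equals(other.beta) or self.age_unit != other.age_unit:
            return False
        for name in ("age", "group"):
            a, b = getattr(self, name), getattr(other, name)
            if (a is None) != (b is None):
                return False
            if a is not None and not a.equals(b):
                return False
        return True


@dataclass
class CoverageMatrix:
    """Integer read-count matrix aligned to a beta matrix (samples × CpGs)."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if np.issubdtype(values.dtype, np.number) and np.all(values == np.floor(values)):
                self.counts = self.counts.astype(int)
                values = self.counts.to_numpy()
            else:
                raise FormatError("coverage counts must be integers")
        if values.size and (values < 0).any():
            raise FormatError("coverage counts must be non-negative")

    def aligned_to(self, dataset: MethylationDataset) -> bool:
        return self.counts.index.equals(dataset.beta.index) and self.counts.columns.equals(
            dataset.beta.columns
        )
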