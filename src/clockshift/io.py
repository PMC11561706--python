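"""Reading, writing and assembling methylation datasets.

Beta matrices are delimited text (TSV by default, CSV by extension) with the
sample id in the first column and CpG ids in the header row — always samples
× CpGs; transposed inputs are never auto-detected, pass ``transpose=True``
explicitly. Metadata tables carry columns ``sample_id``, ``age``, ``group``,
``tissue`` (all but ``sample_id`` optional). Assembly follows the usual RRBS
conventions: CpG universes are intersected across dataset pairs, and sites
are kept only if covered ≥5× in ≥90% of samples on autosomes.
"""

from __future__ import annotations

import json
import math
import re
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .dataset import CoverageMatrix, FormatError, MethylationDataset

#: CpG ids flagged as sex-chromosomal: "chrX:123", "X_456", "cgY_7", ...
DEFAULT_SEX_CHROM_REGEX = r"^(?:chr|cg)?[XY][:_.]"


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_beta_matrix(path, metadata_path=None, age_unit: str = "years",
                     transpose: bool = False) -> MethylationDataset:
    """Read a beta matrix plus optional metadata table into a dataset.

    Raises :class:`FormatError` naming the offending cell for non-numeric or
    out-of-range beta values, and for metadata sample ids that do not match
    the matrix.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0, float_precision="round_trip")
    if transpose:
        raw = raw.T
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    for col in raw.columns:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna()
        if bad.any():
            sample = bad.idxmax()
            raise FormatError(
                f"non-numeric beta value {raw.loc[sample, col]!r} at sample "
                f"{sample!r}, CpG {col!r}"
            )
        raw[col] = coerced
    if raw.isna().any().any():
        stacked = raw.isna().stack()
        sample, cpg = stacked.index[np.argmax(stacked.to_numpy())]
        raise FormatError(f"missing beta value at sample {sample!r}, CpG {cpg!r}")

    age = group = tissue = None
    if metadata_path is not None:
        metadata_path = Path(metadata_path)
        meta = pd.read_csv(metadata_path, sep=_sep_for(metadata_path))
        if "sample_id" not in meta.columns:
            raise FormatError("metadata table lacks a 'sample_id' column")
        meta["sample_id"] = meta["sample_id"].astype(str)
        meta = meta.set_index("sample_id")
        unmatched = sorted(set(raw.index).symmetric_difference(meta.index))
        if unmatched:
            raise FormatError(f"sample ids not shared by matrix and metadata: {unmatched[:5]}")
        meta = meta.loc[raw.index]
        if "age" in meta.columns and meta["age"].notna().any():
            age = pd.to_numeric(meta["age"], errors="raise")
        if "group" in meta.columns and meta["group"].notna().any():
            group = meta["group"]
        if "tissue" in meta.columns and meta["tissue"].notna().any():
            tissue = str(meta["tissue"].dropna().iloc[0])

    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        age_unit = info.get("age_unit", age_unit)
        tissue = info.get("tissue", tissue)

    return MethylationDataset(beta=raw, age=age, group=group, tissue=tissue, age_unit=age_unit)


def write_beta_matrix(dataset: MethylationDataset, path, metadata_path=None,
                      sidecar: bool = True) -> None:
    """Write a dataset as delimited text; round-trips through :func:`read_beta_matrix`."""
    path = Path(path)
    out = dataset.beta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep=_sep_for(path))
    if metadata_path is not None:
        meta = pd.DataFrame(index=dataset.beta.index)
        meta.index.name = "sample_id"
        if dataset.age is not None:
            meta["age"] = dataset.age
        if dataset.group is not None:
            meta["group"] = dataset.group
        if dataset.tissue is not None:
            meta["tissue"] = dataset.tissue
        meta.to_csv(metadata_path, sep=_sep_for(metadata_path))
    if sidecar:
        info = {"age_unit": dataset.age_unit, "tissue": dataset.tissue}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(info, sort_keys=True))


def intersect_cpgs(a: MethylationDataset, b: MethylationDataset):
    """Restrict both datasets to their shared CpGs, in a's column order."""
    if a.n_cpgs == 0 or b.n_cpgs == 0:
        raise ValueError("cannot intersect an empty dataset")
    common = [c for c in a.cpg_ids if c in set(b.cpg_ids)]
    if not common:
        raise ValueError("CpG universes are disjoint: empty intersection")
    return a.select_cpgs(common), b.select_cpgs(common)


def filter_by_coverage(dataset: MethylationDataset, coverage: CoverageMatrix,
                       min_cov: int = 5, min_frac: float = 0.9,
                       autosomal_only: bool = True,
                       sex_chrom_regex: str = DEFAULT_SEX_CHROM_REGEX) -> MethylationDataset:
    """Keep CpGs covered ≥ ``min_cov``× in at least ``ceil(min_frac · n)`` samples.

    With the defaults this is the standard RRBS site filter (≥5× coverage in
    ≥90% of samples, autosomes only). Sex-chromosome CpGs are recognized by
    an id-prefix regex since id conventions are platform-specific.
    """
    if not coverage.aligned_to(dataset):
        raise ValueError("coverage matrix axes do not match the beta matrix")
    required = math.ceil(min_frac * dataset.n_samples)
    enough = (coverage.counts.to_numpy() >= min_cov).sum(axis=0) >= required
    keep = [c for c, ok in zip(dataset.cpg_ids, enough) if ok]
    if autosomal_only:
        sex = re.compile(sex_chrom_regex)
        keep = [c for c in keep if not sex.match(c)]
    return dataset.select_cpgs(keep)


def split_train_test(dataset: MethylationDataset, test_frac: float, seed: int):
    """Random, disjoint, exhaustive sample split; reproducible under ``seed``."""
    if not 0.0 < test_frac < 1.0:
        raise ValueError(f"test_frac must be in (0, 1), got {test_frac}")
    n_test = int(round(test_frac * dataset.n_samples))
    if n_test == 0 or n_test == dataset.n_samples:
        raise ValueError(
            f"test_frac={test_frac} leaves an empty side for n={dataset.n_samples}"
        )
    train_ids, test_ids = train_test_split(
        dataset.sample_ids, test_size=n_test, random_state=seed, shuffle=True
    )
    return dataset.select_samples(train_ids), dataset.select_samples(test_ids)
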