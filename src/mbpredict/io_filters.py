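"""Data model, TSV readers/writers, and quality-control filters.

A microbiome study is represented by two aligned objects: an
:class:`OTUTable` (samples × OTUs integer counts plus per-sample total
reads) and :class:`SampleCovariates` (phenotype, fixed factors, random
factors).  Total reads ``T_i`` are kept separate from the count matrix
because they serve as the model offset: after OTU-level filtering the
totals still refer to the full sequencing depth, not the post-filter
row sums.

Quality control follows the usual two-step order: drop shallow samples
(total reads below a floor) first, then drop rare OTUs (prevalence
below a floor).  The order matters and is fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

TOTAL_READS_COLUMN = "total_reads"
SAMPLE_ID_COLUMN = "sample_id"


class DataError(ValueError):
    """Raised for malformed input tables or degenerate filter results."""


@dataclass(frozen=True)
class OTUTable:
    """Samples × OTUs count matrix with per-sample total reads.

    Attributes
    ----------
    counts : (n, m) int array
        Non-negative read counts Z_i^(j).
    totals : (n,) int array
        Total sequencing reads T_i per sample.  May exceed the row sum
        of ``counts`` when some OTUs were removed upstream.
    sample_ids, taxon_ids : lists of unique strings.
    """

    counts: np.ndarray
    totals: np.ndarray
    sample_ids: tuple[str, ...]
    taxon_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        totals = np.asarray(self.totals)
        if counts.ndim != 2:
            raise DataError("counts must be a 2-D matrix")
        if counts.shape[0] == 0:
            raise DataError("no samples")
        if counts.shape[1] == 0:
            raise DataError("no OTUs")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise DataError("counts must be integral")
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            i, j = np.argwhere(counts < 0)[0]
            raise DataError(f"negative count at sample {self.sample_ids[i]!r}, taxon {self.taxon_ids[j]!r}")
        totals = totals.astype(np.int64)
        if totals.shape != (counts.shape[0],):
            raise DataError("totals length must equal the number of samples")
        if (totals <= 0).any():
            raise DataError("totals must be positive")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicate sample ids")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise DataError("duplicate taxon ids")
        if len(self.sample_ids) != counts.shape[0] or len(self.taxon_ids) != counts.shape[1]:
            raise DataError("id lengths do not match the count matrix")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "totals", totals)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "taxon_ids", tuple(self.taxon_ids))

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def take_samples(self, idx: np.ndarray) -> "OTUTable":
        idx = np.asarray(idx)
        return OTUTable(
            counts=self.counts[idx],
            totals=self.totals[idx],
            sample_ids=tuple(self.sample_ids[i] for i in idx),
            taxon_ids=self.taxon_ids,
        )

    def take_taxa(self, idx: np.ndarray) -> "OTUTable":
        idx = np.asarray(idx)
        return OTUTable(
            counts=self.counts[:, idx],
            totals=self.totals,
            sample_ids=self.sample_ids,
            taxon_ids=tuple(self.taxon_ids[j] for j in idx),
        )


@dataclass(frozen=True)
class SampleCovariates:
    """Phenotype, fixed factors and random factors, row-aligned with an OTUTable.

    ``fixed`` maps factor name -> length-n array (float for continuous,
    object/str for categorical); ``random`` maps factor name -> length-n
    array of group labels.
    """

    phenotype: np.ndarray
    fixed: dict[str, np.ndarray] = field(default_factory=dict)
    random: dict[str, np.ndarray] = field(default_factory=dict)
    sample_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        y = np.asarray(self.phenotype)
        if y.ndim != 1 or y.shape[0] == 0:
            raise DataError("phenotype must be a nonempty vector")
        # K >= 2 is enforced where models are fit, not here: CV slices
        # (e.g. a single held-out sample) legitimately carry one level
        n = y.shape[0]
        for name, v in {**self.fixed, **self.random}.items():
            if np.asarray(v).shape[0] != n:
                raise DataError(f"factor {name!r} length does not match phenotype")
        object.__setattr__(self, "phenotype", y)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))

    @property
    def n_samples(self) -> int:
        return self.phenotype.shape[0]

    @property
    def n_levels(self) -> int:
        return int(np.unique(self.phenotype).size)

    def take(self, idx: np.ndarray) -> "SampleCovariates":
        idx = np.asarray(idx)
        return SampleCovariates(
            phenotype=self.phenotype[idx],
            fixed={k: np.asarray(v)[idx] for k, v in self.fixed.items()},
            random={k: np.asarray(v)[idx] for k, v in self.random.items()},
            sample_ids=tuple(self.sample_ids[i] for i in idx) if self.sample_ids else (),
        )


def read_counts(path) -> OTUTable:
    """Read a TSV count table (samples as rows, header = taxon ids).

    The first column must be ``sample_id``.  An optional ``total_reads``
    column supplies sequencing depths; otherwise totals are row sums.
    Round-trips bit-exactly with :func:`write_counts`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[0] == 0:
        raise DataError("no samples")
    if df.columns[0] != SAMPLE_ID_COLUMN:
        raise DataError(f"first column must be {SAMPLE_ID_COLUMN!r}, got {df.columns[0]!r}")
    sample_ids = df[SAMPLE_ID_COLUMN].tolist()
    taxon_cols = [c for c in df.columns[1:] if c != TOTAL_READS_COLUMN]
    if not taxon_cols:
        raise DataError("no OTUs")
    mat = np.empty((len(sample_ids), len(taxon_cols)), dtype=np.int64)
    for j, c in enumerate(taxon_cols):
        col = pd.to_numeric(df[c], errors="coerce")
        bad = col.isna() | (np.mod(col.fillna(0), 1) != 0)
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise DataError(f"non-integer count at sample {sample_ids[i]!r}, taxon {c!r}")
        mat[:, j] = col.astype(np.int64)
    if TOTAL_READS_COLUMN in df.columns:
        totals = pd.to_numeric(df[TOTAL_READS_COLUMN]).to_numpy(dtype=np.int64)
    else:
        totals = mat.sum(axis=1)
    return OTUTable(counts=mat, totals=totals, sample_ids=tuple(sample_ids), taxon_ids=tuple(taxon_cols))


def write_counts(table: OTUTable, path, include_totals: bool | None = None) -> None:
    """Write a count table as TSV; inverse of :func:`read_counts`.

    ``include_totals=None`` writes a ``total_reads`` column only when the
    totals differ from the row sums (so a read/write cycle is lossless
    either way).
    """
    row_sums = table.counts.sum(axis=1)
    if include_totals is None:
        include_totals = bool(np.any(row_sums != table.totals))
    df = pd.DataFrame(table.counts, columns=list(table.taxon_ids))
    df.insert(0, SAMPLE_ID_COLUMN, list(table.sample_ids))
    if include_totals:
        df[TOTAL_READS_COLUMN] = table.totals
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_metadata(
    path,
    table: OTUTable,
    phenotype: str,
    fixed: dict[str, str] | None = None,
    random: tuple[str, ...] = (),
) -> SampleCovariates:
    """Read a sample-metadata TSV and align it with ``table``.

    ``fixed`` maps column name -> type ("continuous" or "categorical");
    factor typing is declared, never inferred.  The join on sample_id is
    strict: samples present in the counts but missing from the metadata
    (or vice versa) raise an error rather than being dropped silently.
    """
    fixed = fixed or {}
    df = pd.read_csv(path, sep="\t", dtype=str)
    if SAMPLE_ID_COLUMN not in df.columns:
        raise DataError(f"metadata must contain a {SAMPLE_ID_COLUMN!r} column")
    df = df.set_index(SAMPLE_ID_COLUMN)
    missing = [s for s in table.sample_ids if s not in df.index]
    if missing:
        raise DataError(f"samples missing from metadata: {missing[:5]}")
    extra = [s for s in df.index if s not in set(table.sample_ids)]
    if extra:
        raise DataError(f"metadata samples not in counts: {extra[:5]}")
    df = df.loc[list(table.sample_ids)]
    fixed_arrays: dict[str, np.ndarray] = {}
    for name, kind in fixed.items():
        if name not in df.columns:
            raise DataError(f"fixed factor column {name!r} not in metadata")
        if kind == "continuous":
            fixed_arrays[name] = pd.to_numeric(df[name]).to_numpy(dtype=float)
        elif kind == "categorical":
            fixed_arrays[name] = df[name].to_numpy(dtype=object)
        else:
            raise DataError(f"unknown factor type {kind!r} for {name!r}")
    random_arrays = {}
    for name in random:
        if name not in df.columns:
            raise DataError(f"random factor column {name!r} not in metadata")
        random_arrays[name] = df[name].to_numpy(dtype=object)
    if phenotype not in df.columns:
        raise DataError(f"phenotype column {phenotype!r} not in metadata")
    if df[phenotype].nunique() < 2:
        raise DataError("phenotype must have at least 2 levels")
    return SampleCovariates(
        phenotype=df[phenotype].to_numpy(dtype=object),
        fixed=fixed_arrays,
        random=random_arrays,
        sample_ids=tuple(table.sample_ids),
    )


def write_metadata(covs: SampleCovariates, path, phenotype_name: str = "phenotype") -> None:
    """Write covariates as a metadata TSV readable by :func:`read_metadata`."""
    data = {SAMPLE_ID_COLUMN: list(covs.sample_ids)}
    data[phenotype_name] = covs.phenotype
    for name, v in covs.fixed.items():
        data[name] = v
    for name, v in covs.random.items():
        data[name] = v
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, lineterminator="\n")


def filter_min_reads(
    table: OTUTable, covs: SampleCovariates | None, min_reads: int
) -> tuple[OTUTable, SampleCovariates | None]:
    """Retain samples with total reads >= ``min_reads`` (covariates in lockstep)."""
    if min_reads < 1:
        raise DataError("min_reads must be >= 1")
    keep = np.flatnonzero(table.totals >= min_reads)
    if keep.size == 0:
        raise DataError("empty dataset after filtering")
    out_covs = covs.take(keep) if covs is not None else None
    return table.take_samples(keep), out_covs


def prevalence(table: OTUTable) -> np.ndarray:
    """Per-OTU share of samples with a nonzero count."""
    return (table.counts > 0).mean(axis=0)


def filter_prevalence(table: OTUTable, min_prevalence: float) -> OTUTable:
    """Retain OTUs whose prevalence is >= ``min_prevalence``.

    Totals are untouched: they remain the full sequencing depth, which
    is what the count-model offset log(T_i) requires.
    """
    if not (0 < min_prevalence <= 1):
        raise DataError("min_prevalence must be in (0, 1]")
    keep = np.flatnonzero(prevalence(table) >= min_prevalence)
    if keep.size == 0:
        raise DataError("empty dataset after filtering")
    return table.take_taxa(keep)


def quality_filter(
    table: OTUTable,
    covs: SampleCovariates | None,
    min_reads: int = 10_000,
    min_prevalence: float = 0.20,
) -> tuple[OTUTable, SampleCovariates | None]:
    """Canonical QC: sample read filter first, then OTU prevalence filter."""
    table, covs = filter_min_reads(table, covs, min_reads)
    table = filter_prevalence(table, min_prevalence)
    return table, covs
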