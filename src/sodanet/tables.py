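"""OTU count tables, sample metadata, and the standard table transformations.

The central container is :class:`OtuTable`, a thin wrapper around a pandas
DataFrame with samples as rows and OTUs as columns.  Tables hold either raw
read counts (``unit="counts"``) or row-relative fractions
(``unit="fraction"``).  All downstream statistics (dissimilarities, local
similarity, core partitions) consume these tables.

Dry sampling dates are represented purely in the metadata (``missing=True``)
and carry no count row: a zero-filled row would silently distort both
Bray–Curtis dissimilarities and association statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEASONS = ("spring", "summer", "autumn")

#: Default season partition of the 14 fortnightly sampling occasions:
#: spring = times 1-4, summer = 5-10, autumn = 11-14.
DEFAULT_SEASON_PARTITION: dict[str, tuple[int, int]] = {
    "spring": (1, 4),
    "summer": (5, 10),
    "autumn": (11, 14),
}


def season_of(time_index: int, partition: dict[str, tuple[int, int]] | None = None) -> str:
    """Map a 1-based sampling time index to its season label."""
    partition = partition or DEFAULT_SEASON_PARTITION
    for season, (lo, hi) in partition.items():
        if lo <= time_index <= hi:
            return season
    raise ValueError(f"time index {time_index} outside the season partition")


@dataclass
class OtuTable:
    """Samples x OTUs abundance matrix.

    Parameters
    ----------
    data:
        DataFrame indexed by sample id with OTU ids as columns.  Entries are
        non-negative reads (``unit='counts'``) or fractions summing to one per
        row (``unit='fraction'``).
    unit:
        ``"counts"`` or ``"fraction"``.
    """

    data: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "fraction"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate OTU ids")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("non-finite abundance values")
        if (values < 0).any():
            raise ValueError("negative abundance values")
        if self.unit == "fraction":
            sums = values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("fraction rows must sum to 1")

    # -- convenience accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def row_sums(self) -> pd.Series:
        return self.data.sum(axis=1)

    def select_samples(self, sample_ids) -> "OtuTable":
        return OtuTable(self.data.loc[list(sample_ids)].copy(), unit=self.unit)

    def select_otus(self, otu_ids) -> "OtuTable":
        return OtuTable(self.data.loc[:, list(otu_ids)].copy(), unit=self.unit)


@dataclass
class SampleMetadata:
    """Per-sample annotations: lake, time index, season, environment, missingness.

    ``table`` is indexed by sample id with at least columns ``lake``,
    ``time_index``, ``season`` and ``missing``; any additional numeric columns
    are treated as environmental variables.
    """

    table: pd.DataFrame
    environment_columns: list[str] = field(default_factory=list)

    REQUIRED = ("lake", "time_index", "season", "missing")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        self.table = self.table.copy()
        self.table["time_index"] = self.table["time_index"].astype(int)
        self.table["missing"] = self.table["missing"].astype(bool)
        bad = set(self.table["season"]) - set(SEASONS)
        if bad:
            raise ValueError(f"unknown season labels: {sorted(bad)}")
        for lake, sub in self.table.groupby("lake", sort=False):
            t = sub["time_index"].to_numpy()
            if (np.diff(t) <= 0).any():
                raise ValueError(f"time_index not strictly increasing within lake {lake!r}")
        if not self.environment_columns:
            self.environment_columns = [
                c
                for c in self.table.columns
                if c not in self.REQUIRED and pd.api.types.is_numeric_dtype(self.table[c])
            ]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def present(self) -> pd.DataFrame:
        """Rows for samples that were actually collected (non-dry dates)."""
        return self.table.loc[~self.table["missing"]]

    def for_lake(self, lake: str) -> "SampleMetadata":
        sub = self.table.loc[self.table["lake"] == lake]
        if sub.empty:
            raise ValueError(f"unknown lake {lake!r}")
        return SampleMetadata(sub.copy(), list(self.environment_columns))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_otu_table(path, metadata_path) -> tuple[OtuTable, SampleMetadata]:
    """Read a tab-separated count matrix and its sample metadata.

    The count table has a header row of OTU ids and a first column of sample
    ids.  The metadata file has one row per sample (dry dates included, with
    ``missing`` true and no corresponding count row).  Samples are returned in
    metadata order.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):
        raise ValueError("duplicate OTU ids in count table")
    raw = pd.read_csv(path, sep="\t", index_col=0)
    raw.index = raw.index.astype(str)
    raw.index.name = None
    raw.columns = raw.columns.astype(str)
    if raw.index.has_duplicates:
        raise ValueError("duplicate sample ids in count table")
    try:
        raw = raw.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric counts: {exc}") from exc

    meta_raw = pd.read_csv(metadata_path, sep="\t", index_col=0)
    meta_raw.index = meta_raw.index.astype(str)
    meta_raw.index.name = None
    meta = SampleMetadata(meta_raw)
    expected = [s for s in meta.sample_ids if not meta.table.loc[s, "missing"]]
    absent = sorted(set(expected) - set(raw.index))
    if absent:
        raise ValueError(f"metadata samples missing from count table: {absent}")
    table = OtuTable(raw.loc[expected], unit="counts")
    return table, meta


def write_otu_table(table: OtuTable, path) -> None:
    """Write the table as TSV with a deterministic column order."""
    table.data.to_csv(path, sep="\t", index_label="sample_id")


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="sample_id")


def read_taxonomy(path) -> pd.Series:
    """Read an optional two-column taxonomy TSV (otu_id, semicolon lineage)."""
    tax = pd.read_csv(path, sep="\t", index_col=0).iloc[:, 0]
    tax.index = tax.index.astype(str)
    return tax


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def rarefy(table: OtuTable, depth: int | None = None, seed: int = 0) -> OtuTable:
    """Subsample every sample to a common read depth, without replacement.

    Each sample is an independent multivariate-hypergeometric draw seeded from
    ``(seed, sample position)``, so the result is reproducible and per-sample
    draws are independent.  ``depth`` defaults to the minimum row sum.
    """
    if table.unit != "counts":
        raise ValueError("rarefaction requires a count table")
    counts = table.counts
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("rarefaction requires integer counts")
    counts = np.round(counts).astype(np.int64)
    sums = counts.sum(axis=1)
    if depth is None:
        depth = int(sums.min())
    if depth <= 0:
        raise ValueError("depth must be positive")
    low = np.nonzero(sums < depth)[0]
    if low.size:
        bad = table.sample_ids[low[0]]
        raise ValueError(
            f"sample {bad!r} has only {sums[low[0]]} reads, fewer than depth {depth}"
        )
    out = np.empty_like(counts)
    for i in range(counts.shape[0]):
        rng = np.random.default_rng([seed, i])
        out[i] = rng.multivariate_hypergeometric(counts[i], depth)
    return OtuTable(
        pd.DataFrame(out, index=table.data.index, columns=table.data.columns),
        unit="counts",
    )


def relative_abundance(table: OtuTable) -> OtuTable:
    """Convert counts to row-relative fractions."""
    if table.unit == "fraction":
        raise ValueError("table is already in fraction units")
    sums = table.counts.sum(axis=1)
    zero = np.nonzero(sums == 0)[0]
    if zero.size:
        raise ValueError(f"sample {table.sample_ids[zero[0]]!r} has zero total count")
    frac = table.data.div(table.data.sum(axis=1), axis=0)
    return OtuTable(frac, unit="fraction")


def filter_for_network(
    table: OtuTable,
    abun_threshold: float = 0.01,
    read_threshold: int = 10,
    sample_min: int = 3,
) -> OtuTable:
    """Keep OTUs eligible for association testing.

    An OTU is retained only if it is both above ``abun_threshold`` relative
    abundance in at least one sample (strict) and present with more than
    ``read_threshold`` reads in at least ``sample_min`` samples (strict read
    count, on rarefied counts).  The sample set is unchanged; the OTU set may
    come back empty.
    """
    if table.unit != "counts":
        raise ValueError("network filter operates on counts")
    counts = table.counts
    sums = counts.sum(axis=1, keepdims=True)
    if (sums == 0).any():
        raise ValueError("all-zero sample in table")
    frac = counts / sums
    abundant = (frac > abun_threshold).any(axis=0)
    prevalent = (counts > read_threshold).sum(axis=0) >= sample_min
    keep = abundant & prevalent
    kept = [o for o, k in zip(table.otu_ids, keep) if k]
    return table.select_otus(kept)


def ec_to_salinity(ec, slope: float = 0.792, intercept: float = 179.0):
    """Convert electrical conductivity (mS/cm) to total ion content (g/L).

    The default coefficients are the regional calibration for these soda
    lakes, ``total ions = 0.792 * EC + 179``, applied as printed; both
    coefficients are configurable (the intercept's magnitude suggests a
    different unit convention than g/L at EC=0, so overriding may be
    appropriate for other systems).
    """
    ec_arr = np.asarray(ec, dtype=float)
    if (ec_arr < 0).any():
        raise ValueError("EC must be non-negative")
    out = slope * ec_arr + intercept
    return float(out) if np.isscalar(ec) or out.ndim == 0 else out
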