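"""Core data containers, tabular readers/writers and the abundance filter.

Tables are held samples-in-rows internally.  All containers are thin,
validated wrappers around :class:`pandas.DataFrame` so that downstream code
can rely on invariants (non-negative integer counts, unique labels, aligned
metadata) without re-checking them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SPECIES_CODES = ("BD", "BZ", "CC", "CQ", "DC", "DD", "NC", "ZC")
PHYLOGENY_GROUPS = ("Neoceratitis", "Ceratitis", "Dacus", "Bactrocera+Zeugodacus")
TRIBES = ("Ceratitinae", "Dacinae")
SPECIALIZATIONS = ("generalist", "Cucurbitaceae", "Solanaceae")
ENVIRONMENTS = ("laboratory", "field")

TAXONOMIC_RANKS = ("genus", "family", "order", "class", "phylum")


def _check_unique(labels: Iterable[str], what: str) -> None:
    labels = list(labels)
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if list(labels).count(x) > 1})
        raise ValueError(f"duplicate {what} labels: {dupes}")


@dataclass
class ReadCountTable:
    """Samples x genera matrix of non-negative integer read counts.

    Rows are samples, columns are bacterial genera (or any other taxonomic
    rank after aggregation).  Row sums are per-sample sequencing depths.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValueError("empty read-count table")
        df.index = df.index.astype(str).str.strip()
        df.columns = df.columns.astype(str).str.strip()
        _check_unique(df.index, "sample")
        _check_unique(df.columns, "genus")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("non-numeric cells in read-count table")
        if np.any(~np.isfinite(arr.astype(float))):
            raise ValueError("non-finite cells in read-count table")
        if np.any(arr < 0):
            raise ValueError("negative read counts")
        if not np.allclose(arr, np.round(arr.astype(float))):
            raise ValueError("non-integer read counts")
        self.counts = df.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genus_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.counts.to_numpy()

    @property
    def depths(self) -> pd.Series:
        """Per-sample total read counts."""
        return self.counts.sum(axis=1)

    @property
    def relative_abundance(self) -> pd.DataFrame:
        """Within-sample relative abundances (rows sum to 1)."""
        depths = self.depths
        if (depths == 0).any():
            raise ValueError("sample with zero reads has no relative abundances")
        return self.counts.div(depths, axis=0)

    def subset_samples(self, sample_ids: Iterable[str]) -> "ReadCountTable":
        ids = list(sample_ids)
        missing = set(ids) - set(self.sample_ids)
        if missing:
            raise KeyError(f"unknown samples: {sorted(missing)}")
        return ReadCountTable(self.counts.loc[ids].copy())

    def require_analysable(self) -> None:
        if self.counts.shape[0] < 2 or self.counts.shape[1] < 2:
            raise ValueError("need at least 2 samples and 2 genera for analysis")


@dataclass
class SampleMetadata:
    """Per-sample host factors: species, phylogeny group, tribe, specialization, environment."""

    table: pd.DataFrame

    REQUIRED = ("species", "phylogeny_group", "tribe", "specialization", "environment")

    def __post_init__(self) -> None:
        df = self.table
        missing = set(self.REQUIRED) - set(df.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        df.index = df.index.astype(str).str.strip()
        _check_unique(df.index, "sample")
        checks = {
            "species": SPECIES_CODES,
            "phylogeny_group": PHYLOGENY_GROUPS,
            "tribe": TRIBES,
            "specialization": SPECIALIZATIONS,
            "environment": ENVIRONMENTS,
        }
        for col, allowed in checks.items():
            bad = set(df[col].astype(str)) - set(allowed)
            if bad:
                raise ValueError(f"metadata column {col!r} has unknown levels {sorted(bad)}")
        self.table = df

    def aligned_to(self, table: ReadCountTable) -> "SampleMetadata":
        """Metadata reordered to the samples of ``table`` (error if any is missing)."""
        missing = set(table.sample_ids) - set(self.table.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        return SampleMetadata(self.table.loc[table.sample_ids].copy())

    def factor(self, name: str) -> pd.Series:
        if name not in self.table.columns:
            raise KeyError(name)
        return self.table[name]


@dataclass
class TaxonomyTable:
    """Genus -> (family, order, class, phylum) lookup."""

    table: pd.DataFrame

    REQUIRED = ("family", "order", "class", "phylum")

    def __post_init__(self) -> None:
        df = self.table
        missing = set(self.REQUIRED) - set(df.columns)
        if missing:
            raise ValueError(f"taxonomy missing columns: {sorted(missing)}")
        df.index = df.index.astype(str).str.strip()
        _check_unique(df.index, "genus")
        for col in self.REQUIRED:
            vals = df[col].astype(str).str.strip()
            if (vals == "").any():
                raise ValueError(f"empty {col} names in taxonomy")
            df[col] = vals
        self.table = df

    def rank_of(self, genus_ids: Iterable[str], rank: str) -> pd.Series:
        if rank not in TAXONOMIC_RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {TAXONOMIC_RANKS}")
        ids = list(genus_ids)
        missing = set(ids) - set(self.table.index)
        if missing:
            raise KeyError(f"genera missing from taxonomy: {sorted(missing)}")
        if rank == "genus":
            return pd.Series(ids, index=ids)
        return self.table.loc[ids, rank]


@dataclass
class BinaryIncidence:
    """0/1 samples x genera matrix with the rarefaction provenance that made it."""

    incidence: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.incidence.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("incidence entries must be 0 or 1")
        self.incidence = self.incidence.astype(np.int8)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.incidence.index)

    @property
    def genus_ids(self) -> list[str]:
        return list(self.incidence.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.incidence.to_numpy()

    def require_no_empty_samples(self) -> None:
        empty = self.incidence.sum(axis=1) == 0
        if empty.any():
            raise ValueError(
                f"samples with no present genera: {list(self.incidence.index[empty])}"
            )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty table in {path}")
    return df


def read_count_table(path: str | Path, orientation: str = "samples-in-rows") -> ReadCountTable:
    """Read a TSV/CSV read-count table.

    Parameters
    ----------
    path
        TSV (default) or CSV file with a header row and a leading label column.
    orientation
        ``"samples-in-rows"`` or ``"samples-in-columns"``; the latter is
        transposed on read so tables are always samples-in-rows in memory.
    """
    if orientation not in ("samples-in-rows", "samples-in-columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_table(path)
    if orientation == "samples-in-columns":
        df = df.T
    return ReadCountTable(df)


def write_count_table(table: ReadCountTable, path: str | Path) -> None:
    sep = "," if Path(path).suffix.lower() == ".csv" else "\t"
    table.counts.to_csv(path, sep=sep)


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    return SampleMetadata(_read_table(path))


def write_sample_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="sample_id")


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    return TaxonomyTable(_read_table(path))


def write_taxonomy(tax: TaxonomyTable, path: str | Path) -> None:
    tax.table.to_csv(path, sep="\t", index_label="genus")


# ---------------------------------------------------------------------------
# Aggregation and filtering
# ---------------------------------------------------------------------------


def aggregate_to_rank(table: ReadCountTable, taxonomy: TaxonomyTable, rank: str) -> ReadCountTable:
    """Sum genus columns within groups of the requested taxonomic rank.

    Total reads are conserved; ``rank="genus"`` is the identity.
    """
    if rank == "genus":
        return ReadCountTable(table.counts.copy())
    groups = taxonomy.rank_of(table.genus_ids, rank)
    agg = table.counts.T.groupby(groups.to_numpy()).sum().T
    agg = agg[sorted(agg.columns)]
    return ReadCountTable(agg)


def filter_low_abundance(
    table: ReadCountTable, threshold_rel: float, mode: str = "per-sample"
) -> ReadCountTable:
    """Drop genera that never reach a relative-abundance threshold.

    With ``mode="per-sample"`` (default) a genus is kept iff its within-sample
    relative abundance is >= ``threshold_rel`` in at least one sample — the
    natural reading when the threshold comes from the worst per-sample
    false-positive abundance in mock-community runs.  ``mode="global"`` keeps
    a genus iff its share of all reads pooled over samples is >= the threshold.
    """
    if not 0 <= threshold_rel < 1:
        raise ValueError("threshold_rel must be in [0, 1)")
    if mode == "per-sample":
        keep = (table.relative_abundance >= threshold_rel).any(axis=0)
    elif mode == "global":
        total = table.counts.sum().sum()
        keep = (table.counts.sum(axis=0) / total) >= threshold_rel
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not keep.any():
        raise ValueError("abundance filter removed every genus")
    return ReadCountTable(table.counts.loc[:, keep].copy())


def relative_abundance_rollup(
    table: ReadCountTable, taxonomy: TaxonomyTable, rank: str
) -> pd.Series:
    """Fraction of all reads per group of the requested rank (sums to 1)."""
    agg = aggregate_to_rank(table, taxonomy, rank)
    totals = agg.counts.sum(axis=0)
    return totals / totals.sum()
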