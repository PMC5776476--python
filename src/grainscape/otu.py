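"""OTU count tables: I/O, rare-OTU filtering, rarefaction and taxonomic aggregation.

The central container is :class:`OtuTable`, an integer samples x OTUs count
matrix backed by a pandas DataFrame. Tables are read and written as plain TSV
(rows = samples, header = OTU ids); the mothur ``.shared`` dialect
(``label``/``Group``/``numOtus`` leading columns) is accepted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "OtuTableError",
    "TaxonomyMap",
    "RANKS",
    "read_otu_table",
    "write_otu_table",
    "read_taxonomy",
    "write_taxonomy",
    "remove_rare_otus",
    "subsample",
    "abundance_threshold",
    "aggregate_by_rank",
]

#: Canonical rank order for semicolon-separated lineages.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

_SHARED_LEAD = ("label", "group", "numotus")


class OtuTableError(ValueError):
    """Raised for malformed tables, filters or subsampling requests."""


class OtuTable:
    """Samples x OTUs matrix of non-negative integer read counts.

    Parameters
    ----------
    data :
        DataFrame with sample ids as index and OTU ids as columns. Values
        must be non-negative integers; both axes must be duplicate-free.
    """

    def __init__(self, data: pd.DataFrame, validate: bool = True):
        if validate:
            _validate_counts(data)
        self.data = data.astype(np.int64)

    # -- construction -------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        counts: np.ndarray,
        sample_ids: Sequence[str],
        otu_ids: Sequence[str],
    ) -> "OtuTable":
        return cls(pd.DataFrame(np.asarray(counts), index=list(sample_ids), columns=list(otu_ids)))

    # -- views ---------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_otus(self) -> int:
        return self.data.shape[1]

    def depths(self) -> pd.Series:
        """Per-sample sequencing depth (row sums)."""
        return self.data.sum(axis=1)

    def sample(self, sample_id: str) -> pd.Series:
        """Counts of one sample as a Series indexed by OTU id."""
        if sample_id not in self.data.index:
            raise KeyError(f"unknown sample {sample_id!r}")
        return self.data.loc[sample_id]

    def select_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        return OtuTable(self.data.loc[list(sample_ids)], validate=False)

    def drop_empty_otus(self) -> "OtuTable":
        keep = self.data.sum(axis=0) > 0
        return OtuTable(self.data.loc[:, keep], validate=False)

    def relative_abundance(self) -> pd.DataFrame:
        depths = self.depths()
        if (depths == 0).any():
            raise OtuTableError("cannot compute relative abundance of empty sample(s)")
        return self.data.div(depths, axis=0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return self.data.equals(other.data)

    def __repr__(self) -> str:
        return f"OtuTable({self.n_samples} samples x {self.n_otus} OTUs)"


def _validate_counts(data: pd.DataFrame) -> None:
    if data.shape[0] < 1:
        raise OtuTableError("table must contain at least one sample")
    if data.index.has_duplicates:
        dup = data.index[data.index.duplicated()].unique().tolist()
        raise OtuTableError(f"duplicate sample ids: {dup}")
    if data.columns.has_duplicates:
        dup = data.columns[data.columns.duplicated()].unique().tolist()
        raise OtuTableError(f"duplicate OTU ids: {dup}")
    arr = data.to_numpy()
    if arr.size and not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            bad = np.argwhere(np.mod(arr, 1) != 0)[0]
            raise OtuTableError(
                f"non-integer count at sample {data.index[bad[0]]!r}, OTU {data.columns[bad[1]]!r}"
            )
    if arr.size and (arr < 0).any():
        bad = np.argwhere(arr < 0)[0]
        raise OtuTableError(
            f"negative count at sample {data.index[bad[0]]!r}, OTU {data.columns[bad[1]]!r}"
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_otu_table(path: str | Path, dialect: str = "auto") -> OtuTable:
    """Read an OTU table from TSV.

    ``dialect`` is one of ``"plain"`` (first column = sample id, remaining
    columns = OTU counts), ``"shared"`` (mothur: ``label``, ``Group``,
    ``numOtus`` lead columns) or ``"auto"`` (sniff the header).
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.shape[1] < 2:
        raise OtuTableError(f"{path}: expected at least two tab-separated columns")
    header = [c.strip().lower() for c in raw.columns[:3]]
    if dialect == "auto":
        dialect = "shared" if tuple(header) == _SHARED_LEAD else "plain"
    if dialect == "shared":
        if tuple(header) != _SHARED_LEAD:
            raise OtuTableError(f"{path}: not a mothur shared file (header {list(raw.columns[:3])})")
        body = raw.iloc[:, 3:]
        index = raw.iloc[:, 1]  # Group column
    elif dialect == "plain":
        body = raw.iloc[:, 1:]
        index = raw.iloc[:, 0]
    else:
        raise OtuTableError(f"unknown dialect {dialect!r}")

    values = np.empty(body.shape, dtype=np.int64)
    for j, col in enumerate(body.columns):
        for i, cell in enumerate(body[col]):
            try:
                v = int(cell)
            except (TypeError, ValueError):
                raise OtuTableError(
                    f"{path}: invalid count {cell!r} at sample {index.iloc[i]!r}, OTU {col!r}"
                ) from None
            if v < 0:
                raise OtuTableError(
                    f"{path}: negative count {v} at sample {index.iloc[i]!r}, OTU {col!r}"
                )
            values[i, j] = v
    frame = pd.DataFrame(values, index=pd.Index(index, name="sample"), columns=list(body.columns))
    return OtuTable(frame)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    """Write a table in the canonical plain-TSV dialect."""
    out = table.data.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

@dataclass
class TaxonomyMap:
    """OTU id -> ranked lineage (tuple of taxon names, domain first).

    Lineages may be partial; missing ranks are handled at aggregation time by
    bucketing into ``unclassified_<deepest known taxon>``.
    """

    lineages: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __getitem__(self, otu_id: str) -> tuple[str, ...]:
        return self.lineages[otu_id]

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self.lineages

    def __len__(self) -> int:
        return len(self.lineages)

    def at_rank(self, otu_id: str, rank: str) -> str:
        """Taxon name of ``otu_id`` at ``rank``, with unclassified bucketing."""
        idx = RANKS.index(rank)
        lineage = self.lineages.get(otu_id)
        if lineage is None:
            return "unclassified"
        if idx < len(lineage) and lineage[idx]:
            return lineage[idx]
        known = [t for t in lineage[:idx] if t]
        return f"unclassified_{known[-1]}" if known else "unclassified"


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a 2-column TSV of ``otu_id<TAB>domain;phylum;...;genus``."""
    lineages: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise OtuTableError(f"{path}:{line_no}: expected 2 tab-separated fields")
            otu_id, lineage = parts
            lineages[otu_id] = tuple(t.strip() for t in lineage.strip(";").split(";"))
    return TaxonomyMap(lineages)


def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for otu_id, lineage in tax.lineages.items():
            fh.write(f"{otu_id}\t{';'.join(lineage)}\n")


# ---------------------------------------------------------------------------
# Filtering and subsampling
# ---------------------------------------------------------------------------

def remove_rare_otus(table: OtuTable, min_total: int = 3, per_sample: bool = False) -> OtuTable:
    """Remove OTUs represented by fewer than ``min_total`` reads.

    With the default ``min_total=3`` this removes absolute singletons and
    doubletons: OTUs whose summed count across *all* samples in the table is
    below three. Retained counts are never altered and sample/OTU order is
    preserved.

    With ``per_sample=True`` the threshold is instead applied within each
    sample (counts below ``min_total`` zeroed per cell) and OTUs that become
    empty everywhere are dropped.
    """
    if min_total < 1:
        raise OtuTableError(f"min_total must be >= 1, got {min_total}")
    if per_sample:
        data = table.data.where(table.data >= min_total, 0)
        return OtuTable(data.loc[:, data.sum(axis=0) > 0], validate=False)
    totals = table.data.sum(axis=0)
    return OtuTable(table.data.loc[:, totals >= min_total], validate=False)


def subsample(
    table: OtuTable,
    depth: int | None = None,
    seed: int | np.random.Generator | None = None,
    keep_zeros: bool = False,
) -> OtuTable:
    """Rarefy every sample to ``depth`` reads without replacement.

    ``depth=None`` uses the lowest per-sample depth in the table (the
    equal-depth convention for comparing samples). Each sample's counts are
    drawn from a multivariate hypergeometric distribution, i.e. reads are
    subsampled without replacement. OTUs left with zero total are dropped
    unless ``keep_zeros`` is set.
    """
    depths = table.depths()
    if depth is None:
        depth = int(depths.min())
    if depth < 1:
        raise OtuTableError(f"subsampling depth must be >= 1, got {depth}")
    shallow = depths[depths < depth]
    if len(shallow):
        sid = shallow.index[0]
        raise OtuTableError(
            f"depth {depth} exceeds depth of sample {sid!r} ({int(shallow.iloc[0])})"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = np.empty_like(table.counts)
    for i, row in enumerate(table.counts):
        rows[i] = rng.multivariate_hypergeometric(row, depth, method="count")
    out = OtuTable(pd.DataFrame(rows, index=table.data.index, columns=table.data.columns),
                   validate=False)
    return out if keep_zeros else out.drop_empty_otus()


def abundance_threshold(table: OtuTable, min_permille: float) -> OtuTable:
    """Zero counts at or below a within-sample relative abundance threshold.

    An OTU's count in a sample is kept only if its relative abundance is
    strictly greater than ``min_permille`` per mill of the sample's depth
    (so ``min_permille=0`` keeps every nonzero count). OTUs zeroed in every
    sample are dropped. Intended to be applied after equal-depth subsampling.
    """
    if min_permille < 0:
        raise OtuTableError(f"min_permille must be >= 0, got {min_permille}")
    depths = table.depths().to_numpy()[:, None]
    counts = table.counts
    # strict inequality on count/depth > min_permille/1000, in integer-exact form
    keep = counts * 1000.0 > min_permille * depths
    data = pd.DataFrame(np.where(keep, counts, 0), index=table.data.index,
                        columns=table.data.columns)
    return OtuTable(data, validate=False).drop_empty_otus()


def aggregate_by_rank(table: OtuTable, tax: TaxonomyMap, rank: str = "family") -> OtuTable:
    """Sum OTU columns into one column per taxon at ``rank``.

    OTUs missing from the taxonomy are bucketed as ``unclassified`` (with a
    warning); lineages that stop above ``rank`` go to
    ``unclassified_<deepest known taxon>``. The grand total is preserved.
    """
    if rank not in RANKS:
        raise OtuTableError(f"unknown rank {rank!r}; expected one of {RANKS}")
    unmapped = [o for o in table.otu_ids if o not in tax]
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} OTU(s) missing from taxonomy assigned to 'unclassified'",
            stacklevel=2,
        )
    labels = [tax.at_rank(o, rank) for o in table.otu_ids]
    grouped = table.data.T.groupby(pd.Index(labels, name=rank), sort=True).sum().T
    return OtuTable(grouped, validate=False)
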