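"""Community (OTU) tables and table-level transforms.

The central container is :class:`CommunityTable`: an OTU-by-sample count (or
relative-abundance) matrix with optional ranked taxonomy lineages.  On disk it
is the classic tab-delimited OTU table — first column ``#OTU ID``, one column
per sample, optional terminal ``taxonomy`` column holding a semicolon-separated
lineage.  Transforms implemented here are the standard table-level steps of a
16S workflow: rarefaction to even depth, conversion to relative abundance,
aggregation to a taxonomic rank, and the dominant-taxon / core-OTU screens used
to select taxa for downstream statistics.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CommunityTable",
    "RANKS",
    "rarefy",
    "relative_abundance",
    "aggregate_rank",
    "dominant_taxa",
    "core_otus",
]

#: Ranks of a standard 7-level lineage, in lineage order.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: Greengenes-style rank prefixes, by position.
_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")


class CommunityTable:
    """An OTUs-by-samples abundance matrix with optional taxonomy.

    Parameters
    ----------
    counts : pandas.DataFrame
        Rows indexed by OTU ID, columns by sample ID.  Values must be
        nonnegative and finite.
    taxonomy : mapping or pandas.Series, optional
        Maps OTU ID to a semicolon-separated ranked lineage string
        (e.g. ``"k__Bacteria; p__Proteobacteria; ...; f__Rhodobacteraceae"``).
        Keys must be a subset of the OTU IDs.
    """

    def __init__(self, counts: pd.DataFrame, taxonomy: Mapping[str, str] | pd.Series | None = None):
        counts = pd.DataFrame(counts)
        if counts.index.has_duplicates:
            raise ValueError("duplicate OTU IDs in table")
        if counts.columns.has_duplicates:
            raise ValueError("duplicate sample IDs in table")
        values = counts.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("table contains non-finite values")
        if (values < 0).any():
            raise ValueError("table contains negative abundances")
        counts.index = counts.index.astype(str)
        counts.columns = counts.columns.astype(str)
        counts.index.name = None
        counts.columns.name = None
        self.data = counts
        if taxonomy is not None:
            taxonomy = pd.Series(dict(taxonomy) if not isinstance(taxonomy, pd.Series) else taxonomy,
                                 dtype=str)
            taxonomy.index = taxonomy.index.astype(str)
            unknown = taxonomy.index.difference(counts.index)
            if len(unknown):
                raise ValueError(f"taxonomy refers to unknown OTUs: {list(unknown)[:5]}")
            taxonomy = taxonomy.reindex(counts.index)
        self.taxonomy = taxonomy

    # ---------------------------------------------------------------- basics
    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_otus(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def sample_sums(self) -> pd.Series:
        return self.data.sum(axis=0)

    def copy(self) -> "CommunityTable":
        tax = None if self.taxonomy is None else self.taxonomy.copy()
        return CommunityTable(self.data.copy(), tax)

    def select_otus(self, otu_ids: Sequence[str]) -> "CommunityTable":
        sub = self.data.loc[list(otu_ids)]
        tax = None if self.taxonomy is None else self.taxonomy.loc[list(otu_ids)]
        return CommunityTable(sub, tax)

    def select_samples(self, sample_ids: Sequence[str]) -> "CommunityTable":
        sub = self.data[list(sample_ids)]
        return CommunityTable(sub, self.taxonomy)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        tax = "with" if self.taxonomy is not None else "without"
        return f"<CommunityTable: {self.n_otus} OTUs x {self.n_samples} samples, {tax} taxonomy>"

    # ------------------------------------------------------------------- io
    @classmethod
    def from_tsv(cls, path) -> "CommunityTable":
        """Read a classic tab-delimited OTU table.

        The first column must be ``#OTU ID``; a terminal ``taxonomy`` column,
        if present, is split off into the taxonomy map.
        """
        frame = pd.read_csv(path, sep="\t", index_col=0, comment=None, dtype=str)
        frame.index.name = "#OTU ID"
        taxonomy = None
        cols = list(frame.columns)
        if cols and cols[-1].lower() == "taxonomy":
            taxonomy = frame[cols[-1]]
            frame = frame[cols[:-1]]
        counts = frame.astype(float)
        # preserve integer counts exactly when the file held integers
        as_int = counts.round()
        if np.allclose(counts.to_numpy(), as_int.to_numpy(), rtol=0, atol=0):
            counts = as_int.astype(np.int64)
        return cls(counts, taxonomy)

    def to_tsv(self, path) -> None:
        """Write the classic tab-delimited OTU table (round-trip exact)."""
        out = self.data.copy()
        out.index.name = "#OTU ID"
        if self.taxonomy is not None:
            out = out.assign(taxonomy=self.taxonomy.reindex(out.index).fillna(""))
        out.to_csv(path, sep="\t")


# --------------------------------------------------------------------------
# transforms
# --------------------------------------------------------------------------

def rarefy(table: CommunityTable, depth: int, seed: int, prune: bool = False) -> CommunityTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Each retained sample is a single uniform draw of ``depth`` individual
    reads from its observed reads (multivariate hypergeometric), the same
    semantics as QIIME's ``single_rarefaction``.  Samples whose total is
    below ``depth`` are dropped (reported via ``UserWarning`` and the
    ``dropped_samples`` attribute of the result).  All-zero OTU rows are
    retained unless ``prune`` is set.
    """
    if int(depth) != depth or depth <= 0:
        raise ValueError("rarefaction depth must be a positive integer")
    depth = int(depth)
    counts = table.data.to_numpy()
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("rarefaction requires an integer count table")
    counts = np.round(counts).astype(np.int64)
    totals = counts.sum(axis=0)
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if not keep.any():
        raise ValueError(f"all samples have fewer than {depth} reads")
    if dropped:
        warnings.warn(f"dropped {len(dropped)} sample(s) below depth {depth}: {dropped}",
                      UserWarning, stacklevel=2)
    rng = np.random.default_rng(seed)
    out = np.empty((counts.shape[0], int(keep.sum())), dtype=np.int64)
    for j, col in enumerate(np.flatnonzero(keep)):
        out[:, j] = rng.multivariate_hypergeometric(counts[:, col], depth)
    frame = pd.DataFrame(out, index=table.data.index,
                         columns=[s for s in table.sample_ids if s not in set(dropped)])
    result = CommunityTable(frame, table.taxonomy)
    if prune:
        nonzero = frame.index[frame.sum(axis=1) > 0]
        result = result.select_otus(list(nonzero))
    result.dropped_samples = dropped
    return result


def relative_abundance(table: CommunityTable) -> CommunityTable:
    """Convert counts to per-sample proportions (columns sum to 1)."""
    sums = table.data.sum(axis=0)
    zero = sums.index[sums == 0]
    if len(zero):
        raise ValueError(f"zero-sum sample(s): {list(zero)}")
    return CommunityTable(table.data / sums, table.taxonomy)


def _lineage_rank(lineage: str, rank: str) -> str:
    """Extract one rank label from a semicolon-separated lineage."""
    idx = RANKS.index(rank)
    prefix = _RANK_PREFIXES[idx]
    parts = [p.strip() for p in str(lineage).split(";")]
    # prefer prefix match; fall back to position
    for part in parts:
        if part.startswith(prefix) and len(part) > len(prefix):
            return part
    if idx < len(parts):
        label = parts[idx]
        if label and not label.endswith("__"):
            return label
    return "Unassigned"


def aggregate_rank(table: CommunityTable, rank: str) -> CommunityTable:
    """Sum OTU rows within identical labels at a taxonomic rank.

    OTUs whose lineage lacks the rank contribute to ``"Unassigned"``.  Column
    sums are conserved exactly.
    """
    if table.taxonomy is None:
        raise ValueError("table has no taxonomy; cannot aggregate by rank")
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    labels = table.taxonomy.fillna("").map(lambda s: _lineage_rank(s, rank))
    grouped = table.data.groupby(labels.to_numpy()).sum()
    grouped.index.name = rank
    return CommunityTable(grouped)


def dominant_taxa(table: CommunityTable, threshold: float = 0.01) -> list[str]:
    """Taxa whose mean relative abundance across samples is strictly > threshold.

    The table is converted to relative abundance internally if any column sum
    differs from 1.  Returned IDs are sorted by descending mean abundance.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    sums = table.data.sum(axis=0)
    rel = table if np.allclose(sums, 1.0) else relative_abundance(table)
    means = rel.data.mean(axis=1)
    hits = means[means > threshold].sort_values(ascending=False)
    return list(hits.index)


def core_otus(table: CommunityTable, min_prevalence: float = 0.5) -> CommunityTable:
    """Retain OTUs detected (count > 0) in strictly more than ``min_prevalence``
    of the samples ("core" taxa)."""
    if not (0 <= min_prevalence < 1):
        raise ValueError("min_prevalence must lie in [0, 1)")
    prevalence = (table.data > 0).mean(axis=1)
    keep = prevalence.index[prevalence > min_prevalence]
    return table.select_otus(list(keep))
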