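"""Reading, writing and rank-collapsing of OTU count tables.

The on-disk format is the QIIME "classic" tab-delimited OTU table: OTUs as
rows, samples as columns, first header cell ``#OTU ID``, and an optional
trailing ``taxonomy`` column holding a Greengenes-style lineage string.
In memory the table is oriented samples x OTUs (a :class:`pandas.DataFrame`
of non-negative integers) bundled with per-sample metadata (treatment group
and tank).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_RANKS",
    "Lineage",
    "TaxonomyMap",
    "OtuTable",
    "parse_greengenes_lineage",
    "read_otu_table",
    "write_otu_table",
    "read_sample_metadata",
    "collapse_to_rank",
]

#: Canonical taxonomic ranks, shallowest to deepest.
CANONICAL_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: Greengenes single-letter rank prefixes in canonical order.
_RANK_PREFIXES = ("k", "p", "c", "o", "f", "g", "s")
_PREFIX_TO_RANK = dict(zip(_RANK_PREFIXES, CANONICAL_RANKS))

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class Lineage:
    """An ordered Greengenes lineage; missing ranks are ``"unassigned"``."""

    ranks: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ranks) != len(CANONICAL_RANKS):
            raise ValueError(
                f"a lineage has {len(CANONICAL_RANKS)} ranks, got {len(self.ranks)}"
            )

    def __getitem__(self, rank: str) -> str:
        return self.ranks[CANONICAL_RANKS.index(rank)]

    def prefix(self, rank: str) -> tuple[str, ...]:
        """Names from kingdom down to (and including) ``rank``."""
        return self.ranks[: CANONICAL_RANKS.index(rank) + 1]

    def deepest_assigned(self) -> int:
        """Index of the deepest assigned rank, or -1 if fully unassigned."""
        idx = -1
        for i, name in enumerate(self.ranks):
            if name != UNASSIGNED:
                idx = i
        return idx

    def to_string(self) -> str:
        return "; ".join(
            f"{p}__{'' if n == UNASSIGNED else n}"
            for p, n in zip(_RANK_PREFIXES, self.ranks)
        )


def parse_greengenes_lineage(s: str) -> Lineage:
    """Parse a Greengenes lineage string like ``"k__Bacteria; p__Proteobacteria"``.

    Empty fields (``"s__"``) and absent trailing ranks parse to ``"unassigned"``.
    An unknown rank prefix raises :class:`ValueError`.
    """
    names = [UNASSIGNED] * len(CANONICAL_RANKS)
    tokens = [tok.strip() for tok in s.split(";") if tok.strip()]
    for tok in tokens:
        if "__" not in tok:
            raise ValueError(f"malformed lineage token {tok!r} (expected 'x__Name')")
        prefix, _, name = tok.partition("__")
        prefix = prefix.strip().lower()
        if prefix not in _PREFIX_TO_RANK:
            raise ValueError(f"unknown rank prefix {prefix!r} in token {tok!r}")
        idx = CANONICAL_RANKS.index(_PREFIX_TO_RANK[prefix])
        names[idx] = name.strip() or UNASSIGNED
    return Lineage(tuple(names))


class TaxonomyMap(dict):
    """Mapping of OTU id to :class:`Lineage`.

    ``orphans(table)`` reports mapped ids that are missing from a companion
    table, which usually signals an id mismatch between files.
    """

    def orphans(self, table: "OtuTable") -> set[str]:
        return set(self) - set(table.otu_ids)

    def lineage_string(self, otu_id: str) -> str:
        lin = self.get(otu_id)
        return lin.to_string() if lin is not None else ""


@dataclass
class OtuTable:
    """A samples x OTUs count matrix with per-sample group/tank metadata."""

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            raise ValueError("duplicate sample ids in count table")
        if counts.columns.has_duplicates:
            raise ValueError("duplicate OTU ids in count table")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be integers")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(counts.index) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)}")
        # keep metadata aligned and restricted to the samples present
        self.sample_meta = self.sample_meta.loc[counts.index]

    # -- convenience accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    @property
    def groups(self) -> pd.Series:
        return self.sample_meta["group"]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def select_samples(self, sample_ids: Iterable[str]) -> "OtuTable":
        ids = list(sample_ids)
        return OtuTable(self.counts.loc[ids].copy(), self.sample_meta.loc[ids].copy())

    def select_group(self, group: str) -> "OtuTable":
        keep = self.groups[self.groups == group].index
        if len(keep) == 0:
            raise KeyError(f"no samples in group {group!r}")
        return self.select_samples(keep)

    def select_otus(self, otu_ids: Iterable[str]) -> "OtuTable":
        return OtuTable(self.counts[list(otu_ids)].copy(), self.sample_meta.copy())

    def relative_abundance(self) -> pd.DataFrame:
        return self.counts.div(self.counts.sum(axis=1), axis=0)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read a 3-column TSV (sample_id, group, tank) into a metadata frame."""
    meta = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    cols = {c.lower().lstrip("#"): c for c in meta.columns}
    for required in ("sample_id", "group", "tank"):
        if required not in cols:
            raise ValueError(f"metadata file missing column {required!r}")
    meta = meta.rename(columns={v: k for k, v in cols.items()})
    return meta.set_index("sample_id")[["group", "tank"]]


def read_otu_table(
    path: str | Path,
    metadata: str | Path | pd.DataFrame,
    samples_as_rows: bool = False,
) -> tuple[OtuTable, TaxonomyMap]:
    """Read a QIIME-classic tab-delimited OTU table plus sample metadata.

    Parameters
    ----------
    path
        Tab-delimited table. Canonical dialect: OTUs as rows, ``#OTU ID``
        first header cell, optional trailing ``taxonomy`` column. With
        ``samples_as_rows=True`` the transposed dialect is accepted.
    metadata
        Path to a (sample_id, group, tank) TSV, or an equivalent frame
        indexed by sample id.

    Returns
    -------
    (OtuTable, TaxonomyMap)
        The taxonomy map is empty when the file carries no taxonomy column.
    """
    if not isinstance(metadata, pd.DataFrame):
        metadata = read_sample_metadata(metadata)

    raw = pd.read_csv(path, sep="\t", comment=None, skiprows=_qiime_comment_rows(path))
    first = raw.columns[0]
    raw = raw.set_index(first)
    raw.index = raw.index.astype(str)

    taxonomy = TaxonomyMap()
    tax_col = next((c for c in raw.columns if c.strip().lower() == "taxonomy"), None)
    if tax_col is not None:
        if samples_as_rows:
            raise ValueError("a taxonomy column is only valid with OTUs as rows")
        for otu_id, tax in raw[tax_col].items():
            if isinstance(tax, str) and tax.strip():
                taxonomy[str(otu_id)] = parse_greengenes_lineage(tax)
        raw = raw.drop(columns=[tax_col])

    counts = raw if samples_as_rows else raw.T
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    counts.index.name = None
    counts.columns.name = None
    counts = _coerce_integer_counts(counts)

    missing = set(counts.index) - set(metadata.index)
    if missing:
        raise ValueError(
            f"samples present in table but missing from metadata: {sorted(missing)}"
        )
    return OtuTable(counts, metadata.loc[counts.index].copy()), taxonomy


def _qiime_comment_rows(path: str | Path) -> list[int]:
    """Row indices of leading comment lines that are not the header itself.

    QIIME classic tables often start with '# Constructed from biom file'
    followed by the '#OTU ID' header line; only the former is skipped.
    """
    skip = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.startswith("#"):
                break
            if not line.startswith("#OTU ID"):
                skip.append(i)
            else:
                break
    return skip


def _coerce_integer_counts(counts: pd.DataFrame) -> pd.DataFrame:
    values = counts.to_numpy()
    numeric = np.asarray(values, dtype=float)
    if np.isnan(numeric).any():
        i, j = np.argwhere(np.isnan(numeric))[0]
        raise ValueError(
            f"non-numeric count at sample {counts.index[i]!r}, OTU {counts.columns[j]!r}"
        )
    rounded = np.rint(numeric)
    if not np.allclose(numeric, rounded, rtol=0, atol=0):
        i, j = np.argwhere(numeric != rounded)[0]
        raise ValueError(
            f"non-integer count {numeric[i, j]} at sample {counts.index[i]!r}, "
            f"OTU {counts.columns[j]!r}"
        )
    return pd.DataFrame(
        rounded.astype(np.int64), index=counts.index, columns=counts.columns
    )


def write_otu_table(
    table: OtuTable,
    path: str | Path,
    taxonomy: TaxonomyMap | None = None,
) -> None:
    """Write a table in the QIIME classic layout (OTUs as rows)."""
    out = table.counts.T.copy()
    out.index.name = "#OTU ID"
    if taxonomy:
        out["taxonomy"] = [taxonomy.lineage_string(o) for o in out.index]
    out.to_csv(path, sep="\t")


def write_sample_metadata(table: OtuTable, path: str | Path) -> None:
    meta = table.sample_meta.copy()
    meta.index.name = "sample_id"
    meta.to_csv(path, sep="\t")


def collapse_to_rank(
    table: OtuTable, taxonomy: Mapping[str, Lineage], rank: str
) -> OtuTable:
    """Sum OTU counts into phylotypes at a taxonomic rank.

    OTUs sharing the lineage prefix down to ``rank`` are pooled. OTUs
    unassigned at ``rank`` are pooled under their deepest assigned prefix, so
    unassigned genera from two different families never merge; OTUs with no
    taxonomy at all pool into a single ``unassigned`` phylotype. Total counts
    per sample are conserved.
    """
    if rank not in CANONICAL_RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {CANONICAL_RANKS}")
    rank_idx = CANONICAL_RANKS.index(rank)

    labels: dict[str, str] = {}
    for otu_id in table.otu_ids:
        lin = taxonomy.get(otu_id)
        if lin is None:
            labels[otu_id] = UNASSIGNED
            continue
        if lin.ranks[rank_idx] != UNASSIGNED:
            key = lin.ranks[: rank_idx + 1]
        else:
            # key on the full assigned prefix above `rank` to keep distinct
            # parents' unassigned children apart
            deepest = min(lin.deepest_assigned(), rank_idx)
            key = lin.ranks[: deepest + 1] + (UNASSIGNED,) if deepest >= 0 else (UNASSIGNED,)
        labels[otu_id] = ";".join(key)

    collapsed = table.counts.T.groupby(
        table.counts.columns.map(labels)
    ).sum().T.sort_index(axis=1)
    return OtuTable(collapsed, table.sample_meta.copy())
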