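"""Data model and I/O for OTU reports and sample metadata.

An OTU report is a flat tab-separated table with one row per operational
taxonomic unit (OTU).  Each row carries the OTU identifier, a six-rank
taxonomic lineage (domain, phylum, class, order, family, genus) and the
integer number of reads observed per sample.  Ranks below the deepest
confident classification hold the sentinel ``unclassified``; such OTUs are
kept as explicit bins so that they count toward sequencing depth without
polluting named-taxon tests.

Sample metadata is a second tab-separated table with columns ``sample_id``,
``soil``, ``treatment`` and ``replicate``; the soil x treatment combination
defines the comparison groups.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The six taxonomic ranks of a lineage, coarse to fine.
RANKS: tuple[str, ...] = ("domain", "phylum", "class", "order", "family", "genus")

#: Sentinel for ranks below the deepest confident classification.
UNCLASSIFIED = "unclassified"


class OtuReportFormatError(ValueError):
    """Raised when an OTU report or metadata file violates the format."""


class EmptySubsetError(KeyError):
    """Raised when a taxon subset matches no OTU (never a silent empty table)."""


class DegenerateSampleError(ValueError):
    """Raised when an operation meets a sample with zero reads."""


def _validate_lineage(values: Sequence[str], row_label: str) -> tuple[str, ...]:
    """Check the unclassified-suffix rule: once a rank is unclassified every
    finer rank must be unclassified too."""
    values = tuple(str(v).strip() for v in values)
    if len(values) != len(RANKS):
        raise OtuReportFormatError(
            f"OTU {row_label!r}: expected {len(RANKS)} ranks, got {len(values)}"
        )
    seen_unclassified = False
    for rank, value in zip(RANKS, values):
        if not value:
            raise OtuReportFormatError(f"OTU {row_label!r}: empty name at rank {rank!r}")
        if seen_unclassified and value != UNCLASSIFIED:
            raise OtuReportFormatError(
                f"OTU {row_label!r}: rank {rank!r} is classified ({value!r}) below an "
                f"unclassified ancestor"
            )
        if value == UNCLASSIFIED:
            seen_unclassified = True
    return values


@dataclass(frozen=True)
class Lineage:
    """Six-rank taxonomic lineage of one OTU."""

    domain: str
    phylum: str
    class_: str
    order: str
    family: str
    genus: str

    def __post_init__(self) -> None:
        _validate_lineage(self.as_tuple(), self.domain)

    def as_tuple(self) -> tuple[str, ...]:
        return (self.domain, self.phylum, self.class_, self.order, self.family, self.genus)

    def at(self, rank: str) -> str:
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return self.as_tuple()[RANKS.index(rank)]

    def prefix(self, rank: str) -> tuple[str, ...]:
        """Lineage truncated at (and including) `rank`."""
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return self.as_tuple()[: RANKS.index(rank) + 1]


def bin_label(prefix: Sequence[str]) -> str:
    """Human-readable name of a lineage prefix.

    Named taxa keep their own name; unclassified bins are labelled
    ``unclassified_<nearest classified ancestor>`` so that two unclassified
    genera under different families remain distinct, recognisable bins.
    """
    if prefix[-1] != UNCLASSIFIED:
        return prefix[-1]
    named = [p for p in prefix if p != UNCLASSIFIED]
    parent = named[-1] if named else "root"
    return f"{UNCLASSIFIED}_{parent}"


class OtuTable:
    """OTU x sample matrix of read counts with per-OTU lineages.

    Parameters
    ----------
    counts :
        Non-negative integer matrix, rows indexed by OTU id, columns by
        sample id.
    lineages :
        One row per OTU (same index as `counts`), columns exactly `RANKS`.
    """

    def __init__(self, counts: pd.DataFrame, lineages: pd.DataFrame) -> None:
        counts = counts.copy()
        lineages = lineages.copy()
        if list(lineages.columns) != list(RANKS):
            raise OtuReportFormatError(
                f"lineage columns must be {list(RANKS)}, got {list(lineages.columns)}"
            )
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise OtuReportFormatError(f"duplicate OTU ids: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise OtuReportFormatError(f"duplicate sample ids: {dups}")
        if not counts.index.equals(lineages.index):
            raise OtuReportFormatError("counts and lineages must share the same OTU index")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise OtuReportFormatError("counts must be numeric")
        if np.any(arr < 0) or np.any(arr != np.floor(arr)):
            bad = np.argwhere((arr < 0) | (arr != np.floor(arr)))[0]
            raise OtuReportFormatError(
                f"negative or non-integer count at OTU {counts.index[bad[0]]!r}, "
                f"sample {counts.columns[bad[1]]!r}"
            )
        counts = counts.astype(np.int64)
        empty = counts.sum(axis=1) == 0
        if empty.any():
            raise OtuReportFormatError(
                f"OTUs with zero reads in every sample: {counts.index[empty].tolist()}"
            )
        for otu_id, row in lineages.iterrows():
            _validate_lineage(row.tolist(), str(otu_id))
        self.counts = counts
        self.lineages = lineages.astype(str)

    # -- basic introspection -------------------------------------------------

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def depths(self) -> pd.Series:
        """Reads per sample (column sums)."""
        return self.counts.sum(axis=0)

    def lineage_of(self, otu_id: str) -> Lineage:
        row = self.lineages.loc[otu_id]
        return Lineage(*row.tolist())

    def __repr__(self) -> str:  # pragma: no cover
        return f"<OtuTable: {self.n_otus} OTUs x {self.n_samples} samples>"

    # -- operations ----------------------------------------------------------

    def aggregate_at_rank(self, rank: str) -> "OtuTable":
        """Sum counts over OTUs sharing the same lineage prefix up to `rank`.

        Unclassified prefixes under different parents stay distinct bins, so
        aggregation always conserves the per-sample read totals.
        """
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}; expected one of {RANKS}")
        upto = RANKS.index(rank) + 1
        prefix_cols = list(RANKS[:upto])
        keys = [tuple(row) for row in self.lineages[prefix_cols].itertuples(index=False)]
        order: list[tuple[str, ...]] = []
        seen: set[tuple[str, ...]] = set()
        for k in keys:
            if k not in seen:
                seen.add(k)
                order.append(k)
        grouped = self.counts.groupby(pd.Index(keys, tupleize_cols=False), sort=False).sum()
        grouped = grouped.loc[order]
        new_ids = [bin_label(k) for k in order]
        # disambiguate rare label clashes (same terminal name under two parents)
        counts_per_label: dict[str, int] = {}
        uniq_ids = []
        for lbl in new_ids:
            n = counts_per_label.get(lbl, 0)
            uniq_ids.append(lbl if n == 0 else f"{lbl}__{n}")
            counts_per_label[lbl] = n + 1
        lin_rows = [list(k) + [UNCLASSIFIED] * (len(RANKS) - upto) for k in order]
        new_counts = pd.DataFrame(grouped.to_numpy(), index=uniq_ids, columns=self.sample_ids)
        new_lineages = pd.DataFrame(lin_rows, index=uniq_ids, columns=list(RANKS))
        return OtuTable(new_counts, new_lineages)

    def subset_by_taxon(self, rank: str, name: str) -> "OtuTable":
        """Rows whose lineage matches `name` at `rank`; all samples retained.

        Raises
        ------
        EmptySubsetError
            If no OTU carries `name` at `rank` — an absent taxon is reported
            explicitly rather than returned as a silently empty table.
        """
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}; expected one of {RANKS}")
        mask = self.lineages[rank] == name
        if not mask.any():
            raise EmptySubsetError(f"no OTU has {name!r} at rank {rank!r}")
        return OtuTable(self.counts.loc[mask], self.lineages.loc[mask])

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample proportions; every column sums to one."""
        depths = self.depths()
        zero = depths[depths == 0]
        if len(zero):
            raise DegenerateSampleError(
                f"samples with zero reads: {zero.index.tolist()}"
            )
        return self.counts / depths


# -- I/O ----------------------------------------------------------------------

_HEADER = ("otu_id",) + RANKS


def read_otu_report(path: str | Path | io.TextIOBase) -> OtuTable:
    """Read a tab-separated OTU report.

    Dialect: UTF-8, ``#`` comment lines ignored; header row names the
    ``otu_id`` column, the six ranks, then one column per sample.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = [c.strip() for c in df.columns]
    if tuple(cols[: len(_HEADER)]) != _HEADER:
        raise OtuReportFormatError(
            f"header must start with {list(_HEADER)}, got {cols[: len(_HEADER)]}"
        )
    sample_cols = cols[len(_HEADER):]
    if not sample_cols:
        raise OtuReportFormatError("no sample columns found")
    df.columns = cols
    df = df.set_index("otu_id")
    lineages = df[list(RANKS)]
    raw = df[sample_cols]
    try:
        counts = raw.astype(np.int64)
    except ValueError:
        for col in sample_cols:
            bad = pd.to_numeric(raw[col], errors="coerce")
            nan = bad.isna()
            frac = (bad % 1 != 0) & ~nan
            if nan.any() or frac.any():
                row = raw.index[(nan | frac)][0]
                raise OtuReportFormatError(
                    f"non-integer count at OTU {row!r}, sample {col!r}: "
                    f"{raw.loc[row, col]!r}"
                ) from None
        raise
    neg = counts < 0
    if neg.to_numpy().any():
        r, c = np.argwhere(neg.to_numpy())[0]
        raise OtuReportFormatError(
            f"negative count at OTU {counts.index[r]!r}, sample {sample_cols[c]!r}"
        )
    return OtuTable(counts, lineages)


def write_otu_report(table: OtuTable, path: str | Path | io.TextIOBase) -> None:
    """Write the canonical tab-separated OTU report (inverse of
    :func:`read_otu_report` on canonical files)."""
    out = table.lineages.copy()
    out.insert(0, "otu_id", table.otu_ids)
    for s in table.sample_ids:
        out[s] = table.counts[s].to_numpy()
    out.to_csv(path, sep="\t", index=False)


# -- sample metadata -----------------------------------------------------------


@dataclass
class SampleGroups:
    """Experimental design: soil, treatment and replicate per sample.

    The derived ``group`` label is ``<soil>:<treatment>``; all group tests
    require at least two samples per group.
    """

    frame: pd.DataFrame = field(repr=False)

    CONTROL = "control"
    SPIKED = "spiked"

    def __post_init__(self) -> None:
        required = {"soil", "treatment", "replicate"}
        missing = required - set(self.frame.columns)
        if missing:
            raise OtuReportFormatError(f"metadata missing columns: {sorted(missing)}")
        if self.frame.index.has_duplicates:
            raise OtuReportFormatError("duplicate sample_id in metadata")
        bad = set(self.frame["treatment"]) - {self.CONTROL, self.SPIKED}
        if bad:
            raise OtuReportFormatError(
                f"treatment must be '{self.CONTROL}' or '{self.SPIKED}', got {sorted(bad)}"
            )
        self.frame = self.frame.copy()
        self.frame["group"] = self.frame["soil"] + ":" + self.frame["treatment"]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def soils(self) -> list[str]:
        return sorted(self.frame["soil"].unique())

    @property
    def groups(self) -> list[str]:
        return sorted(self.frame["group"].unique())

    def group_of(self, sample_id: str) -> str:
        return str(self.frame.loc[sample_id, "group"])

    def samples_in(self, group: str) -> list[str]:
        return list(self.frame.index[self.frame["group"] == group])

    def samples_for(self, soil: str, treatment: str) -> list[str]:
        mask = (self.frame["soil"] == soil) & (self.frame["treatment"] == treatment)
        return list(self.frame.index[mask])

    def check_samples(self, sample_ids: Iterable[str]) -> None:
        missing = set(sample_ids) - set(self.frame.index)
        if missing:
            raise OtuReportFormatError(f"samples without metadata: {sorted(missing)}")


def read_metadata(path: str | Path | io.TextIOBase) -> SampleGroups:
    """Read sample metadata (TSV: sample_id, soil, treatment, replicate)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise OtuReportFormatError("metadata must have a 'sample_id' column")
    return SampleGroups(df.set_index("sample_id"))


def write_metadata(groups: SampleGroups, path: str | Path | io.TextIOBase) -> None:
    out = groups.frame[["soil", "treatment", "replicate"]].copy()
    out.insert(0, "sample_id", groups.sample_ids)
    out.to_csv(path, sep="\t", index=False)
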