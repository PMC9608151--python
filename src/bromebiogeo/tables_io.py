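"""Data model and file I/O for ASV community tables.

The central object is :class:`CountTable`, an integer abundance matrix of
ASVs (rows) by samples (columns) together with a sample -> group mapping
(here a group is a forest type). Companion tables hold taxonomy lineages,
environmental measurements and per-sample relative abundances. All files
are plain TSV, UTF-8, with the conventions documented in each reader.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ENV_VARIABLES = ("temperature", "pH", "salinity", "DO", "IC", "OC", "N", "P")

OTHERS_LABEL = "others"


class TableFormatError(ValueError):
    """Raised when an input file violates the documented table format."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        raise TableFormatError(f"duplicate {what}: {dupes}")


@dataclass
class CountTable:
    """ASV x sample integer count matrix with optional sample grouping.

    ``counts`` is a pandas DataFrame indexed by ASV id with sample ids as
    columns; ``groups`` maps sample id -> group label and may be None when
    no group-wise operation is needed.
    """

    counts: pd.DataFrame
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        _check_unique(list(self.counts.index), "asv_id")
        _check_unique(list(self.counts.columns), "sample_id")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise TableFormatError("counts must be integral")
            self.counts = self.counts.round().astype(np.int64)
        if values.size and (self.counts.to_numpy() < 0).any():
            bad = np.argwhere(self.counts.to_numpy() < 0)[0]
            raise TableFormatError(
                f"negative count at ASV {self.counts.index[bad[0]]!r}, "
                f"sample {self.counts.columns[bad[1]]!r}"
            )
        if self.groups is not None:
            self.groups = pd.Series(self.groups)
            missing = [s for s in self.counts.columns if s not in self.groups.index]
            if missing:
                raise TableFormatError(f"samples without group label: {missing}")
            self.groups = self.groups.loc[list(self.counts.columns)]

    # -- convenience views -------------------------------------------------
    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def matrix(self) -> np.ndarray:
        """ASV x sample ndarray view of the counts."""
        return self.counts.to_numpy()

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def group_samples(self, group: str) -> list[str]:
        if self.groups is None:
            raise ValueError("count table has no group labels")
        if group not in set(self.groups):
            raise KeyError(f"unknown group {group!r}")
        return [s for s in self.sample_ids if self.groups[s] == group]

    def group_labels(self) -> list[str]:
        if self.groups is None:
            raise ValueError("count table has no group labels")
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.groups[s], None)
        return list(seen)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        groups = self.groups.loc[list(sample_ids)] if self.groups is not None else None
        return CountTable(self.counts[list(sample_ids)].copy(), groups)

    def presence(self) -> np.ndarray:
        """Boolean ASV x sample occupancy matrix."""
        return self.matrix > 0

    def occupied_asvs(self) -> list[str]:
        keep = self.presence().any(axis=1)
        return [a for a, k in zip(self.asv_ids, keep) if k]


@dataclass
class RelAbundTable:
    """Per-sample proportions with the same shape conventions as CountTable."""

    proportions: pd.DataFrame
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        sums = self.proportions.sum(axis=0).to_numpy()
        ok = np.isclose(sums, 1.0, atol=1e-9) | np.isclose(sums, 0.0, atol=1e-12)
        if not ok.all():
            bad = self.proportions.columns[~ok].tolist()
            raise TableFormatError(f"columns do not sum to 1 (or 0): {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.proportions.columns)


@dataclass
class TaxonomyTable:
    """ASV id -> lineage, a list of up to 7 rank names (domain..species)."""

    lineages: dict[str, list[str]]

    def __post_init__(self) -> None:
        for asv, lineage in self.lineages.items():
            if len(lineage) > 7:
                raise TableFormatError(f"lineage of {asv!r} has {len(lineage)} ranks (>7)")

    def lineage(self, asv_id: str) -> list[str]:
        return self.lineages.get(asv_id, [])


@dataclass
class EnvTable:
    """Sample x variable numeric table; missing values stay NaN, never 0."""

    values: pd.DataFrame  # samples as index, variables as columns

    def __post_init__(self) -> None:
        _check_unique(list(self.values.index), "sample_id")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    def complete_samples(self, variable: str) -> list[str]:
        col = self.values[variable]
        return list(col.index[col.notna()])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path, metadata: str | Path | None = None) -> CountTable:
    """Read an ASV x sample TSV (first header cell ``asv_id``).

    Cells must be non-negative integers; the row and column order of the
    file is preserved. ``metadata`` optionally points at a sample->group
    TSV (see :func:`read_metadata`).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        counts = df.apply(pd.to_numeric)
    except ValueError as exc:
        raise TableFormatError(f"{path}: non-numeric cell ({exc})") from exc
    arr = counts.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        bad = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
        raise TableFormatError(
            f"{path}: non-integer cell at row {counts.index[bad[0]]!r}, "
            f"column {counts.columns[bad[1]]!r}"
        )
    groups = read_metadata(metadata) if metadata is not None else None
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    return CountTable(counts.astype(np.int64), groups)


def write_count_table(t: CountTable, path: str | Path) -> None:
    out = t.counts.copy()
    out.index.name = "asv_id"
    out.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.Series:
    """Read a TSV with columns ``sample_id`` and ``group``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing column {col!r}")
    _check_unique(df["sample_id"].tolist(), "sample_id")
    return pd.Series(df["group"].to_numpy(), index=df["sample_id"], name="group")


def write_metadata(groups: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample_id": groups.index, "group": groups.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read a TSV with columns ``asv_id`` and semicolon-delimited ``lineage``."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("asv_id", "lineage"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing column {col!r}")
    _check_unique(df["asv_id"].tolist(), "asv_id")
    lineages = {
        row.asv_id: [r.strip() for r in row.lineage.split(";")] if row.lineage else []
        for row in df.itertuples()
    }
    return TaxonomyTable(lineages)


def write_taxonomy(tax: TaxonomyTable, path: str | Path) -> None:
    rows = [(asv, ";".join(lin)) for asv, lin in tax.lineages.items()]
    pd.DataFrame(rows, columns=["asv_id", "lineage"]).to_csv(path, sep="\t", index=False)


def read_env_table(path: str | Path) -> EnvTable:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return EnvTable(df.apply(pd.to_numeric))


def write_env_table(env: EnvTable, path: str | Path) -> None:
    out = env.values.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# filters and transforms
# ---------------------------------------------------------------------------

def filter_low_depth(t: CountTable, min_reads: int = 1000) -> CountTable:
    """Drop samples whose total read count is below ``min_reads``.

    Shallow amplicon libraries carry too little information to represent a
    community, so samples under the cutoff are discarded entirely. ASV rows
    that become all-zero afterwards are kept (so ASV indices stay stable
    across pipeline stages) and logged.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    sums = t.sample_sums()
    keep = [s for s in t.sample_ids if sums[s] >= min_reads]
    if not keep:
        raise ValueError(
            f"all samples fall below min_reads={min_reads}; lower the threshold"
        )
    dropped = [s for s in t.sample_ids if s not in set(keep)]
    if dropped:
        logger.info("filter_low_depth: discarded %d samples: %s", len(dropped), dropped)
    out = t.subset_samples(keep)
    n_zero = int((~out.presence().any(axis=1)).sum())
    if n_zero:
        logger.info("filter_low_depth: %d ASV rows are now all-zero (kept)", n_zero)
    return out


def to_relative(t: CountTable) -> RelAbundTable:
    """Normalise each sample column to proportions; zero columns stay zero."""
    sums = t.sample_sums().to_numpy().astype(float)
    zero = sums == 0
    if zero.any():
        logger.warning(
            "to_relative: zero-total samples left all-zero: %s",
            [s for s, z in zip(t.sample_ids, zero) if z],
        )
    safe = np.where(zero, 1.0, sums)
    props = t.counts.to_numpy() / safe
    df = pd.DataFrame(props, index=t.counts.index, columns=t.counts.columns)
    return RelAbundTable(df, t.groups)


def aggregate_at_rank(
    rel: RelAbundTable, tax: TaxonomyTable, rank: int, unknown_label: str = "unclassified"
) -> RelAbundTable:
    """Sum per-sample proportions over taxa sharing the name at ``rank``.

    ``rank`` is 0-based (0 = domain, 1 = phylum, ... 5 = genus). ASVs whose
    lineage is shorter than the rank, or empty at it, are pooled under
    ``unknown_label``.
    """
    names = []
    for asv in rel.proportions.index:
        lin = tax.lineage(asv)
        name = lin[rank] if rank < len(lin) and lin[rank] else unknown_label
        names.append(name)
    agg = rel.proportions.groupby(pd.Index(names, name="taxon"), sort=False).sum()
    return RelAbundTable(agg, rel.groups)


def collapse_rare(rel: RelAbundTable, threshold: float = 0.01) -> RelAbundTable:
    """Merge taxa whose dataset-wide mean proportion is below ``threshold``
    into a single ``others`` row; per-sample column sums are unchanged.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    means = rel.proportions.mean(axis=1)
    rare = means < threshold
    if not rare.any():
        return RelAbundTable(rel.proportions.copy(), rel.groups)
    kept = rel.proportions.loc[~rare]
    others = rel.proportions.loc[rare].sum(axis=0)
    out = pd.concat([kept, others.to_frame(OTHERS_LABEL).T])
    out.index.name = rel.proportions.index.name
    return RelAbundTable(out, rel.groups)
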