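"""Count-table containers, readers/writers, rank collapsing and rarefaction.

The canonical in-memory container is :class:`TaxonCountTable`, a thin
validated wrapper around a samples x taxa :class:`pandas.DataFrame` of
integer read counts.  On disk the convention is taxa as rows and samples as
columns (first column header ``taxon_id``), the layout most amplicon
pipelines emit, so the reader transposes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaxonCountTable",
    "TaxonomyMap",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "collapse_to_rank",
    "rarefy",
]

REQUIRED_METADATA_COLUMNS = ("sample_id", "group", "gi_site", "sample_type")


class TableValidationError(ValueError):
    """Raised when a count table violates its invariants."""


class TableParseError(ValueError):
    """Raised when an on-disk table cannot be parsed; names the offending cell."""


class TaxonCountTable:
    """Integer read counts per taxon per sample.

    Parameters
    ----------
    counts
        Samples x taxa matrix of non-negative integer read counts.  A
        DataFrame is used as-is (index = sample ids, columns = taxon ids);
        anything array-like is converted first.

    Notes
    -----
    ``read_depth`` is always the row sum; it is recomputed, never stored, so
    it cannot drift from the counts.  Taxa with all-zero counts are retained:
    they carry presence/absence information relative to other tables (e.g.
    blanks, replicate sets) and can be dropped explicitly with
    :meth:`drop_empty_taxa`.
    """

    def __init__(self, counts, *, validate: bool = True) -> None:
        frame = pd.DataFrame(counts)
        if validate:
            self._validate(frame)
        self.counts = frame.astype(np.int64)
        self.counts.index = self.counts.index.astype(str)
        self.counts.columns = self.counts.columns.astype(str)

    @staticmethod
    def _validate(frame: pd.DataFrame) -> None:
        if frame.index.has_duplicates:
            dupes = frame.index[frame.index.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate sample ids: {dupes}")
        if frame.columns.has_duplicates:
            dupes = frame.columns[frame.columns.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate taxon ids: {dupes}")
        values = frame.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise TableValidationError("counts must be numeric")
        if values.size:
            if np.any(~np.isfinite(values.astype(float))):
                raise TableValidationError("counts must be finite")
            if np.any(values < 0):
                rows, cols = np.nonzero(values < 0)
                raise TableValidationError(
                    "negative count at sample "
                    f"{frame.index[rows[0]]!r}, taxon {frame.columns[cols[0]]!r}"
                )
            if np.any(values != np.floor(values)):
                rows, cols = np.nonzero(values != np.floor(values))
                raise TableValidationError(
                    "non-integer count at sample "
                    f"{frame.index[rows[0]]!r}, taxon {frame.columns[cols[0]]!r}"
                )

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def read_depth(self) -> pd.Series:
        """Total reads per sample (row sums)."""
        return self.counts.sum(axis=1)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample proportions.  Zero-depth samples come back as all-zero
        rows; operations that cannot tolerate them (anchoring) check depth
        explicitly."""
        depth = self.read_depth.replace(0, np.nan)
        rel = self.counts.div(depth, axis=0)
        return rel.fillna(0.0)

    def subset_samples(self, sample_ids: Sequence[str]) -> "TaxonCountTable":
        missing = [s for s in sample_ids if s not in self.counts.index]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return TaxonCountTable(self.counts.loc[list(sample_ids)], validate=False)

    def drop_empty_taxa(self) -> "TaxonCountTable":
        keep = self.counts.columns[self.counts.sum(axis=0) > 0]
        return TaxonCountTable(self.counts[keep], validate=False)

    def equals(self, other: "TaxonCountTable") -> bool:
        return isinstance(other, TaxonCountTable) and self.counts.equals(other.counts)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, m = self.shape
        return f"TaxonCountTable({n} samples x {m} taxa)"


@dataclass(frozen=True)
class TaxonomyMap:
    """Lineage lookup used for rank collapsing.

    ``ranks`` is ordered coarse to fine (e.g. phylum ... genus); ``lineages``
    maps each taxon id to its labels per rank.  An empty/missing label means
    the rank is unnamed for that taxon, in which case :meth:`label_at` falls
    back to the nearest named ancestor, suffixed with its own rank letter so
    distinct ancestors never merge silently.
    """

    ranks: tuple[str, ...]
    lineages: Mapping[str, Mapping[str, str]] = field(default_factory=dict)

    def label_at(self, taxon_id: str, rank: str) -> str:
        if rank not in self.ranks:
            raise KeyError(f"unknown rank {rank!r}; known ranks: {self.ranks}")
        if taxon_id not in self.lineages:
            raise KeyError(f"taxon {taxon_id!r} not in taxonomy")
        lineage = self.lineages[taxon_id]
        idx = self.ranks.index(rank)
        for r in self.ranks[idx::-1]:
            label = lineage.get(r, "")
            if label:
                return label if r == rank else f"{label}({r[0]})"
        raise KeyError(f"taxon {taxon_id!r} has no named rank at or above {rank!r}")


def read_count_table(path, fmt: str = "tsv") -> TaxonCountTable:
    """Read a taxa-as-rows count table.

    ``fmt='tsv'`` expects a tab-separated matrix whose first column
    (header ``taxon_id``) holds taxon labels and remaining columns hold
    per-sample integer counts.  ``fmt='biom'`` requires the optional
    ``biom`` package.
    """
    if fmt == "biom":
        try:
            import biom  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "BIOM input requires the optional 'biom-format' package; "
                "convert to TSV or install it"
            ) from exc
        table = biom.load_table(str(path))  # pragma: no cover
        frame = table.to_dataframe(dense=True).T  # pragma: no cover
        return TaxonCountTable(frame)  # pragma: no cover
    if fmt != "tsv":
        raise ValueError(f"unknown format {fmt!r}; expected 'tsv' or 'biom'")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    parsed = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            taxon = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise TableParseError(
                f"non-numeric entry {raw.loc[taxon, col]!r} at taxon {taxon!r}, "
                f"sample {col!r} in {path}"
            )
        parsed[col] = converted
    return TaxonCountTable(parsed.T)


def write_count_table(table: TaxonCountTable, path) -> None:
    """Write taxa-as-rows TSV (first column header ``taxon_id``)."""
    out = table.counts.T
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata CSV.

    Requires columns ``sample_id, group, gi_site, sample_type``; optional
    ``subject_id`` and ``day`` pass through.  Blank samples
    (``sample_type == 'blank'``) carry no group.
    """
    meta = pd.read_csv(path, dtype=str)
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise TableValidationError(f"metadata missing required columns: {missing}")
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise TableValidationError(f"duplicate metadata rows for samples: {dupes}")
    blanks = meta["sample_type"] == "blank"
    meta.loc[blanks, "group"] = ""
    if "day" in meta.columns:
        meta["day"] = pd.to_numeric(meta["day"], errors="coerce")
    return meta.set_index("sample_id", drop=False)


def collapse_to_rank(
    table: TaxonCountTable, taxonomy: TaxonomyMap, rank: str
) -> TaxonCountTable:
    """Sum counts of taxa sharing a label at ``rank``.

    Taxa whose lineage is unknown raise, listing every offender, rather than
    silently vanishing from the totals; per-sample read depth is conserved.
    """
    unmapped = [t for t in table.taxon_ids if t not in taxonomy.lineages]
    if unmapped:
        raise KeyError(f"taxa missing from taxonomy: {unmapped}")
    labels = {t: taxonomy.label_at(t, rank) for t in table.taxon_ids}
    collapsed = table.counts.T.groupby(
        table.counts.columns.map(labels), sort=True
    ).sum()
    return TaxonCountTable(collapsed.T, validate=False)


def rarefy(
    table: TaxonCountTable,
    depth: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> TaxonCountTable:
    """Subsample every sample without replacement to a common depth.

    Draws are multivariate hypergeometric (the reads of one sample form a
    finite urn), so a taxon absent from a sample stays absent and row sums
    are exactly ``depth``.  ``depth`` defaults to the smallest per-sample
    read depth in the table.  A seed (or Generator) makes the draw
    reproducible.
    """
    depths = table.read_depth
    if depth is None:
        depth = int(depths.min())
    depth = int(depth)
    if depth < 0:
        raise ValueError("depth must be non-negative")
    shallow = depths[depths < depth]
    if not shallow.empty:
        raise ValueError(
            f"cannot rarefy to {depth}: samples with fewer reads: "
            f"{list(shallow.index)}"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rows = [
        rng.multivariate_hypergeometric(row, depth)
        for row in table.counts.to_numpy()
    ]
    out = pd.DataFrame(rows, index=table.counts.index, columns=table.counts.columns)
    return TaxonCountTable(out, validate=False)
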