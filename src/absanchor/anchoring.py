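"""Total microbial load from dPCR and anchoring of relative abundances.

The anchor is a per-sample total 16S rRNA gene copy load measured by digital
PCR on the same eluate that was sequenced:

    load [copies/g] = dPCR concentration [copies/uL eluate]
                      x elution volume [uL]
                      x (dead volume / extraction volume)
                      / sample mass [g]

The dead/extraction volume ratio corrects for loading only part of the
lysate on the extraction column (lysate produced / lysate loaded, >= 1).
Each taxon's absolute abundance is then its relative read abundance times
the sample's total load, so anchored loads sum to the total load exactly.

Relative abundances for anchoring are computed from the raw (unrarefied)
counts; rarefaction is reserved for beta-diversity distances where equal
depth matters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .tables_io import TaxonCountTable

__all__ = [
    "ExtractionRecord",
    "SampleLoad",
    "AbsoluteAbundanceTable",
    "PrecisionReport",
    "DPCRAnchor",
    "microbial_load",
    "anchor_absolute",
    "error_analysis",
    "read_dpcr_sheet",
    "write_abundance_table",
    "read_abundance_table",
]

#: two-sided 97.5% standard-normal quantile used in the fold-precision CI
Z_95 = 1.959964

DPCR_SHEET_COLUMNS = (
    "sample_id",
    "dpcr_conc_copies_per_ul",
    "elution_ul",
    "dead_ul",
    "loaded_ul",
    "mass_g",
)


@dataclass(frozen=True)
class ExtractionRecord:
    """One sample's dPCR/extraction bookkeeping (the load-equation inputs)."""

    sample_id: str
    dpcr_concentration: float  # 16S copies per uL of eluate
    elution_volume: float  # uL
    dead_volume: float  # uL lysate produced
    extraction_volume: float  # uL lysate loaded on the column
    sample_mass: float  # grams

    def __post_init__(self) -> None:
        if self.dpcr_concentration < 0:
            raise ValueError(f"{self.sample_id}: dPCR concentration must be >= 0")
        for name in ("elution_volume", "dead_volume", "extraction_volume", "sample_mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{self.sample_id}: {name} must be positive")
        if self.dead_volume < self.extraction_volume:
            raise ValueError(
                f"{self.sample_id}: dead_volume must be >= extraction_volume "
                "(cannot load more lysate than was produced)"
            )


@dataclass(frozen=True)
class SampleLoad:
    """Total 16S copies per gram of input sample."""

    sample_id: str
    total_load: float

    def __post_init__(self) -> None:
        if self.total_load < 0:
            raise ValueError(f"{self.sample_id}: total load must be >= 0")


class AbsoluteAbundanceTable:
    """Copies-per-gram matrix (samples x taxa) produced by anchoring."""

    def __init__(self, loads, *, validate: bool = True) -> None:
        frame = pd.DataFrame(loads, dtype=float)
        if validate and frame.size and (frame.to_numpy() < 0).any():
            raise ValueError("absolute abundances must be non-negative")
        self.loads = frame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.loads.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.loads.columns)

    @property
    def total_load(self) -> pd.Series:
        return self.loads.sum(axis=1)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, m = self.loads.shape
        return f"AbsoluteAbundanceTable({n} samples x {m} taxa)"


def microbial_load(record: ExtractionRecord) -> SampleLoad:
    """Evaluate the load equation for one sample, in copies per gram."""
    total = (
        record.dpcr_concentration
        * record.elution_volume
        * (record.dead_volume / record.extraction_volume)
        / record.sample_mass
    )
    return SampleLoad(record.sample_id, total)


def _as_load_series(loads) -> pd.Series:
    """Normalise the accepted load inputs to a Series indexed by sample id."""
    if isinstance(loads, pd.Series):
        return loads.astype(float)
    if isinstance(loads, Mapping):
        return pd.Series(loads, dtype=float)
    items = list(loads)
    if items and isinstance(items[0], ExtractionRecord):
        items = [microbial_load(r) for r in items]
    if items and isinstance(items[0], SampleLoad):
        return pd.Series({r.sample_id: r.total_load for r in items})
    raise TypeError(
        "loads must be a Series/mapping of sample_id -> copies/g, or a "
        "sequence of SampleLoad or ExtractionRecord"
    )


class DPCRAnchor(BaseEstimator, TransformerMixin):
    """Transformer turning read counts into absolute abundances.

    ``fit`` ingests the per-sample total loads (a mapping/Series of
    copies-per-gram, or SampleLoad / ExtractionRecord collections);
    ``transform`` multiplies each sample's relative abundances by its total
    load.  Row sums of the output equal the dPCR totals by construction.
    """

    def fit(self, loads, y=None) -> "DPCRAnchor":
        series = _as_load_series(loads)
        if series.index.has_duplicates:
            raise ValueError("duplicate sample ids in loads")
        if (series < 0).any():
            raise ValueError("total loads must be non-negative")
        self.total_load_ = series
        return self

    def transform(self, table: TaxonCountTable) -> AbsoluteAbundanceTable:
        if not hasattr(self, "total_load_"):
            raise RuntimeError("DPCRAnchor must be fit with loads before transform")
        missing = [s for s in table.sample_ids if s not in self.total_load_.index]
        if missing:
            raise KeyError(f"no dPCR load for samples: {missing}")
        depth = table.read_depth
        empty = depth[depth == 0]
        if not empty.empty:
            raise ValueError(
                f"zero read depth, cannot form relative abundances: "
                f"{list(empty.index)}"
            )
        rel = table.counts.div(depth, axis=0)
        loads = rel.mul(self.total_load_.loc[table.sample_ids], axis=0)
        return AbsoluteAbundanceTable(loads, validate=False)


def anchor_absolute(counts: TaxonCountTable, loads) -> AbsoluteAbundanceTable:
    """One-shot anchoring: ``DPCRAnchor().fit(loads).transform(counts)``."""
    return DPCRAnchor().fit(loads).transform(counts)


@dataclass(frozen=True)
class PrecisionReport:
    """Log2 measurement-error summary against taxon-specific truth.

    ``fold_precision`` is ``2**(z * sd)`` of the mean-centered log2 relative
    errors: the half-width, as a fold factor, of the 95% interval around a
    single measurement.  The mean log2 error captures any systematic
    per-taxon offset (reported, never corrected).
    """

    log2_errors: np.ndarray
    mean_log2_error: float
    centered_errors: np.ndarray
    sd: float
    shapiro_p: float
    fold_precision: float


def error_analysis(
    observed_loads: Sequence[float],
    true_loads: Sequence[float],
    z: float = Z_95,
) -> PrecisionReport:
    """Characterise measurement error of anchored loads against truth.

    Errors are ``log2(observed / true)``; they are mean-centered before the
    spread is summarised so a constant accuracy offset does not inflate the
    precision estimate.  Normality of the centered errors is screened with
    Shapiro-Wilk.  Requires >= 3 strictly positive pairs.
    """
    obs = np.asarray(observed_loads, dtype=float)
    true = np.asarray(true_loads, dtype=float)
    if obs.shape != true.shape:
        raise ValueError("observed and true loads must be paired (same length)")
    if obs.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.any(obs <= 0) or np.any(true <= 0):
        raise ValueError("loads must be strictly positive (log2 undefined at 0)")
    errors = np.log2(obs / true)
    mean = float(errors.mean())
    centered = errors - mean
    sd = float(centered.std(ddof=1))
    shapiro_p = float(stats.shapiro(centered).pvalue) if sd > 0 else 1.0
    return PrecisionReport(
        log2_errors=errors,
        mean_log2_error=mean,
        centered_errors=centered,
        sd=sd,
        shapiro_p=shapiro_p,
        fold_precision=float(2.0 ** (z * sd)),
    )


def fold_precision(sd: float, z: float = Z_95) -> float:
    """95% single-measurement precision, as a fold factor, from a log2-error sd."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    return float(2.0 ** (z * sd))


def read_dpcr_sheet(path) -> list[ExtractionRecord]:
    """Read the dPCR/extraction CSV (columns: sample_id, dpcr_conc_copies_per_ul,
    elution_ul, dead_ul, loaded_ul, mass_g)."""
    sheet = pd.read_csv(path)
    missing = [c for c in DPCR_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"dPCR sheet missing columns: {missing}")
    return [
        ExtractionRecord(
            sample_id=str(row.sample_id),
            dpcr_concentration=float(row.dpcr_conc_copies_per_ul),
            elution_volume=float(row.elution_ul),
            dead_volume=float(row.dead_ul),
            extraction_volume=float(row.loaded_ul),
            sample_mass=float(row.mass_g),
        )
        for row in sheet.itertuples(index=False)
    ]


def write_abundance_table(table: AbsoluteAbundanceTable, path) -> None:
    out = table.loads.T
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


def read_abundance_table(path) -> AbsoluteAbundanceTable:
    frame = pd.read_csv(path, sep="\t", index_col=0).T
    return AbsoluteAbundanceTable(frame)
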