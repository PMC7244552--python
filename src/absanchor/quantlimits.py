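"""Quantitative limits of amplicon sequencing.

Technical sequencing replicates of one specimen give a per-taxon coefficient
of variation (%CV) of relative abundance.  Plotted against mean relative
abundance, the cloud follows a power law ``%CV = a * x**(-b)`` whose
crossing with a chosen CV level (30% by default) defines the relative
abundance threshold below which measurements are no longer quantitative.
Poisson counting statistics set the theoretical floor: a taxon measured
from an expected ``lambda = N * p`` reads (or template copies) cannot have a
CV below ``100 / sqrt(lambda)`` percent.

The module also carries the detection-side bookkeeping: dropout and
contaminant flags from high- vs low-input library pairs, contaminants seen
in extraction blanks, bootstrap Poisson CV confidence bands, and the
per-gram lower limit of quantification implied by the minimum reliable
template input and the maximum extractable sample mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .tables_io import TaxonCountTable, rarefy

__all__ = [
    "CVPoint",
    "PoissonCIBand",
    "ThresholdFit",
    "ThresholdDepthResult",
    "LLOQResult",
    "PowerLawCVFit",
    "replicate_cv",
    "cv_table",
    "flag_dropouts_contaminants",
    "flag_blank_taxa",
    "poisson_ci_band",
    "fit_threshold",
    "threshold_vs_depth",
    "poisson_threshold",
    "expected_copies",
    "lloq_per_gram",
    "round_sig",
]


@dataclass(frozen=True)
class CVPoint:
    """Mean relative abundance (fraction) and %CV of one taxon across replicates."""

    taxon_id: str
    mean_rel_abundance: float
    cv_percent: float
    n_replicates: int


@dataclass(frozen=True)
class PoissonCIBand:
    """Bootstrap %CV band expected from Poisson counting alone."""

    grid: np.ndarray  # relative abundances (fractions)
    lower: np.ndarray  # 2.5th percentile %CV
    upper: np.ndarray  # 97.5th percentile %CV
    n_input: float  # read depth or template copy input
    n_boot: int
    poisson_sample_size: int


@dataclass(frozen=True)
class ThresholdFit:
    """Fitted %CV power law and the abundance threshold it implies.

    ``a`` and ``b`` parameterise ``%CV = a * x**(-b)`` with ``x`` the
    relative abundance in percent; ``threshold`` (percent) is where the
    fitted curve crosses ``cv_level``.
    """

    a: float
    b: float
    cv_level: float
    threshold: float
    read_depth: int | None = None
    n_points: int = 0


@dataclass(frozen=True)
class ThresholdDepthResult:
    """Threshold fits across subsampling depths plus the depth-scaling exponent.

    ``gamma[cv_level]`` is the exponent of ``threshold ~ depth**(-gamma)``
    (log-log least squares); ``None`` when fewer than two depths were fit.
    """

    fits: pd.DataFrame  # columns: read_depth, cv_level, a, b, threshold_percent
    gamma: dict[float, float | None] = field(default_factory=dict)


@dataclass(frozen=True)
class LLOQResult:
    """Per-gram lower limit of quantification."""

    input_copy_threshold: float
    max_mass: float
    lloq: float


# ---------------------------------------------------------------------------
# replicate %CV
# ---------------------------------------------------------------------------

def _replicates_as_table(replicates) -> TaxonCountTable:
    if isinstance(replicates, TaxonCountTable):
        return replicates
    tables = list(replicates)
    if not tables:
        raise ValueError("no replicate tables given")
    taxa = tables[0].taxon_ids
    for t in tables[1:]:
        if t.taxon_ids != taxa:
            raise ValueError("replicate tables have mismatched taxon sets")
    counts = pd.concat([t.counts for t in tables], axis=0)
    return TaxonCountTable(counts, validate=False)


def replicate_cv(replicates) -> list[CVPoint]:
    """Per-taxon mean relative abundance and %CV across technical replicates.

    ``replicates`` is a TaxonCountTable whose samples are the replicates of
    one specimen (or a sequence of tables over identical taxa, concatenated
    row-wise).  The sd uses ddof=1; taxa with zero reads in every replicate
    are omitted.
    """
    table = _replicates_as_table(replicates)
    if table.shape[0] < 2:
        raise ValueError("need at least 2 replicates to compute a CV")
    rel = table.relative_abundance()
    present = table.counts.sum(axis=0) > 0
    points = []
    for taxon in table.counts.columns[present]:
        vals = rel[taxon].to_numpy()
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        points.append(
            CVPoint(
                taxon_id=str(taxon),
                mean_rel_abundance=mean,
                cv_percent=100.0 * sd / mean,
                n_replicates=len(vals),
            )
        )
    return points


def cv_table(points: Iterable[CVPoint]) -> pd.DataFrame:
    """CVPoints as a DataFrame indexed by taxon."""
    rows = [
        (p.taxon_id, p.mean_rel_abundance, p.cv_percent, p.n_replicates)
        for p in points
    ]
    return pd.DataFrame(
        rows, columns=["taxon_id", "mean_rel_abundance", "cv_percent", "n_replicates"]
    ).set_index("taxon_id")


# ---------------------------------------------------------------------------
# detection bookkeeping
# ---------------------------------------------------------------------------

def _present_taxa(obj) -> set[str]:
    if isinstance(obj, TaxonCountTable):
        return {t for t, tot in obj.counts.sum(axis=0).items() if tot > 0}
    obj = list(obj)
    if obj and isinstance(obj[0], CVPoint):
        return {p.taxon_id for p in obj if p.mean_rel_abundance > 0}
    return set(map(str, obj))


def flag_dropouts_contaminants(high_input, low_input) -> tuple[list[str], list[str]]:
    """Partition taxa by presence in a high- vs low-DNA-input library pair.

    Dropouts are present only at high input (lost from the low-input
    library); contaminants are present only at low input (reagent-borne
    signal that surfaces when real template is scarce).  Taxa in both get
    neither flag.  Inputs may be count tables, CVPoint collections, or taxon
    id iterables.
    """
    high = _present_taxa(high_input)
    low = _present_taxa(low_input)
    return sorted(high - low), sorted(low - high)


def flag_blank_taxa(
    table: TaxonCountTable, blanks: TaxonCountTable | None
) -> pd.DataFrame:
    """Rank the experiment's taxa by their prevalence in negative-control blanks.

    Returns one row per taxon of ``table`` with the number of blanks it
    appears in, its total blank reads, and a ``flagged`` bool (present in at
    least one blank).  Rows are ordered by blank prevalence, then total
    blank reads, then taxon id, so the top rows are the most ubiquitous
    contaminants.  With no blanks the result is empty and a warning is
    raised.
    """
    columns = ["n_blanks_present", "blank_reads", "flagged"]
    if blanks is None or blanks.shape[0] == 0:
        warnings.warn("no blank samples supplied; cannot flag contaminants")
        return pd.DataFrame(columns=columns)
    shared = [t for t in table.taxon_ids if t in blanks.counts.columns]
    sub = blanks.counts[shared]
    out = pd.DataFrame(
        {
            "n_blanks_present": (sub > 0).sum(axis=0),
            "blank_reads": sub.sum(axis=0),
        }
    ).reindex(table.taxon_ids, fill_value=0)
    out["flagged"] = out["n_blanks_present"] > 0
    # prevalence desc, then blank reads desc, then lexical taxon id
    out = out.loc[
        sorted(
            out.index,
            key=lambda t: (-out.at[t, "n_blanks_present"], -out.at[t, "blank_reads"], t),
        )
    ]
    out.index.name = "taxon_id"
    return out


# ---------------------------------------------------------------------------
# Poisson floor
# ---------------------------------------------------------------------------

def default_abundance_grid(n: int = 50) -> np.ndarray:
    """Log-spaced relative abundances covering 1e-6..1."""
    return np.logspace(-6, 0, n)


def poisson_ci_band(
    N: float,
    n_boot: int = 10_000,
    poisson_sample_size: int = 4,
    grid: np.ndarray | None = None,
    seed: int | np.random.Generator | None = None,
) -> PoissonCIBand:
    """Bootstrap the %CV expected from Poisson counting at input ``N``.

    For each grid abundance ``p`` the expected count is ``lambda = p * N``;
    one bootstrap replicate draws ``poisson_sample_size`` Poisson(lambda)
    variates and records their %CV (sd/mean, ddof=1).  The band is the
    middle 95% (2.5th-97.5th percentile) over ``n_boot`` replicates.
    Replicates whose mean is zero leave the CV undefined and are dropped;
    grid points where every replicate is all-zero come back NaN with a
    warning, as do points with ``lambda == 0``.
    """
    if N <= 0:
        raise ValueError("N (read depth or copy input) must be positive")
    if grid is None:
        grid = default_abundance_grid()
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < 0) or np.any(grid > 1):
        raise ValueError("grid abundances must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lower = np.full(grid.shape, np.nan)
    upper = np.full(grid.shape, np.nan)
    for i, p in enumerate(grid):
        lam = p * N
        if lam == 0:
            warnings.warn(f"grid point {p} gives rate 0; CV undefined, skipped")
            continue
        draws = rng.poisson(lam, size=(n_boot, poisson_sample_size))
        means = draws.mean(axis=1)
        sds = draws.std(axis=1, ddof=1)
        valid = means > 0
        if not valid.any():
            warnings.warn(f"grid point {p}: all bootstrap replicates empty; skipped")
            continue
        cvs = 100.0 * sds[valid] / means[valid]
        lower[i], upper[i] = np.percentile(cvs, [2.5, 97.5])
    return PoissonCIBand(
        grid=grid,
        lower=lower,
        upper=upper,
        n_input=float(N),
        n_boot=n_boot,
        poisson_sample_size=poisson_sample_size,
    )


def poisson_threshold(cv_level: float, N: float) -> float:
    """Theoretical relative-abundance threshold (percent) at a CV level.

    The Poisson CV at expected count ``lambda = N*p`` is ``1/sqrt(lambda)``,
    so the abundance where it equals ``cv_level`` percent is
    ``p = (100/cv_level)**2 / N``, returned in percent.
    """
    if cv_level <= 0 or N <= 0:
        raise ValueError("cv_level and N must be positive")
    return 100.0 / ((cv_level / 100.0) ** 2 * N)


def expected_copies(rel_abundance: float, N: float, rounded: bool = False) -> float:
    """Expected reads (or template copies) behind a relative abundance."""
    if not 0 <= rel_abundance <= 1:
        raise ValueError("rel_abundance must be a fraction in [0, 1]")
    value = rel_abundance * N
    return float(np.rint(value)) if rounded else float(value)


# ---------------------------------------------------------------------------
# power-law threshold fit
# ---------------------------------------------------------------------------

class PowerLawCVFit(BaseEstimator):
    """Least-squares power law ``y = a * x**(-b)`` fit in log-log space.

    Used with ``x`` = mean relative abundance in percent and ``y`` = %CV.
    Points with non-positive x or y cannot enter the log fit and are
    excluded.  Fitted attributes: ``a_``, ``b_``, ``n_points_``.
    """

    def fit(self, x, y) -> "PowerLawCVFit":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("x and y must have the same length")
        keep = (x > 0) & (y > 0)
        if not keep.any() and y.size:
            raise ValueError("no variation to fit: all CV values are zero")
        x, y = x[keep], y[keep]
        if x.size < 3:
            raise ValueError("need at least 3 positive points to fit the power law")
        slope, intercept = np.polyfit(np.log(x), np.log(y), 1)
        self.a_ = float(np.exp(intercept))
        self.b_ = float(-slope)
        self.n_points_ = int(x.size)
        return self

    def predict(self, x) -> np.ndarray:
        return self.a_ * np.asarray(x, dtype=float) ** (-self.b_)

    def threshold(self, cv_level: float) -> float:
        """Abundance (same units as x) where the fitted curve crosses ``cv_level``."""
        if cv_level <= 0:
            raise ValueError("cv_level must be positive")
        return float((self.a_ / cv_level) ** (1.0 / self.b_))


def fit_threshold(
    points: Iterable[CVPoint],
    cv_level: float = 30.0,
    read_depth: int | None = None,
    exclude_taxa: Iterable[str] = (),
) -> ThresholdFit:
    """Fit the replicate %CV power law and locate the quantitation threshold.

    ``exclude_taxa`` removes e.g. flagged contaminants before fitting.
    Abundances enter the fit in percent, so the returned threshold is a
    percent relative abundance.
    """
    excluded = set(exclude_taxa)
    pts = [p for p in points if p.taxon_id not in excluded]
    x = np.array([100.0 * p.mean_rel_abundance for p in pts])
    y = np.array([p.cv_percent for p in pts])
    model = PowerLawCVFit().fit(x, y)
    return ThresholdFit(
        a=model.a_,
        b=model.b_,
        cv_level=float(cv_level),
        threshold=model.threshold(cv_level),
        read_depth=read_depth,
        n_points=model.n_points_,
    )


def threshold_vs_depth(
    replicates,
    depths: Sequence[int],
    cv_levels: Sequence[float] = (30.0, 40.0, 50.0),
    seed: int | np.random.Generator | None = None,
    exclude_taxa: Iterable[str] = (),
) -> ThresholdDepthResult:
    """Re-derive abundance thresholds after subsampling replicates to each depth.

    Each replicate is rarefied (without replacement) to every requested
    depth, the per-taxon %CV points are recomputed, and the power law is
    refit per CV level.  With two or more depths the scaling exponent
    ``gamma`` of ``threshold ~ depth**(-gamma)`` is estimated per CV level
    by log-log least squares.
    """
    table = _replicates_as_table(replicates)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for depth in sorted(set(int(d) for d in depths), reverse=True):
        sub = rarefy(table, depth, seed=rng)
        points = replicate_cv(sub)
        for level in cv_levels:
            fit = fit_threshold(points, cv_level=level, read_depth=depth,
                                exclude_taxa=exclude_taxa)
            rows.append((depth, float(level), fit.a, fit.b, fit.threshold))
    fits = pd.DataFrame(
        rows, columns=["read_depth", "cv_level", "a", "b", "threshold_percent"]
    )
    gamma: dict[float, float | None] = {}
    for level in cv_levels:
        sub = fits[fits["cv_level"] == float(level)]
        if len(sub) < 2:
            gamma[float(level)] = None
        else:
            slope, _ = np.polyfit(
                np.log(sub["read_depth"]), np.log(sub["threshold_percent"]), 1
            )
            gamma[float(level)] = float(-slope)
    return ThresholdDepthResult(fits=fits, gamma=gamma)


# ---------------------------------------------------------------------------
# LLOQ per gram
# ---------------------------------------------------------------------------

def round_sig(x: float, sig_figs: int) -> float:
    """Round-half-up to ``sig_figs`` significant figures.

    Values are first canonicalised to 12 significant digits so binary
    floating-point residue (e.g. ``8.3e4 / 0.2 -> 414999.99999999994``)
    does not flip a half-up boundary.
    """
    if sig_figs < 1:
        raise ValueError("sig_figs must be >= 1")
    if x == 0:
        return 0.0
    d = Decimal(f"{x:.12g}")
    quantum = Decimal(1).scaleb(d.adjusted() - sig_figs + 1)
    return float(d.quantize(quantum, rounding=ROUND_HALF_UP))


def lloq_per_gram(
    input_copy_threshold: float,
    max_mass: float,
    sig_figs: int | None = None,
) -> LLOQResult:
    """Lower limit of quantification in copies per gram.

    ``input_copy_threshold`` is the smallest total 16S copy input that
    extracts reliably; ``max_mass`` the largest mass (g) the extraction
    column tolerates.  Their ratio is the smallest per-gram load that can be
    quantified.  ``sig_figs`` applies half-up significant-figure rounding
    for reporting.
    """
    if input_copy_threshold <= 0 or max_mass <= 0:
        raise ValueError("input_copy_threshold and max_mass must be positive")
    lloq = input_copy_threshold / max_mass
    if sig_figs is not None:
        lloq = round_sig(lloq, sig_figs)
    return LLOQResult(
        input_copy_threshold=float(input_copy_threshold),
        max_mass=float(max_mass),
        lloq=float(lloq),
    )
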