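"""Differential abundance on absolute (or relative) tables.

The workflow mirrors standard practice for small-cohort microbiome
comparisons: a prevalence filter, a per-taxon Kruskal-Wallis rank test,
Benjamini-Hochberg control of the false-discovery rate, and log2 fold
changes of the group mean loads.  Because ranks are scale-invariant within
a sample set, running the same test on relative and on anchored absolute
values can disagree whenever total loads differ between groups - the
``pvalue_comparison`` table makes that disagreement explicit.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .tables_io import TaxonCountTable

__all__ = [
    "KruskalBHDifferential",
    "prevalence_filter",
    "kruskal_bh",
    "differential_table",
    "fold_change",
    "pvalue_comparison",
    "volcano_table",
]


def prevalence_filter(
    table: TaxonCountTable,
    groups: Mapping[str, Sequence[str]],
    min_count: int = 4,
    min_fraction: float | None = None,
) -> list[str]:
    """Taxa present (>=1 read) in enough samples of at least one group.

    The default keeps a taxon if some group has it in >= ``min_count``
    samples (the 4-of-6 rule for n=6 cohorts); pass ``min_fraction`` instead
    for unequal group sizes.
    """
    kept = []
    for taxon in table.taxon_ids:
        for samples in groups.values():
            present = int((table.counts.loc[list(samples), taxon] >= 1).sum())
            need = (
                min_count
                if min_fraction is None
                else int(np.ceil(min_fraction * len(samples)))
            )
            if present >= need:
                kept.append(taxon)
                break
    return kept


def _kruskal_h(values: np.ndarray, sizes: Sequence[int]) -> float:
    """Tie-corrected Kruskal-Wallis H for pooled ``values`` split by ``sizes``."""
    n = len(values)
    ranks = stats.rankdata(values)
    h = 0.0
    start = 0
    for size in sizes:
        r = ranks[start : start + size].sum()
        h += r * r / size
        start += size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie if tie > 0 else 0.0


def _exact_two_group_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact permutation p-value for the two-group Kruskal-Wallis statistic.

    Enumerates every split of the pooled values into groups of the observed
    sizes and reports the fraction with H at least as large as observed.
    Feasible for small cohorts only (the enumeration is C(n, n_a)).
    """
    from itertools import combinations

    pooled = np.concatenate([a, b])
    n = len(pooled)
    h_obs = _kruskal_h(pooled, [len(a), len(b)])
    count = total = 0
    idx = np.arange(n)
    for chosen in combinations(range(n), len(a)):
        rest = np.setdiff1d(idx, chosen, assume_unique=True)
        h = _kruskal_h(np.concatenate([pooled[list(chosen)], pooled[rest]]),
                       [len(a), len(b)])
        count += h >= h_obs - 1e-12
        total += 1
    return count / total


class KruskalBHDifferential(BaseEstimator):
    """Per-feature Kruskal-Wallis tests with Benjamini-Hochberg correction.

    Parameters
    ----------
    fdr_level
        q-value cutoff for the ``significant`` call (default 0.1, i.e. a
        10% false-discovery rate).
    method
        ``'chi2'`` (default) uses the standard chi-square approximation for
        the H statistic (df = n_groups - 1); ``'exact'`` computes the exact
        permutation p-value by enumerating group assignments, available for
        two groups with at most 16 pooled samples - preferable when n per
        group is tiny and the chi-square tail is unreliable.

    After ``fit(X, y)`` - ``X`` a samples x features frame of loads (or
    relative abundances) and ``y`` the group label per sample - the
    ``results_`` frame holds per feature the tie-corrected H statistic, the
    p-value, the BH q-value, and a ``constant`` flag for features identical
    in every sample (p = 1 by convention: ranks carry no information).
    """

    def __init__(self, fdr_level: float = 0.1, method: str = "chi2") -> None:
        self.fdr_level = fdr_level
        self.method = method

    def fit(self, X, y) -> "KruskalBHDifferential":
        X = pd.DataFrame(X)
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError("y must give one group label per sample (row of X)")
        labels, counts = np.unique(y, return_counts=True)
        if len(labels) < 2:
            raise ValueError("need at least 2 groups")
        if (counts < 2).any():
            small = labels[counts < 2].tolist()
            raise ValueError(f"groups with fewer than 2 samples: {small}")
        if self.method not in ("chi2", "exact"):
            raise ValueError("method must be 'chi2' or 'exact'")
        if self.method == "exact" and (len(labels) != 2 or counts.sum() > 16):
            raise ValueError(
                "exact permutation p-values are limited to 2 groups with "
                "at most 16 pooled samples"
            )
        rows = []
        for feature in X.columns:
            values = [X.loc[y == g, feature].to_numpy(dtype=float) for g in labels]
            flat = np.concatenate(values)
            if np.all(flat == flat[0]):
                rows.append((feature, 0.0, 1.0, True))
                continue
            h, p = stats.kruskal(*values)
            if self.method == "exact":
                p = _exact_two_group_p(values[0], values[1])
            rows.append((feature, float(h), float(p), False))
        results = pd.DataFrame(
            rows, columns=["feature", "H", "p_value", "constant"]
        ).set_index("feature")
        results["q_value"] = multipletests(
            results["p_value"].to_numpy(), method="fdr_bh"
        )[1]
        results["significant"] = results["q_value"] < self.fdr_level
        self.groups_ = list(map(str, labels))
        self.results_ = results
        return self


def kruskal_bh(
    values_by_taxon, groups, fdr_level: float = 0.1
) -> pd.DataFrame:
    """Functional form of :class:`KruskalBHDifferential`; returns ``results_``."""
    return KruskalBHDifferential(fdr_level=fdr_level).fit(values_by_taxon, groups).results_


def fold_change(loads_a, loads_b) -> float:
    """log2 ratio of arithmetic group means (negative = lower in group A).

    Arithmetic means of copies/g are used - the quantity of interest is the
    average load, not the average log load.  When only one mean is zero the
    ratio is infinite and the taxon belongs in the presence/absence class
    rather than on a fold-change axis; both means zero is an error.
    """
    mean_a = float(np.mean(np.asarray(loads_a, dtype=float)))
    mean_b = float(np.mean(np.asarray(loads_b, dtype=float)))
    if mean_a == 0 and mean_b == 0:
        raise ValueError("fold change undefined: both group means are zero")
    if mean_b == 0:
        return float("inf")
    if mean_a == 0:
        return float("-inf")
    return float(np.log2(mean_a / mean_b))


def differential_table(
    values: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    fdr_level: float = 0.1,
    taxa: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Two-group differential records: fold change + Kruskal-Wallis + BH.

    ``values`` is samples x taxa (loads or relative abundances); ``groups``
    maps exactly two labels to sample ids.  ``taxa`` restricts the tested
    set (e.g. after a prevalence filter); BH correction runs across exactly
    the taxa tested here, so callers analysing several body sites should
    call this once per site.
    """
    if len(groups) != 2:
        raise ValueError("differential_table compares exactly two groups")
    (label_a, samples_a), (label_b, samples_b) = groups.items()
    if taxa is not None:
        values = values[list(taxa)]
    sub = values.loc[list(samples_a) + list(samples_b)]
    y = np.array([label_a] * len(samples_a) + [label_b] * len(samples_b))
    results = kruskal_bh(sub, y, fdr_level=fdr_level)
    mean_a = values.loc[list(samples_a)].mean(axis=0)
    mean_b = values.loc[list(samples_b)].mean(axis=0)
    log2fc = []
    for taxon in results.index:
        a, b = mean_a[taxon], mean_b[taxon]
        if a == 0 and b == 0:
            log2fc.append(np.nan)
        elif a == 0 or b == 0:
            log2fc.append(np.inf if b == 0 else -np.inf)
        else:
            log2fc.append(np.log2(a / b))
    out = results.copy()
    out.insert(0, "log2_fold_change", log2fc)
    out[f"mean_{label_a}"] = mean_a[results.index]
    out[f"mean_{label_b}"] = mean_b[results.index]
    out.index.name = "taxon_id"
    out.attrs["groups"] = (label_a, label_b)
    out.attrs["fdr_level"] = fdr_level
    return out


def pvalue_comparison(
    relative_records: pd.DataFrame,
    absolute_records: pd.DataFrame,
    discordance_threshold: float = 2.5,
) -> pd.DataFrame:
    """Pair relative- and absolute-analysis p-values per taxon.

    Both inputs need a ``p_value`` column indexed by taxon.  The output
    carries ``-log10 p`` for each analysis plus a ``discordant`` flag where
    ``|log10(p_rel / p_abs)|`` exceeds ``discordance_threshold`` - taxa for
    which the two analyses tell materially different stories.  Taxa missing
    from either side are skipped with a warning.
    """
    shared = relative_records.index.intersection(absolute_records.index)
    missing = relative_records.index.symmetric_difference(absolute_records.index)
    if len(missing):
        warnings.warn(f"taxa missing from one analysis, skipped: {list(missing)}")
    p_rel = relative_records.loc[shared, "p_value"].astype(float)
    p_abs = absolute_records.loc[shared, "p_value"].astype(float)
    log_ratio = np.log10(p_rel / p_abs)
    out = pd.DataFrame(
        {
            "neg_log10_p_relative": -np.log10(p_rel),
            "neg_log10_p_absolute": -np.log10(p_abs),
            "log10_p_ratio": log_ratio,
            "discordant": np.abs(log_ratio) > discordance_threshold,
        },
        index=shared,
    )
    out.index.name = "taxon_id"
    return out


def volcano_table(records: pd.DataFrame, fdr_level: float | None = None) -> pd.DataFrame:
    """Plot-ready volcano columns from a differential table.

    x = log2 fold change, y = -log10 q, point size = log10 of the larger
    group mean load, plus the horizontal position of the FDR line.
    """
    if fdr_level is None:
        fdr_level = float(records.attrs.get("fdr_level", 0.1))
    label_a, label_b = records.attrs.get(
        "groups",
        tuple(c.removeprefix("mean_") for c in records.columns if c.startswith("mean_"))[:2],
    )
    larger_mean = records[[f"mean_{label_a}", f"mean_{label_b}"]].max(axis=1)
    with np.errstate(divide="ignore"):
        size = np.log10(larger_mean.to_numpy(dtype=float))
    out = pd.DataFrame(
        {
            "log2_fold_change": records["log2_fold_change"],
            "neg_log10_q": -np.log10(records["q_value"].to_numpy(dtype=float)),
            "point_size": size,
            "fdr_line": -np.log10(fdr_level),
        },
        index=records.index,
    )
    out.index.name = "taxon_id"
    return out
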