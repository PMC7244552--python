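"""Compositional transforms, ordination, and correlation networks.

Relative read counts are compositional: only ratios between components are
meaningful.  The centered log-ratio (CLR) transform,

    clr(x) = [log(x_1 / G(x)), ..., log(x_D / G(x))],   G(x) = (prod x_i)^(1/D),

maps a composition onto a zero-sum real vector on which ordinary Euclidean
geometry applies; the Euclidean distance between CLR vectors is the
Aitchison distance.  Because CLR is invariant to per-sample rescaling, the
same distances come out of relative and anchored-absolute versions of the
same samples - anchoring matters for ordination only through the log
transform applied to absolute loads instead.

Natural logarithms are used throughout.  A pseudocount (1 read by default)
makes zero counts transformable; for absolute data the scale-consistent
equivalent is one read's worth of load, ``total_load / read_depth``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .anchoring import AbsoluteAbundanceTable
from .tables_io import TaxonCountTable

__all__ = [
    "CLRTransform",
    "PCAWithLoadings",
    "CorrelationNetwork",
    "clr_transform",
    "log_abs_transform",
    "absolute_pseudocount",
    "aitchison_distance",
    "aitchison_distance_matrix",
    "bray_curtis_matrix",
    "pcoa",
    "taxon_impact",
    "spearman_network",
]


def _as_matrix(X) -> tuple[np.ndarray, pd.Index | None, pd.Index | None]:
    if isinstance(X, TaxonCountTable):
        frame = X.counts
    elif isinstance(X, AbsoluteAbundanceTable):
        frame = X.loads
    elif isinstance(X, pd.DataFrame):
        frame = X
    else:
        arr = np.asarray(X, dtype=float)
        return arr, None, None
    return frame.to_numpy(dtype=float), frame.index, frame.columns


def _wrap(values: np.ndarray, index, columns):
    if index is None:
        return values
    return pd.DataFrame(values, index=index, columns=columns)


class CLRTransform(BaseEstimator, TransformerMixin):
    """Centered log-ratio transform with a pseudocount.

    ``pseudocount`` may be a scalar (added to every entry; 1 read by
    default) or a per-sample vector (used when the input is on the absolute
    scale and the pseudocount must stay worth one read).  Output rows sum to
    zero.  An all-zero sample transforms to a valid all-zero row (uniform
    after the pseudocount) but is flagged with a warning.
    """

    def __init__(self, pseudocount=1.0) -> None:
        self.pseudocount = pseudocount

    def fit(self, X, y=None) -> "CLRTransform":
        arr, _, _ = _as_matrix(X)
        self.n_features_in_ = arr.shape[1]
        return self

    def transform(self, X):
        arr, index, columns = _as_matrix(X)
        if np.any(arr < 0):
            raise ValueError("compositional data must be non-negative")
        zero_rows = ~arr.any(axis=1)
        pc = np.asarray(self.pseudocount, dtype=float)
        if pc.ndim == 1:
            arr = arr + pc[:, None]
        else:
            arr = arr + pc
        if np.any(arr <= 0):
            raise ValueError(
                "zeros remain after pseudocount; use a positive pseudocount"
            )
        if zero_rows.any():
            warnings.warn(
                f"{int(zero_rows.sum())} sample(s) are uniform after the "
                "pseudocount (all-zero input); their CLR rows are all zero"
            )
        logs = np.log(arr)
        out = logs - logs.mean(axis=1, keepdims=True)
        return _wrap(out, index, columns)


def clr_transform(X, pseudocount=1.0):
    """Functional CLR (see :class:`CLRTransform`)."""
    return CLRTransform(pseudocount=pseudocount).fit(X).transform(X)


def absolute_pseudocount(total_load, read_depth) -> np.ndarray:
    """Per-sample pseudocount worth one read on the copies-per-gram scale.

    Adding ``total_load / read_depth`` to absolute loads is exactly
    equivalent to adding 1 read before anchoring, which keeps CLR output -
    and hence Aitchison distances - identical between the relative and
    absolute branches of an analysis.
    """
    return np.asarray(total_load, dtype=float) / np.asarray(read_depth, dtype=float)


def log_abs_transform(X, pseudocount=1.0):
    """Elementwise natural log of absolute loads after a pseudocount.

    The log tames the heteroscedasticity of load data spanning many orders
    of magnitude; unlike CLR it preserves between-sample scale differences,
    which is the point of working on absolute abundances.
    """
    arr, index, columns = _as_matrix(X)
    if np.any(arr < 0):
        raise ValueError("absolute loads must be non-negative")
    pc = np.asarray(pseudocount, dtype=float)
    arr = arr + (pc[:, None] if pc.ndim == 1 else pc)
    if np.any(arr <= 0):
        raise ValueError("zeros remain after pseudocount; use a positive pseudocount")
    return _wrap(np.log(arr), index, columns)


def aitchison_distance(sample_i, sample_j, pseudocount: float = 0.0) -> float:
    """Euclidean distance between the CLR vectors of two compositions."""
    x = np.asarray(sample_i, dtype=float)
    y = np.asarray(sample_j, dtype=float)
    if x.shape != y.shape:
        raise ValueError("samples must have the same number of components")
    clr = CLRTransform(pseudocount=pseudocount)
    pair = clr.fit(np.vstack([x, y])).transform(np.vstack([x, y]))
    return float(np.linalg.norm(pair[0] - pair[1]))


def aitchison_distance_matrix(X, pseudocount: float = 1.0) -> pd.DataFrame:
    """All-pairs Aitchison distances (square form)."""
    arr, index, _ = _as_matrix(X)
    clr = clr_transform(arr, pseudocount=pseudocount)
    d = squareform(pdist(clr, metric="euclidean"))
    if index is None:
        index = pd.RangeIndex(arr.shape[0])
    return pd.DataFrame(d, index=index, columns=index)


def bray_curtis_matrix(X) -> pd.DataFrame:
    """All-pairs Bray-Curtis dissimilarities, for comparison on rarefied
    relative data (non-Euclidean; pair with PCoA, not PCA)."""
    arr, index, _ = _as_matrix(X)
    d = squareform(pdist(arr, metric="braycurtis"))
    if index is None:
        index = pd.RangeIndex(arr.shape[0])
    return pd.DataFrame(d, index=index, columns=index)


def pcoa(distance_matrix: pd.DataFrame, n_axes: int = 2):
    """Principal coordinates analysis (classical MDS) of a distance matrix.

    Delegates to scikit-bio; returns (scores DataFrame, eigenvalues array).
    """
    from skbio import DistanceMatrix
    from skbio.stats.ordination import pcoa as _skbio_pcoa

    dm = DistanceMatrix(distance_matrix.to_numpy(), ids=[str(i) for i in distance_matrix.index])
    result = _skbio_pcoa(dm, number_of_dimensions=n_axes)
    scores = result.samples.iloc[:, :n_axes]
    scores.index = distance_matrix.index
    return scores, result.eigvals.to_numpy()[:n_axes]


class PCAWithLoadings(BaseEstimator, TransformerMixin):
    """PCA via eigendecomposition of the sample covariance, with loadings.

    Feature loadings are each eigenvector scaled by the square root of its
    eigenvalue - the covariance between feature and principal component -
    so ``loadings_ @ loadings_.T`` reconstructs the covariance matrix in
    the full-rank case.  Eigenvector signs are fixed by making each
    vector's largest-magnitude entry positive, giving deterministic output.

    Fitted attributes: ``mean_``, ``eigenvalues_`` (descending),
    ``components_`` (n_components x n_features), ``loadings_``
    (n_features x n_components DataFrame when the input carries labels).
    """

    def fit(self, X, y=None) -> "PCAWithLoadings":
        arr, index, columns = _as_matrix(X)
        n, m = arr.shape
        if n < 2:
            raise ValueError("PCA needs at least 2 samples")
        if m < 2:
            raise ValueError("PCA needs at least 2 features")
        self.mean_ = arr.mean(axis=0)
        centered = arr - self.mean_
        cov = centered.T @ centered / (n - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
        # deterministic sign: largest-|entry| of each eigenvector positive
        flip = np.sign(evecs[np.abs(evecs).argmax(axis=0), np.arange(m)])
        flip[flip == 0] = 1.0
        evecs = evecs * flip
        self.eigenvalues_ = evals
        self.components_ = evecs.T
        loadings = evecs * np.sqrt(evals)
        if columns is not None:
            loadings = pd.DataFrame(
                loadings, index=columns,
                columns=[f"PC{i + 1}" for i in range(m)],
            )
        self.loadings_ = loadings
        self.feature_names_ = columns
        return self

    def transform(self, X):
        arr, index, _ = _as_matrix(X)
        scores = (arr - self.mean_) @ self.components_.T
        if index is not None:
            scores = pd.DataFrame(
                scores, index=index,
                columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
            )
        return scores


def pca_with_loadings(X) -> PCAWithLoadings:
    """Fit :class:`PCAWithLoadings` on a (transformed) samples x taxa matrix."""
    return PCAWithLoadings().fit(X)


def taxon_impact(loadings, n_components: int = 2, method: str = "norm") -> pd.Series:
    """Overall impact of each taxon on the leading principal-component plane.

    ``method='norm'`` (default) takes the Euclidean magnitude of each
    taxon's (PC1, PC2) loading vector - the length of the summed loading
    vectors; ``method='abs_sum'`` sums absolute loadings instead.  Accepts a
    fitted :class:`PCAWithLoadings` or a loadings matrix.
    """
    if isinstance(loadings, PCAWithLoadings):
        loadings = loadings.loadings_
    frame = pd.DataFrame(loadings)
    if frame.shape[1] < n_components:
        raise ValueError(f"need at least {n_components} components")
    block = frame.iloc[:, :n_components].to_numpy(dtype=float)
    if method == "norm":
        impact = np.linalg.norm(block, axis=1)
    elif method == "abs_sum":
        impact = np.abs(block).sum(axis=1)
    else:
        raise ValueError("method must be 'norm' or 'abs_sum'")
    return pd.Series(impact, index=frame.index, name="taxon_impact")


@dataclass(frozen=True)
class CorrelationNetwork:
    """Spearman co-abundance network over the dominant taxa."""

    features: list[str]
    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    edges: pd.DataFrame  # feature_i, feature_j, rho, p_value, q_value at q < fdr
    fdr: float


def spearman_network(
    abs_table: AbsoluteAbundanceTable,
    top_k: int = 30,
    include_total_load: bool = True,
    fdr: float = 0.1,
) -> CorrelationNetwork:
    """Spearman correlations among the top-k most abundant taxa (+ total load).

    Taxa are ranked by mean absolute load; all pairwise rank correlations
    among the selected features (optionally including the per-sample total
    load) are tested, BH-corrected across the pair set, and thresholded at
    ``q < fdr`` to form the edge list.  Constant features have undefined
    rank correlations; their entries stay NaN and they form no edges.
    """
    loads = abs_table.loads
    if loads.shape[0] < 4:
        raise ValueError("need at least 4 samples for a rank-correlation network")
    order = loads.mean(axis=0).sort_values(ascending=False)
    features = list(order.index[: min(top_k, len(order))])
    data = loads[features].copy()
    if include_total_load:
        data["total_load"] = abs_table.total_load
    names = list(data.columns)
    k = len(names)
    rho = np.eye(k)
    pmat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            xi = data.iloc[:, i].to_numpy(dtype=float)
            xj = data.iloc[:, j].to_numpy(dtype=float)
            if np.all(xi == xi[0]) or np.all(xj == xj[0]):
                rho[i, j] = rho[j, i] = np.nan
                pmat[i, j] = pmat[j, i] = np.nan
                continue
            r, p = stats.spearmanr(xi, xj)
            rho[i, j] = rho[j, i] = r
            pmat[i, j] = pmat[j, i] = p
    iu = np.triu_indices(k, 1)
    pvals = pmat[iu]
    qmat = np.full_like(pmat, np.nan)
    finite = np.isfinite(pvals)
    if finite.any():
        qvals = np.full(pvals.shape, np.nan)
        qvals[finite] = multipletests(pvals[finite], method="fdr_bh")[1]
        qmat[iu] = qvals
        qmat[(iu[1], iu[0])] = qvals
    np.fill_diagonal(qmat, 0.0)
    edges = []
    for a, b in zip(*iu):
        q = qmat[a, b]
        if np.isfinite(q) and q < fdr:
            edges.append((names[a], names[b], rho[a, b], pmat[a, b], q))
    edge_frame = pd.DataFrame(
        edges, columns=["feature_i", "feature_j", "rho", "p_value", "q_value"]
    )
    idx = pd.Index(names, name="feature")
    return CorrelationNetwork(
        features=names,
        rho=pd.DataFrame(rho, index=idx, columns=names),
        p=pd.DataFrame(pmat, index=idx, columns=names),
        q=pd.DataFrame(qmat, index=idx, columns=names),
        edges=edge_frame,
        fdr=fdr,
    )
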