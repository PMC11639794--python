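"""Inter-tissue similarity: Pearson correlation, PCA and sample dendrogram.

Tissues (columns) are the observations.  By default both the correlation
matrix and the PCA operate on log2(TPM + 1) values, which stabilises the
variance of TPM data; a raw-scale mode is available via the ``log`` flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix

__all__ = ["PcaResult", "Dendrogram", "pearson_matrix", "pca", "hclust_samples"]


def pearson_matrix(m: ExpressionMatrix, log: bool = True) -> pd.DataFrame:
    """Pairwise Pearson correlation between tissue columns.

    Zero-variance tissues yield NaN rows/columns and a warning; the diagonal
    is exactly 1 for well-defined tissues.
    """
    if m.n_genes < 2:
        raise ValueError("need at least 2 genes for a correlation")
    X = np.log2(m.values + 1.0) if log else m.values
    sd = X.std(axis=0)
    degenerate = [t for t, s in zip(m.tissue_labels, sd) if s == 0]
    if degenerate:
        warnings.warn(
            f"pearson_matrix: zero-variance tissue(s) {degenerate}; "
            "their correlations are undefined (NaN)",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    ok = sd > 0
    np.fill_diagonal(corr, np.where(ok, 1.0, np.nan))
    return pd.DataFrame(corr, index=m.tissue_labels, columns=m.tissue_labels)


@dataclass
class PcaResult:
    """PCA of tissues-as-observations.

    ``scores`` holds the component scores per tissue (tissues x components);
    ``variance_explained`` the percentage of variance per component,
    non-increasing and summing to 100.
    """

    scores: pd.DataFrame
    variance_explained: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(m: ExpressionMatrix, log: bool = True) -> PcaResult:
    """Singular-value PCA of the tissue x gene matrix with genes centered."""
    if m.n_tissues < 2:
        raise ValueError("need at least 2 tissues")
    X = (np.log2(m.values + 1.0) if log else m.values).T  # tissues x genes
    X = X - X.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    total = float(np.sum(s**2))
    n_comp = min(m.n_tissues, m.n_genes)
    if total == 0:
        warnings.warn("pca: matrix has no variance across tissues", stacklevel=2)
        var = np.zeros(n_comp)
        scores = np.zeros((m.n_tissues, n_comp))
    else:
        var = s**2 / total * 100.0
        scores = u * s
    rank = int(np.sum(s > s[0] * 1e-12)) if total else 0
    if rank < 2:
        warnings.warn(
            "pca: fewer than 2 non-degenerate dimensions; partial result",
            stacklevel=2,
        )
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PcaResult(
        scores=pd.DataFrame(scores, index=m.tissue_labels, columns=cols),
        variance_explained=np.asarray(var, dtype=float),
    )


@dataclass
class Dendrogram:
    """Average-linkage merge tree over samples.

    ``merges`` is a scipy linkage matrix: each row (a, b, height, size)
    merges clusters ``a`` and ``b`` (ids < n are leaves in ``labels``
    order).  Deterministic given the input correlation matrix.
    """

    merges: np.ndarray = field(repr=False)
    labels: list[str]

    def to_newick(self) -> str:
        """Serialise the tree as a Newick string with branch lengths."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        node = {i: self.labels[i] for i in range(n)}
        for i, (a, b, h, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            la = f"{node[a]}:{h - height[a]:.6g}"
            lb = f"{node[b]}:{h - height[b]:.6g}"
            node[n + i] = f"({la},{lb})"
            height[n + i] = float(h)
        return node[n + len(self.merges) - 1] + ";"


def hclust_samples(corr: pd.DataFrame) -> Dendrogram:
    """Average-linkage agglomeration of samples on distance 1 - r."""
    values = corr.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("correlation matrix has undefined entries")
    if not np.allclose(values, values.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    dist = 1.0 - values
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    return Dendrogram(merges=Z, labels=list(corr.index))
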