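"""K-means clustering of expression profiles with three optimal-k criteria.

The number of clusters is chosen by consensus of

* the **elbow** of the within-cluster sum-of-squares (WSS) curve, located
  deterministically as the k with maximum perpendicular distance from the
  (axis-normalised) WSS curve to the chord joining its endpoints;
* the mean **silhouette** width (maximised over k >= 2);
* the **gap statistic** of Tibshirani et al., with reference datasets drawn
  uniformly from the data's principal-axis-aligned bounding box, choosing
  the smallest k with ``Gap(k) >= Gap(k+1) - se(k+1)``.

Consensus is the majority of the three; when all three disagree the
silhouette's choice wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .io import ExpressionMatrix

__all__ = ["KMeansResult", "OptimalKReport", "kmeans", "optimal_k", "cluster_hkg_profiles"]


@dataclass
class KMeansResult:
    """Best-of-restarts Lloyd's clustering of a point set."""

    assignments: np.ndarray
    centroids: np.ndarray = field(repr=False)
    wss: float
    seed: int
    n_init: int

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


def kmeans(data, k: int, seed: int = 0, n_init: int = 10) -> KMeansResult:
    """Lloyd's algorithm with greedy spread-out (k-means++) seeding.

    Runs ``n_init`` restarts and keeps the solution with the lowest total
    within-cluster sum of squares; deterministic given the seed.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    return KMeansResult(
        assignments=labels,
        centroids=km.cluster_centers_,
        wss=float(km.inertia_),
        seed=seed,
        n_init=n_init,
    )


def _elbow_k(ks: np.ndarray, wss: np.ndarray) -> int:
    """k of maximum perpendicular distance to the chord of the WSS curve.

    Both axes are normalised to [0, 1] first so the criterion is invariant
    to the scale of the data.
    """
    x = (ks - ks[0]) / max(ks[-1] - ks[0], 1)
    span = wss[0] - wss[-1]
    y = (wss - wss[-1]) / span if span > 0 else np.zeros_like(wss)
    # distance from (x, y) to the chord joining (0, y0) and (1, y_last)
    x0, y0, x1, y1 = x[0], y[0], x[-1], y[-1]
    num = np.abs((y1 - y0) * x - (x1 - x0) * y + x1 * y0 - y1 * x0)
    den = np.hypot(y1 - y0, x1 - x0)
    dist = num / den if den > 0 else np.zeros_like(x)
    return int(ks[int(np.argmax(dist))])


def _gap_reference(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniform sample over the PCA-aligned bounding box of the data."""
    mean = X.mean(axis=0)
    Xc = X - mean
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    proj = Xc @ vt.T
    lo, hi = proj.min(axis=0), proj.max(axis=0)
    unif = rng.uniform(lo, hi, size=proj.shape)
    return unif @ vt + mean


@dataclass
class OptimalKReport:
    """Per-k diagnostics and the per-criterion / consensus choices."""

    table: pd.DataFrame
    chosen_k: dict[str, int]
    consensus_k: int


def optimal_k(
    data,
    k_range=range(1, 9),
    seed: int = 0,
    gap_B: int = 50,
    n_init: int = 10,
) -> OptimalKReport:
    """Evaluate elbow, silhouette and gap criteria over ``k_range``."""
    X = np.asarray(data, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    ks = np.asarray(sorted(set(int(k) for k in k_range)))
    n = X.shape[0]
    if len(ks) < 3:
        raise ValueError("k_range must contain at least 3 values")
    if ks[0] < 1 or ks[-1] >= n:
        raise ValueError(f"k_range must lie within [1, {n - 1}]")

    if np.allclose(X, X[0]):
        warnings.warn("optimal_k: all points identical; consensus k = 1", stacklevel=2)
        table = pd.DataFrame(
            {"k": ks, "wss": 0.0, "silhouette": np.nan, "gap": np.nan, "gap_se": np.nan}
        ).set_index("k")
        return OptimalKReport(table, {"elbow": 1, "silhouette": 1, "gap": 1}, 1)

    rng = np.random.default_rng(seed)
    wss = np.empty(len(ks))
    sil = np.full(len(ks), np.nan)
    log_w = np.empty(len(ks))
    for i, k in enumerate(ks):
        res = kmeans(X, k, seed=seed, n_init=n_init)
        wss[i] = res.wss
        log_w[i] = np.log(max(res.wss, 1e-300))
        if 2 <= k < n:
            sil[i] = silhouette_score(X, res.assignments)

    # gap statistic against B uniform reference draws in the PCA box
    ref_log_w = np.empty((gap_B, len(ks)))
    for b in range(gap_B):
        ref = _gap_reference(X, rng)
        ref_seed = int(rng.integers(0, 2**31 - 1))
        for i, k in enumerate(ks):
            res = kmeans(ref, k, seed=ref_seed, n_init=max(2, n_init // 3))
            ref_log_w[b, i] = np.log(max(res.wss, 1e-300))
    gap = ref_log_w.mean(axis=0) - log_w
    gap_se = ref_log_w.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / gap_B)

    elbow_k = _elbow_k(ks, wss)
    sil_k = int(ks[int(np.nanargmax(sil))]) if np.isfinite(sil).any() else int(ks[0])
    gap_k = int(ks[-1])
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - gap_se[i + 1]:
            gap_k = int(ks[i])
            break

    chosen = {"elbow": elbow_k, "silhouette": sil_k, "gap": gap_k}
    votes = pd.Series(list(chosen.values())).value_counts()
    consensus = int(votes.index[0]) if votes.iloc[0] >= 2 else sil_k

    table = pd.DataFrame(
        {"k": ks, "wss": wss, "silhouette": sil, "gap": gap, "gap_se": gap_se}
    ).set_index("k")
    return OptimalKReport(table=table, chosen_k=chosen, consensus_k=consensus)


def cluster_hkg_profiles(
    m: ExpressionMatrix,
    hkg_ids,
    k: int,
    seed: int = 0,
    n_init: int = 10,
) -> tuple[KMeansResult, pd.DataFrame]:
    """Cluster housekeeping-gene expression profiles.

    Rows are log2(TPM + 1)-transformed and z-scored per gene before
    clustering, so clusters reflect profile shape on a comparable scale.
    Returns the clustering plus a per-cluster summary (size and mean
    log2 expression) ordered by descending mean expression, as in reports
    where "cluster 1" is the most highly expressed.
    """
    hkg_ids = list(hkg_ids)
    sub = m.subset(hkg_ids)
    if k > len(hkg_ids):
        raise ValueError(f"k={k} exceeds the {len(hkg_ids)} housekeeping genes")
    log_x = np.log2(sub.values + 1.0)
    sd = log_x.std(axis=1, keepdims=True)
    z = (log_x - log_x.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
    res = kmeans(z, k, seed=seed, n_init=n_init)
    rows = []
    for cid in range(k):
        mask = res.assignments == cid
        rows.append(
            {
                "cluster": cid,
                "size": int(mask.sum()),
                "mean_log2_tpm": float(log_x[mask].mean()) if mask.any() else float("nan"),
            }
        )
    summary = (
        pd.DataFrame(rows)
        .sort_values("mean_log2_tpm", ascending=False)
        .reset_index(drop=True)
    )
    summary.index = pd.RangeIndex(1, k + 1, name="rank")
    return res, summary
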