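"""Tissue-specificity statistics and the 2-of-3 voting classifier.

Three per-gene statistics, each in [0, 1] with 0 = perfectly uniform and
1 = single-tissue expression:

* **tau** — the canonical tissue-specificity index,
  ``sum_i (1 - x_i / max(x)) / (n - 1)``;
* **Gini** — the inequality coefficient of the expression vector,
  rescaled by ``n / (n - 1)`` so that single-tissue expression scores
  exactly 1 and the three indicators share a common scale;
* **counts** — ``(n - m) / (n - 1)`` where ``m`` is the number of tissues
  expressing the gene at or above a TPM threshold (default 1).

A gene is called tissue-specific (TSG) when at least two of the three
indicators strictly exceed the high threshold (default 0.8), and
housekeeping (HKG) when at least two fall strictly below the low threshold
(default 0.2).  With three indicators and low < high, no gene can receive
two high votes and two low votes, so the TSG and HKG sets are provably
disjoint.  All statistics are computed on raw TPM (an optional log2
pre-transform is available but off by default).

The module also provides the coefficient-of-variation triage (quartile
variability bands) and the TPM abundance bands used to characterise
housekeeping expression.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "tau",
    "gini",
    "counts_score",
    "score_matrix",
    "classify",
    "assign_tsg_tissue",
    "coefficient_of_variation",
    "variability_bands",
    "tpm_bands",
]

TSG = "TSG"
HKG = "HKG"
UNCLASSIFIED = "UNCLASSIFIED"


def _as_vector(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("expected a 1-D expression vector over >= 2 tissues")
    if not np.isfinite(x).all() or (x < 0).any():
        raise ValueError("expression values must be finite and non-negative")
    return x


def tau(x) -> float:
    """Tissue-specificity index; NaN for an all-zero vector.

    Scale-invariant: tau(c * x) == tau(x) for any c > 0.
    """
    x = _as_vector(x)
    mx = x.max()
    if mx == 0:
        return float("nan")
    return float(np.sum(1.0 - x / mx) / (x.size - 1))


def gini(x) -> float:
    """Rescaled Gini coefficient; NaN for an all-zero vector.

    The raw Gini ``sum_ij |x_i - x_j| / (2 n^2 mean)`` maxes out at
    (n-1)/n for a single-tissue vector; the ``n/(n-1)`` rescale maps that
    case to exactly 1.  The result is clamped to [0, 1].
    """
    x = _as_vector(x)
    if x.max() == 0:
        return float("nan")
    n = x.size
    xs = np.sort(x)
    # sum_ij |x_i - x_j| = 2 * sum_k (2k - n - 1) x_(k), k = 1..n ascending
    weights = 2.0 * np.arange(1, n + 1) - n - 1
    raw = float(weights @ xs) / (n * n * xs.mean())
    return float(np.clip(raw * n / (n - 1), 0.0, 1.0))


def counts_score(x, threshold: float = 1.0) -> float:
    """Counts-based specificity; NaN when no tissue reaches the threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    x = _as_vector(x)
    n = x.size
    m = int(np.sum(x >= threshold))
    if m == 0:
        return float("nan")
    return float((n - m) / (n - 1))


def score_matrix(m: ExpressionMatrix, threshold: float = 1.0, log: bool = False) -> pd.DataFrame:
    """Compute tau, Gini and counts for every gene of the matrix.

    Returns a DataFrame indexed by gene id with columns ``tau``, ``gini``,
    ``counts`` and ``defined``.  All-zero genes are marked ``defined=False``
    with NaN scores; a gene below the counts threshold everywhere keeps its
    tau/Gini but has a NaN counts score.  With ``log=True`` tau and Gini are
    computed on log2(x + 1) (the counts score always uses raw TPM against
    its threshold).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    raw = m.values
    n = m.n_tissues
    X = np.log2(raw + 1.0) if log else raw
    mx = X.max(axis=1)
    defined = mx > 0

    with np.errstate(invalid="ignore", divide="ignore"):
        tau_v = np.sum(1.0 - X / mx[:, None], axis=1) / (n - 1)

    xs = np.sort(X, axis=1)
    weights = 2.0 * np.arange(1, n + 1) - n - 1
    means = X.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        gini_v = (xs @ weights) / (n * n * means) * (n / (n - 1))
    gini_v = np.clip(gini_v, 0.0, 1.0)

    m_counts = (raw >= threshold).sum(axis=1)
    counts_v = np.where(m_counts > 0, (n - m_counts) / (n - 1), np.nan)

    tau_v = np.where(defined, tau_v, np.nan)
    gini_v = np.where(defined, gini_v, np.nan)
    counts_v = np.where(defined, counts_v, np.nan)
    return pd.DataFrame(
        {"tau": tau_v, "gini": gini_v, "counts": counts_v, "defined": defined},
        index=m.data.index,
    )


def classify(scores: pd.DataFrame, high: float = 0.8, low: float = 0.2) -> pd.DataFrame:
    """Apply the 2-of-3 voting rule to a score table.

    ``high`` votes are strict (score > high), ``low`` votes are strict
    (score < low); NaN scores cast no vote, and undefined genes are always
    UNCLASSIFIED.  Returns a DataFrame with ``label``, ``votes_high`` and
    ``votes_low`` per gene.
    """
    if not 0 <= low < high <= 1:
        raise ValueError("need 0 <= low < high <= 1")
    s = scores[["tau", "gini", "counts"]].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        votes_high = np.nansum(s > high, axis=1).astype(int)
        votes_low = np.nansum(s < low, axis=1).astype(int)
    defined = scores["defined"].to_numpy(dtype=bool) if "defined" in scores else np.ones(len(scores), bool)
    label = np.where(votes_high >= 2, TSG, np.where(votes_low >= 2, HKG, UNCLASSIFIED))
    label = np.where(defined, label, UNCLASSIFIED)
    return pd.DataFrame(
        {"label": label, "votes_high": votes_high, "votes_low": votes_low},
        index=scores.index,
    )


def assign_tsg_tissue(m: ExpressionMatrix, tsg_ids) -> pd.Series:
    """Attribute each TSG to its maximum-TPM tissue.

    Exact ties are broken by tissue (column) order with a logged warning.
    """
    tsg_ids = list(tsg_ids)
    missing = [g for g in tsg_ids if g not in m.data.index]
    if missing:
        raise KeyError(f"unknown gene ids: {missing[:5]}")
    sub = m.data.loc[tsg_ids]
    values = sub.to_numpy()
    arg = values.argmax(axis=1)
    ties = (values == values.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        tied = [tsg_ids[i] for i in np.flatnonzero(ties)[:5]]
        logger.warning(
            "assign_tsg_tissue: %d gene(s) tied across tissues (e.g. %s); "
            "first tissue in column order used",
            int(ties.sum()), tied,
        )
    tissues = np.asarray(m.tissue_labels, dtype=object)
    return pd.Series(tissues[arg], index=sub.index, name="tsg_tissue")


def coefficient_of_variation(x) -> float:
    """Sample CV: standard deviation (n-1 divisor) over the mean.

    Undefined (NaN) for a zero-mean vector; invariant to positive rescaling.
    """
    x = _as_vector(x)
    mean = x.mean()
    if mean == 0:
        return float("nan")
    return float(x.std(ddof=1) / mean)


def variability_bands(cvs: pd.Series) -> pd.Series:
    """Quartile triage of per-gene CVs into high / moderate / low bands.

    CV above the upper quartile is "high" (about 25% of genes), below the
    lower quartile "low", the interquartile range "moderate".  Quartiles use
    linear interpolation; with degenerate quartiles (all CVs equal) every
    gene is moderate.
    """
    cvs = cvs.astype(float)
    if len(cvs) < 4:
        raise ValueError("need at least 4 genes for quartile bands")
    q1, q3 = np.nanquantile(cvs.to_numpy(), [0.25, 0.75])
    band = np.where(cvs > q3, "high", np.where(cvs < q1, "low", "moderate"))
    return pd.Series(band, index=cvs.index, name="variability_band")


def tpm_bands(m: ExpressionMatrix) -> pd.DataFrame:
    """Assign every matrix cell to a TPM abundance band.

    Bands: ``gt50`` (> 50), ``b10_50`` ((10, 50]), ``b1_10`` ([1, 10]) and
    ``excluded`` (< 1, below the expression filter).
    """
    v = m.values
    band = np.full(v.shape, "b1_10", dtype=object)
    band[v < 1] = "excluded"
    band[v > 10] = "b10_50"
    band[v > 50] = "gt50"
    return pd.DataFrame(band, index=m.data.index, columns=m.data.columns)
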