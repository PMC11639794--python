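"""Weighted co-expression network: soft threshold, adjacency, TOM, modules,
eigengenes, module-trait statistics and hub genes.

The network is unsigned: for genes i, j with Pearson correlation r_ij of
their log2 expression profiles, the adjacency is ``a_ij = |r_ij| ** beta``.
The soft power beta is chosen as the smallest power on the candidate grid
whose connectivity distribution satisfies the scale-free topology criterion
(signed R^2 of the log-log connectivity regression >= a target, default
0.8); if no power reaches the target the best-fitting power is used with a
warning.

Module detection clusters genes by average linkage on the topological
overlap dissimilarity (1 - TOM) and applies a deterministic static cut
(at a quantile of the merge heights, or an absolute height); clusters
smaller than the minimum module size fall into the "grey" (unassigned)
module.  Surviving modules are named by descending size with the
conventional colour sequence (turquoise, blue, brown, yellow, ...).

Each module is summarised by its eigengene: the first right singular
vector, over samples, of the module's gene-standardised expression,
sign-oriented so the mean correlation with member genes is non-negative.
Hub genes are the top fraction (default 5%) of each module by intramodular
connectivity kIM, with count ``max(1, floor(fraction * size))``.

With one sample per tissue the module-trait p-values have only
``n_samples - 2`` degrees of freedom; they are reported, but treat them
as descriptive rather than inferential at atlas scale (a warning is
logged once per call).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "COLOR_SEQUENCE",
    "GREY",
    "SoftThresholdReport",
    "CoexpressionNetwork",
    "HubGeneSet",
    "pick_soft_threshold",
    "adjacency",
    "tom_similarity",
    "detect_modules",
    "refine_modules",
    "module_eigengenes",
    "module_trait_correlation",
    "gene_module_statistics",
    "hub_genes",
    "eigengene_network",
    "build_network",
]

GREY = "grey"

#: Conventional module colour names, assigned by descending module size.
COLOR_SEQUENCE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)


def _expr_frame(m) -> pd.DataFrame:
    """Accept a genes x samples DataFrame (log scale expected)."""
    if isinstance(m, pd.DataFrame):
        return m
    # ExpressionMatrix duck-typing
    if hasattr(m, "data"):
        return m.data
    raise TypeError("expected a genes x samples DataFrame")


def _drop_constant_rows(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"removing {int(constant.sum())} constant gene row(s) before "
            "correlation",
            stacklevel=3,
        )
        df = df.loc[~constant]
    return df


def _abs_corr(df: pd.DataFrame) -> np.ndarray:
    corr = np.corrcoef(df.to_numpy(dtype=float))
    return np.clip(np.abs(corr), 0.0, 1.0)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit of a connectivity vector.

    The connectivity range is split into ``n_bins`` equal-width bins (a
    quantile binning would make every bin frequency identical by
    construction); the log10 bin frequency is regressed on the log10 mean
    bin connectivity, and the R^2 is sign-corrected by the slope (a
    scale-free network has a negative slope, hence a positive signed R^2).
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < n_bins or np.allclose(k, k[0]):
        return float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, len(edges) - 2)
    mean_k = np.array([k[idx == b].mean() for b in range(len(edges) - 1) if (idx == b).any()])
    freq = np.array([(idx == b).sum() for b in range(len(edges) - 1) if (idx == b).any()]) / k.size
    ok = (mean_k > 0) & (freq > 0)
    if ok.sum() < 3:
        return float("nan")
    res = stats.linregress(np.log10(mean_k[ok]), np.log10(freq[ok]))
    return float(-np.sign(res.slope) * res.rvalue**2)


@dataclass
class SoftThresholdReport:
    """Scale-free fit and mean connectivity over the candidate power grid."""

    table: pd.DataFrame
    chosen_beta: int
    target_r2: float

    @property
    def fit_at_chosen(self) -> float:
        return float(self.table.loc[self.chosen_beta, "fit_r2"])


def pick_soft_threshold(
    m,
    powers=range(1, 21),
    target_r2: float = 0.8,
    n_bins: int = 10,
) -> SoftThresholdReport:
    """Choose the soft power by the scale-free topology criterion.

    For each candidate beta the unsigned adjacency ``|r|**beta`` is formed,
    per-gene connectivity summed, and the signed scale-free fit computed.
    The chosen beta is the smallest with fit >= ``target_r2``; if none
    qualifies, the best-fitting beta is returned with a warning.
    """
    df = _drop_constant_rows(_expr_frame(m))
    if df.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if df.shape[0] < 20:
        warnings.warn("fewer than 20 genes: scale-free fit will be unstable", stacklevel=2)
    corr = _abs_corr(df)
    n = corr.shape[0]
    rows = []
    for beta in powers:
        a = corr**beta
        k = a.sum(axis=1) - 1.0  # exclude the self-adjacency of 1
        rows.append(
            {"power": int(beta), "fit_r2": scale_free_fit(k, n_bins), "mean_k": float(k.mean())}
        )
    table = pd.DataFrame(rows).set_index("power")
    qualifying = table.index[table["fit_r2"] >= target_r2]
    if len(qualifying):
        chosen = int(qualifying[0])
    else:
        if table["fit_r2"].notna().any():
            chosen = int(table["fit_r2"].idxmax())
        else:
            chosen = int(table.index[0])
        warnings.warn(
            f"no power reaches scale-free fit {target_r2}; using best fit at "
            f"beta={chosen} (R2={table.loc[chosen, 'fit_r2']:.3f})",
            stacklevel=2,
        )
    return SoftThresholdReport(table=table, chosen_beta=chosen, target_r2=target_r2)


def adjacency(m, beta: int) -> pd.DataFrame:
    """Unsigned weighted adjacency ``|Pearson r| ** beta`` with unit diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    df = _drop_constant_rows(_expr_frame(m))
    a = _abs_corr(df) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=df.index, columns=df.index)


def tom_similarity(a: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a weighted adjacency.

    ``TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` for i != j,
    where ``L_ij = sum_{u != i,j} a_iu a_uj`` counts shared neighbours and
    ``k_i`` is the connectivity of gene i; the diagonal is 1.
    """
    A = a.to_numpy(dtype=float) if isinstance(a, pd.DataFrame) else np.asarray(a, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if (A < -1e-12).any() or (A > 1 + 1e-12).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    # L_ij = (A @ A)_ij - a_ii a_ij - a_ij a_jj = (A @ A)_ij - 2 a_ij  (unit diagonal)
    L = A @ A - 2.0 * A
    k = A.sum(axis=1) - np.diag(A)
    min_k = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (L + A) / (min_k + 1.0 - A)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    if isinstance(a, pd.DataFrame):
        return pd.DataFrame(tom, index=a.index, columns=a.columns)
    return pd.DataFrame(tom)


def detect_modules(
    tom: pd.DataFrame,
    min_module_size: int = 30,
    cut_quantile: float = 0.98,
    cut_height: float | None = None,
    cut_height_max: float = 0.99,
) -> tuple[pd.Series, np.ndarray]:
    """Static-cut module detection on the TOM dissimilarity dendrogram.

    Genes are clustered by average linkage on ``1 - TOM``; the tree is cut
    at ``cut_height`` if given, else at the ``cut_quantile`` quantile of the
    merge heights capped at ``cut_height_max`` — merges at dissimilarity
    near 1 join genes with essentially no topological overlap, so a cut is
    never placed there even when most merge heights crowd the root (as they
    do for an uncorrelated pool).  Clusters below ``min_module_size`` become
    "grey" (unassigned); surviving modules are named by descending size with
    the conventional colour sequence.  Returns (labels, linkage matrix).
    """
    T = tom.to_numpy(dtype=float)
    dist = 1.0 - T
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    heights = Z[:, 2]
    if cut_height is not None:
        h = float(cut_height)
    else:
        h = min(float(np.quantile(heights, cut_quantile)), cut_height_max)
    raw = fcluster(Z, t=h, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    big = sizes[sizes >= min_module_size].sort_values(ascending=False)
    names: dict[int, str] = {}
    for rank, cid in enumerate(big.index):
        names[cid] = COLOR_SEQUENCE[rank] if rank < len(COLOR_SEQUENCE) else f"module{rank + 1}"
    labels = pd.Series(
        [names.get(c, GREY) for c in raw], index=tom.index, name="module"
    )
    if (labels == GREY).all():
        warnings.warn("detect_modules: all genes unassigned (grey)", stacklevel=2)
    return labels, Z


def refine_modules(
    m,
    labels: pd.Series,
    min_kme: float = 0.5,
    min_module_size: int = 30,
) -> pd.Series:
    """Re-assign genes by module membership after the static cut.

    Provisional module eigengenes are computed, then every gene moves to the
    module with its highest |kME| provided that value reaches ``min_kme``;
    otherwise it is grey.  Modules that fall below ``min_module_size`` are
    dissolved into grey and the survivors are renamed by descending size.
    This purges genes swept into a module by the global cut despite weak
    membership (with few samples, chance correlation is substantial) and
    rescues strong members the cut left unassigned.
    """
    df = _expr_frame(m)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        eig, _ = module_eigengenes(df, labels)
    mods = [c for c in eig.index if c != GREY and not eig.loc[c].isna().any()]
    if not mods:
        return labels
    X = df.to_numpy(dtype=float)
    Xz = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xz**2).sum(axis=1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        Xn = np.where(norms > 0, Xz / norms, 0.0)
    E = eig.loc[mods].to_numpy(dtype=float)
    Ez = E - E.mean(axis=1, keepdims=True)
    En = Ez / np.sqrt((Ez**2).sum(axis=1, keepdims=True))
    kme = np.abs(Xn @ En.T)
    best = kme.argmax(axis=1)
    best_val = kme.max(axis=1)
    assigned = np.where(
        best_val >= min_kme, np.asarray(mods, dtype=object)[best], GREY
    )
    out = pd.Series(assigned, index=df.index, name="module")
    sizes = out.value_counts()
    survivors = [c for c in sizes.index if c != GREY and sizes[c] >= min_module_size]
    out[~out.isin(survivors)] = GREY
    order = [c for c in out.value_counts().index if c != GREY]
    rename = {
        c: (COLOR_SEQUENCE[i] if i < len(COLOR_SEQUENCE) else f"module{i + 1}")
        for i, c in enumerate(order)
    }
    return out.map(lambda c: rename.get(c, GREY))


def module_eigengenes(m, labels: pd.Series) -> tuple[pd.DataFrame, dict[str, bool]]:
    """First-singular-vector eigengene of every module.

    Member genes are z-scored across samples; the eigengene is the first
    right singular vector (over samples) of that standardised block, unit
    norm, sign-oriented so that its mean correlation with member genes is
    non-negative.  The grey module's eigengene is computed but flagged.
    Returns ``(eigengenes, flagged)`` where eigengenes is modules x samples
    and flagged marks unassigned/degenerate modules.
    """
    df = _expr_frame(m)
    out = {}
    flagged = {}
    for label in labels.unique():
        genes = labels.index[labels == label]
        block = df.loc[genes].to_numpy(dtype=float)
        sd = block.std(axis=1, keepdims=True)
        degenerate = (sd == 0).ravel()
        if degenerate.any():
            warnings.warn(
                f"module {label}: {int(degenerate.sum())} zero-variance gene(s) "
                "dropped from the eigengene decomposition",
                stacklevel=2,
            )
            block = block[~degenerate]
        if block.shape[0] == 0:
            out[label] = np.full(df.shape[1], np.nan)
            flagged[label] = True
            continue
        z = (block - block.mean(axis=1, keepdims=True)) / block.std(axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        me = vt[0]
        corr_sign = np.mean([np.corrcoef(row, me)[0, 1] for row in z])
        if corr_sign < 0:
            me = -me
        out[label] = me
        flagged[label] = label == GREY
    order = sorted(out, key=lambda c: (c == GREY, c))
    eigengenes = pd.DataFrame(
        np.vstack([out[c] for c in order]), index=order, columns=df.columns
    )
    return eigengenes, flagged


def _corr_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p of a Pearson r via Student's t with n - 2 df."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return p


def tissue_indicator_traits(sample_labels) -> pd.DataFrame:
    """One-hot tissue indicator matrix (samples x tissues)."""
    s = pd.Series(list(sample_labels), dtype=str)
    return pd.get_dummies(s).astype(float).set_axis(list(sample_labels), axis=0)


def module_trait_correlation(
    eigengenes: pd.DataFrame, traits: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-sided p between module eigengenes and traits.

    Traits are columns of a samples x traits indicator (or quantitative)
    matrix.  With one sample per tissue the degrees of freedom are
    ``n_samples - 2``; interpret p-values descriptively.
    """
    n = eigengenes.shape[1]
    if traits.shape[0] != n:
        raise ValueError("traits must have one row per sample")
    logger.warning(
        "module-trait p-values use df = %d (n_samples - 2); with one sample "
        "per tissue treat them as descriptive", n - 2,
    )
    E = eigengenes.to_numpy(dtype=float)
    T = traits.to_numpy(dtype=float)
    const = T.std(axis=0) == 0
    if const.any():
        warnings.warn(
            f"constant trait column(s) {list(traits.columns[const])}: "
            "correlation undefined",
            stacklevel=2,
        )
    Ez = E - E.mean(axis=1, keepdims=True)
    Tz = T - T.mean(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Ez @ Tz) / np.outer(
            np.sqrt((Ez**2).sum(axis=1)), np.sqrt((Tz**2).sum(axis=0))
        )
    r = np.clip(r, -1.0, 1.0)
    p = _corr_p(r, n)
    p[:, const] = np.nan
    r[:, const] = np.nan
    idx, cols = eigengenes.index, traits.columns
    return pd.DataFrame(r, index=idx, columns=cols), pd.DataFrame(p, index=idx, columns=cols)


def gene_module_statistics(
    m,
    eigengenes: pd.DataFrame,
    labels: pd.Series,
    traits: pd.DataFrame,
) -> dict:
    """Module membership (kME), gene significance (GS) and their coupling.

    * ``kme``: correlation of each gene with each module eigengene;
    * ``gs``: absolute correlation of each gene with each trait;
    * ``gs_mm``: per module, the Pearson r (with p) between member genes'
      GS for the module's most-correlated trait and their |kME|, the
      classic check that central module genes are also the trait-relevant
      ones.
    """
    df = _drop_constant_rows(_expr_frame(m))
    X = df.to_numpy(dtype=float)
    n = X.shape[1]
    Xz = X - X.mean(axis=1, keepdims=True)
    Xn = Xz / np.sqrt((Xz**2).sum(axis=1, keepdims=True))

    E = eigengenes.to_numpy(dtype=float)
    Ez = E - E.mean(axis=1, keepdims=True)
    En = Ez / np.sqrt((Ez**2).sum(axis=1, keepdims=True))
    kme = pd.DataFrame(Xn @ En.T, index=df.index, columns=eigengenes.index)

    T = traits.to_numpy(dtype=float)
    Tz = T - T.mean(axis=0, keepdims=True)
    norms = np.sqrt((Tz**2).sum(axis=0, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        Tn = Tz / norms
    gs = pd.DataFrame(np.abs(Xn @ Tn), index=df.index, columns=traits.columns)

    mt_r, _ = module_trait_correlation(eigengenes, traits)
    rows = []
    for module in eigengenes.index:
        genes = labels.index[labels == module].intersection(df.index)
        if len(genes) < 3 or module not in mt_r.index:
            continue
        trait = mt_r.loc[module].abs().idxmax()
        gs_vec = gs.loc[genes, trait].to_numpy()
        mm_vec = kme.loc[genes, module].abs().to_numpy()
        if np.std(gs_vec) == 0 or np.std(mm_vec) == 0:
            r_val, p_val = float("nan"), float("nan")
        else:
            r_val, p_val = stats.pearsonr(gs_vec, mm_vec)
        rows.append(
            {"module": module, "trait": trait, "n_genes": len(genes),
             "gs_mm_r": r_val, "gs_mm_p": p_val}
        )
    return {"kme": kme, "gs": gs, "gs_mm": pd.DataFrame(rows).set_index("module")}


@dataclass
class HubGeneSet:
    """Per-module hub genes: top fraction by intramodular connectivity."""

    hubs: dict[str, list[str]]
    kim: pd.Series = field(repr=False)
    fraction: float

    def counts(self) -> dict[str, int]:
        return {m: len(g) for m, g in self.hubs.items()}


def hub_genes(a: pd.DataFrame, labels: pd.Series, fraction: float = 0.05) -> HubGeneSet:
    """Select each module's hubs by descending intramodular connectivity.

    ``kIM(g)`` sums the adjacency of g to the other members of its module;
    the top ``max(1, floor(fraction * size))`` genes per module are the
    hubs.  Grey is excluded; exact kIM ties fall back to gene order with a
    logged warning.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    A = a.to_numpy(dtype=float)
    kim = pd.Series(0.0, index=a.index, name="kim")
    hubs: dict[str, list[str]] = {}
    for module in labels.unique():
        genes = labels.index[labels == module]
        pos = a.index.get_indexer(genes)
        block = A[np.ix_(pos, pos)]
        k_in = block.sum(axis=1) - np.diag(block)
        kim.iloc[pos] = k_in
        if module == GREY:
            continue
        size = len(genes)
        n_hub = max(1, int(np.floor(fraction * size)))
        order = np.argsort(-k_in, kind="stable")
        top = k_in[order]
        if n_hub < size and top[n_hub - 1] == top[n_hub]:
            logger.warning(
                "hub_genes: kIM tie at the %s-module hub boundary; "
                "gene order breaks the tie", module,
            )
        hubs[module] = [genes[i] for i in order[:n_hub]]
    return HubGeneSet(hubs=hubs, kim=kim, fraction=fraction)


def eigengene_network(eigengenes: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between module eigengenes."""
    if eigengenes.shape[0] < 2:
        raise ValueError("need at least 2 modules")
    corr = np.corrcoef(eigengenes.to_numpy(dtype=float))
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=eigengenes.index, columns=eigengenes.index)


@dataclass
class CoexpressionNetwork:
    """Bundle of every network artefact for a gene set."""

    beta: int
    soft_threshold: SoftThresholdReport
    labels: pd.Series = field(repr=False)
    tom: pd.DataFrame = field(repr=False)
    adjacency: pd.DataFrame = field(repr=False)
    eigengenes: pd.DataFrame = field(repr=False)
    eigengene_flags: dict[str, bool]
    linkage: np.ndarray = field(repr=False)

    @property
    def module_sizes(self) -> pd.Series:
        return self.labels.value_counts()


def build_network(
    log_expr,
    beta: int | None = None,
    powers=range(1, 21),
    target_r2: float = 0.8,
    min_module_size: int = 30,
    cut_quantile: float = 0.98,
    cut_height: float | None = None,
    min_kme: float | None = 0.5,
) -> CoexpressionNetwork:
    """Run soft-threshold selection through eigengenes in one call.

    ``min_kme`` enables the membership refinement pass after the static cut
    (pass None to keep the raw cut labels).
    """
    df = _drop_constant_rows(_expr_frame(log_expr))
    report = pick_soft_threshold(df, powers=powers, target_r2=target_r2)
    chosen = int(beta) if beta is not None else report.chosen_beta
    adj = adjacency(df, chosen)
    tom = tom_similarity(adj)
    labels, Z = detect_modules(
        tom, min_module_size=min_module_size, cut_quantile=cut_quantile, cut_height=cut_height
    )
    if min_kme is not None:
        labels = refine_modules(
            df, labels, min_kme=min_kme, min_module_size=min_module_size
        )
    eig, flags = module_eigengenes(df, labels)
    return CoexpressionNetwork(
        beta=chosen,
        soft_threshold=report,
        labels=labels,
        tom=tom,
        adjacency=adj,
        eigengenes=eig,
        eigengene_flags=flags,
        linkage=Z,
    )
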