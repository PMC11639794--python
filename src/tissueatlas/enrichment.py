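"""Over-representation analysis against user-supplied term -> gene maps.

Any gene set produced upstream (tissue-specific genes, housekeeping genes,
K-means clusters, co-expression modules) can be tested against a GMT-style
annotation map.  Each term is scored with the hypergeometric upper tail
(equivalently a one-sided Fisher exact test), p-values are adjusted by
Benjamini-Hochberg within each annotation category (e.g. GO vs pathway,
mirroring how the two vocabularies are reported separately), and a term is
*retained* when its FDR <= 0.05 and at least three query genes overlap it.
An empty result table is a legitimate outcome, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationMap",
    "read_gmt",
    "hypergeom_p",
    "bh_adjust",
    "enrich",
]


@dataclass
class AnnotationMap:
    """Term -> gene-set map with per-term name and category metadata."""

    genes: dict[str, frozenset] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)

    def add(self, term: str, genes, name: str = "", category: str = "default") -> None:
        genes = frozenset(map(str, genes))
        if not genes:
            raise ValueError(f"term {term!r} has an empty gene set")
        self.genes[term] = genes
        self.names[term] = name or term
        self.categories[term] = category

    def __len__(self) -> int:
        return len(self.genes)


def read_gmt(path, category: str = "default") -> AnnotationMap:
    """Read a GMT file: one term per line — id, description, genes...

    All terms from one file share one ``category`` label; read several files
    (GO, pathway, ...) into the same map with different categories by
    merging the returned objects' dictionaries, or call once per file and
    pass each map to :func:`enrich`.
    """
    ann = AnnotationMap()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs id, description, >=1 gene")
        term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        ann.add(term, genes, name=desc, category=category)
    return ann


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the universe size, K the term size, n the query size and k the
    observed overlap.
    """
    k, K, n, N = int(k), int(K), int(n), int(N)
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if K > N or n > N or min(K, n, N) < 0:
        raise ValueError(f"need K, n <= N and non-negative; got K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query,
    universe,
    ann: AnnotationMap,
    fdr_max: float = 0.05,
    min_overlap: int = 3,
) -> pd.DataFrame:
    """Over-representation of ``query`` within ``universe`` for every term.

    Terms are restricted to their universe genes; terms with no universe
    gene are skipped.  BH adjustment runs within each annotation category.
    Returns one row per tested term with columns term, name, category,
    k (overlap), K (term size in universe), n (query size), N (universe
    size), p, fdr, genes (semicolon-joined overlap) and retained.
    """
    query = set(map(str, query))
    universe = set(map(str, universe))
    stray = sorted(query - universe)
    if stray:
        raise ValueError(f"query genes outside the universe: {stray[:10]}")
    N, n = len(universe), len(query)
    rows = []
    for term, genes in ann.genes.items():
        in_universe = genes & universe
        if not in_universe:
            continue
        overlap = sorted(in_universe & query)
        rows.append(
            {
                "term": term,
                "name": ann.names.get(term, term),
                "category": ann.categories.get(term, "default"),
                "k": len(overlap),
                "K": len(in_universe),
                "n": n,
                "N": N,
                "p": hypergeom_p(len(overlap), len(in_universe), n, N),
                "genes": ";".join(overlap),
            }
        )
    table = pd.DataFrame(
        rows, columns=["term", "name", "category", "k", "K", "n", "N", "p", "genes"]
    )
    if table.empty:
        table["fdr"] = pd.Series(dtype=float)
        table["retained"] = pd.Series(dtype=bool)
        return table
    table["fdr"] = np.nan
    for _, idx in table.groupby("category").groups.items():
        table.loc[idx, "fdr"] = bh_adjust(table.loc[idx, "p"].to_numpy())
    table["retained"] = (table["fdr"] <= fdr_max) & (table["k"] >= min_overlap)
    return table.sort_values(["fdr", "p"]).reset_index(drop=True)
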