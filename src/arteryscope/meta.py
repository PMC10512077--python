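"""Cross-layer integration of per-layer DE results.

Covers the Venn partition of layer DEG sets, the meta up/down gene sets
(up in at least one layer and down in none, and vice versa; conflicting
genes are set aside), seed-gene fold-change profile similarity, Pearson
correlation hierarchical clustering of ROIs and per-layer PCA summaries.
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, FrozenSet, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .de import DEG_DOWN, DEG_UP


def venn_partition(deg_sets: Dict[str, Set[str]]) -> Dict[FrozenSet[str], int]:
    """Count genes that are DEGs in exactly each non-empty subset of layers.

    Region counts sum to the size of the union of all layer DEG sets.
    """
    if len(deg_sets) < 2:
        raise ValueError("venn_partition needs at least 2 layers")
    layers = list(deg_sets)
    regions: Dict[FrozenSet[str], int] = {}
    for r in range(1, len(layers) + 1):
        for combo in combinations(layers, r):
            regions[frozenset(combo)] = 0
    union = set().union(*deg_sets.values())
    for gene in union:
        membership = frozenset(l for l in layers if gene in deg_sets[l])
        regions[membership] += 1
    return regions


def venn_table(deg_sets: Dict[str, Set[str]]) -> pd.DataFrame:
    """Venn regions as a TSV-friendly table with member gene lists."""
    regions = venn_partition(deg_sets)
    rows = []
    layers = list(deg_sets)
    for subset, count in regions.items():
        genes = sorted(
            g
            for g in set().union(*deg_sets.values())
            if frozenset(l for l in layers if g in deg_sets[l]) == subset
        )
        rows.append(
            {"region": "&".join(sorted(subset)), "n_layers": len(subset),
             "count": count, "genes": ",".join(genes)}
        )
    return pd.DataFrame(rows).sort_values(
        ["n_layers", "region"]).reset_index(drop=True)


def meta_up_down(
    de_results: Dict[str, pd.DataFrame]
) -> Tuple[Set[str], Set[str], Set[str]]:
    """Union-based meta sets: (up, down, conflict).

    A gene is meta-up when it is an up-DEG in at least one layer and a
    down-DEG in none; symmetrically for down. Genes up in one layer and down
    in another form the conflict set and belong to neither.
    """
    up_any: Set[str] = set()
    down_any: Set[str] = set()
    for table in de_results.values():
        up_any |= set(table.index[table["deg"] == DEG_UP])
        down_any |= set(table.index[table["deg"] == DEG_DOWN])
    conflict = up_any & down_any
    return up_any - conflict, down_any - conflict, conflict


def fc_profiles(de_results: Dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Gene x layer matrix of log2 fold changes (NaN where untestable)."""
    cols = {}
    for layer, table in de_results.items():
        beta = table["beta"].copy()
        beta[table["model_used"] == "untestable"] = np.nan
        cols[layer] = beta
    return pd.DataFrame(cols)


def profile_similarity(
    profiles: pd.DataFrame,
    seed_gene: str,
    min_r: float = 0.95,
    min_layers: int = 3,
) -> pd.DataFrame:
    """Genes whose layer-wise log2FC profile correlates with the seed's.

    Pearson r is computed over layers where both profiles are non-missing
    (at least ``min_layers`` required). Output: genes with r >= min_r,
    sorted by r descending, ties broken by gene id; the seed ranks first.
    """
    if seed_gene not in profiles.index:
        raise KeyError(f"seed gene {seed_gene!r} has no profile")
    seed = profiles.loc[seed_gene]
    if seed.isna().any():
        raise ValueError(f"seed gene {seed_gene!r} profile is incomplete")
    rows = []
    seed_v = seed.to_numpy(dtype=float)
    for gene, prof in profiles.iterrows():
        v = prof.to_numpy(dtype=float)
        ok = ~np.isnan(v)
        if ok.sum() < min_layers:
            continue
        a, b = seed_v[ok], v[ok]
        if np.std(a) == 0 or np.std(b) == 0:
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        rows.append({"gene": gene, "r": r, "n_layers": int(ok.sum())})
    out = pd.DataFrame(rows)
    out = out[out["r"] >= min_r]
    return out.sort_values(["r", "gene"], ascending=[False, True]).reset_index(drop=True)


def correlation_cluster(
    expr: pd.DataFrame, log_transform: bool = True, pseudocount: float = 1.0
) -> Tuple[pd.DataFrame, np.ndarray, List[str]]:
    """ROI-ROI Pearson correlation with average-linkage clustering.

    Returns (correlation matrix in leaf order, linkage matrix, leaf order).
    Distance is 1 - r. Constant ROIs get correlation 0 to every other ROI.
    ROIs are pre-sorted by id so the leaf order is deterministic.
    """
    if expr.shape[1] < 3:
        raise ValueError("correlation clustering needs at least 3 ROIs")
    data = np.log2(expr + pseudocount) if log_transform else expr.copy()
    data = data[sorted(data.columns)]
    mat = data.to_numpy(dtype=float)
    sd = mat.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat, rowvar=False)
    constant = sd == 0
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr_df = pd.DataFrame(corr, index=data.columns, columns=data.columns)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    leaves = hierarchy.leaves_list(linkage)
    order = [data.columns[i] for i in leaves]
    return corr_df.loc[order, order], linkage, order


def pca_scores(
    expr: pd.DataFrame, log_transform: bool = True, pseudocount: float = 1.0,
    n_components: int = 2,
) -> Tuple[pd.DataFrame, np.ndarray]:
    """PCA of ROIs on centered log2 expression.

    Returns (scores DataFrame with PC columns, explained-variance fractions).
    Component signs are fixed by making each component's largest-magnitude
    gene loading positive, so scores are fully deterministic.
    """
    if expr.shape[1] < 3:
        raise ValueError("PCA needs at least 3 ROIs")
    data = np.log2(expr + pseudocount) if log_transform else expr.copy()
    x = data.to_numpy(dtype=float).T  # ROIs x genes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    for i in range(k):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    scores = u[:, :k] * s[:k]
    var = s**2
    explained = var / var.sum() if var.sum() > 0 else var
    cols = [f"PC{i+1}" for i in range(k)]
    return pd.DataFrame(scores, index=data.columns, columns=cols), explained[:k]
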