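"""Cross-species codon-usage comparison.

Each species corpus is reduced to a profile (codon counts, GC partition,
a 59-long RSCU vector in fixed codon order, and a 61 x 61 codon-context
adjusted-residual matrix).  Species are then compared three ways:

* hierarchical clustering of per-codon-standardised RSCU vectors
  (Euclidean distance, average linkage by default; Spearman rank-order
  distance also supported), with codon columns clustered the same way for
  heat-map ordering;
* PCA of the RSCU matrix (centered, deterministic sign convention);
* codon-context trees: pairwise distance = 1 - Pearson correlation of the
  flattened adjusted-residual matrices, average linkage.

The adjusted residual of contingency cell (i, j) with expectation
e_ij = row_i col_j / N is (o_ij - e_ij) / sqrt(e_ij (1 - row_i/N)
(1 - col_j/N)); under independence it is approximately standard normal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.decomposition import PCA

from .pairs import PairTable, count_pairs
from .seqio import OrfRecord, filter_orfs
from .tables import DEGENERATE_SENSE_CODONS, SENSE_CODONS
from .usage import GcPartition, count_codons, gc_partition

logger = logging.getLogger(__name__)

RSCU_CODON_ORDER: tuple[str, ...] = DEGENERATE_SENSE_CODONS  # 59 codons


@dataclass
class SpeciesProfile:
    name: str
    n_orfs: int
    n_codons: int
    gc: GcPartition
    rscu_vector: np.ndarray  # 59 values in RSCU_CODON_ORDER
    residual_matrix: np.ndarray  # 61 x 61


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: list[str]
    leaf_order: list[int]
    newick: str


def context_residuals(pair_table: PairTable) -> np.ndarray:
    """Adjusted residuals of the 61 x 61 neighbouring-pair table.

    Cells in a zero row or column marginal get residual 0 by convention.
    """
    o = pair_table.counts.astype(float)
    n = o.sum()
    if n == 0:
        raise ValueError("empty pair table")
    row = o.sum(axis=1)
    col = o.sum(axis=0)
    e = np.outer(row, col) / n
    corr = np.outer(1.0 - row / n, 1.0 - col / n)
    denom = np.sqrt(e * corr)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (o - e) / np.where(denom > 0, denom, 1.0), 0.0)
    n_degenerate = int((denom == 0).sum())
    if n_degenerate:
        logger.info("context_residuals: %d cells with zero marginal", n_degenerate)
    return r


def build_profiles(
    corpora: Mapping[str, Sequence[OrfRecord]],
    prefiltered: bool = False,
    min_len_bp: int = 300,
) -> list[SpeciesProfile]:
    """One profile per named corpus; species with zero kept ORFs are dropped."""
    profiles: list[SpeciesProfile] = []
    for name, records in corpora.items():
        kept = (
            list(records)
            if prefiltered
            else filter_orfs(records, min_len_bp=min_len_bp).kept
        )
        if not kept:
            logger.warning("species %s: no ORFs kept, excluded", name)
            continue
        table = count_codons(kept)
        rscu_vec = np.array([table.rscu.get(c, 0.0) for c in RSCU_CODON_ORDER])
        residuals = context_residuals(count_pairs(kept, distance=0))
        profiles.append(
            SpeciesProfile(
                name=name,
                n_orfs=len(kept),
                n_codons=table.total_codons,
                gc=gc_partition(kept),
                rscu_vector=rscu_vec,
                residual_matrix=residuals,
            )
        )
    return profiles


def _sanitize(name: str) -> str:
    return name.replace(" ", "_").replace("(", "").replace(")", "").replace(
        ",", ""
    ).replace(";", "").replace(":", "_")


def linkage_to_newick(z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string (heights as depths)."""
    root = to_tree(z)

    def rec(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{_sanitize(labels[node.id])}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(root, root.dist) + ";"


def _rank_distance(matrix: np.ndarray) -> np.ndarray:
    """Condensed 1 - Spearman rank correlation distance between rows."""
    ranks = np.apply_along_axis(rankdata, 1, matrix)
    corr = np.corrcoef(ranks)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return squareform(d, checks=False)


def cluster_species_rscu(
    profiles: Sequence[SpeciesProfile],
    metric: str = "euclidean",
    method: str = "average",
    standardize: bool = True,
) -> tuple[ClusterResult, ClusterResult, pd.DataFrame]:
    """Bi-cluster species (rows) and codons (columns) on the RSCU matrix.

    Each codon column is z-scored across species before clustering when
    ``standardize`` is set (constant columns are left at 0).  Returns the
    species tree, the codon tree, and the heat-map matrix reordered by both
    leaf orders.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 species")
    names = [p.name for p in profiles]
    m = np.vstack([p.rscu_vector for p in profiles])
    if standardize:
        mu = m.mean(axis=0)
        sd = m.std(axis=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        m = (m - mu) / sd_safe
    if metric == "euclidean":
        row_d = pdist(m, metric="euclidean")
        col_d = pdist(m.T, metric="euclidean")
    elif metric in ("spearman", "rank"):
        row_d = _rank_distance(m)
        col_d = _rank_distance(m.T)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    row_z = linkage(row_d, method=method)
    col_z = linkage(col_d, method=method)
    row_order = list(leaves_list(row_z))
    col_order = list(leaves_list(col_z))
    species_tree = ClusterResult(
        linkage=row_z,
        labels=names,
        leaf_order=row_order,
        newick=linkage_to_newick(row_z, names),
    )
    codon_labels = list(RSCU_CODON_ORDER)
    codon_tree = ClusterResult(
        linkage=col_z,
        labels=codon_labels,
        leaf_order=col_order,
        newick=linkage_to_newick(col_z, codon_labels),
    )
    heat = pd.DataFrame(m, index=names, columns=codon_labels)
    heat = heat.iloc[row_order, col_order]
    return species_tree, codon_tree, heat


@dataclass
class PcaResult:
    scores: pd.DataFrame  # species x components
    loadings: pd.DataFrame  # codons x components
    variance_ratios: np.ndarray


def _pca_matrix(matrix: np.ndarray, labels: Sequence[str], n_components: int | None):
    n_comp = n_components or min(matrix.shape)
    n_comp = min(n_comp, min(matrix.shape))
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(matrix)
    loadings = pca.components_.T
    # deterministic sign: the largest-|loading| entry of each PC is positive
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    comp_names = [f"PC{k + 1}" for k in range(loadings.shape[1])]
    return (
        pd.DataFrame(scores, index=list(labels), columns=comp_names),
        pd.DataFrame(loadings, index=list(RSCU_CODON_ORDER), columns=comp_names),
        pca.explained_variance_ratio_,
    )


def pca_rscu(
    profiles: Sequence[SpeciesProfile], n_components: int | None = None
) -> PcaResult:
    """Centered PCA of the species x 59-codon RSCU matrix."""
    if len(profiles) < 3:
        raise ValueError("need at least 3 species for PCA")
    m = np.vstack([p.rscu_vector for p in profiles])
    scores, loadings, ratios = _pca_matrix(m, [p.name for p in profiles], n_components)
    return PcaResult(scores=scores, loadings=loadings, variance_ratios=ratios)


def pca_gene_rscu(
    rscu_matrix: np.ndarray,
    gene_ids: Sequence[str],
    n_components: int | None = None,
) -> PcaResult:
    """Per-gene PCA with the same conventions as the species PCA."""
    scores, loadings, ratios = _pca_matrix(
        np.asarray(rscu_matrix, dtype=float), gene_ids, n_components
    )
    return PcaResult(scores=scores, loadings=loadings, variance_ratios=ratios)


def species_context_tree(profiles: Sequence[SpeciesProfile]) -> ClusterResult:
    """Average-linkage tree on 1 - Pearson correlation of residual matrices."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 species")
    names = [p.name for p in profiles]
    flat = np.vstack([p.residual_matrix.ravel() for p in profiles])
    corr = np.corrcoef(flat)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    return ClusterResult(
        linkage=z,
        labels=names,
        leaf_order=list(leaves_list(z)),
        newick=linkage_to_newick(z, names),
    )
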