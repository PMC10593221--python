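"""Evaluation of inferred clonal trees against a ground truth.

Pair-based tree metrics classify every unordered pair of items (cells or
SNVs, each placed on a tree node) as *clustered* (same node), *ancestral*
(one's node a proper ancestor of the other's) or *incomparable* (neither).
Recall of each class — APR, IPR, CPR — is the fraction of ground-truth pairs
of that class receiving the same classification in the inference, with
ancestral pairs also required to keep their orientation.  The single
*accuracy* value is the average of the three recalls weighted by the number
of ground-truth pairs per class (empty classes are excluded).

*Genotype similarity* is 1 minus the normalized Hamming distance between the
true and inferred cell-level genotype matrices, where each cell inherits its
clone's genotype row.  The *cell mutational burden* CMB(i, M) of cell ``i``
over an SNV set ``M`` is the fraction of covered loci of ``M`` with at least
one variant read — a specificity diagnostic: cells outside a clade should
show near-zero CMB over the clade's gained SNVs.

The *Baseline* genotyper reproduces the common practice of clustering cells
on the copy-number embedding alone (density-based, cluster count automatic)
and genotyping each cluster by pooling reads: an SNV is called present when
the pooled alternate/total read ratio strictly exceeds 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.cluster import HDBSCAN, KMeans

from .tree import ClonalTree


@dataclass
class MetricsReport:
    """Pair recalls and accuracies for SNVs and cells, plus genotype similarity."""

    snv_apr: float
    snv_ipr: float
    snv_cpr: float
    snv_accuracy: float
    cell_apr: float
    cell_ipr: float
    cell_cpr: float
    cell_accuracy: float
    genotype_similarity: float

    def to_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def pair_relation(tree: ClonalTree, assignment: np.ndarray, pair: tuple[int, int]) -> str:
    """Relation of an unordered item pair on a tree: clustered/ancestral/incomparable."""
    i, j = pair
    u, v = int(assignment[i]), int(assignment[j])
    if u not in tree.parent or v not in tree.parent:
        raise ValueError(f"pair ({i}, {j}) maps to unplaced nodes ({u}, {v})")
    if u == v:
        return "clustered"
    if tree.is_ancestor(u, v) or tree.is_ancestor(v, u):
        return "ancestral"
    return "incomparable"


def _ancestor_matrix(tree: ClonalTree) -> tuple[np.ndarray, dict[int, int]]:
    nodes = tree.nodes
    idx = {v: j for j, v in enumerate(nodes)}
    anc = np.zeros((len(nodes), len(nodes)), dtype=bool)
    for v in nodes:
        for a in tree.ancestors(v):
            anc[idx[a], idx[v]] = True
    return anc, idx


def _relation_code(anc: np.ndarray, idx: dict[int, int], u: int, v: int) -> int:
    """0 clustered, 1 u-above-v, 2 v-above-u, 3 incomparable."""
    if u == v:
        return 0
    if anc[idx[u], idx[v]]:
        return 1
    if anc[idx[v], idx[u]]:
        return 2
    return 3


def pair_recalls(
    truth_tree: ClonalTree,
    truth_assign: np.ndarray,
    inferred_tree: ClonalTree,
    inferred_assign: np.ndarray,
) -> dict[str, float]:
    """APR/IPR/CPR and their pair-weighted accuracy for one item universe.

    Counts unordered item pairs grouped by their (truth node, inferred node)
    labels, so the cost is quadratic in the number of distinct label pairs
    rather than in the number of items.  A truth-ancestral pair is recalled
    only if the inferred relation is ancestral with the same orientation.
    """
    truth_assign = np.asarray(truth_assign)
    inferred_assign = np.asarray(inferred_assign)
    if truth_assign.shape != inferred_assign.shape:
        raise ValueError("truth and inferred assignments cover different items")
    anc_t, idx_t = _ancestor_matrix(truth_tree)
    anc_i, idx_i = _ancestor_matrix(inferred_tree)
    pairs, counts = np.unique(
        np.stack([truth_assign, inferred_assign]), axis=1, return_counts=True
    )
    groups = list(zip(pairs[0].tolist(), pairs[1].tolist(), counts.tolist()))
    total = {"ancestral": 0.0, "incomparable": 0.0, "clustered": 0.0}
    hit = {"ancestral": 0.0, "incomparable": 0.0, "clustered": 0.0}
    names = {1: "ancestral", 2: "ancestral", 3: "incomparable", 0: "clustered"}
    for (g1, g2) in combinations_with_replacement(range(len(groups)), 2):
        t1, i1, c1 = groups[g1]
        t2, i2, c2 = groups[g2]
        n_pairs = c1 * (c1 - 1) / 2 if g1 == g2 else c1 * c2
        if n_pairs == 0:
            continue
        rel_t = _relation_code(anc_t, idx_t, t1, t2)
        rel_i = _relation_code(anc_i, idx_i, i1, i2)
        cls = names[rel_t]
        total[cls] += n_pairs
        if rel_t == rel_i:  # orientation-sensitive for ancestral pairs
            hit[cls] += n_pairs
    out = {}
    for cls, short in (("ancestral", "apr"), ("incomparable", "ipr"), ("clustered", "cpr")):
        out[short] = hit[cls] / total[cls] if total[cls] > 0 else np.nan
    weights = {c: total[c] for c in total if total[c] > 0}
    wsum = sum(weights.values())
    out["accuracy"] = sum(
        (hit[c] / total[c]) * (total[c] / wsum) for c in weights
    ) if wsum else np.nan
    return out


def genotype_similarity(truth_cell_genotypes: np.ndarray, inferred_cell_genotypes: np.ndarray) -> float:
    """1 minus the normalized Hamming distance of cell-level genotype matrices."""
    t = np.asarray(truth_cell_genotypes)
    f = np.asarray(inferred_cell_genotypes)
    if t.shape != f.shape:
        raise ValueError(f"genotype matrices differ in shape: {t.shape} vs {f.shape}")
    return 1.0 - float(np.mean(t != f))


def recall_metrics(
    truth_tree: ClonalTree,
    inferred_tree: ClonalTree,
) -> MetricsReport:
    """Full metrics report comparing an inferred solution against the truth.

    Both trees carry their cell clustering and SNV attachments; cell-level
    genotypes for the similarity term are derived from each tree's genotype
    matrix (for a simulated truth with explicit genotypes — e.g. Dollo
    losses — pass the matrices to :func:`genotype_similarity` directly).
    """
    if truth_tree.n_cells != inferred_tree.n_cells or truth_tree.n_snvs != inferred_tree.n_snvs:
        raise ValueError("truth and inferred solutions cover different items")
    snv = pair_recalls(
        truth_tree, truth_tree.snv_assignment, inferred_tree, inferred_tree.snv_assignment
    )
    cell = pair_recalls(
        truth_tree, truth_tree.cell_assignment, inferred_tree, inferred_tree.cell_assignment
    )
    gsim = genotype_similarity(truth_tree.cell_genotypes(), inferred_tree.cell_genotypes())
    return MetricsReport(
        snv_apr=snv["apr"],
        snv_ipr=snv["ipr"],
        snv_cpr=snv["cpr"],
        snv_accuracy=snv["accuracy"],
        cell_apr=cell["apr"],
        cell_ipr=cell["ipr"],
        cell_cpr=cell["cpr"],
        cell_accuracy=cell["accuracy"],
        genotype_similarity=gsim,
    )


def cmb(cell: int, snv_set: np.ndarray, A: sparse.spmatrix, D: sparse.spmatrix) -> float | None:
    """Cell mutational burden of one cell over an SNV set.

    Fraction of loci in ``snv_set`` with nonzero depth that carry at least one
    variant read; ``None`` (undefined) when the cell covers no locus of the
    set.
    """
    snv_set = np.asarray(snv_set)
    if snv_set.size == 0:
        raise ValueError("CMB requires a nonempty SNV set")
    a = np.asarray(sparse.csr_matrix(A)[cell, snv_set].todense()).ravel()
    d = np.asarray(sparse.csr_matrix(D)[cell, snv_set].todense()).ravel()
    covered = int((d > 0).sum())
    if covered == 0:
        return None
    return float((a > 0).sum() / covered)


def cmb_clade_report(
    tree: ClonalTree, A: sparse.spmatrix, D: sparse.spmatrix
) -> pd.DataFrame:
    """Within- vs outside-clade CMB distributions for every node with gains.

    For each node with a nonempty gain set, computes the CMB of every cell
    with respect to that set, split by whether the cell lies inside the
    node's clade; undefined CMBs (no covered locus) are excluded.  Returns
    medians, interquartile ranges and counts per (node, side).
    """
    A_pos = sparse.csr_matrix(A, copy=True)
    A_pos.data = (A_pos.data > 0).astype(np.float64)
    D_pos = sparse.csr_matrix(D, copy=True)
    D_pos.data = (D_pos.data > 0).astype(np.float64)
    n = tree.n_cells
    rows = []
    for v in tree.nodes:
        gains = tree.gains(v)
        if gains.size == 0:
            continue
        num = np.asarray(A_pos[:, gains].sum(axis=1)).ravel()
        den = np.asarray(D_pos[:, gains].sum(axis=1)).ravel()
        inside = np.zeros(n, dtype=bool)
        inside[tree.cells_of_clade(v)] = True
        for side, mask in (("inside", inside), ("outside", ~inside)):
            covered = mask & (den > 0)
            vals = num[covered] / den[covered]
            rows.append(
                {
                    "node": v,
                    "n_gained_snvs": int(gains.size),
                    "side": side,
                    "n_cells": int(mask.sum()),
                    "n_cells_covered": int(covered.sum()),
                    "median_cmb": float(np.median(vals)) if vals.size else np.nan,
                    "iqr_cmb": float(
                        np.subtract(*np.percentile(vals, [75, 25]))
                    ) if vals.size else np.nan,
                }
            )
    return pd.DataFrame(rows)


def baseline_genotyper(
    R_tilde: np.ndarray,
    A: sparse.spmatrix,
    D: sparse.spmatrix,
    n_clusters: int | None = None,
    ratio_threshold: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Embedding-only cell clustering plus pooled-read clonal genotyping.

    Cells are clustered on the copy-number embedding alone — density-based
    (HDBSCAN) with automatic cluster count by default, or k-means when
    ``n_clusters`` is fixed.  Density outliers join the nearest cluster
    centroid.  Cluster ``j`` is assigned genotype 1 at locus ``q`` iff the
    pooled alternate/total read ratio strictly exceeds ``ratio_threshold``;
    pools with zero depth get genotype 0.

    Returns (cluster labels per cell, clusters x SNVs genotype matrix).
    """
    R_tilde = np.asarray(R_tilde, dtype=np.float64)
    n = R_tilde.shape[0]
    if n_clusters is not None:
        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
        labels = km.fit_predict(R_tilde)
    else:
        min_size = max(10, int(round(0.01 * n)))
        labels = HDBSCAN(
            min_cluster_size=min(min_size, max(2, n // 2)), copy=True
        ).fit_predict(R_tilde)
        if (labels >= 0).sum() == 0:
            labels = np.zeros(n, dtype=int)
        elif (labels < 0).any():  # attach outliers to the nearest centroid
            centers = np.stack(
                [R_tilde[labels == c].mean(axis=0) for c in np.unique(labels[labels >= 0])]
            )
            cluster_ids = np.unique(labels[labels >= 0])
            noise = np.flatnonzero(labels < 0)
            dists = ((R_tilde[noise, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            labels[noise] = cluster_ids[np.argmin(dists, axis=1)]
        labels = np.unique(labels, return_inverse=True)[1]
    A = sparse.csr_matrix(A)
    D = sparse.csr_matrix(D)
    k = int(labels.max()) + 1
    Y = np.zeros((k, A.shape[1]), dtype=np.int8)
    for j in range(k):
        cells = np.flatnonzero(labels == j)
        a_pool = np.asarray(A[cells].sum(axis=0)).ravel()
        d_pool = np.asarray(D[cells].sum(axis=0)).ravel()
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d_pool > 0, a_pool / np.maximum(d_pool, 1), 0.0)
        Y[j] = (ratio > ratio_threshold).astype(np.int8)
    return labels, Y
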