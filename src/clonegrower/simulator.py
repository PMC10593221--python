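"""Ground-truth simulator for ultra-low coverage scDNA-seq of a tumor.

Emulates the data a clonal tumor would produce under uniform ultra-low
coverage sequencing: a random rooted clonal tree, binary SNV genotypes under
infinite-sites (optionally Dollo) evolution, allele-specific copy-number
profiles acquired along edges, and per-cell read counts.

Read model: for cell ``i`` of clone ``j`` and SNV locus ``q`` with total
copies ``y`` at the locus, the depth is ``d_iq ~ Poisson(g y / 2)`` where
``g`` is the haploid-normalized mean coverage, and the variant count is
``a_iq ~ Binom(d_iq, vaf')`` with ``vaf' = (x/y)(1-alpha) + (1-x/y) alpha``
for a clone carrying ``x`` mutated copies, and ``vaf' = alpha`` otherwise.
Binned counts are ``r_ib ~ Poisson(lambda_b cn_b / 2)`` with ``lambda_b``
calibrated so a diploid bin at coverage ``g`` receives ``g * bin_read_depth``
reads (default 5000 reads per 1x, i.e. 500-kb bins sequenced with 100-bp
reads).  At ``g = 0.01`` a diploid locus is uncovered in about 99% of
(cell, locus) entries — the sparsity regime the inference is built for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import sparse

from .data_io import ReadCountData
from .tree import ClonalTree


@dataclass
class SimulationConfig:
    """Study conditions for one simulated instance.

    Defaults follow current ultra-low coverage tumor scDNA-seq practice:
    ~1000 cells, thousands of SNV loci, mean coverage in the 0.01-0.1x
    range, a large truncal mutation share, and a handful of clones none of
    which is vanishingly small.
    """

    k: int = 5  # tree nodes
    n: int = 1000  # cells
    m: int = 5000  # SNV loci
    g: float = 0.05  # mean haploid-normalized coverage
    alpha: float = 0.001  # per-base sequencing error
    b: int = 1000  # genomic bins
    cna_mode: str = "on"  # {"on", "off"}
    evolution: str = "infinite_sites"  # {"infinite_sites", "dollo"}
    max_copies: int = 5
    seed: int = 0
    truncal_fraction: float = 0.3
    min_clone_fraction: float = 0.02
    dollo_loss_prob: float = 0.05
    events_per_edge: tuple[int, int] = (1, 3)
    bin_read_depth: float = 5000.0  # reads per bin per 1x coverage, diploid

    def __post_init__(self) -> None:
        if min(self.k, self.n, self.m, self.b) <= 0:
            raise ValueError("k, n, m and b must be positive")
        if not 0.0 < self.g <= 1.0:
            raise ValueError("coverage g must lie in (0, 1]")
        if self.k > self.n or self.k > self.m:
            raise ValueError("need at least as many cells and SNVs as tree nodes")
        if self.cna_mode not in ("on", "off"):
            raise ValueError("cna_mode must be 'on' or 'off'")
        if self.evolution not in ("infinite_sites", "dollo"):
            raise ValueError("evolution must be 'infinite_sites' or 'dollo'")


@dataclass
class GroundTruth:
    """Latent truth of one simulated instance."""

    tree: ClonalTree  # carries phi* (cells) and omega* (SNV attachments)
    Y: np.ndarray  # k x m clonal genotypes (may violate infinite sites in dollo mode)
    profiles: np.ndarray  # k x b x 2 allele-specific copy numbers
    variant_copies: np.ndarray  # k x m mutated copies x
    total_copies: np.ndarray  # k x m total copies y at the SNV's bin
    snv_bin: np.ndarray  # m, bin index of each SNV locus
    config: SimulationConfig = field(repr=False, default=None)

    @property
    def cell_genotypes(self) -> np.ndarray:
        return self.Y[self.tree.cell_assignment]


def _random_rooted_tree(k: int, rng: np.random.Generator) -> dict[int, int]:
    """Uniform labeled tree on k nodes via a random Pruefer sequence, rooted at 0."""
    if k == 1:
        return {0: -1}
    if k == 2:
        return {0: -1, 1: 0}
    seq = rng.integers(0, k, size=k - 2).tolist()
    T = nx.from_prufer_sequence(seq)
    parent = {0: -1}
    for u, v in nx.bfs_edges(T, 0):
        parent[v] = u
    return parent


def _clone_proportions(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Dirichlet clone proportions with a minimum clone fraction."""
    for _ in range(200):
        p = rng.dirichlet(np.ones(cfg.k))
        if p.min() >= cfg.min_clone_fraction:
            return p
    p = np.clip(p, cfg.min_clone_fraction, None)
    return p / p.sum()


def _counts_from_proportions(p: np.ndarray, n: int) -> np.ndarray:
    counts = np.floor(p * n).astype(int)
    counts[counts == 0] = 1
    while counts.sum() > n:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < n:
        counts[np.argmax(p - counts / n)] += 1
    return counts


def simulate_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Draw a clonal tree, genotypes and copy-number profiles.

    The root receives a truncal share of the SNVs; the rest are spread over
    the non-root nodes with Dirichlet proportions.  With CNAs on, every
    non-root edge acquires 1-3 segmental events (gain or loss of one allele
    over a contiguous bin range); with CNAs off every locus stays heterozygous
    diploid.  In Dollo mode each SNV is additionally lost on at most one
    descendant edge with small probability.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    parent = _random_rooted_tree(cfg.k, rng)
    k, n, m, b = cfg.k, cfg.n, cfg.m, cfg.b

    # cells -> clones
    props = _clone_proportions(cfg, rng)
    counts = _counts_from_proportions(props, n)
    phi = np.repeat(np.arange(k), counts)
    rng.shuffle(phi)

    # SNVs -> nodes (truncal share at the root)
    m_trunk = int(round(cfg.truncal_fraction * m))
    omega = np.empty(m, dtype=np.int64)
    omega[:m_trunk] = 0
    if k > 1:
        rest_props = rng.dirichlet(np.ones(k - 1))
        rest_counts = _counts_from_proportions(rest_props, m - m_trunk)
        omega[m_trunk:] = np.repeat(np.arange(1, k), rest_counts)
    else:
        omega[m_trunk:] = 0
    rng.shuffle(omega)

    tree = ClonalTree(parent=parent, cell_assignment=phi, snv_assignment=omega)

    # allele-specific copy-number profiles along the tree
    profiles = np.ones((k, b, 2), dtype=np.int64)
    if cfg.cna_mode == "on":
        order, queue = [], [0]
        while queue:  # parents before children
            v = queue.pop(0)
            order.append(v)
            queue.extend(tree.children(v))
        for v in order:
            if tree.parent[v] < 0:
                continue
            prof = profiles[tree.parent[v]].copy()
            n_events = rng.integers(cfg.events_per_edge[0], cfg.events_per_edge[1] + 1)
            for _ in range(n_events):
                for _attempt in range(10):
                    length = int(rng.integers(max(1, b // 50), max(2, b // 10) + 1))
                    start = int(rng.integers(0, max(1, b - length + 1)))
                    allele = int(rng.integers(0, 2))
                    delta = int(rng.choice([-1, 1]))
                    seg = prof[start : start + length, allele] + delta
                    tot = prof[start : start + length].sum(axis=1) + delta
                    if seg.min() >= 0 and tot.max() <= cfg.max_copies:
                        prof[start : start + length, allele] = seg
                        break
            profiles[v] = prof

    # genotypes from attachments; optional Dollo losses
    Y, nodes = tree.genotype_matrix()
    Y = Y.astype(np.int8)
    if cfg.evolution == "dollo":
        edges = tree.edges()
        for q in range(m):
            if rng.random() >= cfg.dollo_loss_prob:
                continue
            carriers = {v for v in nodes if Y[v, q] == 1}
            loss_edges = [
                (p, v) for p, v in edges if p in carriers and v in carriers and v != omega[q]
            ]
            if not loss_edges:
                continue
            _, v = loss_edges[rng.integers(0, len(loss_edges))]
            Y[list(tree.clade(v)), q] = 0

    # per-SNV copy states
    snv_bin = rng.integers(0, b, size=m)
    snv_allele = rng.integers(0, 2, size=m)
    total = profiles.sum(axis=2)[:, snv_bin]  # k x m
    x = np.zeros((k, m), dtype=np.int64)
    carrier = Y == 1
    allele_copies = profiles[:, snv_bin, :][
        :, np.arange(m), snv_allele
    ]  # k x m copies of the mutated allele
    x[carrier] = allele_copies[carrier]
    # keep carried SNVs observable: a mutation is never fully lost to a CNA
    x[carrier & (x == 0)] = 1
    total = np.maximum(total, x)
    return GroundTruth(
        tree=tree,
        Y=Y,
        profiles=profiles,
        variant_copies=x,
        total_copies=total,
        snv_bin=snv_bin,
        config=cfg,
    )


def simulate_reads(gt: GroundTruth, config: SimulationConfig | None = None) -> ReadCountData:
    """Sample SNV read counts and binned counts from a ground truth."""
    cfg = config or gt.config
    rng = np.random.default_rng(cfg.seed + 1)
    n, m, b, k = cfg.n, cfg.m, cfg.b, cfg.k
    phi = gt.tree.cell_assignment
    vaf_raw = np.where(gt.Y == 1, gt.variant_copies / np.maximum(gt.total_copies, 1), 0.0)
    vaf = np.where(
        gt.Y == 1, vaf_raw * (1 - cfg.alpha) + (1 - vaf_raw) * cfg.alpha, cfg.alpha
    )
    rows, cols, a_data, d_data = [], [], [], []
    R = np.empty((n, b), dtype=np.float64)
    bin_cn = gt.profiles.sum(axis=2)  # k x b
    for j in range(k):
        cells = np.flatnonzero(phi == j)
        if cells.size == 0:
            continue
        lam_d = cfg.g * gt.total_copies[j] / 2.0
        d = rng.poisson(lam_d, size=(cells.size, m))
        nz = d > 0
        a = np.zeros_like(d)
        a[nz] = rng.binomial(d[nz], np.broadcast_to(vaf[j], d.shape)[nz])
        rr, cc = np.nonzero(nz)
        rows.append(cells[rr])
        cols.append(cc)
        a_data.append(a[nz])
        d_data.append(d[nz])
        lam_r = cfg.bin_read_depth * cfg.g * bin_cn[j] / 2.0
        R[cells] = rng.poisson(np.broadcast_to(lam_r, (cells.size, b)))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    shape = (n, m)
    A = sparse.csr_matrix((np.concatenate(a_data), (rows, cols)), shape=shape)
    D = sparse.csr_matrix((np.concatenate(d_data), (rows, cols)), shape=shape)
    cell_ids = [f"cell{i}" for i in range(n)]
    snv_ids = [f"snv{q}" for q in range(m)]
    bin_ids = [f"bin{j}" for j in range(b)]
    return ReadCountData(
        cell_ids=cell_ids, snv_ids=snv_ids, A=A, D=D, R=R, bin_ids=bin_ids
    )


def simulate(config: SimulationConfig) -> tuple[ReadCountData, GroundTruth]:
    """Draw a ground truth and its read counts in one call."""
    gt = simulate_ground_truth(config)
    return simulate_reads(gt), gt
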