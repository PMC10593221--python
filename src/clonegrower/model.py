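"""Probabilistic model for read counts and the clonal tree posterior.

The generative model couples three observations to the latent clonal tree
``(T, Y, phi)``:

* SNV read counts.  Conditional on the total depth ``d_iq``, the variant count
  ``a_iq`` of cell ``i`` at locus ``q`` is binomial.  If the cell's clone does
  not carry the SNV (``y = 0``) the success probability is the per-base
  sequencing error ``alpha``.  If it does (``y = 1``) the variant allele
  fraction depends on the unobserved allele-specific copy number state
  ``(x, y_tot)`` at the locus — ``x`` mutated copies out of ``y_tot`` total,
  ``1 <= x <= y_tot <= c`` — which is marginalized under a uniform prior:

      P(a | d, y=1) = sum_{(x,y_tot)} pi(x, y_tot) Binom(a; d, vaf'(x, y_tot))

  with ``vaf = x / y_tot`` and the error-adjusted ``vaf' = vaf (1 - alpha) +
  (1 - vaf) alpha``.  Entries with ``d = 0`` carry no information and
  contribute exactly 0 in log space, which keeps posteriors comparable
  across trees.

* Binned read count embedding.  Cells of a clone are modeled as a spherical
  Gaussian around the clone's centroid in the embedding, with a single pooled
  spread shared by all clones and profiled out at its maximum-likelihood
  value.

* Priors.  Uniform over trees, and per-SNV uniform over attachment nodes
  (contributing ``-m log k`` for a tree with ``k`` nodes); no cell-assignment
  prior.  The posterior ordering of trees is therefore a likelihood ordering
  with a mild penalty on node count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.special import betaln, logsumexp

_LOG_2PI = float(np.log(2.0 * np.pi))
MIN_SPREAD = 1e-6  # variance floor for the embedding likelihood


@dataclass
class ModelParams:
    """Hyperparameters of the model and the search.

    Parameters
    ----------
    alpha
        Per-base sequencing error probability, in (0, 1).
    max_copies
        Upper bound ``c`` on the total number of copies at any locus.
    threshold
        Detection threshold ``t``: the minimum mean number of clone cells
        covering each SNV newly introduced in the clone.
    qc
        Quality-check upper bound on the median mutational burden of cells
        outside a clade, over the clade's gained SNVs.
    restarts
        Number of seeded restarts per elementary tree operation.
    max_iter
        Maximum coordinate-descent iterations per elementary tree operation.
    seed
        Base seed for all randomized steps.
    min_clone_size
        Minimum number of cells per inferred clone; ``None`` means
        ``max(10, 0.01 n)``.
    embedding_dim
        Dimension of the binned read count embedding when computed internally.
    snv_feature_weight
        Relative weight of the SNV-evidence column in the combined
        CNA + SNV feature fed to the normalized cut.
    """

    alpha: float = 0.001
    max_copies: int = 5
    threshold: int = 5
    qc: float = 0.025
    restarts: int = 15
    max_iter: int = 50
    seed: int = 0
    min_clone_size: int | None = None
    embedding_dim: int = 10
    snv_feature_weight: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.max_copies < 2:
            raise ValueError("max_copies must be at least 2")
        if self.threshold < 1 or self.restarts < 1 or self.max_iter < 1:
            raise ValueError("threshold, restarts and max_iter must be positive")
        if not 0.0 < self.qc < 1.0:
            raise ValueError(f"qc must lie in (0, 1), got {self.qc}")

    def resolved_min_clone_size(self, n_cells: int) -> int:
        if self.min_clone_size is not None:
            return self.min_clone_size
        return max(10, int(round(0.01 * n_cells)))


@dataclass
class CopyStateSet:
    """Allele-specific copy number states marginalized in the genotype-1 emission.

    States are pairs ``(x, y_tot)`` of mutated and total copies with
    ``1 <= y_tot <= c``; genotype-0 states have ``x = 0`` and genotype-1
    states ``x >= 1``.  The prior is uniform within each genotype class.
    """

    max_copies: int
    states: list[tuple[int, int]] = field(init=False)
    prior: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.states = [
            (x, y) for y in range(1, self.max_copies + 1) for x in range(1, y + 1)
        ]
        self.prior = np.full(len(self.states), 1.0 / len(self.states))

    def adjusted_vafs(self, alpha: float) -> np.ndarray:
        vaf = np.array([x / y for x, y in self.states])
        return vaf * (1.0 - alpha) + (1.0 - vaf) * alpha


def _log_binom_pmf(a, d, p):
    """log Binom(a; d, p) without the scipy.stats dispatch overhead."""
    a = np.asarray(a, dtype=np.float64)
    d = np.asarray(d, dtype=np.float64)
    log_coef = -betaln(d - a + 1.0, a + 1.0) - np.log(d + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = log_coef + a * np.log(p) + (d - a) * np.log1p(-p)
    return np.where(d == 0, 0.0, out)


def snv_entry_loglik(a: int, d: int, genotype: int, params: ModelParams) -> float:
    """Log-likelihood of one (variant, total) read count under genotype 0 or 1.

    Returns 0.0 for ``d = 0`` under both genotypes (no observation).
    """
    if a < 0 or d < 0 or a > d:
        raise ValueError(f"invalid read counts a={a}, d={d}")
    if genotype not in (0, 1):
        raise ValueError(f"genotype must be 0 or 1, got {genotype}")
    if d == 0:
        return 0.0
    if genotype == 0:
        return float(_log_binom_pmf(a, d, params.alpha))
    states = CopyStateSet(params.max_copies)
    vafs = states.adjusted_vafs(params.alpha)
    terms = _log_binom_pmf(a, d, vafs) + np.log(states.prior)
    return float(logsumexp(terms))


def embedding_loglik(rows: np.ndarray, center: np.ndarray, spread: float) -> float:
    """Spherical-normal log-density of embedding rows around a clone center.

    ``spread`` is the per-coordinate variance; must be positive.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=np.float64))
    if rows.shape[0] == 0:
        raise ValueError("embedding_loglik requires at least one row")
    if spread <= 0:
        raise ValueError("spread must be positive")
    ell = rows.shape[1]
    sq = np.sum((rows - center) ** 2, axis=1)
    return float(np.sum(-0.5 * (sq / spread + ell * (_LOG_2PI + np.log(spread)))))


class LikelihoodCache:
    """Precomputed per-entry log-likelihoods for fast posterior evaluation.

    Stores, over the nonzero entries of ``D``, the genotype-0 log-likelihood
    total and the sparse matrix of log-likelihood differences
    ``delta = loglik(genotype 1) - loglik(genotype 0)``, so that the SNV term
    of any tree's posterior is ``l0_total + sum of delta over genotype-1
    entries``.
    """

    def __init__(self, A: sparse.spmatrix, D: sparse.spmatrix, params: ModelParams):
        self.params = params
        D = sparse.csr_matrix(D)
        A = sparse.csr_matrix(A)
        D.sum_duplicates()
        A.sum_duplicates()
        coo = D.tocoo()
        if coo.nnz == 0:
            self.l0_total = 0.0
            self.delta = sparse.csr_matrix(D.shape)
            self.shape = D.shape
            return
        d = coo.data.astype(np.int64)
        a = np.asarray(A[coo.row, coo.col]).ravel().astype(np.int64)
        if np.any(a > d) or np.any(a < 0) or np.any(d < 0):
            raise ValueError("invalid read counts: need 0 <= a <= d")
        # vectorize over the (few) unique (a, d) pairs of ultra-low coverage data
        pairs = a * (d.max() + 1) + d
        uniq, inv = np.unique(pairs, return_inverse=True)
        ua, ud = uniq // (d.max() + 1), uniq % (d.max() + 1)
        l0_u = _log_binom_pmf(ua, ud, params.alpha)
        states = CopyStateSet(params.max_copies)
        vafs = states.adjusted_vafs(params.alpha)
        terms = _log_binom_pmf(ua[:, None], ud[:, None], vafs[None, :]) + np.log(
            states.prior
        )[None, :]
        l1_u = logsumexp(terms, axis=1)
        l0 = l0_u[inv]
        l1 = l1_u[inv]
        self.l0_total = float(np.sum(l0))
        self.delta = sparse.csr_matrix(
            (l1 - l0, (coo.row, coo.col)), shape=D.shape
        )
        self.shape = D.shape

    def delta_colsums(self, cells: np.ndarray) -> np.ndarray:
        """Per-SNV sum of ``delta`` over a subset of cells (length m)."""
        if len(cells) == 0:
            return np.zeros(self.shape[1])
        return np.asarray(self.delta[cells].sum(axis=0)).ravel()


def _embedding_term(embedding: np.ndarray, cell_assignment: np.ndarray) -> float:
    """Clone-wise spherical Gaussian log-likelihood with profiled pooled spread."""
    n, ell = embedding.shape
    total_sq = 0.0
    for v in np.unique(cell_assignment):
        rows = embedding[cell_assignment == v]
        center = rows.mean(axis=0)
        total_sq += float(np.sum((rows - center) ** 2))
    spread = max(total_sq / (n * ell), MIN_SPREAD)
    return -0.5 * n * ell * (_LOG_2PI + np.log(spread) + total_sq / (n * ell * spread))


def tree_log_posterior(tree, cache: LikelihoodCache, embedding: np.ndarray) -> float:
    """Unnormalized log posterior of a clonal tree given the data.

    Sum of (i) the SNV read-count log-likelihood under the tree's genotypes,
    (ii) the clone-wise embedding log-likelihood, and (iii) the uniform
    per-SNV attachment prior ``-m log k``.  Additive over clones, so
    elementary operations can score incremental changes consistently.
    """
    snv_term = cache.l0_total
    for v in tree.nodes:
        gained = tree.gains(v)
        if gained.size == 0:
            continue
        clade_cells = tree.cells_of_clade(v)
        if clade_cells.size == 0:
            continue
        colsums = cache.delta_colsums(clade_cells)
        snv_term += float(np.sum(colsums[gained]))
    emb_term = _embedding_term(embedding, tree.cell_assignment)
    prior = -tree.n_snvs * np.log(tree.n_nodes)
    return snv_term + emb_term + prior


def assign_snvs(
    tree,
    snvs: np.ndarray,
    candidate_nodes: list[int],
    cache: LikelihoodCache,
) -> np.ndarray:
    """Attach each SNV in ``snvs`` to its maximum-posterior candidate node.

    For each SNV the marginal contribution of attaching at node ``v`` is the
    sum of ``delta`` over the cells of the clade of ``v`` (entries outside the
    clade contribute the genotype-0 likelihood, which is attachment-invariant).
    Runs in O(nm): one sparse column-sum per candidate node.  Ties — e.g. SNVs
    with zero coverage everywhere — go to the earliest candidate node in
    ``candidate_nodes`` order, so zero-data SNVs land on the shallowest
    (prior-preferred) node.  The returned assignment obeys infinite sites by
    construction of the genotype representation.
    """
    snvs = np.asarray(snvs)
    scores = np.empty((len(candidate_nodes), snvs.size))
    for j, v in enumerate(candidate_nodes):
        clade_cells = tree.cells_of_clade(v)
        scores[j] = cache.delta_colsums(clade_cells)[snvs]
    # np.argmax returns the first maximizer, i.e. the earliest candidate node
    choice = np.argmax(scores, axis=0)
    assignment = tree.snv_assignment.copy()
    assignment[snvs] = np.array(candidate_nodes)[choice]
    return assignment
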