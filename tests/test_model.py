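"""Read-count likelihoods, posterior evaluation and SNV assignment."""

import numpy as np
import pytest
from scipy import sparse
from scipy.special import logsumexp
from scipy.stats import binom, norm

from clonegrower import (
    ClonalTree,
    LikelihoodCache,
    ModelParams,
    ReadCountData,
    assign_snvs,
    embedding_loglik,
    snv_entry_loglik,
    tree_log_posterior,
)


def brute_force_entry_loglik(a, d, genotype, alpha, c):
    """Independent oracle: explicit enumeration of copy states with scipy."""
    if d == 0:
        return 0.0
    if genotype == 0:
        return binom.logpmf(a, d, alpha)
    states = [(x, y) for y in range(1, c + 1) for x in range(1, y + 1)]
    terms = []
    for x, y in states:
        vaf = x / y
        vaf_adj = vaf * (1 - alpha) + (1 - vaf) * alpha
        terms.append(np.log(1.0 / len(states)) + binom.logpmf(a, d, vaf_adj))
    return logsumexp(terms)


class TestEntryLoglik:
    def test_no_observation_is_zero(self, default_params):
        assert snv_entry_loglik(0, 0, 0, default_params) == 0.0
        assert snv_entry_loglik(0, 0, 1, default_params) == 0.0

    def test_single_error_read(self, default_params):
        val = snv_entry_loglik(1, 1, 0, default_params)
        assert np.isclose(val, np.log(default_params.alpha))

    @pytest.mark.parametrize("a,d,genotype", [
        (1, 2, 1), (0, 3, 1), (2, 2, 1), (1, 5, 0), (3, 7, 1), (0, 1, 0),
    ])
    def test_matches_enumeration_oracle(self, a, d, genotype, default_params):
        got = snv_entry_loglik(a, d, genotype, default_params)
        want = brute_force_entry_loglik(
            a, d, genotype, default_params.alpha, default_params.max_copies
        )
        assert np.isclose(got, want, atol=1e-10)

    def test_invalid_counts_rejected(self, default_params):
        with pytest.raises(ValueError):
            snv_entry_loglik(3, 2, 0, default_params)

    def test_genotype_crossover_matches_scan(self, default_params):
        """Genotype 1 wins exactly above the brute-force crossover VAF."""
        d = 20
        diffs = [
            snv_entry_loglik(a, d, 1, default_params)
            - snv_entry_loglik(a, d, 0, default_params)
            for a in range(d + 1)
        ]
        # likelihood ratio is monotone in a, so there is a single crossover
        signs = np.sign(diffs)
        assert np.all(np.diff(signs) >= 0)
        assert signs[0] < 0 < signs[-1]


class TestEmbeddingLoglik:
    def test_matches_normal_density_sum(self):
        rng = np.random.default_rng(0)
        rows = rng.normal(size=(5, 2))
        center = rng.normal(size=2)
        spread = 0.7
        want = norm.logpdf(rows, loc=center, scale=np.sqrt(spread)).sum()
        assert np.isclose(embedding_loglik(rows, center, spread), want)

    def test_own_center_is_maximal(self):
        row = np.array([[1.0, -2.0]])
        at_center = embedding_loglik(row, row[0], 1.0)
        off = embedding_loglik(row, row[0] + 0.5, 1.0)
        assert at_center > off

    def test_symmetric_cells_contribute_equally(self):
        center = np.zeros(2)
        a = embedding_loglik(np.array([[1.0, 0.0]]), center, 1.0)
        b = embedding_loglik(np.array([[-1.0, 0.0]]), center, 1.0)
        assert np.isclose(a, b)

    def test_empty_rows_rejected(self):
        with pytest.raises(ValueError):
            embedding_loglik(np.empty((0, 2)), np.zeros(2), 1.0)


def _random_instance(rng, n=6, m=4, k=3):
    """Small random tree + counts for posterior cross-checks."""
    parent = {0: -1}
    for v in range(1, k):
        parent[v] = int(rng.integers(0, v))
    phi = rng.integers(0, k, size=n)
    omega = rng.integers(0, k, size=m)
    tree = ClonalTree(parent=parent, cell_assignment=phi, snv_assignment=omega)
    D = rng.integers(0, 3, size=(n, m))
    A = np.array([[rng.integers(0, d + 1) for d in row] for row in D])
    data = ReadCountData(
        cell_ids=[f"c{i}" for i in range(n)],
        snv_ids=[f"s{q}" for q in range(m)],
        A=sparse.csr_matrix(A),
        D=sparse.csr_matrix(D),
    )
    embedding = rng.normal(size=(n, 2))
    return tree, data, embedding


def dense_posterior_oracle(tree, data, embedding, params):
    """Independent dense evaluation of the log posterior.

    Loops over every (cell, SNV) entry with the scipy-based emission oracle,
    adds the pooled-spread Gaussian clone likelihood and the uniform per-SNV
    attachment prior.
    """
    from clonegrower.model import MIN_SPREAD

    Y, nodes = tree.genotype_matrix()
    idx = {v: j for j, v in enumerate(nodes)}
    A, D = data.A.toarray(), data.D.toarray()
    snv_term = 0.0
    for i in range(data.n_cells):
        row = idx[int(tree.cell_assignment[i])]
        for q in range(data.n_snvs):
            snv_term += brute_force_entry_loglik(
                A[i, q], D[i, q], int(Y[row, q]), params.alpha, params.max_copies
            )
    n, ell = embedding.shape
    total_sq = 0.0
    for v in np.unique(tree.cell_assignment):
        rows = embedding[tree.cell_assignment == v]
        total_sq += np.sum((rows - rows.mean(axis=0)) ** 2)
    spread = max(total_sq / (n * ell), MIN_SPREAD)
    emb_term = norm.logpdf(
        embedding,
        loc=np.stack([
            embedding[tree.cell_assignment == v].mean(axis=0)
            for v in tree.cell_assignment
        ]),
        scale=np.sqrt(spread),
    ).sum()
    prior = -data.n_snvs * np.log(tree.n_nodes)
    return snv_term + emb_term + prior


class TestTreePosterior:
    def test_matches_dense_oracle(self, default_params):
        rng = np.random.default_rng(3)
        for _ in range(5):
            tree, data, embedding = _random_instance(rng)
            cache = LikelihoodCache(data.A, data.D, default_params)
            fast = tree_log_posterior(tree, cache, embedding)
            slow = dense_posterior_oracle(tree, data, embedding, default_params)
            assert np.isclose(fast, slow, atol=1e-8)

    def test_zero_depth_gives_zero_snv_term(self, default_params):
        n, m = 3, 2
        data = ReadCountData(
            cell_ids=["a", "b", "c"],
            snv_ids=["s", "t"],
            A=sparse.csr_matrix((n, m)),
            D=sparse.csr_matrix((n, m)),
        )
        cache = LikelihoodCache(data.A, data.D, default_params)
        assert cache.l0_total == 0.0 and cache.delta.nnz == 0

    def test_flipping_supported_genotype_decreases_score(self, default_params):
        """Removing an SNV from a clone whose cells all show variant reads hurts."""
        n, m = 4, 1
        A = sparse.csr_matrix(np.ones((n, m), dtype=int))
        D = sparse.csr_matrix(np.ones((n, m), dtype=int))
        data = ReadCountData(
            cell_ids=list("abcd"), snv_ids=["s"], A=A, D=D
        )
        emb = np.zeros((n, 2))
        cache = LikelihoodCache(data.A, data.D, default_params)
        with_snv = ClonalTree({0: -1, 1: 0}, np.array([0, 0, 1, 1]), np.array([0]))
        without = ClonalTree({0: -1, 1: 0}, np.array([0, 0, 1, 1]), np.array([1]))
        assert tree_log_posterior(with_snv, cache, emb) > tree_log_posterior(
            without, cache, emb
        )

    def test_invariant_under_cell_permutation_within_clone(self, default_params):
        rng = np.random.default_rng(4)
        tree, data, embedding = _random_instance(rng)
        cache = LikelihoodCache(data.A, data.D, default_params)
        base = tree_log_posterior(tree, cache, embedding)
        # swap two cells of the same clone (data rows swap with them)
        phi = tree.cell_assignment
        vals, counts = np.unique(phi, return_counts=True)
        clone = vals[np.argmax(counts)]
        i, j = np.flatnonzero(phi == clone)[:2]
        perm = np.arange(data.n_cells)
        perm[[i, j]] = [j, i]
        data2 = ReadCountData(
            cell_ids=data.cell_ids,
            snv_ids=data.snv_ids,
            A=data.A[perm],
            D=data.D[perm],
        )
        cache2 = LikelihoodCache(data2.A, data2.D, default_params)
        swapped = tree_log_posterior(tree, cache2, embedding[perm])
        assert np.isclose(base, swapped, atol=1e-9)


class TestAssignSnvs:
    def _chain(self, n=6, m=3):
        return ClonalTree(
            parent={0: -1, 1: 0},
            cell_assignment=np.array([0, 0, 0, 1, 1, 1]),
            snv_assignment=np.zeros(m, dtype=int),
        )

    def test_variant_reads_in_child_clade_pull_snv_down(self, default_params):
        tree = self._chain()
        A = np.zeros((6, 3), dtype=int)
        D = np.zeros((6, 3), dtype=int)
        D[:, 0] = 1
        A[3:, 0] = 1  # variants only in child cells
        D[:, 1] = 1
        A[:, 1] = 1  # variants everywhere -> clonal
        cache = LikelihoodCache(sparse.csr_matrix(A), sparse.csr_matrix(D), default_params)
        out = assign_snvs(tree, np.arange(3), [0, 1], cache)
        assert out[0] == 1  # child-private
        assert out[1] == 0  # clonal
        assert out[2] == 0  # zero coverage -> prior-preferred (first) node

    def test_matches_exhaustive_argmax(self, default_params):
        """Assignment agrees with brute-force enumeration of attachments."""
        rng = np.random.default_rng(5)
        for _ in range(3):
            tree, data, embedding = _random_instance(rng, n=5, m=3, k=3)
            cache = LikelihoodCache(data.A, data.D, default_params)
            nodes = tree.nodes
            got = assign_snvs(tree, np.arange(3), nodes, cache)
            for q in range(3):
                scores = []
                for v in nodes:
                    trial = tree.copy()
                    trial.snv_assignment = got.copy()
                    trial.snv_assignment[q] = v
                    scores.append(
                        dense_posterior_oracle(trial, data, embedding, default_params)
                    )
                best = max(scores)
                chosen = scores[nodes.index(int(got[q]))]
                assert np.isclose(chosen, best, atol=1e-8)

    def test_never_decreases_posterior(self, default_params):
        """Coordinate-ascent guarantee of the SNV reassignment step."""
        rng = np.random.default_rng(6)
        for _ in range(10):
            tree, data, embedding = _random_instance(rng)
            cache = LikelihoodCache(data.A, data.D, default_params)
            before = tree_log_posterior(tree, cache, embedding)
            tree.snv_assignment = assign_snvs(
                tree, np.arange(data.n_snvs), tree.nodes, cache
            )
            after = tree_log_posterior(tree, cache, embedding)
            assert after >= before - 1e-9
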