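"""Elementary tree operations: Linear, Branching and Identity.

A clonal tree is grown by repeatedly extending a frontier leaf ``v_j``,
reassigning only the SNVs gained at the leaf and the cells assigned to it:

* **Linear** replaces the leaf by a two-node chain (stepwise SNV
  acquisition): cells are bipartitioned, the side with more variant-read
  evidence becomes the descendant, and each SNV is re-attached to parent or
  child.
* **Branching** replaces the leaf by a parent with two children (divergence
  from a common ancestor): cells are split between the children — the parent
  keeps none during the operation — and each SNV is attached to parent, left
  or right child.
* **Identity** leaves the tree unchanged and closes the leaf.

Linear and Branching are solved by coordinate descent: with genotypes fixed,
cells are bipartitioned by a normalized cut over a combined CNA + SNV
feature; with the clustering fixed, SNVs are re-attached to their
maximum-posterior node.  The loop stops when the cell bipartition (nearly)
repeats, or when the local score stagnates, within a ``max_iter`` cap.
Restarts diversify the search — the kernel bandwidth is perturbed by up to
±20%, the eigenvector sweep threshold is jittered, and a balance floor on
the sweep rises across restarts — and the best-scoring distinct admissible
iterates are kept, so the grower can weigh alternative splits by full-tree
posterior.  One operation costs O(n^3 + nm): the cubic term bounds the
spectral bipartition, the linear term the SNV reassignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse
from scipy.linalg import eigh
from scipy.sparse.linalg import lobpcg
from scipy.spatial.distance import pdist, squareform

from .model import (
    MIN_SPREAD,
    _LOG_2PI,
    LikelihoodCache,
    ModelParams,
    tree_log_posterior,
)
from .tree import ClonalTree

__all__ = [
    "ClonalTree",
    "ElementaryResult",
    "InferenceContext",
    "combined_feature",
    "normalized_cut_bipartition",
    "linear_op",
    "branching_op",
    "identity_op",
]


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0, keepdims=True)
    sd = X.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def combined_feature(
    R_tilde: np.ndarray,
    A: sparse.spmatrix,
    D: sparse.spmatrix,
    cells: np.ndarray,
    snv_set: np.ndarray,
    weight: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Combined CNA + SNV feature for a set of cells.

    Concatenates each cell's embedding row (standardized per dimension over
    ``cells``) with a standardized SNV-evidence score over ``snv_set``: the
    fraction of covered loci in the set carrying at least one variant read
    (the cell mutational burden).  Cells covering no locus of the set get the
    cohort mean and are flagged in the returned missing mask.  With an empty
    ``snv_set`` the embedding-only features are returned.
    """
    cells = np.asarray(cells)
    A_pos = sparse.csc_matrix(A, copy=True)
    A_pos.data = (A_pos.data > 0).astype(np.float64)
    D_pos = sparse.csc_matrix(D, copy=True)
    D_pos.data = (D_pos.data > 0).astype(np.float64)
    ctxless = _FeatureBuilder(np.asarray(R_tilde, float), A_pos, D_pos, weight)
    return ctxless.build(cells, [np.asarray(snv_set)])


class _FeatureBuilder:
    """Vectorized CMB evidence + embedding feature construction."""

    def __init__(self, R_tilde, A_pos_csc, D_pos_csc, weight):
        self.R_tilde = R_tilde
        self.A_pos = A_pos_csc
        self.D_pos = D_pos_csc
        self.weight = weight
        self._memo: dict[bytes, tuple[np.ndarray, np.ndarray]] = {}

    def _colsums(self, snv_set: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        key = snv_set.tobytes()
        hit = self._memo.get(key)
        if hit is None:
            num = np.asarray(self.A_pos[:, snv_set].sum(axis=1)).ravel()
            den = np.asarray(self.D_pos[:, snv_set].sum(axis=1)).ravel()
            if len(self._memo) > 256:
                self._memo.clear()
            hit = self._memo[key] = (num, den)
        return hit

    def cmb_stats(self, cells: np.ndarray, snv_set: np.ndarray):
        """CMB of each cell over ``snv_set`` and a covered mask."""
        num_all, den_all = self._colsums(snv_set)
        num, den = num_all[cells], den_all[cells]
        covered = den > 0
        vals = np.zeros(len(cells))
        vals[covered] = num[covered] / den[covered]
        return vals, covered

    def build(self, cells: np.ndarray, snv_sets: list[np.ndarray]):
        base = _standardize(self.R_tilde[cells])
        cols, missing_any = [], np.zeros(len(cells), dtype=bool)
        for snv_set in snv_sets:
            if snv_set is None or len(snv_set) == 0:
                continue
            vals, covered = self.cmb_stats(cells, snv_set)
            if covered.any():
                vals[~covered] = vals[covered].mean()
            missing_any |= ~covered
            cols.append(self.weight * _standardize(vals[:, None]))
        if cols:
            base = np.hstack([base] + cols)
        return base, missing_any


# ---------------------------------------------------------------------------
# normalized cut
# ---------------------------------------------------------------------------


def similarity_matrix(features: np.ndarray, bandwidth_factor: float = 1.0) -> np.ndarray:
    """Gaussian-kernel similarity ``W_ij = exp(-(d_ij / sigma)^2)``.

    The bandwidth ``sigma`` is the median pairwise Euclidean distance times
    ``bandwidth_factor``; a zero median (all cells identical) yields the
    all-ones matrix.
    """
    d = pdist(np.asarray(features, dtype=np.float64))
    if d.size > 20001:  # deterministic subsample for the median at scale
        med = float(np.median(d[:: d.size // 20001 + 1]))
    elif d.size:
        med = float(np.median(d))
    else:
        med = 0.0
    n = features.shape[0]
    if med == 0.0:
        return np.ones((n, n))
    sigma = med * bandwidth_factor
    W = squareform(np.exp(-((d / sigma) ** 2)))
    np.fill_diagonal(W, 1.0)
    return W


def ncut_value(W: np.ndarray, left_mask: np.ndarray) -> float:
    """Exact Ncut(L, R) = cut/assoc(L,V) + cut/assoc(R,V) of a bipartition."""
    left_mask = np.asarray(left_mask, dtype=bool)
    deg = W.sum(axis=1)
    vol_l = float(deg[left_mask].sum())
    vol_r = float(deg[~left_mask].sum())
    if vol_l == 0 or vol_r == 0:
        return np.inf
    cut = float(W[np.ix_(left_mask, ~left_mask)].sum())
    return cut / vol_l + cut / vol_r


def _fiedler_vector(
    W: np.ndarray, deg: np.ndarray, seed: int, warm: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Second generalized eigenvector of (Deg - W) x = lambda Deg x.

    Equivalently the second-largest eigenvector of the symmetrically
    normalized similarity ``Deg^{-1/2} W Deg^{-1/2}``, computed with LOBPCG
    (deterministically initialized, optionally warm-started from a previous
    call) and a dense-eigensolver fallback for small or ill-conditioned
    problems.
    """
    n = W.shape[0]
    inv_sqrt = 1.0 / np.sqrt(deg)
    M = (W * inv_sqrt[:, None]) * inv_sqrt[None, :]
    if n >= 64:
        if warm is None or warm.shape != (n, 2):
            rng = np.random.default_rng(seed)
            warm = np.stack([np.sqrt(deg), rng.standard_normal(n)], axis=1)
        try:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")  # benign near-tolerance exits
                vals, vecs = lobpcg(M, warm, largest=True, maxiter=100, tol=1e-6)
            vecs = vecs[:, np.argsort(-vals)]
            if np.all(np.isfinite(vecs)):
                return inv_sqrt * vecs[:, 1], vecs
        except Exception:  # fall through to the dense path
            pass
    L_sym = np.eye(n) - M
    L_sym = 0.5 * (L_sym + L_sym.T)
    _, vecs = eigh(L_sym, subset_by_index=[0, 1])
    return inv_sqrt * vecs[:, 1], vecs[:, ::-1]


def normalized_cut_bipartition(
    features: np.ndarray,
    seed: int = 0,
    bandwidth_factor: float = 1.0,
    threshold_jitter: float = 0.0,
    min_side: int = 1,
    warm: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Bipartition cells by an approximate minimum normalized cut.

    Builds a Gaussian-kernel similarity graph, takes the second generalized
    eigenvector of the graph Laplacian, and thresholds it at the sweep
    position minimizing the exact Ncut.  With ``threshold_jitter > 0`` the
    threshold is drawn (seeded) among sweep positions within that relative
    slack of the minimum, which diversifies restarts; ``min_side`` restricts
    the sweep to bipartitions leaving at least that many cells on each side.
    Returns index arrays of the two (nonempty) sides and an info dict with
    the achieved ``ncut`` value and a ``no_signal`` flag set when all
    features coincide.
    """
    X = np.asarray(features, dtype=np.float64)
    n = X.shape[0]
    if n < 2:
        raise ValueError("normalized cut requires at least 2 cells")
    W = similarity_matrix(X, bandwidth_factor)
    if np.all(W == 1.0):
        half = n // 2
        left, right = np.arange(half), np.arange(half, n)
        return left, right, {
            "ncut": ncut_value(W, np.arange(n) < half),
            "no_signal": True,
            "warm": None,
        }

    deg = W.sum(axis=1)
    v, warm_out = _fiedler_vector(W, deg, seed, warm=warm)

    order = np.argsort(v, kind="stable")
    W_ord = W[np.ix_(order, order)]
    deg_ord = deg[order]
    vol = float(deg.sum())
    vol_l = np.cumsum(deg_ord)[:-1]
    # within-prefix association: row_prefix[p] = sum_{j<p} W_ord[p, j]
    csum = np.cumsum(W_ord, axis=1)
    diag = np.diagonal(W_ord)
    row_prefix = csum[np.arange(1, n), np.arange(0, n - 1)]
    within = np.cumsum(2.0 * row_prefix + diag[1:])
    within = np.concatenate([[diag[0]], diag[0] + within[:-1]])
    cut = vol_l - within
    with np.errstate(divide="ignore", invalid="ignore"):
        ncuts = cut / vol_l + cut / (vol - vol_l)
    min_side = max(1, min(min_side, n // 2))
    if min_side > 1:
        ncuts[: min_side - 1] = np.inf
        ncuts[n - min_side :] = np.inf
    best = float(np.nanmin(ncuts[np.isfinite(ncuts)]))
    if threshold_jitter > 0.0:
        rng = np.random.default_rng(seed)
        slack = abs(best) * threshold_jitter + 1e-12
        candidates = np.flatnonzero(ncuts <= best + slack)
        p = int(rng.choice(candidates)) + 1
    else:
        finite = np.where(np.isfinite(ncuts), ncuts, np.inf)
        p = int(np.argmin(finite)) + 1
    left, right = np.sort(order[:p]), np.sort(order[p:])
    return left, right, {
        "ncut": float(ncuts[p - 1]),
        "no_signal": False,
        "warm": warm_out,
    }


# ---------------------------------------------------------------------------
# operation machinery
# ---------------------------------------------------------------------------


@dataclass
class ElementaryResult:
    """Outcome of one elementary tree operation on a leaf."""

    tree: ClonalTree | None
    log_posterior: float
    converged: bool
    iterations: int
    applied: bool
    op: str


@dataclass
class _LocalSplit:
    """Tree-independent solution of one Linear/Branching subproblem."""

    op: str
    parent_cells: np.ndarray  # empty for branching
    left_cells: np.ndarray  # linear: child cells
    right_cells: np.ndarray  # linear: empty
    parent_snvs: np.ndarray
    left_snvs: np.ndarray
    right_snvs: np.ndarray
    local_score: float
    converged: bool
    iterations: int


class InferenceContext:
    """Bundles data, hyperparameters and precomputed likelihood terms."""

    def __init__(self, data, params: ModelParams, embedding: np.ndarray):
        self.data = data
        self.params = params
        self.embedding = np.asarray(embedding, dtype=np.float64)
        if self.embedding.shape[0] != data.n_cells:
            raise ValueError("embedding rows do not match the number of cells")
        self.cache = LikelihoodCache(data.A, data.D, params)
        A_pos = sparse.csc_matrix(data.A, copy=True)
        A_pos.data = (A_pos.data > 0).astype(np.float64)
        D_pos = sparse.csc_matrix(data.D, copy=True)
        D_pos.data = (D_pos.data > 0).astype(np.float64)
        self.A_pos = A_pos
        self.D_pos = D_pos
        # covered, variant-free observations: evidence an SNV is absent
        self.absent_obs = (D_pos - A_pos).tocsc()
        self.features = _FeatureBuilder(
            self.embedding, A_pos, D_pos, params.snv_feature_weight
        )

    def log_posterior(self, tree: ClonalTree) -> float:
        return tree_log_posterior(tree, self.cache, self.embedding)


def _local_embedding_score(rows: np.ndarray, parts: list[np.ndarray]) -> float:
    """Two-/three-way clustering likelihood of the leaf's embedding rows.

    Spherical Gaussian per part with the spread pooled over the leaf's own
    cells, so the score does not depend on the rest of the tree and the
    operation subproblem is self-contained.
    """
    n, ell = rows.shape
    total_sq = 0.0
    for part in parts:
        if len(part) == 0:
            continue
        sub = rows[part]
        total_sq += float(np.sum((sub - sub.mean(axis=0)) ** 2))
    spread = max(total_sq / (n * ell), MIN_SPREAD)
    return -0.5 * n * ell * (_LOG_2PI + np.log(spread) + total_sq / (n * ell * spread))


def _restart_min_side(r: int, restarts: int, n: int) -> int:
    """Sweep balance floor for restart ``r``: from unconstrained to near-even.

    The minimum-Ncut bipartition often shaves off one small, tight cluster;
    when that cluster is too small to ever support a detectable clone the
    unconstrained cut is a dead end.  Later restarts therefore search
    increasingly balanced bipartitions, up to a 40/60 split.
    """
    frac = 0.4 * r / max(restarts - 1, 1)
    return max(1, int(frac * n))


def _solve_linear(
    cells: np.ndarray,
    snvs: np.ndarray,
    ctx: InferenceContext,
    admissible=None,
    top_k: int = 1,
) -> list[_LocalSplit]:
    """Coordinate descent for the Linear subproblem on (cells, snvs).

    Returns up to ``top_k`` distinct admissible splits collected over all
    restarts, best local score first (both orientations of each bipartition
    are considered, since the evidence heuristic that picks the descendant
    side can err and the full-tree posterior is the better judge).  When an
    ``admissible`` predicate is supplied and no iterate satisfies it, the
    single best iterate overall is returned so the caller can report why it
    was rejected.
    """
    params = ctx.params
    rows = ctx.embedding[cells]
    s_all = ctx.cache.delta_colsums(cells)[snvs]
    pool: dict[bytes, _LocalSplit] = {}
    best: _LocalSplit | None = None

    def make_split(par_pos, child_pos, s_child, it):
        to_child = s_child > s_all  # ties stay at the (shallower) parent
        snv_score = float(np.sum(s_all[~to_child]) + s_child[to_child].sum())
        emb_score = _local_embedding_score(rows, [par_pos, child_pos])
        return _LocalSplit(
            op="linear",
            parent_cells=cells[par_pos],
            left_cells=cells[child_pos],
            right_cells=np.array([], dtype=np.int64),
            parent_snvs=snvs[~to_child],
            left_snvs=snvs[to_child],
            right_snvs=np.array([], dtype=np.int64),
            local_score=snv_score + emb_score,
            converged=False,
            iterations=it,
        )

    def consider(cand):
        nonlocal best
        if best is None or _better(cand, best):
            best = cand
        key = cand.left_cells.tobytes()
        held = pool.get(key)
        if held is None or cand.local_score > held.local_score:
            pool[key] = cand

    for r in range(params.restarts):
        seed_r = (params.seed + r) % (2**31 - 1)
        rng = np.random.default_rng(seed_r)
        bw = float(rng.uniform(0.8, 1.2))
        jitter = 0.0 if r == 0 else 0.05
        min_side = _restart_min_side(r, params.restarts, cells.size)
        evidence: list[np.ndarray] = [snvs]
        seen_keys: set[bytes] = set()
        best_score_r = -np.inf
        prev_mask: np.ndarray | None = None
        warm: np.ndarray | None = None
        stale = 0
        for it in range(1, params.max_iter + 1):
            feats, _ = ctx.features.build(cells, evidence)
            li, ri, info = normalized_cut_bipartition(
                feats, seed=seed_r + 1000 * it, bandwidth_factor=bw,
                threshold_jitter=jitter, min_side=min_side, warm=warm,
            )
            warm = info.get("warm")
            # orient: the side with higher mean SNV evidence is the descendant
            ev_set = evidence[0]
            cmb_vals, _ = ctx.features.cmb_stats(cells, ev_set)
            if cmb_vals[ri].mean() >= cmb_vals[li].mean():
                par_pos, child_pos = li, ri
            else:
                par_pos, child_pos = ri, li
            s_child = ctx.cache.delta_colsums(cells[child_pos])[snvs]
            cand = make_split(par_pos, child_pos, s_child, it)
            consider(cand)
            consider(make_split(child_pos, par_pos, s_all - s_child, it))
            if cand.local_score > best_score_r:
                best_score_r = cand.local_score
                stale = 0
            else:
                stale += 1
            if stale >= 3:  # coordinate descent stagnated
                break
            mask = np.zeros(cells.size, dtype=bool)
            mask[child_pos] = True
            key = mask.tobytes()
            stable = prev_mask is not None and (
                np.count_nonzero(mask ^ prev_mask) <= max(1, cells.size // 100)
            )
            if stable or key in seen_keys:  # fixpoint (up to a few cells) or cycle
                consider(replace(cand, converged=True))
                break
            seen_keys.add(key)
            prev_mask = mask
            child_snvs = cand.left_snvs
            evidence = [child_snvs if child_snvs.size else snvs]
    # gate lazily: admissibility does not steer the search, so only the
    # best-scoring distinct partitions need checking
    ranked = sorted(pool.values(), key=lambda s: -s.local_score)
    if admissible is not None:
        ranked = [s for s in ranked if admissible(s)]
    return ranked[:top_k] if ranked else [best]


def _solve_branching(
    cells: np.ndarray,
    snvs: np.ndarray,
    ctx: InferenceContext,
    admissible=None,
    top_k: int = 1,
) -> list[_LocalSplit]:
    """Coordinate descent for the Branching subproblem on (cells, snvs).

    Same restart/collection scheme as :func:`_solve_linear`, without the
    orientation question (children are unordered).
    """
    params = ctx.params
    rows = ctx.embedding[cells]
    s_all = ctx.cache.delta_colsums(cells)[snvs]
    pool: dict[bytes, _LocalSplit] = {}
    best: _LocalSplit | None = None

    def consider(cand):
        nonlocal best
        if best is None or _better(cand, best):
            best = cand
        key = cand.left_cells.tobytes()
        held = pool.get(key)
        if held is None or cand.local_score > held.local_score:
            pool[key] = cand

    for r in range(params.restarts):
        seed_r = (params.seed + r) % (2**31 - 1)
        rng = np.random.default_rng(seed_r)
        bw = float(rng.uniform(0.8, 1.2))
        jitter = 0.0 if r == 0 else 0.05
        min_side = _restart_min_side(r, params.restarts, cells.size)
        evidence: list[np.ndarray] = [snvs]
        seen_keys: set[bytes] = set()
        best_score_r = -np.inf
        prev_mask: np.ndarray | None = None
        warm: np.ndarray | None = None
        stale = 0
        for it in range(1, params.max_iter + 1):
            feats, _ = ctx.features.build(cells, evidence)
            li, ri, info = normalized_cut_bipartition(
                feats, seed=seed_r + 1000 * it, bandwidth_factor=bw,
                threshold_jitter=jitter, min_side=min_side, warm=warm,
            )
            warm = info.get("warm")
            # deterministic labels: the side holding the smallest cell goes left
            if cells[ri].min() < cells[li].min():
                li, ri = ri, li
            s_left = ctx.cache.delta_colsums(cells[li])[snvs]
            s_right = s_all - s_left
            scores = np.stack([s_all, s_left, s_right])
            choice = np.argmax(scores, axis=0)  # ties: parent, then left
            left_snvs = snvs[choice == 1]
            right_snvs = snvs[choice == 2]
            snv_score = float(scores[choice, np.arange(snvs.size)].sum())
            emb_score = _local_embedding_score(rows, [li, ri])
            cand = _LocalSplit(
                op="branching",
                parent_cells=np.array([], dtype=np.int64),
                left_cells=cells[li],
                right_cells=cells[ri],
                parent_snvs=snvs[choice == 0],
                left_snvs=left_snvs,
                right_snvs=right_snvs,
                local_score=snv_score + emb_score,
                converged=False,
                iterations=it,
            )
            consider(cand)
            if cand.local_score > best_score_r:
                best_score_r = cand.local_score
                stale = 0
            else:
                stale += 1
            if stale >= 3:  # coordinate descent stagnated
                break
            mask = np.zeros(cells.size, dtype=bool)
            mask[li] = True
            key = mask.tobytes()
            stable = prev_mask is not None and (
                min(
                    np.count_nonzero(mask ^ prev_mask),
                    np.count_nonzero(mask ^ ~prev_mask),
                )
                <= max(1, cells.size // 100)
            )
            if stable or key in seen_keys:  # fixpoint (up to a few cells) or cycle
                consider(replace(cand, converged=True))
                break
            seen_keys.add(key)
            prev_mask = mask
            new_evidence = [s for s in (left_snvs, right_snvs) if s.size]
            evidence = new_evidence if new_evidence else [snvs]
    # gate lazily: admissibility does not steer the search, so only the
    # best-scoring distinct partitions need checking
    ranked = sorted(pool.values(), key=lambda s: -s.local_score)
    if admissible is not None:
        ranked = [s for s in ranked if admissible(s)]
    return ranked[:top_k] if ranked else [best]


def _better(a: _LocalSplit, b: _LocalSplit) -> bool:
    """Restart comparison: higher score, then fewer iterations."""
    if not np.isclose(a.local_score, b.local_score):
        return a.local_score > b.local_score
    return a.iterations < b.iterations


def _apply_split(tree: ClonalTree, leaf: int, split: _LocalSplit) -> ClonalTree:
    """Graft a local split onto ``tree`` at ``leaf`` (only the leaf changes)."""
    new = tree.copy()
    next_id = max(new.parent) + 1
    if split.op == "linear":
        child = next_id
        new.parent[child] = leaf
        new.cell_assignment[split.left_cells] = child
        new.cell_assignment[split.parent_cells] = leaf
        new.snv_assignment[split.parent_snvs] = leaf
        new.snv_assignment[split.left_snvs] = child
        new.frontier = (set(tree.frontier) - {leaf}) | {child}
    else:
        left, right = next_id, next_id + 1
        new.parent[left] = leaf
        new.parent[right] = leaf
        new.cell_assignment[split.left_cells] = left
        new.cell_assignment[split.right_cells] = right
        new.snv_assignment[split.parent_snvs] = leaf
        new.snv_assignment[split.left_snvs] = left
        new.snv_assignment[split.right_snvs] = right
        new.frontier = (set(tree.frontier) - {leaf}) | {left, right}
    new.validate()
    return new


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def linear_op(tree: ClonalTree, leaf: int, ctx: InferenceContext) -> ElementaryResult:
    """Replace ``leaf`` by a parent -> child chain (stepwise SNV acquisition).

    Inapplicable (signaled, not fatal) when the leaf holds fewer than two
    cells or no reassignable SNVs.
    """
    cells = tree.cells_of(leaf)
    snvs = tree.gains(leaf)
    if cells.size < 2 or snvs.size == 0:
        return ElementaryResult(None, -np.inf, False, 0, False, "linear")
    split = _solve_linear(cells, snvs, ctx)[0]
    new = _apply_split(tree, leaf, split)
    return ElementaryResult(
        new, ctx.log_posterior(new), split.converged, split.iterations, True, "linear"
    )


def branching_op(tree: ClonalTree, leaf: int, ctx: InferenceContext) -> ElementaryResult:
    """Replace ``leaf`` by a parent with two children (clonal divergence).

    The parent keeps no cells during the operation; cells are split between
    the children and SNVs attached to parent, left or right child.
    """
    cells = tree.cells_of(leaf)
    snvs = tree.gains(leaf)
    if cells.size < 2 or snvs.size == 0:
        return ElementaryResult(None, -np.inf, False, 0, False, "branching")
    split = _solve_branching(cells, snvs, ctx)[0]
    new = _apply_split(tree, leaf, split)
    return ElementaryResult(
        new, ctx.log_posterior(new), split.converged, split.iterations, True, "branching"
    )


def identity_op(tree: ClonalTree, leaf: int, ctx: InferenceContext) -> ElementaryResult:
    """Return the tree unchanged with its posterior recomputed."""
    return ElementaryResult(tree, ctx.log_posterior(tree), True, 0, True, "identity")
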