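"""Three-phase clonal tree growth: initialize, grow recursively, rank.

The candidate set starts from a single root clone holding every cell with all
SNVs clonal.  Growth repeatedly extends each frontier leaf of each candidate
tree with the Linear and Branching elementary operations (Identity closes a
leaf); a proposal enters the candidate set only if every affected clone is
*detectable* — on average at least ``t`` of its cells cover each of its newly
introduced SNVs — and at least the minimum clone size, and the tree passes a
specificity *quality check*: cells outside a new clade must show a low median
mutational burden over the clade's gained SNVs.  Because an elementary
operation only touches the operated leaf's cells and SNVs, its solution is
reused across candidate trees that share the same leaf state.  Growth stops
at a fixpoint (no new candidates); every accepted operation increases the
clone count by one and clones cannot be smaller than the minimum size, so the
fixpoint is reached after finitely many steps.  Finally each candidate is
post-processed and the tree with maximum posterior is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .embedding import embed_read_counts
from .model import ModelParams
from .tree import ClonalTree, single_node_tree
from .tree_ops import (
    InferenceContext,
    _apply_split,
    _LocalSplit,
    _solve_branching,
    _solve_linear,
)


@dataclass
class CandidateSet:
    """Deduplicated collection of candidate clonal trees."""

    trees: dict[bytes, ClonalTree] = field(default_factory=dict)
    closed: dict[bytes, bool] = field(default_factory=dict)

    def add(self, tree: ClonalTree) -> bool:
        """Add a tree unless an identical (T, Y, phi) is already present."""
        key = tree.canonical_key()
        if key in self.trees:
            return False
        self.trees[key] = tree
        self.closed[key] = False
        return True

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees.values())


@dataclass
class GrowResult:
    """Output of :func:`grow`: the selected tree plus search diagnostics."""

    tree: ClonalTree
    log_posterior: float
    candidates: list[ClonalTree]
    log: list[dict]

    @property
    def n_nodes(self) -> int:
        return self.tree.n_nodes

    @property
    def n_clones(self) -> int:
        return self.tree.n_clones


def initialize(data) -> CandidateSet:
    """Candidate set holding the single-root tree: all cells, all SNVs clonal."""
    if data.n_cells == 0 or data.n_snvs == 0:
        raise ValueError("cannot initialize with zero cells or zero SNVs")
    cs = CandidateSet()
    cs.add(single_node_tree(data.n_cells, data.n_snvs))
    return cs


def is_detectable(
    clone_cells: np.ndarray,
    introduced_snvs: np.ndarray,
    D: sparse.spmatrix,
    t: int,
) -> bool:
    """Whether a clone has enough observed data to be trusted.

    True iff the clone and its introduced SNV set are nonempty and, averaged
    over the introduced SNVs, at least ``t`` cells of the clone have nonzero
    depth at the SNV.  Couples exactly the three quantities that determine
    detectability: sequencing coverage, clone size and the number of newly
    introduced SNVs.
    """
    clone_cells = np.asarray(clone_cells)
    introduced_snvs = np.asarray(introduced_snvs)
    if clone_cells.size == 0 or introduced_snvs.size == 0:
        return False
    sub = sparse.csr_matrix(D)[clone_cells][:, introduced_snvs]
    covered_entries = int((sub > 0).sum())
    return covered_entries / introduced_snvs.size >= t


def quality_check(tree: ClonalTree, ctx: InferenceContext, qc: float | None = None) -> bool:
    """Specificity check on every non-root node with gained SNVs.

    For a node with gain set ``S``, cells placed outside its clade that cover
    at least one locus of ``S`` should carry essentially no variant reads
    there: the check requires their median mutational burden over ``S`` to be
    at most ``qc``.  Nodes whose outside cells cover no locus pass vacuously.
    """
    if qc is None:
        qc = ctx.params.qc
    n = tree.n_cells
    for v in tree.nodes:
        gains = tree.gains(v)
        if gains.size == 0:
            continue
        inside = tree.cells_of_clade(v)
        outside = np.setdiff1d(np.arange(n), inside, assume_unique=True)
        if not _passes_qc(outside, gains, ctx, qc):
            return False
    return True


def _passes_qc(outside: np.ndarray, gains: np.ndarray, ctx, qc: float) -> bool:
    if outside.size == 0:
        return True
    vals, covered = ctx.features.cmb_stats(outside, gains)
    if not covered.any():
        return True
    return float(np.median(vals[covered])) <= qc


def _absence_supported(
    snvs: np.ndarray, complement_cells: np.ndarray, ctx: InferenceContext
) -> bool:
    """Whether demoting ``snvs`` below ``complement_cells`` is data-supported.

    Pushing an SNV out of a clone asserts that the remaining cells lack it;
    that assertion needs observations: on average at least ``t`` covered,
    variant-free entries per demoted SNV among the complement cells.  This
    mirrors detectability (which demands the new clone *shows* its gains) and
    closes the selection loophole of coordinate descent, where SNVs are
    demoted precisely because the complement happens to carry no variant
    reads — with too little coverage for that absence to mean anything.
    """
    if snvs.size == 0:
        return True
    if complement_cells.size == 0:
        return False
    per_cell = np.asarray(ctx.absent_obs[:, snvs].sum(axis=1)).ravel()
    return float(per_cell[complement_cells].sum()) / snvs.size >= ctx.params.threshold


def _accept_split(split: _LocalSplit, ctx: InferenceContext) -> tuple[bool, str]:
    """Gate a local elementary-operation result on detectability and quality."""
    params = ctx.params
    n = ctx.data.n_cells
    min_size = params.resolved_min_clone_size(n)
    if split.op == "linear":
        clones = [
            (split.parent_cells, split.parent_snvs),
            (split.left_cells, split.left_snvs),
        ]
        leaf_cells = np.concatenate([split.parent_cells, split.left_cells])
        qc_nodes = [
            (leaf_cells, split.parent_snvs),
            (split.left_cells, split.left_snvs),
        ]
    else:
        clones = [
            (split.left_cells, split.left_snvs),
            (split.right_cells, split.right_snvs),
        ]
        leaf_cells = np.concatenate([split.left_cells, split.right_cells])
        qc_nodes = [
            (leaf_cells, split.parent_snvs),
            (split.left_cells, split.left_snvs),
            (split.right_cells, split.right_snvs),
        ]
    for cells, gains in clones:
        if cells.size < min_size:
            return False, f"clone below minimum size {min_size}"
        if not _detectable_fast(cells, gains, ctx):
            return False, "clone not detectable"
    if split.op == "linear":
        absence = [(split.left_snvs, split.parent_cells)]
    else:
        absence = [
            (split.left_snvs, split.right_cells),
            (split.right_snvs, split.left_cells),
        ]
    for gains, complement in absence:
        if not _absence_supported(gains, complement, ctx):
            return False, "demotion not supported by absence observations"
    all_cells = np.arange(n)
    for clade_cells, gains in qc_nodes:
        if gains.size == 0:
            continue
        outside = np.setdiff1d(all_cells, clade_cells, assume_unique=True)
        if not _passes_qc(outside, gains, ctx, params.qc):
            return False, "failed quality check"
    return True, "accepted"


def _detectable_fast(cells: np.ndarray, snvs: np.ndarray, ctx) -> bool:
    if cells.size == 0 or snvs.size == 0:
        return False
    per_cell = np.asarray(ctx.D_pos[:, snvs].sum(axis=1)).ravel()
    return float(per_cell[cells].sum()) / snvs.size >= ctx.params.threshold


def post_process(tree: ClonalTree, ctx: InferenceContext, max_rounds: int = 10) -> ClonalTree:
    """Refine a grown tree: re-place cells, contract empty gain-free nodes.

    Cells are iteratively re-assigned to their maximum-posterior node with
    genotypes held fixed (an EM-style ascent: the assignment step maximizes
    with clone centers and spread fixed, the update step re-fits them), then
    nodes left with neither cells nor introduced SNVs are contracted.  The
    posterior never decreases.
    """
    tree = tree.copy()
    emb = ctx.embedding
    n, ell = emb.shape
    for _ in range(max_rounds):
        Y, nodes = tree.genotype_matrix()
        snv_scores = ctx.cache.delta @ Y.T.astype(np.float64)  # n x k
        centers = np.empty((len(nodes), ell))
        total_sq = 0.0
        for j, v in enumerate(nodes):
            cells = tree.cells_of(v)
            if cells.size:
                centers[j] = emb[cells].mean(axis=0)
                total_sq += float(np.sum((emb[cells] - centers[j]) ** 2))
            else:  # free parameter: place the center at the clade centroid
                clade_cells = tree.cells_of_clade(v)
                pool = emb[clade_cells] if clade_cells.size else emb
                centers[j] = pool.mean(axis=0)
        spread = max(total_sq / (n * ell), 1e-6)
        sq = ((emb[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        scores = snv_scores - 0.5 * sq / spread
        new_assign = np.array(nodes, dtype=np.int64)[np.argmax(scores, axis=1)]
        if np.array_equal(new_assign, tree.cell_assignment):
            break
        tree.cell_assignment = new_assign
    # contract nodes with no cells and no introduced SNVs
    changed = True
    while changed:
        changed = False
        for v in tree.nodes:
            if tree.cells_of(v).size or tree.gains(v).size:
                continue
            children = tree.children(v)
            if tree.parent[v] >= 0:
                for c in children:
                    tree.parent[c] = tree.parent[v]
                del tree.parent[v]
                tree.frontier.discard(v)
                changed = True
            elif len(children) == 1:  # empty root with a single child
                child = children[0]
                tree.parent[child] = -1
                del tree.parent[v]
                tree.frontier.discard(v)
                changed = True
    tree.validate()
    return tree


def _node_snv_contrib(tree: ClonalTree, v: int, ctx: InferenceContext) -> float:
    """SNV log-likelihood contribution of the gains attached at node ``v``."""
    gains = tree.gains(v)
    if gains.size == 0:
        return 0.0
    clade_cells = tree.cells_of_clade(v)
    if clade_cells.size == 0:
        return 0.0
    return float(ctx.cache.delta_colsums(clade_cells)[gains].sum())


def _decode_pruefer(seq: tuple[int, ...], n: int) -> dict[int, int]:
    """Labeled tree on ``n`` nodes from a Pruefer sequence, rooted at node 0."""
    degree = [1] * n
    for x in seq:
        degree[x] += 1
    adj: dict[int, list[int]] = {v: [] for v in range(n)}
    import heapq

    leaves = [v for v in range(n) if degree[v] == 1]
    heapq.heapify(leaves)
    for x in seq:
        leaf = heapq.heappop(leaves)
        adj[leaf].append(x)
        adj[x].append(leaf)
        degree[x] -= 1
        if degree[x] == 1:
            heapq.heappush(leaves, x)
    u = heapq.heappop(leaves)
    v = heapq.heappop(leaves)
    adj[u].append(v)
    adj[v].append(u)
    parent = {0: -1}
    stack = [0]
    seen = {0}
    while stack:
        w = stack.pop()
        for x in adj[w]:
            if x not in seen:
                seen.add(x)
                parent[x] = w
                stack.append(x)
    return parent


def restructure_clones(
    tree: ClonalTree, ctx: InferenceContext, max_clones: int = 6
) -> ClonalTree:
    """Exhaustive search over clone arrangements for a fixed cell partition.

    With the clustering fixed, the embedding term and the node-count prior
    are constant over all arrangements of the clones, and the SNV term
    decomposes into per-clone column sums, so every rooted tree over the
    clones (plus an optional cell-free root, which covers branching
    ancestors) can be scored in closed form: attach each SNV to the clade
    maximizing its summed evidence.  For up to ``max_clones`` clones all
    ``(k+1)^(k-1)`` labeled arrangements are enumerated and the best is
    kept if it improves the posterior; beyond that the tree is returned
    unchanged (the local moves of :func:`refine_topology` still apply).
    This repairs arrangement errors that greedy top-down growth cannot
    revisit, using exactly the model the growth itself optimizes.
    """
    from itertools import product

    clones = [v for v in tree.nodes if tree.cells_of(v).size]
    k = len(clones)
    if k < 2 or k > max_clones:
        return tree
    s = np.stack([ctx.cache.delta_colsums(tree.cells_of(v)) for v in clones])
    m = tree.n_snvs
    n_nodes = k + 1  # node 0 is a cell-free root, nodes 1..k the clones
    best_parent, best_score, best_omega = None, -np.inf, None
    for seq in product(range(n_nodes), repeat=k - 1):
        parent = _decode_pruefer(seq, n_nodes)
        member = np.zeros((n_nodes, k), dtype=np.float64)
        for v in range(n_nodes):
            stack = [v]
            while stack:
                w = stack.pop()
                if w > 0:
                    member[v, w - 1] = 1.0
                stack.extend(c for c, pp in parent.items() if pp == w)
        clade_sums = member @ s  # (n_nodes, m)
        choice = np.argmax(clade_sums, axis=0)
        # the attachment prior counts effective nodes: a cell-free root with a
        # single child is contracted, so nested chains beat tied star shapes
        n_children_root = sum(1 for pp in parent.values() if pp == 0)
        n_eff = n_nodes - (1 if n_children_root == 1 else 0)
        score = float(clade_sums[choice, np.arange(m)].sum()) - m * np.log(n_eff)
        if score > best_score:
            best_parent, best_score, best_omega = parent, score, choice
    cell_assignment = np.empty_like(tree.cell_assignment)
    for j, v in enumerate(clones):
        cell_assignment[tree.cells_of(v)] = j + 1
    best_omega = best_omega.astype(np.int64)
    root_children = [v for v, pp in best_parent.items() if pp == 0]
    if len(root_children) == 1:
        # a cell-free root with one child spans the same clade as the child:
        # contract it so clonal SNVs sit on the top clone
        child = root_children[0]
        del best_parent[0]
        best_parent[child] = -1
        best_omega[best_omega == 0] = child
    rebuilt = ClonalTree(
        parent=best_parent,
        cell_assignment=cell_assignment,
        snv_assignment=best_omega,
    )
    if ctx.log_posterior(rebuilt) > ctx.log_posterior(tree):
        return rebuilt
    return tree


def refine_topology(tree: ClonalTree, ctx: InferenceContext, max_passes: int = 8) -> ClonalTree:
    """Posterior-guided repair of clone placement ambiguities.

    Top-down growth fixes each split before seeing the data below it, so the
    final tree can carry the right clones in the wrong arrangement: a truly
    ancestral clone parked as a sibling, a parent-child pair nested upside
    down, or a clone attached beside the clone it actually descends from.
    Four local moves repair these motifs:

    * *promote*: move a clone's cells into its empty parent node;
    * *invert*: swap the cell sets of a parent and child clone;
    * *adopt*: re-attach a node (with its subtree) under one of its siblings;
    * *hoist*: re-attach a node to its grandparent.

    After each move the two affected nodes' gained SNVs are re-attached by
    maximum posterior.  None of the moves changes the cell partition, so the
    embedding term is untouched and a move's posterior delta reduces to the
    two nodes' SNV contributions — each trial costs two sparse column-sums.
    Moves are kept only when the posterior strictly improves (an ascent);
    passes repeat until no move helps.
    """
    from .model import assign_snvs

    best = tree.copy()
    for _ in range(max_passes):
        improved = False
        for v in sorted(best.parent):
            if best.parent.get(v, -1) < 0:
                continue
            p = best.parent[v]
            cells_v = best.cells_of(v)

            trials: list[tuple[ClonalTree, int]] = []
            if cells_v.size:
                cells_p = best.cells_of(p)
                swap = best.copy()
                swap.cell_assignment[cells_v] = p
                if cells_p.size:
                    swap.cell_assignment[cells_p] = v  # invert
                trials.append((swap, p))
            for s in best.children(p):
                if s == v:
                    continue
                adopt = best.copy()
                adopt.parent[v] = s
                trials.append((adopt, s))
            gp = best.parent[p]
            if gp >= 0:
                hoist = best.copy()
                hoist.parent[v] = gp
                trials.append((hoist, p))

            base = None
            for trial, other in trials:
                if base is None:
                    base = _node_snv_contrib(best, v, ctx)
                old = base + _node_snv_contrib(best, other, ctx)
                moved = np.concatenate([best.gains(other), best.gains(v)])
                if moved.size:
                    trial.snv_assignment = assign_snvs(
                        trial, moved, [other, v], ctx.cache
                    )
                new = _node_snv_contrib(trial, v, ctx) + _node_snv_contrib(
                    trial, other, ctx
                )
                if new > old + 1e-6:
                    best = trial
                    improved = True
                    break
        if not improved:
            break
    return best


def grow(
    data,
    params: ModelParams,
    embedding: np.ndarray | None = None,
    splits_per_op: int = 3,
    beam_width: int = 5,
    rank_top: int = 10,
) -> GrowResult:
    """Infer the maximum-posterior clonal tree for a dataset.

    Runs the full initialize/grow/rank pipeline.  ``embedding`` defaults to
    the linear embedding of the binned read counts in ``data.R``.  Each
    elementary operation contributes up to ``splits_per_op`` distinct
    admissible splits to the candidate set, so the final posterior ranking
    arbitrates between alternative topologies rather than committing to each
    leaf's single best local split.  To keep enumeration tractable the search
    expands candidates in waves, carrying the ``beam_width`` highest-posterior
    trees of each wave forward (every accepted tree still enters the
    candidate set and the final ranking); post-processing is applied to the
    ``rank_top`` best candidates before the final ranking.  Fully
    reproducible for a fixed ``params.seed``.
    """
    if embedding is None:
        if data.R is None:
            raise ValueError("either binned counts R or an embedding is required")
        embedding = embed_read_counts(
            data.R, n_components=params.embedding_dim, seed=params.seed
        )
    ctx = InferenceContext(data, params, embedding)
    candidates = initialize(data)
    posteriors: dict[bytes, float] = {
        key: ctx.log_posterior(tree) for key, tree in candidates.trees.items()
    }
    wave = list(candidates)
    op_cache: dict[tuple, tuple[list[_LocalSplit], str]] = {}
    log: list[dict] = []
    min_size = params.resolved_min_clone_size(data.n_cells)
    solvers = {"linear": _solve_linear, "branching": _solve_branching}

    while wave:
        next_wave: list[ClonalTree] = []
        for tree in wave:
            for leaf in sorted(tree.frontier):
                cells = tree.cells_of(leaf)
                snvs = tree.gains(leaf)
                for op_name, solver in solvers.items():
                    key = (op_name, cells.tobytes(), snvs.tobytes())
                    if key not in op_cache:
                        if cells.size < 2 * min_size or snvs.size == 0:
                            op_cache[key] = ([], "inapplicable")
                        else:
                            gate = lambda sp: _accept_split(sp, ctx)[0]  # noqa: E731
                            found = solver(
                                cells, snvs, ctx, admissible=gate, top_k=splits_per_op
                            )
                            accepted = [
                                sp for sp in found if _accept_split(sp, ctx)[0]
                            ]
                            reason = (
                                "accepted"
                                if accepted
                                else _accept_split(found[0], ctx)[1]
                            )
                            op_cache[key] = (accepted, reason)
                    splits, reason = op_cache[key]
                    log.append(
                        {
                            "op": op_name,
                            "leaf": leaf,
                            "n_cells": int(cells.size),
                            "n_snvs": int(snvs.size),
                            "status": reason,
                            "n_accepted": len(splits),
                            "local_score": splits[0].local_score if splits else None,
                        }
                    )
                    for split in splits:
                        new = _apply_split(tree, leaf, split)
                        new_key = new.canonical_key()
                        if candidates.add(new):
                            posteriors[new_key] = ctx.log_posterior(new)
                            next_wave.append((posteriors[new_key], new))
        next_wave.sort(key=lambda kv: -kv[0])
        wave = [t for _, t in next_wave[:beam_width]]

    ranked = [
        candidates.trees[k]
        for k in sorted(candidates.trees, key=lambda k: -posteriors[k])
    ]
    finalists: list[tuple[float, ClonalTree]] = []
    for cand in ranked[:rank_top]:
        refined = post_process(cand, ctx)
        finalists.append((ctx.log_posterior(refined), refined))
    finalists.sort(key=lambda kv: -kv[0])
    best_tree, best_lp = None, -np.inf
    for lp0, cand in finalists[:3]:
        refined = restructure_clones(cand, ctx)
        refined = post_process(refine_topology(refined, ctx), ctx)
        lp = ctx.log_posterior(refined)
        if best_tree is None or lp > best_lp + 1e-9 or (
            abs(lp - best_lp) <= 1e-9 and refined.n_nodes < best_tree.n_nodes
        ):
            best_tree, best_lp = refined, lp
    return GrowResult(
        tree=best_tree.relabeled(),
        log_posterior=float(best_lp),
        candidates=list(candidates),
        log=log,
    )
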