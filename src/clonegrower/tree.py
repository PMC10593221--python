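"""Clonal trees: rooted trees with node genotypes and a cell clustering.

A clonal tree couples three objects: a rooted tree over nodes ``v_0..v_{k-1}``
(node 0 is the root), an SNV attachment map assigning every SNV to the node
where it is gained, and a cell assignment map placing every cell at exactly one
node.  Genotypes follow the infinite sites model by construction: node ``j``
carries SNV ``q`` (``y_jq = 1``) exactly when the attachment node of ``q`` is
an ancestor of ``j`` or ``j`` itself, so each SNV is gained once and never
lost.  SNVs attached at the root are clonal.

Nodes may have an empty cell set (e.g. the unobserved common ancestor created
by a branching event); nodes with a nonempty cell set are *clones*, so the
node count can exceed the clone count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class TreeValidationError(ValueError):
    """Raised when (tree, genotypes, clustering) are mutually inconsistent."""


@dataclass
class ClonalTree:
    """Rooted clonal tree with SNV attachments and a cell clustering.

    Parameters
    ----------
    parent
        ``parent[v]`` is the parent node of ``v``; the root has parent ``-1``.
        Node ids are ``0..k-1`` with 0 the root.
    cell_assignment
        Integer array of length ``n``; ``cell_assignment[i]`` is the node
        holding cell ``i``.
    snv_assignment
        Integer array of length ``m``; ``snv_assignment[q]`` is the node where
        SNV ``q`` is gained (0 means clonal).
    """

    parent: dict[int, int]
    cell_assignment: np.ndarray
    snv_assignment: np.ndarray
    frontier: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.cell_assignment = np.asarray(self.cell_assignment, dtype=np.int64)
        self.snv_assignment = np.asarray(self.snv_assignment, dtype=np.int64)
        self.validate()

    # -- structure -----------------------------------------------------------

    @property
    def nodes(self) -> list[int]:
        return sorted(self.parent)

    @property
    def root(self) -> int:
        roots = [v for v, p in self.parent.items() if p < 0]
        return roots[0]

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_cells(self) -> int:
        return int(self.cell_assignment.shape[0])

    @property
    def n_snvs(self) -> int:
        return int(self.snv_assignment.shape[0])

    def children(self, v: int) -> list[int]:
        return sorted(u for u, p in self.parent.items() if p == v)

    def edges(self) -> list[tuple[int, int]]:
        return sorted((p, v) for v, p in self.parent.items() if p >= 0)

    def ancestors(self, v: int) -> list[int]:
        """Proper ancestors of ``v``, root first."""
        out = []
        while self.parent[v] >= 0:
            v = self.parent[v]
            out.append(v)
        return out[::-1]

    def clade(self, v: int) -> set[int]:
        """Nodes of the subtree rooted at ``v`` (including ``v``)."""
        out, stack = set(), [v]
        while stack:
            u = stack.pop()
            out.add(u)
            stack.extend(c for c, p in self.parent.items() if p == u)
        return out

    def is_ancestor(self, u: int, v: int) -> bool:
        """True iff ``u`` is a proper ancestor of ``v``."""
        while self.parent[v] >= 0:
            v = self.parent[v]
            if v == u:
                return True
        return False

    # -- cells / SNVs --------------------------------------------------------

    def cells_of(self, v: int) -> np.ndarray:
        return np.flatnonzero(self.cell_assignment == v)

    def cells_of_clade(self, v: int) -> np.ndarray:
        mask = np.isin(self.cell_assignment, list(self.clade(v)))
        return np.flatnonzero(mask)

    def gains(self, v: int) -> np.ndarray:
        """SNVs gained on the edge into ``v`` (clonal SNVs for the root)."""
        return np.flatnonzero(self.snv_assignment == v)

    def clones(self) -> list[int]:
        """Nodes with a nonempty cell set."""
        present = set(np.unique(self.cell_assignment).tolist())
        return sorted(present)

    @property
    def n_clones(self) -> int:
        return len(self.clones())

    def genotype_matrix(self) -> tuple[np.ndarray, list[int]]:
        """Binary genotypes ``Y`` (k x m) and the node order of its rows.

        ``Y[j, q] = 1`` iff the attachment node of ``q`` is ``nodes[j]`` or an
        ancestor of it, i.e. genotypes obey infinite sites by construction.
        """
        nodes = self.nodes
        idx = {v: j for j, v in enumerate(nodes)}
        in_clade = np.zeros((len(nodes), len(nodes)), dtype=bool)
        for v in nodes:
            in_clade[idx[v], idx[v]] = True
            for a in self.ancestors(v):
                in_clade[idx[a], idx[v]] = True
        # Y[j, q] = in_clade[attach(q), j]
        attach_rows = np.array([idx[int(a)] for a in self.snv_assignment])
        Y = in_clade[attach_rows, :].T.astype(np.int8)
        return Y, nodes

    def cell_genotypes(self) -> np.ndarray:
        """n x m genotype matrix where each cell inherits its clone's row."""
        Y, nodes = self.genotype_matrix()
        idx = {v: j for j, v in enumerate(nodes)}
        rows = np.array([idx[int(v)] for v in self.cell_assignment])
        return Y[rows, :]

    # -- invariants ----------------------------------------------------------

    def validate(self) -> None:
        nodes = set(self.parent)
        roots = [v for v, p in self.parent.items() if p < 0]
        if len(roots) != 1:
            raise TreeValidationError(f"expected exactly one root, found {roots}")
        for v, p in self.parent.items():
            if p >= 0 and p not in nodes:
                raise TreeValidationError(f"parent {p} of node {v} does not exist")
        # connectivity / acyclicity
        seen = self.clade(roots[0])
        if seen != nodes:
            raise TreeValidationError("tree is not connected")
        bad_cells = set(np.unique(self.cell_assignment).tolist()) - nodes
        if bad_cells:
            raise TreeValidationError(f"cells assigned to nonexistent nodes {sorted(bad_cells)}")
        bad_snvs = set(np.unique(self.snv_assignment).tolist()) - nodes
        if bad_snvs:
            raise TreeValidationError(f"SNVs assigned to nonexistent nodes {sorted(bad_snvs)}")
        if self.frontier - nodes:
            raise TreeValidationError("frontier contains nonexistent nodes")

    def check_infinite_sites(self, Y: np.ndarray | None = None) -> bool:
        """Verify that no SNV is lost along any edge of the tree."""
        if Y is None:
            Y, nodes = self.genotype_matrix()
        else:
            nodes = self.nodes
        idx = {v: j for j, v in enumerate(nodes)}
        for p, v in self.edges():
            if np.any((Y[idx[p]] == 1) & (Y[idx[v]] == 0)):
                return False
        # each SNV present at root of its presence set exactly once: implied by
        # attachment representation; when Y is supplied check single gain.
        for q in range(Y.shape[1]):
            carriers = {nodes[j] for j in np.flatnonzero(Y[:, q] == 1)}
            if not carriers:
                continue
            tops = [v for v in carriers if self.parent[v] < 0 or self.parent[v] not in carriers]
            if len(tops) != 1:
                return False
        return True

    # -- bookkeeping ---------------------------------------------------------

    def copy(self) -> "ClonalTree":
        return ClonalTree(
            parent=dict(self.parent),
            cell_assignment=self.cell_assignment.copy(),
            snv_assignment=self.snv_assignment.copy(),
            frontier=set(self.frontier),
        )

    def relabeled(self) -> "ClonalTree":
        """Copy with nodes renamed 0..k-1 in BFS order (root first)."""
        order: dict[int, int] = {}
        queue = [self.root]
        while queue:
            v = queue.pop(0)
            order[v] = len(order)
            queue.extend(self.children(v))
        return ClonalTree(
            parent={order[v]: (order[p] if p >= 0 else -1) for v, p in self.parent.items()},
            cell_assignment=np.array([order[int(v)] for v in self.cell_assignment]),
            snv_assignment=np.array([order[int(v)] for v in self.snv_assignment]),
            frontier={order[v] for v in self.frontier},
        )

    def canonical_key(self) -> bytes:
        """Canonical byte key identifying (T, Y, phi) up to node relabeling.

        Nodes are relabeled by a BFS in which children are ordered by the
        smallest cell index in their clade (falling back to the smallest SNV
        index for cell-free clades), which is invariant to creation order.
        """
        order: dict[int, int] = {}
        n = self.n_cells

        def sort_key(v: int) -> tuple[int, int]:
            cells = self.cells_of_clade(v)
            snvs = np.flatnonzero(np.isin(self.snv_assignment, list(self.clade(v))))
            c = int(cells[0]) if cells.size else n
            s = int(snvs[0]) if snvs.size else self.n_snvs
            return (c, s)

        queue = [self.root]
        while queue:
            v = queue.pop(0)
            order[v] = len(order)
            queue.extend(sorted(self.children(v), key=sort_key))
        phi = np.array([order[int(v)] for v in self.cell_assignment], dtype=np.int32)
        omega = np.array([order[int(v)] for v in self.snv_assignment], dtype=np.int32)
        par = np.array(
            [order.get(self.parent[v], -1) for v in sorted(order, key=order.get)],
            dtype=np.int32,
        )
        return phi.tobytes() + b"|" + omega.tobytes() + b"|" + par.tobytes()


def single_node_tree(n_cells: int, n_snvs: int) -> ClonalTree:
    """The initial tree: one root clone holding every cell and every SNV."""
    return ClonalTree(
        parent={0: -1},
        cell_assignment=np.zeros(n_cells, dtype=np.int64),
        snv_assignment=np.zeros(n_snvs, dtype=np.int64),
        frontier={0},
    )
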