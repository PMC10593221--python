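"""Reading and writing of count matrices, embeddings, trees and clusterings.

The canonical on-disk format for SNV read counts is a long (triplet) TSV with
columns ``cell, snv, variant_reads, total_reads``: at ultra-low coverage the
overwhelming majority of (cell, SNV) entries have zero depth, so only covered
entries are stored.  Absent pairs are semantically ``d = 0`` (no coverage),
not missing-at-random markers.  Binned read counts are a dense CSV/TSV with a
cell-id column; bins are opaque features (labels of the form
``chrom:start-end`` are interpreted 0-based half-open but never required).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy import sparse

from .model import ModelParams
from .tree import ClonalTree


class DataValidationError(ValueError):
    """Raised when an input file violates a count-data invariant."""


@dataclass
class ReadCountData:
    """Variant/total SNV read counts plus optional binned read counts.

    Attributes
    ----------
    cell_ids, snv_ids
        Unique labels, in first-appearance order of the source file.
    A, D
        Sparse ``n x m`` variant and total read count matrices,
        ``0 <= A <= D`` entrywise.
    R, bin_ids
        Optional dense ``n x b`` binned read counts aligned with
        ``cell_ids``, and the ``b`` bin labels.
    """

    cell_ids: list[str]
    snv_ids: list[str]
    A: sparse.csr_matrix
    D: sparse.csr_matrix
    R: np.ndarray | None = None
    bin_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise DataValidationError("duplicate cell ids")
        if len(set(self.snv_ids)) != len(self.snv_ids):
            raise DataValidationError("duplicate SNV ids")
        self.A = sparse.csr_matrix(self.A)
        self.D = sparse.csr_matrix(self.D)
        if self.A.shape != (self.n_cells, self.n_snvs) or self.A.shape != self.D.shape:
            raise DataValidationError("A/D shape does not match cell and SNV ids")
        if (self.A - self.D).max() > 0:
            raise DataValidationError("found entries with a > d")
        if self.A.nnz and self.A.data.min() < 0:
            raise DataValidationError("negative variant read counts")
        if self.R is not None:
            self.R = np.asarray(self.R, dtype=np.float64)
            if self.R.shape[0] != self.n_cells:
                raise DataValidationError("R row count does not match cell ids")
            if not np.all(np.isfinite(self.R)) or self.R.min() < 0:
                raise DataValidationError("R must be finite and nonnegative")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_snvs(self) -> int:
        return len(self.snv_ids)


def load_read_counts(path: str | os.PathLike | io.IOBase) -> ReadCountData:
    """Load SNV read counts from a long-format TSV.

    The file needs a header with columns ``cell, snv, variant_reads,
    total_reads`` and integer counts; each (cell, snv) pair may appear at most
    once.  Cell and SNV orderings follow first appearance.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"cell": str, "snv": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise DataValidationError(f"malformed read count file: {exc}") from exc
    required = ["cell", "snv", "variant_reads", "total_reads"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataValidationError(f"missing columns {missing}")
    if len(df) == 0:
        raise DataValidationError("no records")
    for col in ("variant_reads", "total_reads"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round()) | (vals < 0)
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise DataValidationError(
                f"parse error at line {line}: {col} must be a nonnegative integer"
            )
        df[col] = vals.astype(np.int64)
    dup = df.duplicated(subset=["cell", "snv"])
    if dup.any():
        row = df[dup].iloc[0]
        raise DataValidationError(f"duplicate record for ({row['cell']}, {row['snv']})")
    bad = df["variant_reads"] > df["total_reads"]
    if bad.any():
        row = df[bad].iloc[0]
        raise DataValidationError(
            f"variant reads exceed total reads for ({row['cell']}, {row['snv']})"
        )
    cell_ids = list(pd.unique(df["cell"]))
    snv_ids = list(pd.unique(df["snv"]))
    ci = {c: i for i, c in enumerate(cell_ids)}
    si = {s: i for i, s in enumerate(snv_ids)}
    rows = df["cell"].map(ci).to_numpy()
    cols = df["snv"].map(si).to_numpy()
    shape = (len(cell_ids), len(snv_ids))
    A = sparse.csr_matrix((df["variant_reads"].to_numpy(), (rows, cols)), shape=shape)
    D = sparse.csr_matrix((df["total_reads"].to_numpy(), (rows, cols)), shape=shape)
    return ReadCountData(cell_ids=cell_ids, snv_ids=snv_ids, A=A, D=D)


def load_binned_counts(
    path: str | os.PathLike | io.IOBase,
    cell_ids: list[str] | None = None,
    sep: str = ",",
) -> tuple[np.ndarray, list[str]]:
    """Load an ``n x b`` binned read count table (first column: cell id).

    When ``cell_ids`` is given, rows are reconciled against it by id — not by
    position — and an error lists any missing cells.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    R = df.to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(R)):
        raise DataValidationError("binned counts contain NaN or infinite values")
    if R.size and R.min() < 0:
        raise DataValidationError("binned counts must be nonnegative")
    if cell_ids is not None:
        missing = [c for c in cell_ids if c not in df.index]
        if missing:
            raise DataValidationError(f"binned counts missing cells: {missing}")
        df = df.loc[cell_ids]
        R = df.to_numpy(dtype=np.float64)
    return R, [str(c) for c in df.columns]


def load_embedding(
    path: str | os.PathLike | io.IOBase, cell_ids: list[str] | None = None
) -> np.ndarray:
    """Load a precomputed embedding CSV (cell, dim1..dimL), reconciled by id."""
    R_tilde, _ = load_binned_counts(path, cell_ids=cell_ids)
    return R_tilde


def load_params(path: str | os.PathLike) -> ModelParams:
    """Load model hyperparameters from a YAML config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return ModelParams(**raw)


def write_solution(
    tree: ClonalTree,
    cell_ids: list[str],
    snv_ids: list[str],
    out_dir: str | os.PathLike,
) -> None:
    """Write a solution as edge-list, genotype, clustering TSVs and a DOT file.

    Files written: ``tree.tsv`` (parent, child node ids), ``genotypes.tsv``
    (k x m 0/1 matrix indexed by node), ``clustering.tsv`` (cell, node),
    ``snv_assignment.tsv`` (snv, node) and ``tree.dot`` with nodes annotated
    by the number of SNVs gained and cells assigned.
    """
    tree.validate()
    os.makedirs(out_dir, exist_ok=True)
    out = os.fspath(out_dir)
    with open(os.path.join(out, "tree.tsv"), "w") as fh:
        fh.write("parent\tchild\n")
        for p, v in tree.edges():
            fh.write(f"v{p}\tv{v}\n")
    Y, nodes = tree.genotype_matrix()
    pd.DataFrame(Y, index=[f"v{v}" for v in nodes], columns=snv_ids).to_csv(
        os.path.join(out, "genotypes.tsv"), sep="\t", index_label="node"
    )
    pd.DataFrame(
        {"cell": cell_ids, "node": [f"v{int(v)}" for v in tree.cell_assignment]}
    ).to_csv(os.path.join(out, "clustering.tsv"), sep="\t", index=False)
    pd.DataFrame(
        {"snv": snv_ids, "node": [f"v{int(v)}" for v in tree.snv_assignment]}
    ).to_csv(os.path.join(out, "snv_assignment.tsv"), sep="\t", index=False)
    with open(os.path.join(out, "tree.dot"), "w") as fh:
        fh.write("digraph clonal_tree {\n")
        for v in tree.nodes:
            n_gain = int(tree.gains(v).size)
            n_cell = int(tree.cells_of(v).size)
            fh.write(
                f'  v{v} [label="v{v}\\n{n_gain} SNVs\\n{n_cell} cells"];\n'
            )
        for p, v in tree.edges():
            fh.write(f"  v{p} -> v{v};\n")
        fh.write("}\n")


def read_solution(
    in_dir: str | os.PathLike, cell_ids: list[str], snv_ids: list[str]
) -> ClonalTree:
    """Read back a solution written by :func:`write_solution`."""
    out = os.fspath(in_dir)
    edges = pd.read_csv(os.path.join(out, "tree.tsv"), sep="\t")
    parent: dict[int, int] = {}
    for _, row in edges.iterrows():
        p, v = int(row["parent"][1:]), int(row["child"][1:])
        parent[v] = p
        parent.setdefault(p, -1)
    if not parent:  # single-node tree
        parent = {0: -1}
    clustering = pd.read_csv(os.path.join(out, "clustering.tsv"), sep="\t")
    clustering = clustering.set_index("cell").loc[cell_ids]
    snvs = pd.read_csv(os.path.join(out, "snv_assignment.tsv"), sep="\t")
    snvs = snvs.set_index("snv").loc[snv_ids]
    cell_assignment = clustering["node"].str[1:].astype(int).to_numpy()
    snv_assignment = snvs["node"].str[1:].astype(int).to_numpy()
    bad = set(cell_assignment) - set(parent)
    if bad:
        raise DataValidationError(f"cells assigned to nonexistent nodes {sorted(bad)}")
    return ClonalTree(
        parent=parent,
        cell_assignment=cell_assignment,
        snv_assignment=snv_assignment,
    )


def write_read_counts(data: ReadCountData, path: str | os.PathLike) -> None:
    """Write SNV read counts as the canonical long-format TSV."""
    coo = data.D.tocoo()
    a = np.asarray(data.A[coo.row, coo.col]).ravel().astype(np.int64)
    df = pd.DataFrame(
        {
            "cell": [data.cell_ids[i] for i in coo.row],
            "snv": [data.snv_ids[j] for j in coo.col],
            "variant_reads": a,
            "total_reads": coo.data.astype(np.int64),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_binned_counts(data: ReadCountData, path: str | os.PathLike) -> None:
    """Write binned read counts as a CSV with a leading cell-id column."""
    if data.R is None:
        raise ValueError("no binned counts to write")
    bin_ids = data.bin_ids or [f"bin{j}" for j in range(data.R.shape[1])]
    pd.DataFrame(data.R, index=data.cell_ids, columns=bin_ids).to_csv(
        path, index_label="cell"
    )
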