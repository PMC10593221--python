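"""Low-dimensional embedding of binned read counts as a copy-number proxy.

With uniform ultra-low coverage sequencing, per-bin read counts are
proportional to local copy number, so distances between cells in a
low-dimensional embedding of the normalized counts reflect copy-number
similarity.  Normalization removes library-size differences (each cell is
scaled to the median total count) and compresses dynamic range with
``log2(x + 1)``.  The default reduction is linear (principal axes), which is
deterministic and preserves pairwise distances as well as any rank-l
approximation can; a seeded nonlinear UMAP reduction is optional.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA


@dataclass
class Embedding:
    """An ``n x l`` embedding of cells, aligned with the cell ordering."""

    coords: np.ndarray
    seed: int
    method: str = "pca"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding contains non-finite entries")


def normalize_bins(R: np.ndarray, cell_ids: list[str] | None = None) -> np.ndarray:
    """Library-size normalize and log-transform binned read counts.

    Each cell's row is scaled to the median library size (total count) and
    then transformed with ``log2(x + 1)``.  Deterministic; scale-invariant
    per cell.
    """
    R = np.asarray(R, dtype=np.float64)
    totals = R.sum(axis=1)
    zero_rows = np.flatnonzero(totals == 0)
    if zero_rows.size:
        label = cell_ids[zero_rows[0]] if cell_ids else f"row {zero_rows[0]}"
        raise ValueError(f"cell {label} has zero reads in every bin")
    target = float(np.median(totals))
    scaled = R * (target / totals)[:, None]
    return np.log2(scaled + 1.0)


def embed(
    R_norm: np.ndarray,
    n_components: int = 10,
    seed: int = 0,
    method: str = "pca",
) -> Embedding:
    """Embed normalized binned counts into ``n_components`` dimensions.

    ``method="pca"`` (default) projects onto the top principal axes of the
    mean-centered data; ``method="umap"`` applies a seeded nonlinear
    reduction (requires umap-learn).  Identical rows map to identical points
    under the linear method, and a fixed seed gives bitwise-identical output.
    """
    R_norm = np.asarray(R_norm, dtype=np.float64)
    n, b = R_norm.shape
    if n_components < 2:
        raise ValueError("embedding dimension must be at least 2")
    if n_components >= b:
        raise ValueError(
            f"embedding dimension {n_components} must be smaller than "
            f"the number of bins {b}"
        )
    n_components = min(n_components, n)
    if method == "pca":
        pca = PCA(n_components=n_components, svd_solver="full", random_state=seed)
        coords = pca.fit_transform(R_norm)
        # fix signs for reproducibility across BLAS builds
        signs = np.sign(np.where(pca.components_.sum(axis=1) == 0, 1.0,
                                 pca.components_.sum(axis=1)))
        coords = coords * signs[None, :]
    elif method == "umap":
        import umap

        reducer = umap.UMAP(n_components=n_components, random_state=seed)
        coords = np.asarray(reducer.fit_transform(R_norm), dtype=np.float64)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return Embedding(coords=coords, seed=seed, method=method)


def embed_read_counts(R: np.ndarray, n_components: int = 10, seed: int = 0) -> np.ndarray:
    """Convenience: normalize bins and return the default linear embedding."""
    return embed(normalize_bins(R), n_components=n_components, seed=seed).coords
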