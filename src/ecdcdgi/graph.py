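"""Canonical in-memory representation of a labeled gene-gene network.

A :class:`GeneGraph` bundles the three inputs of the driver-gene
identification task: an undirected gene-gene network (symmetric binary
adjacency with zero diagonal), a per-gene multi-omic feature matrix, and a
partial label vector marking each gene as a known driver (1), a confident
non-driver (0), or unlabeled (NaN).  Node order is fixed once at
construction -- lexicographic by gene identifier -- and every matrix uses
that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = ["GeneGraph"]


@dataclass
class GeneGraph:
    """A gene-gene network with node features and partial binary labels.

    Parameters
    ----------
    node_ids : list of str
        Unique gene identifiers, in the canonical (lexicographic) order
        shared by all matrices.
    A : scipy.sparse.csr_array or dense array, shape (N, N)
        Symmetric binary adjacency with zero diagonal.
    X : ndarray, shape (N, F)
        Real-valued feature matrix, one row per gene.
    y : ndarray, shape (N,)
        Label vector with entries in {1.0, 0.0, NaN}; NaN marks
        unlabeled genes, which receive predictions but never enter a loss.
    """

    node_ids: list[str]
    A: sp.csr_array
    X: np.ndarray
    y: np.ndarray
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not sp.issparse(self.A):
            self.A = sp.csr_array(np.asarray(self.A))
        else:
            self.A = sp.csr_array(self.A)
        self.A = self.A.astype(np.float64)
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.index = {g: i for i, g in enumerate(self.node_ids)}
        self.validate()

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        """Check all structural invariants; raise ``ValueError`` on violation."""
        n = len(self.node_ids)
        if len(self.index) != n:
            raise ValueError("duplicate gene ids in node_ids")
        if self.A.shape != (n, n):
            raise ValueError(f"adjacency shape {self.A.shape} != ({n}, {n})")
        if self.A.diagonal().any():
            raise ValueError("adjacency has nonzero diagonal (self-loops)")
        if (self.A != self.A.T).nnz != 0:
            raise ValueError("adjacency is not symmetric")
        if self.X.ndim != 2 or self.X.shape[0] != n:
            raise ValueError(f"feature matrix has {self.X.shape[0]} rows, expected {n}")
        if self.y.shape != (n,):
            raise ValueError(f"label vector length {self.y.shape} != {n}")
        labeled = ~np.isnan(self.y)
        vals = np.unique(self.y[labeled])
        if not np.isin(vals, [0.0, 1.0]).all():
            raise ValueError("labels must be 0, 1 or NaN")

    # -- convenience -----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.A.sum(axis=1)).ravel()

    @property
    def labeled_mask(self) -> np.ndarray:
        """Boolean mask of genes with a 0/1 label."""
        return ~np.isnan(self.y)

    @property
    def n_edges(self) -> int:
        """Number of undirected edges."""
        return int(self.A.nnz // 2)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneGraph):
            return NotImplemented
        return (
            self.node_ids == other.node_ids
            and (self.A != other.A).nnz == 0
            and np.array_equal(self.X, other.X)
            and np.array_equal(self.y, other.y, equal_nan=True)
        )
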