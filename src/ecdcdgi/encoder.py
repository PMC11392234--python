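"""Building blocks of the energy-constrained diffusion attention encoder.

The encoder views message passing on the gene-gene network as a discrete
diffusion process: each gene's embedding is updated by a convex
combination of every other gene's embedding, with per-pair diffusivities
realized as a row-normalized sigmoid-kernel attention matrix.  A parallel
graph-convolution branch injects the network topology through the
symmetrically normalized adjacency.  The two branch outputs are
concatenated, linearly fused, mixed with the previous layer's embedding
(the residual analogue of the diffusion self-term) and layer-normalized.

Orientation convention, fixed repo-wide: embeddings are row vectors, so
every linear map is a right multiplication ``Z @ W`` (the transpose of the
column-vector convention ``W Z`` sometimes written in the literature).

All functions accept either plain ``ndarray`` inputs (pure NumPy forward)
or :class:`~ecdcdgi.autodiff.Tensor` inputs (tracked for gradients); see
:mod:`ecdcdgi.autodiff`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.sparse as sp

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "project_features",
    "compute_qkv",
    "pairwise_similarity",
    "attention_propagate",
    "gcn_propagate",
    "normalized_adjacency",
    "fuse_residual",
    "diffusion_energy",
    "EnergyDiagnosticConfig",
    "LayerState",
]


def _shape(x) -> tuple[int, ...]:
    return x.shape if isinstance(x, Tensor) else np.asarray(x).shape


def _check_2d(name: str, x, cols: int | None = None) -> tuple[int, int]:
    s = _shape(x)
    if len(s) != 2:
        raise ValueError(f"{name} must be 2-D, got shape {s}")
    if cols is not None and s[1] != cols:
        raise ValueError(f"{name} has {s[1]} columns, expected {cols}")
    return s


# ---------------------------------------------------------------------------


def project_features(X, W_I, b_I):
    """Initial embedding ``Z0 = ReLU(X @ W_I + b_I)``.

    Maps the N x F multi-omic feature matrix into the d-dimensional
    embedding space through one fully connected ReLU layer; the result
    serves as the layer-0 embedding of the diffusion stack.
    """
    n, f = _check_2d("X", X)
    fw, d = _check_2d("W_I", W_I)
    if fw != f:
        raise ValueError(f"W_I expects {fw} input features, X has {f}")
    if _shape(b_I)[-1] != d:
        raise ValueError("b_I length does not match embedding dim")
    return ad.relu(X @ W_I + b_I)


def compute_qkv(Z, W_K, W_Q, W_V):
    """Per-layer key/query/value transforms ``K = Z @ W_K`` etc."""
    n, d = _check_2d("Z", Z)
    for name, W in (("W_K", W_K), ("W_Q", W_Q), ("W_V", W_V)):
        rows, _ = _check_2d(name, W)
        if rows != d:
            raise ValueError(f"{name} has {rows} rows, expected {d}")
    return Z @ W_K, Z @ W_Q, Z @ W_V


def pairwise_similarity(Q, K):
    """All-pairs sigmoid-kernel similarity ``R[i, j] = sigmoid(q_i . k_j)``.

    The sigmoid keeps every entry strictly inside (0, 1), so the matrix is
    dense and positive: every gene attends to every other gene (and to
    itself -- the diagonal is included).
    """
    sq = _check_2d("Q", Q)
    sk = _check_2d("K", K)
    if sq != sk:
        raise ValueError(f"Q shape {sq} != K shape {sk}")
    return ad.sigmoid(Q @ ad.transpose(K))


def attention_propagate(R, V):
    """Diffusion step ``P = rownorm(R) @ V``.

    Each row of ``R`` is divided by its sum (strictly positive for a
    sigmoid-kernel similarity), yielding a row-stochastic diffusivity
    matrix; every output row is therefore a convex combination of the
    rows of ``V``.
    """
    n, m = _check_2d("R", R)
    if n != m:
        raise ValueError(f"R must be square, got {(n, m)}")
    nv, _ = _check_2d("V", V)
    if nv != n:
        raise ValueError("V row count does not match R")
    rdata = R.data if isinstance(R, Tensor) else np.asarray(R)
    if not np.isfinite(rdata).all():
        raise ValueError("non-finite entries in similarity matrix R")
    return ad.row_normalize(R) @ V


def normalized_adjacency(A) -> sp.csr_array:
    """Symmetric normalization ``D^{-1/2} A D^{-1/2}`` as a sparse matrix.

    Zero-degree (isolated) nodes use the convention ``0^{-1/2} = 0``:
    their rows and columns are exactly zero, so graph convolution assigns
    them the zero embedding.
    """
    A = sp.csr_array(A) if not sp.issparse(A) else sp.csr_array(A)
    if (A != A.T).nnz != 0:
        raise ValueError("adjacency must be symmetric")
    if A.nnz and A.data.min() < 0:
        raise ValueError("adjacency must be non-negative")
    deg = np.asarray(A.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        dinv = 1.0 / np.sqrt(deg)
    dinv[~np.isfinite(dinv)] = 0.0
    D = sp.diags_array(dinv)
    return sp.csr_array(D @ A @ D)


def gcn_propagate(A, V):
    """Graph-convolution step ``H = D^{-1/2} A D^{-1/2} @ V``.

    Propagates the value matrix over the network topology with symmetric
    degree normalization and no self-loop augmentation; isolated nodes
    receive the zero vector.
    """
    Ahat = normalized_adjacency(A)
    nv, _ = _check_2d("V", V)
    if Ahat.shape[0] != nv:
        raise ValueError("V row count does not match adjacency")
    return ad.const_matmul(Ahat, V)


def fuse_residual(P, H, Z_prev, W_d, beta, gain=None, shift=None, eps: float = 1e-5):
    """Fuse the two branch outputs and apply the residual + LayerNorm step.

    ``Z_next = LayerNorm(beta * (concat[P || H] @ W_d) + (1 - beta) * Z_prev)``.

    ``beta`` in [0, 1] balances fresh propagated information against the
    previous layer's embedding; the residual share ``(1 - beta) Z_prev``
    plays the role of the diffusion self-term and counteracts
    over-smoothing.  ``gain``/``shift`` are the learned LayerNorm affine
    parameters (identity by default).
    """
    if not 0.0 <= float(beta) <= 1.0:
        raise ValueError(f"beta must lie in [0, 1], got {beta}")
    n, d = _check_2d("Z_prev", Z_prev)
    _check_2d("P", P, cols=d)
    _check_2d("H", H, cols=d)
    rows, cols = _check_2d("W_d", W_d)
    if rows != 2 * d or cols != d:
        raise ValueError(f"W_d shape {(rows, cols)} != ({2 * d}, {d})")
    if gain is None:
        gain = np.ones(d)
    if shift is None:
        shift = np.zeros(d)
    fused = ad.concat([P, H], axis=1) @ W_d
    mixed = float(beta) * fused + (1.0 - float(beta)) * Z_prev
    return ad.layer_norm(mixed, gain, shift, eps=eps)


# ---------------------------------------------------------------------------
# Diagnostic energy functional


def _log1p_kappa(s: np.ndarray) -> np.ndarray:
    return np.log1p(s)


@dataclass
class EnergyDiagnosticConfig:
    """Configuration of the diffusion energy diagnostic.

    ``omega`` weighs the global pairwise term against the local
    consistency term; ``kappa`` is a monotonically increasing concave
    penalty with kappa(0) = 0 (default log(1 + s)), chosen concave so that
    already-distant embedding pairs are penalized sub-linearly and
    representation diversity is preserved.
    """

    omega: float = 0.1
    kappa: Callable[[np.ndarray], np.ndarray] = field(default=_log1p_kappa)

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValueError("omega must be non-negative")
        grid = np.linspace(0.0, 10.0, 201)
        vals = np.asarray(self.kappa(grid), dtype=float)
        if abs(vals[0]) > 1e-12:
            raise ValueError("kappa(0) must be 0")
        diffs = np.diff(vals)
        if (diffs < -1e-12).any():
            raise ValueError("kappa must be monotonically increasing")
        if (np.diff(diffs) > 1e-9).any():
            raise ValueError("kappa must be concave on [0, inf)")


def diffusion_energy(Z, Z_ref, cfg: EnergyDiagnosticConfig | None = None) -> float:
    """Energy ``E = ||Z - Z_ref||_F^2 + omega * sum_ij kappa(||z_i - z_j||^2)``.

    The first term measures local consistency of the updated embeddings
    ``Z`` with the reference state ``Z_ref``; the second sums the concave
    penalty over all ordered embedding pairs of ``Z`` (global
    consistency).  Purely diagnostic: the encoder is expected, not forced,
    to drive this quantity down across layers.
    """
    if cfg is None:
        cfg = EnergyDiagnosticConfig()
    Z = np.asarray(Z.data if isinstance(Z, Tensor) else Z, dtype=np.float64)
    Z_ref = np.asarray(Z_ref.data if isinstance(Z_ref, Tensor) else Z_ref, dtype=np.float64)
    if Z.shape != Z_ref.shape:
        raise ValueError(f"Z shape {Z.shape} != Z_ref shape {Z_ref.shape}")
    local = float(((Z - Z_ref) ** 2).sum())
    nrm = (Z ** 2).sum(axis=1)
    sq = np.maximum(nrm[:, None] + nrm[None, :] - 2.0 * (Z @ Z.T), 0.0)
    np.fill_diagonal(sq, 0.0)  # kappa(0)=0 but avoid rounding residue
    pair = float(np.asarray(cfg.kappa(sq)).sum())
    return local + cfg.omega * pair


@dataclass
class LayerState:
    """Intermediate matrices of one encoder layer (diagnostic snapshot)."""

    Z: np.ndarray
    K: np.ndarray | None = None
    Q: np.ndarray | None = None
    V: np.ndarray | None = None
    R: np.ndarray | None = None
    P: np.ndarray | None = None
    H: np.ndarray | None = None
    energy: float | None = None
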