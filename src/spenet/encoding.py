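"""Positional encodings for disease-subgraph transformers.

Three per-node encodings over one shared node index space:

* **LPE** — eigenvectors of the symmetric normalized Laplacian
  ``L_norm = I - D^{-1/2} A D^{-1/2}`` for the k smallest *nonzero*
  eigenvalues. The small nonzero end of the spectrum carries cluster /
  community structure (spectral partitioning), which is what makes it a
  useful transformer positional signal on graphs.
* **GEE** — the graph encoder embedding ``Z = A W`` where ``W`` is the
  disease-membership one-hot matrix normalized per disease
  (``W[i, j] = 1/n_j`` iff node i belongs to disease j). Row i of Z counts
  node i's neighbors inside each disease subgraph, scaled by subgraph size:
  a fast, label-aware embedding.
* **GPE** — the d leading left singular vectors of Z: a fixed-width
  compression of GEE that decouples the encoding width from the number of
  disease labels.

The subgraph positional encoding (SPE) combines all three with the node2vec
node embedding matrix M: ``E = [(M + LPE), GPE]`` — LPE is added to M
(requires matching width) and GPE is concatenated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg

VARIANTS = ("NoPE", "LPE", "SPE")

#: relative eigenvalue threshold below which an eigenvalue counts as zero
ZERO_TOL = 1e-8

#: above this node count the Laplacian eigenproblem switches to a sparse
#: iterative solver (shift-invert Lanczos) for the low end of the spectrum
DENSE_EIG_LIMIT = 2000


@dataclass(frozen=True)
class NormalizedLaplacian:
    """Symmetric normalized Laplacian with its zero-eigenvalue tolerance."""

    matrix: np.ndarray
    zero_tol: float = ZERO_TOL


@dataclass(frozen=True)
class LPEMatrix:
    vectors: np.ndarray  # N x k, columns orthonormal
    eigenvalues: np.ndarray  # k ascending, all above the zero threshold

    @property
    def k(self) -> int:
        return self.vectors.shape[1]


@dataclass(frozen=True)
class GEEWeightMatrix:
    W: np.ndarray  # N x K, entries in {0, 1/n_j}


@dataclass(frozen=True)
class GPEMatrix:
    vectors: np.ndarray  # N x d, left singular vectors
    singular_values: np.ndarray  # d, nonincreasing

    @property
    def d(self) -> int:
        return self.vectors.shape[1]


@dataclass(frozen=True)
class EncodingBundle:
    """Per-node transformer input representation under one PE variant."""

    variant: str
    E: np.ndarray  # N x d_model

    @property
    def d_model(self) -> int:
        return self.E.shape[1]


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive.

    Eigen/singular vectors are defined only up to sign; this deterministic
    convention makes encodings reproducible across runs and solvers. Ties
    (same magnitude) resolve to the first such entry.
    """
    out = vectors.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            out[:, j] = -col
    return out


def normalized_laplacian(A: np.ndarray, zero_tol: float = ZERO_TOL) -> NormalizedLaplacian:
    """L_norm = I - D^{-1/2} A D^{-1/2} for a binary symmetric adjacency.

    Isolated nodes (degree 0) get D^{-1/2} = 0, so their row reduces to the
    identity row e_i: each contributes one eigenvalue exactly 1 and does not
    couple to the rest of the spectrum.
    """
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got {A.shape}")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if np.any(A < 0):
        raise ValueError("adjacency must be nonnegative")
    deg = A.sum(axis=1)
    with np.errstate(divide="ignore"):
        dinv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
    L = np.eye(A.shape[0]) - (dinv_sqrt[:, None] * A) * dinv_sqrt[None, :]
    # exact symmetry despite float rounding
    L = 0.5 * (L + L.T)
    return NormalizedLaplacian(matrix=L, zero_tol=zero_tol)


def laplacian_pe(L: NormalizedLaplacian, k: int) -> LPEMatrix:
    """Eigenvectors of the k smallest eigenvalues strictly above the zero
    threshold, ascending, sign-fixed.

    The zero eigenspace (one zero eigenvalue per connected component) is
    excluded: those eigenvectors are locally constant and carry no intra-
    component position information.
    """
    M = L.matrix
    n = M.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    tol = L.zero_tol
    if n <= DENSE_EIG_LIMIT:
        vals, vecs = scipy.linalg.eigh(M)
    else:
        # number of components is unknown a priori; ask for a margin of
        # extra low-end pairs and grow if the nonzero count falls short
        want = k + 1
        while True:
            want = min(n - 1, want)
            vals, vecs = scipy.sparse.linalg.eigsh(
                sp.csr_matrix(M), k=want, sigma=0, which="LM"
            )
            order = np.argsort(vals)
            vals, vecs = vals[order], vecs[:, order]
            nonzero = int(np.sum(vals > tol * max(vals.max(), 1.0)))
            if nonzero >= k or want == n - 1:
                break
            want = min(n - 1, want * 2)
    scale = max(vals.max(), 1.0)
    keep = vals > tol * scale
    available = int(keep.sum())
    if k > available:
        raise ValueError(
            f"k={k} exceeds the {available} eigenvalues above the zero threshold"
        )
    idx = np.nonzero(keep)[0][:k]
    return LPEMatrix(vectors=_fix_signs(vecs[:, idx]), eigenvalues=vals[idx].copy())


def gee_weight_matrix(dm, n_nodes: int) -> GEEWeightMatrix:
    """Disease-membership weight matrix: W[i, j] = 1/n_j iff node i in disease j."""
    K = dm.n_diseases
    W = np.zeros((n_nodes, K))
    for j, members in enumerate(dm.member_arrays()):
        if members.size == 0:
            raise ValueError(f"disease {dm.diseases[j]!r} is empty")
        if members.max() >= n_nodes:
            raise ValueError(
                f"disease {dm.diseases[j]!r} references node {members.max()} "
                f">= n_nodes {n_nodes}"
            )
        W[members, j] = 1.0 / members.size
    return GEEWeightMatrix(W=W)


def gee_embedding(A: np.ndarray, W: GEEWeightMatrix) -> np.ndarray:
    """Graph encoder embedding Z = A W.

    Entry (i, j) equals |neighbors of i inside disease j| / n_j.
    """
    A = np.asarray(A, dtype=np.float64)
    if A.shape[1] != W.W.shape[0]:
        raise ValueError(f"shape mismatch: A {A.shape} vs W {W.W.shape}")
    return A @ W.W


def gpe(Z: np.ndarray, d: int) -> GPEMatrix:
    """Left singular vectors of Z for the d largest singular values."""
    Z = np.asarray(Z, dtype=np.float64)
    max_d = min(Z.shape)
    if not (1 <= d <= max_d):
        raise ValueError(f"d must be in [1, {max_d}], got {d}")
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    return GPEMatrix(vectors=_fix_signs(U[:, :d]), singular_values=S[:d].copy())


def assemble_encoding(
    M: np.ndarray,
    lpe: LPEMatrix | None = None,
    gpe_m: GPEMatrix | None = None,
    variant: str = "SPE",
) -> EncodingBundle:
    """Assemble the per-node transformer input E under one PE variant.

    NoPE: E = M. LPE: E = M + LPE (k must equal M's width). SPE:
    E = [(M + LPE), GPE] (concatenation; width = dim + d).
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    M = np.asarray(M, dtype=np.float64)
    if variant == "NoPE":
        return EncodingBundle(variant=variant, E=M.copy())
    if lpe is None:
        raise ValueError(f"{variant} requires an LPE matrix")
    if lpe.vectors.shape != M.shape:
        raise ValueError(
            f"LPE shape {lpe.vectors.shape} must match node-embedding shape "
            f"{M.shape} for the additive term"
        )
    base = M + lpe.vectors
    if variant == "LPE":
        return EncodingBundle(variant=variant, E=base)
    if gpe_m is None:
        raise ValueError("SPE requires a GPE matrix")
    if gpe_m.vectors.shape[0] != M.shape[0]:
        raise ValueError(
            f"GPE rows {gpe_m.vectors.shape[0]} != node count {M.shape[0]}"
        )
    return EncodingBundle(variant="SPE", E=np.concatenate([base, gpe_m.vectors], axis=1))
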