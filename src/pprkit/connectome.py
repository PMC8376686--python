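"""Structural connectome container, preprocessing, and graph Laplacians.

The connectome is a symmetric, nonnegative, zero-diagonal region-by-region
matrix of white-matter connectivity weights (streamline counts from
tractography, averaged over healthy subjects). Diffusion computations run on
a graph Laplacian derived from it, held together with its full
eigendecomposition so that every downstream operator (evolution kernel,
accumulation integral, baseline-slope operator) shares one spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components

from ._labels import generic_labels

__all__ = [
    "Connectome",
    "Laplacian",
    "average_connectomes",
    "threshold_connectome",
    "build_laplacian",
]

#: symmetry / nonnegativity tolerance for connectivity matrices
SYMMETRY_TOL = 1e-10
#: relative eigenvalue tolerance below which a mode counts as a zero mode
ZERO_MODE_RTOL = 1e-8


@dataclass(frozen=True)
class Connectome:
    """Symmetric nonnegative connectivity matrix with ordered region labels."""

    C: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        C = np.asarray(self.C, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got {C.shape}")
        if len(self.labels) != C.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for a {C.shape[0]}-region matrix"
            )
        if np.any(C < -SYMMETRY_TOL):
            raise ValueError("connectivity weights must be nonnegative")
        if np.max(np.abs(C - C.T)) > SYMMETRY_TOL:
            raise ValueError(
                "connectivity matrix is asymmetric beyond tolerance; "
                "use Connectome.from_matrix(..., symmetrize=True)"
            )
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "labels", tuple(self.labels))

    @classmethod
    def from_matrix(
        cls,
        M: np.ndarray,
        labels: list[str] | None = None,
        symmetrize: bool = True,
    ) -> "Connectome":
        """Build a Connectome, symmetrizing and zeroing the diagonal as needed.

        Asymmetric input is averaged with its transpose (tractography counts
        i->j and j->i separately; their mean is the undirected weight) with a
        warning. Self-connections carry no meaning and are zeroed.
        """
        M = np.asarray(M, dtype=float).copy()
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got {M.shape}")
        if symmetrize and np.max(np.abs(M - M.T)) > SYMMETRY_TOL:
            warnings.warn(
                "asymmetric connectivity matrix: averaging with its transpose",
                stacklevel=2,
            )
            M = 0.5 * (M + M.T)
        if np.any(np.abs(np.diag(M)) > 0):
            warnings.warn("nonzero diagonal entries zeroed", stacklevel=2)
        np.fill_diagonal(M, 0.0)
        if labels is None:
            labels = generic_labels(M.shape[0])
        return cls(M, tuple(labels))

    @property
    def n_regions(self) -> int:
        return self.C.shape[0]

    @property
    def sparsity(self) -> float:
        """Fraction of zero off-diagonal entries."""
        n = self.n_regions
        off = n * (n - 1)
        nz = int(np.count_nonzero(self.C)) - int(np.count_nonzero(np.diag(self.C)))
        return (off - nz) / off if off else 0.0

    def n_components(self) -> int:
        ncomp, _ = connected_components(self.C > 0, directed=False)
        return int(ncomp)


@dataclass(frozen=True)
class Laplacian:
    """Graph Laplacian with cached eigendecomposition H = U diag(lambdas) U^T.

    ``kind`` is ``"unnormalized"`` (D - C) or ``"normalized"``
    (I - D^-1/2 C D^-1/2). Eigenvalues are clipped at zero from below and
    sorted ascending; ``n_zero_modes`` counts eigenvalues below
    ``zero_tol`` and equals the number of connected components.
    """

    H: np.ndarray
    kind: str
    U: np.ndarray
    lambdas: np.ndarray
    labels: tuple[str, ...]
    zero_tol: float = field(default=0.0)

    @property
    def n_regions(self) -> int:
        return self.H.shape[0]

    @property
    def n_zero_modes(self) -> int:
        return int(np.count_nonzero(self.lambdas < self.zero_tol))

    def is_zero_mode(self) -> np.ndarray:
        return self.lambdas < self.zero_tol


def average_connectomes(matrices: list[np.ndarray]) -> Connectome:
    """Average per-subject connectivity matrices into a canonical connectome.

    Each subject's matrix is first normalized by its total weighted streamline
    count (to control for inter-subject variance in total fibre count), then
    the entrywise mean is taken and symmetrized as (M + M^T)/2.
    """
    if not matrices:
        raise ValueError("no connectivity matrices given")
    mats = [np.asarray(M, dtype=float) for M in matrices]
    shape = mats[0].shape
    if shape[0] != shape[1]:
        raise ValueError(f"matrices must be square, got {shape}")
    for i, M in enumerate(mats):
        if M.shape != shape:
            raise ValueError(
                f"matrix {i} has shape {M.shape}, expected {shape}"
            )
        if np.any(M < 0):
            raise ValueError(f"matrix {i} has negative entries")
    normed = []
    for i, M in enumerate(mats):
        total = M.sum()
        if total <= 0:
            raise ValueError(f"matrix {i} has zero total weight")
        normed.append(M / total)
    mean = np.mean(normed, axis=0)
    mean = 0.5 * (mean + mean.T)
    return Connectome.from_matrix(mean)


def threshold_connectome(conn: Connectome, target_sparsity: float) -> Connectome:
    """Zero the smallest off-diagonal weights until the zero fraction reaches
    ``target_sparsity``, removing as few edges as possible.

    Edges are removed symmetrically (both (i,j) and (j,i)). If the result is
    disconnected a warning is emitted but the thresholded connectome is still
    returned.
    """
    if not 0.0 <= target_sparsity <= 1.0:
        raise ValueError(f"target_sparsity must be in [0, 1], got {target_sparsity}")
    n = conn.n_regions
    C = conn.C.copy()
    iu, ju = np.triu_indices(n, k=1)
    vals = C[iu, ju]
    nonzero = vals > 0
    n_off = n * (n - 1)
    zeros_now = n_off - 2 * int(np.count_nonzero(nonzero))
    needed = int(np.ceil(target_sparsity * n_off)) - zeros_now
    if needed > 0:
        # each removed upper-triangle edge zeroes two off-diagonal entries
        k_remove = int(np.ceil(needed / 2))
        nz_idx = np.flatnonzero(nonzero)
        order = nz_idx[np.argsort(vals[nz_idx], kind="stable")]
        drop = order[:k_remove]
        C[iu[drop], ju[drop]] = 0.0
        C[ju[drop], iu[drop]] = 0.0
    out = Connectome(C, conn.labels)
    if out.n_components() > 1:
        warnings.warn(
            f"thresholding at sparsity {target_sparsity} disconnected the graph "
            f"({out.n_components()} components)",
            stacklevel=2,
        )
    return out


def build_laplacian(conn: Connectome, kind: str = "normalized") -> Laplacian:
    """Construct the graph Laplacian of a connectome with its eigensystem.

    ``kind="unnormalized"`` gives H = D - C; ``kind="normalized"`` gives the
    symmetric-normalized H = I - D^-1/2 C D^-1/2, where D = diag(row sums).
    The normalized kind requires every region to have nonzero degree.
    """
    C = conn.C
    deg = C.sum(axis=1)
    if kind == "unnormalized":
        H = np.diag(deg) - C
    elif kind == "normalized":
        isolated = np.flatnonzero(deg <= 0)
        if isolated.size:
            names = ", ".join(conn.labels[i] for i in isolated)
            raise ValueError(
                f"normalized Laplacian undefined for isolated region(s): {names}"
            )
        dinv = 1.0 / np.sqrt(deg)
        H = np.eye(conn.n_regions) - (dinv[:, None] * C) * dinv[None, :]
    else:
        raise ValueError(f"unknown Laplacian kind {kind!r}")
    H = 0.5 * (H + H.T)  # kill round-off asymmetry before eigh
    lambdas, U = eigh(H)
    lambdas = np.clip(lambdas, 0.0, None)
    lam_max = lambdas[-1] if lambdas.size else 0.0
    zero_tol = ZERO_MODE_RTOL * max(lam_max, 1.0)
    return Laplacian(
        H=H, kind=kind, U=U, lambdas=lambdas, labels=conn.labels, zero_tol=zero_tol
    )
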