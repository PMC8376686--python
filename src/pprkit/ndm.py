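"""Forward network-diffusion operators.

Pathology spread is modelled as heat-like diffusion on the connectome:
x(t) = exp(-beta*H*t) x0, with H a graph Laplacian and beta the diffusivity
(units 1/year). Measured atrophy is the running integral of pathology,
Phi(t) = int_0^t x(tau) dtau, and a modified Laplacian H~(beta*t) relates
the baseline atrophy pattern to its instantaneous rate of change:

    dPhi/dt |_baseline = beta * H~(beta*t_base) * Phi_base

All operators are evaluated spectrally from the Laplacian's cached
eigendecomposition, so evolution, accumulation and the modified Laplacian
are mutually consistent by construction.
"""

from __future__ import annotations

import numpy as np

from .connectome import Laplacian

__all__ = [
    "evolve",
    "accumulate",
    "modified_laplacian",
    "predicted_slope",
    "predicted_slope_grid",
]

# beyond this, exp(lambda*s) overflows; the corresponding mode weight is 0
_EXP_OVERFLOW = 700.0


def _check_x0(L: Laplacian, x0: np.ndarray) -> np.ndarray:
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (L.n_regions,):
        raise ValueError(
            f"x0 has shape {x0.shape}, expected ({L.n_regions},)"
        )
    return x0


def evolve(L: Laplacian, x0: np.ndarray, beta: float, t: float) -> np.ndarray:
    """Evolved pathology x(t) = U diag(exp(-lambda*beta*t)) U^T x0."""
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    x0 = _check_x0(L, x0)
    w = np.exp(-np.clip(L.lambdas * beta * t, None, _EXP_OVERFLOW))
    return L.U @ (w * (L.U.T @ x0))


def accumulate(L: Laplacian, x0: np.ndarray, beta: float, t: float) -> np.ndarray:
    """Accumulated pathology Phi(t) = int_0^t x(tau) dtau, in closed form.

    Spectrally: Phi(t) = U diag(g) U^T x0 with
    g_i = (1 - exp(-lambda_i*beta*t)) / (lambda_i*beta) for nonzero modes and
    g_i = t for zero modes (the conserved component grows linearly).
    """
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    x0 = _check_x0(L, x0)
    lam = L.lambdas
    zero = L.is_zero_mode()
    g = np.empty_like(lam)
    g[zero] = t
    lb = lam[~zero] * beta
    if lb.size:
        if beta == 0.0:
            g[~zero] = t
        else:
            g[~zero] = -np.expm1(-np.clip(lb * t, None, _EXP_OVERFLOW)) / lb
    return L.U @ (g * (L.U.T @ x0))


def _modified_diag(L: Laplacian, betat: float) -> np.ndarray:
    """Eigenbasis weights d_i of the modified Laplacian at s = beta*t.

    d_1 = 1/s on the zero mode; d_i = lambda_i e^{-lambda_i s} / (1 - e^{-lambda_i s})
    = lambda_i / expm1(lambda_i s) otherwise, computed stably and set to 0
    where lambda_i*s overflows the exponential.
    """
    if betat <= 0:
        raise ValueError(f"beta*t must be > 0, got {betat}")
    if L.n_zero_modes != 1:
        raise ValueError(
            f"modified Laplacian requires exactly one zero mode, found "
            f"{L.n_zero_modes} (disconnected or degenerate graph)"
        )
    lam = L.lambdas
    zero = L.is_zero_mode()
    d = np.empty_like(lam)
    d[zero] = 1.0 / betat
    ls = lam[~zero] * betat
    with np.errstate(over="ignore"):
        d_nz = lam[~zero] / np.expm1(ls)
    d[~zero] = np.where(ls > _EXP_OVERFLOW, 0.0, d_nz)
    return d


def modified_laplacian(L: Laplacian, betat: float) -> np.ndarray:
    """The modified Laplacian H~(s) = U diag(d(s)) U^T at s = beta*t."""
    d = _modified_diag(L, betat)
    H_mod = L.U @ (d[:, None] * L.U.T)
    return 0.5 * (H_mod + H_mod.T)


def predicted_slope(
    L: Laplacian, beta: float, t_base: float, phi_base: np.ndarray
) -> np.ndarray:
    """Model-predicted atrophy slope at baseline: beta * H~(beta*t_base) * Phi_base."""
    if beta <= 0:
        raise ValueError(f"beta must be > 0, got {beta}")
    if t_base <= 0:
        raise ValueError(f"t_base must be > 0, got {t_base}")
    phi_base = _check_x0(L, phi_base)
    d = _modified_diag(L, beta * t_base)
    return beta * (L.U @ (d * (L.U.T @ phi_base)))


def predicted_slope_grid(
    L: Laplacian, beta0: float, t_grid: np.ndarray, phi_base: np.ndarray
) -> np.ndarray:
    """Predicted slopes beta0 * H~(beta0*t) * Phi_base for every t in a grid.

    Returns an (len(t_grid), n_regions) matrix. Vectorized over the grid via
    the shared eigenbasis: one projection of Phi_base, one weight matrix, one
    back-projection.
    """
    if beta0 <= 0:
        raise ValueError(f"beta0 must be > 0, got {beta0}")
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size == 0:
        raise ValueError("t_grid must be a nonempty 1-D array")
    if np.any(t_grid <= 0):
        raise ValueError("all grid times must be > 0")
    phi_base = _check_x0(L, phi_base)
    if L.n_zero_modes != 1:
        raise ValueError(
            f"modified Laplacian requires exactly one zero mode, found "
            f"{L.n_zero_modes}"
        )
    lam = L.lambdas
    zero = L.is_zero_mode()
    s = beta0 * t_grid  # (nt,)
    ls = lam[None, :] * s[:, None]  # (nt, n)
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        D = lam[None, :] / np.expm1(ls)
    D[:, zero] = 1.0 / s[:, None]
    D[ls > _EXP_OVERFLOW] = 0.0
    y = L.U.T @ phi_base  # (n,)
    return beta0 * ((D * y[None, :]) @ L.U.T)
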