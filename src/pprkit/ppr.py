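"""Per-subject pathology progression rate (PPR) estimation.

The PPR is the diffusivity beta of the network diffusion model, fitted to a
subject's longitudinal regional atrophy in three steps:

1. regional atrophy slopes by ordinary least squares on the visit times
   (negative slopes clipped to zero — cortical thickening is treated as
   measurement error);
2. with beta pinned at a reference rate beta0, a grid search over the
   unobserved onset-to-baseline interval t_base, maximizing the Pearson
   correlation between the model-predicted slope pattern
   beta0 * H~(beta0*t) * Phi_base and the measured slopes;
3. a scalar least-squares fit of beta in
   slopes = beta * H~(beta0*t_base_hat) * Phi_base.

Steps 2-3 are performed once (no iteration by default). Because the
modified Laplacian depends on beta and t_base only through their product,
only beta0*t_base_hat is identified — t_base_hat alone is a nuisance.

``PPREstimator`` packages the procedure as a scikit-learn-style estimator;
``fit_ppr`` and friends are thin functional wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .connectome import Laplacian
from .ndm import _modified_diag, predicted_slope_grid

__all__ = [
    "AtrophyTrajectory",
    "SlopeEstimate",
    "PPRFit",
    "PPREstimator",
    "fit_slopes",
    "estimate_tbase",
    "estimate_beta",
    "fit_ppr",
    "fit_cohort",
    "flag_outliers",
    "default_tbase_grid",
]

#: reference diffusivity (1/year) used to pin the t_base grid search
DEFAULT_BETA0 = 0.05
#: default t_base grid bounds and step, in years
DEFAULT_TBASE_GRID = (0.25, 50.0, 0.25)


def default_tbase_grid(
    start: float = DEFAULT_TBASE_GRID[0],
    stop: float = DEFAULT_TBASE_GRID[1],
    step: float = DEFAULT_TBASE_GRID[2],
) -> np.ndarray:
    """Inclusive arithmetic grid of candidate t_base values (years)."""
    if start <= 0 or stop < start or step <= 0:
        raise ValueError(f"invalid grid bounds ({start}, {stop}, {step})")
    n = int(np.floor((stop - start) / step + 1e-9)) + 1
    return start + step * np.arange(n)


@dataclass(frozen=True)
class AtrophyTrajectory:
    """One subject's longitudinal regional atrophy observations.

    ``t_long`` holds years since baseline (first entry 0, strictly
    increasing); ``phi`` is the (n_visits, n_regions) atrophy matrix.
    """

    subject_id: str
    t_long: np.ndarray
    phi: np.ndarray
    region_labels: tuple[str, ...]

    def __post_init__(self):
        t = np.asarray(self.t_long, dtype=float)
        phi = np.asarray(self.phi, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValueError(
                f"subject {self.subject_id}: need >= 2 visits, got {t.size}"
            )
        if abs(t[0]) > 1e-12:
            raise ValueError(
                f"subject {self.subject_id}: first visit time must be 0, got {t[0]}"
            )
        if np.any(np.diff(t) <= 0):
            raise ValueError(
                f"subject {self.subject_id}: visit times must be strictly increasing"
            )
        if phi.shape != (t.size, len(self.region_labels)):
            raise ValueError(
                f"subject {self.subject_id}: phi shape {phi.shape} does not match "
                f"{t.size} visits x {len(self.region_labels)} regions"
            )
        if np.any(phi < -1e-12):
            raise ValueError(
                f"subject {self.subject_id}: atrophy values must be nonnegative"
            )
        object.__setattr__(self, "t_long", t)
        object.__setattr__(self, "phi", phi)
        object.__setattr__(self, "region_labels", tuple(self.region_labels))

    @property
    def n_visits(self) -> int:
        return self.t_long.size

    @property
    def phi_base(self) -> np.ndarray:
        """Baseline atrophy pattern: the observed first-visit values."""
        return self.phi[0]


@dataclass(frozen=True)
class SlopeEstimate:
    """Per-region OLS atrophy slopes (clipped at 0) and intercepts."""

    slopes: np.ndarray
    intercepts: np.ndarray
    n_clipped: int


@dataclass(frozen=True)
class PPRFit:
    """Result of the three-step PPR fit for one subject."""

    subject_id: str
    beta_hat: float
    tbase_hat: float
    peak_correlation: float
    beta0: float
    grid: np.ndarray = field(repr=False)
    n_clipped: int = 0
    flags: tuple[str, ...] = ()
    is_outlier: bool = False

    @property
    def betat_hat(self) -> float:
        """The identified product beta0 * t_base_hat."""
        return self.beta0 * self.tbase_hat


def fit_slopes(traj: AtrophyTrajectory) -> SlopeEstimate:
    """Per-region OLS of atrophy on [1, t] via pseudoinverse; negatives -> 0."""
    t = traj.t_long
    if t.size < 2:
        raise ValueError("need at least two visits to fit slopes")
    if np.ptp(t) <= 0:
        raise ValueError("all visit times identical; slope undefined")
    A = np.column_stack([np.ones_like(t), t])
    coef = np.linalg.pinv(A) @ traj.phi  # (2, n_regions)
    intercepts, slopes = coef[0], coef[1]
    neg = slopes < 0
    n_clipped = int(np.count_nonzero(neg))
    slopes = np.where(neg, 0.0, slopes)
    return SlopeEstimate(slopes=slopes, intercepts=intercepts, n_clipped=n_clipped)


def _pearson_grid(preds: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Pearson r of each row of ``preds`` against ``target``; NaN where undefined.

    Variances are compared against a relative floor so that a constant vector
    (whose centered residuals are pure round-off) counts as zero-variance.
    """
    pc = preds - preds.mean(axis=1, keepdims=True)
    tc = target - target.mean()
    pvar = (pc**2).sum(axis=1)
    tvar = float((tc**2).sum())
    p_floor = 1e-24 * np.maximum((preds**2).sum(axis=1), 1e-300)
    t_floor = 1e-24 * max(float((target**2).sum()), 1e-300)
    bad = (pvar <= p_floor) | (tvar <= t_floor)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (pc @ tc) / np.sqrt(pvar * tvar)
    r[bad] = np.nan
    return r


def estimate_tbase(
    phi_base: np.ndarray,
    slopes: np.ndarray,
    L: Laplacian,
    beta0: float = DEFAULT_BETA0,
    grid: np.ndarray | None = None,
) -> tuple[float, float]:
    """Grid-search t_base maximizing Pearson correlation between predicted
    and measured slope patterns.

    Returns ``(tbase_hat, peak_correlation)``. Ties break to the smallest
    grid point; if the correlation is undefined at every grid point (zero
    variance in slopes or predictions), ``peak_correlation`` is NaN and the
    smallest grid point is returned.
    """
    if grid is None:
        grid = default_tbase_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("grid must be a nonempty 1-D array")
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be positive and strictly increasing")
    slopes = np.asarray(slopes, dtype=float)
    preds = predicted_slope_grid(L, beta0, grid, np.asarray(phi_base, dtype=float))
    r = _pearson_grid(preds, slopes)
    if np.all(np.isnan(r)):
        return float(grid[0]), float("nan")
    best = int(np.nanargmax(r))  # first max -> smallest t on ties
    return float(grid[best]), float(r[best])


def estimate_beta(
    phi_base: np.ndarray,
    slopes: np.ndarray,
    L: Laplacian,
    beta0: float = DEFAULT_BETA0,
    tbase_hat: float = 1.0,
) -> float:
    """Scalar least squares of beta in slopes = beta * H~(beta0*tbase) * Phi_base.

    The one-column pseudoinverse solution <v, slopes>/<v, v> with
    v = H~(beta0*tbase_hat) Phi_base, clipped at 0.
    """
    if tbase_hat <= 0:
        raise ValueError(f"tbase_hat must be > 0, got {tbase_hat}")
    phi_base = np.asarray(phi_base, dtype=float)
    slopes = np.asarray(slopes, dtype=float)
    d = _modified_diag(L, beta0 * tbase_hat)
    v = L.U @ (d * (L.U.T @ phi_base))
    vv = float(v @ v)
    if vv <= 0:
        raise ValueError("degenerate baseline pattern: H~ * Phi_base is zero")
    return max(0.0, float(v @ slopes) / vv)


def fit_ppr(
    traj: AtrophyTrajectory,
    L: Laplacian,
    beta0: float = DEFAULT_BETA0,
    grid: np.ndarray | None = None,
    iterate: bool = False,
) -> PPRFit:
    """Full three-step PPR fit for one subject (slopes -> t_base -> beta).

    Performed once by default; ``iterate=True`` runs steps 2-3 a second time
    with beta0 replaced by the first-pass beta estimate.
    """
    if grid is None:
        grid = default_tbase_grid()
    grid = np.asarray(grid, dtype=float)
    if traj.n_visits < 2:
        raise ValueError("need at least two visits")
    if len(traj.region_labels) != L.n_regions:
        raise ValueError(
            f"subject {traj.subject_id}: {len(traj.region_labels)} regions "
            f"vs {L.n_regions}-region Laplacian"
        )
    if traj.region_labels != L.labels:
        bad = [r for r in traj.region_labels if r not in set(L.labels)]
        raise ValueError(
            f"subject {traj.subject_id}: region labels do not match the "
            f"connectome ordering (unknown or misordered: {bad[:5]})"
        )
    se = fit_slopes(traj)
    flags: list[str] = []
    if not np.any(se.slopes > 0):
        return PPRFit(
            subject_id=traj.subject_id,
            beta_hat=0.0,
            tbase_hat=float(grid[0]),
            peak_correlation=float("nan"),
            beta0=beta0,
            grid=grid,
            n_clipped=se.n_clipped,
            flags=("non-progressor",),
        )
    tbase_hat, peak_r = estimate_tbase(traj.phi_base, se.slopes, L, beta0, grid)
    if np.isnan(peak_r):
        return PPRFit(
            subject_id=traj.subject_id,
            beta_hat=0.0,
            tbase_hat=tbase_hat,
            peak_correlation=float("nan"),
            beta0=beta0,
            grid=grid,
            n_clipped=se.n_clipped,
            flags=("degenerate-correlation",),
        )
    beta_hat = estimate_beta(traj.phi_base, se.slopes, L, beta0, tbase_hat)
    if iterate and beta_hat > 0:
        tbase_hat, peak_r = estimate_tbase(
            traj.phi_base, se.slopes, L, beta_hat, grid
        )
        beta_hat = estimate_beta(traj.phi_base, se.slopes, L, beta_hat, tbase_hat)
    if tbase_hat in (grid[0], grid[-1]):
        flags.append("grid-boundary")
    return PPRFit(
        subject_id=traj.subject_id,
        beta_hat=beta_hat,
        tbase_hat=tbase_hat,
        peak_correlation=peak_r,
        beta0=beta0,
        grid=grid,
        n_clipped=se.n_clipped,
        flags=tuple(flags),
    )


def flag_outliers(values, groups=None) -> np.ndarray:
    """Tukey-fence outlier mask computed separately within each group.

    A value is flagged when it lies outside [Q1 - 1.5*IQR, Q3 + 1.5*IQR] of
    its group, with quartiles by linear interpolation of order statistics
    (index (n-1)p). Groups with fewer than 4 members get no flags (warning).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("values must be 1-D")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if groups is None:
        groups = np.zeros(values.size, dtype=int)
    groups = np.asarray(groups)
    if groups.shape != values.shape:
        raise ValueError("groups must have the same length as values")
    mask = np.zeros(values.size, dtype=bool)
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        if idx.size < 4:
            warnings.warn(
                f"group {g!r} has {idx.size} < 4 values; no outlier flags",
                stacklevel=2,
            )
            continue
        q1, q3 = np.quantile(values[idx], [0.25, 0.75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        mask[idx] = (values[idx] < lo) | (values[idx] > hi)
    return mask


class PPREstimator(BaseEstimator):
    """Scikit-learn-style estimator of a subject's pathology progression rate.

    Parameters
    ----------
    laplacian : Laplacian
        Graph Laplacian of the structural connectome (with eigensystem).
    beta0 : float, default 0.05
        Reference diffusivity (1/year) pinning the t_base grid search.
    t_grid_start, t_grid_stop, t_grid_step : float
        Bounds and step (years) of the candidate t_base grid.
    iterate : bool, default False
        Re-run the t_base/beta steps once with beta0 := first-pass beta.

    ``fit(X, y)`` takes ``X`` as the (n_visits, n_regions) atrophy matrix and
    ``y`` as the visit times in years since baseline (first entry 0).

    Attributes
    ----------
    beta_ : float            fitted diffusivity (1/year)
    tbase_ : float           nuisance onset-to-baseline interval (years)
    betat_ : float           the identified product beta0 * tbase_
    peak_correlation_ : float
    slopes_ : ndarray        clipped per-region OLS slopes
    n_clipped_ : int
    flags_ : tuple of str
    """

    def __init__(
        self,
        laplacian: Laplacian = None,
        beta0: float = DEFAULT_BETA0,
        t_grid_start: float = DEFAULT_TBASE_GRID[0],
        t_grid_stop: float = DEFAULT_TBASE_GRID[1],
        t_grid_step: float = DEFAULT_TBASE_GRID[2],
        iterate: bool = False,
    ):
        self.laplacian = laplacian
        self.beta0 = beta0
        self.t_grid_start = t_grid_start
        self.t_grid_stop = t_grid_stop
        self.t_grid_step = t_grid_step
        self.iterate = iterate

    def _grid(self) -> np.ndarray:
        return default_tbase_grid(
            self.t_grid_start, self.t_grid_stop, self.t_grid_step
        )

    def fit(self, X, y, subject_id: str = "subject"):
        if self.laplacian is None:
            raise ValueError("PPREstimator requires a laplacian")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        traj = AtrophyTrajectory(
            subject_id=subject_id,
            t_long=y,
            phi=X,
            region_labels=self.laplacian.labels,
        )
        res = fit_ppr(
            traj,
            self.laplacian,
            beta0=self.beta0,
            grid=self._grid(),
            iterate=self.iterate,
        )
        se = fit_slopes(traj)
        self.beta_ = res.beta_hat
        self.tbase_ = res.tbase_hat
        self.betat_ = res.betat_hat
        self.peak_correlation_ = res.peak_correlation
        self.slopes_ = se.slopes
        self.n_clipped_ = res.n_clipped
        self.flags_ = res.flags
        self.result_ = res
        return self

    def predict(self, X):
        """Model-predicted slope pattern for baseline atrophy rows of ``X``."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "beta_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.beta_ <= 0 or self.tbase_ <= 0:
            return np.zeros_like(X)
        d = _modified_diag(self.laplacian, self.beta0 * self.tbase_)
        U = self.laplacian.U
        return self.beta_ * ((X @ U) * d) @ U.T


def fit_cohort(
    trajectories,
    L: Laplacian,
    groups: dict | None = None,
    beta0: float = DEFAULT_BETA0,
    grid: np.ndarray | None = None,
    iterate: bool = False,
):
    """Fit every subject and flag beta outliers per diagnostic group.

    ``groups`` maps subject_id -> group label (all one group if omitted).
    Returns a pandas DataFrame with one row per subject.
    """
    import pandas as pd

    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("no trajectories given")
    fits = [fit_ppr(t, L, beta0=beta0, grid=grid, iterate=iterate) for t in trajectories]
    global_slope = [float(np.mean(fit_slopes(t).slopes)) for t in trajectories]
    betas = np.array([f.beta_hat for f in fits])
    if groups is None:
        glab = np.zeros(len(fits), dtype=int)
    else:
        glab = np.array([groups.get(f.subject_id, "NA") for f in fits], dtype=object)
    mask = flag_outliers(betas, glab)
    rows = []
    for f, out, gs in zip(fits, mask, global_slope):
        rows.append(
            {
                "subject_id": f.subject_id,
                "beta_hat": f.beta_hat,
                "tbase_hat": f.tbase_hat,
                "peak_correlation": f.peak_correlation,
                "n_clipped": f.n_clipped,
                "global_atrophy_slope": gs,
                "is_outlier": bool(out),
                "flags": ";".join(f.flags),
            }
        )
    return pd.DataFrame(rows)
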