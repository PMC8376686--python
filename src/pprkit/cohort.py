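"""Cohort-level statistics around the progression rate.

Covers CSF biomarker standardization against controls, agglomerative
clustering of the six-dimensional CSF profile with variance-ratio
(Calinski-Harabasz) model selection, nonparametric group comparisons,
selection of the most atrophied regions, and the baseline multivariate
regression predicting the fitted diffusivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import chi2_contingency, kruskal, ranksums, ttest_ind
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.metrics import calinski_harabasz_score

__all__ = [
    "CSF_RAW",
    "CSF_BIOMARKERS",
    "ClusterResult",
    "RegressionReport",
    "ControlZScorer",
    "CSFClusterer",
    "add_csf_ratios",
    "zscore_biomarkers",
    "hierarchical_cluster",
    "compare_groups",
    "select_atrophy_regions",
    "predict_ppr_baseline",
    "atrophy_from_volumes",
]

#: raw CSF analytes, pg/ml
CSF_RAW = ("abeta", "tau", "ptau")
#: the six clustering features: raw analytes plus their ratios
CSF_BIOMARKERS = ("abeta", "tau", "ptau", "abeta_tau", "abeta_ptau", "ptau_tau")


def add_csf_ratios(df: pd.DataFrame) -> pd.DataFrame:
    """Append the three biomarker ratios (recomputed from raw values)."""
    missing = [c for c in CSF_RAW if c not in df.columns]
    if missing:
        raise ValueError(f"CSF table missing columns: {missing}")
    out = df.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        out["abeta_tau"] = out["abeta"] / out["tau"]
        out["abeta_ptau"] = out["abeta"] / out["ptau"]
        out["ptau_tau"] = out["ptau"] / out["tau"]
    return out


class ControlZScorer(TransformerMixin, BaseEstimator):
    """Standardize features against a control cohort (mean 0, sd 1 in controls).

    Sample standard deviation (ddof=1). ``fit`` takes the control matrix;
    ``transform`` standardizes any matrix with the same columns.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need >= 2 control subjects")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        if np.any(self.scale_ <= 0):
            bad = np.flatnonzero(self.scale_ <= 0)
            raise ValueError(f"zero control standard deviation in column(s) {bad}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "mean_")
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) / self.scale_


def zscore_biomarkers(
    patients: pd.DataFrame, controls: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Control-standardized z-scores of the six CSF biomarkers.

    Ratios are recomputed from the raw analytes. Patients missing any of the
    six features are dropped (complete-case analysis); the number dropped is
    returned alongside the z-score table, which keeps ``subject_id`` if
    present.
    """
    pats = add_csf_ratios(patients)
    ctrl = add_csf_ratios(controls)
    cols = list(CSF_BIOMARKERS)
    ctrl_ok = ctrl.dropna(subset=cols)
    if len(ctrl_ok) < 2:
        raise ValueError("need >= 2 complete control subjects per biomarker")
    complete = pats.dropna(subset=cols)
    n_dropped = len(pats) - len(complete)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} patient(s) lacked complete 6-biomarker data and "
            "were excluded",
            stacklevel=2,
        )
    scorer = ControlZScorer().fit(ctrl_ok[cols].to_numpy())
    z = scorer.transform(complete[cols].to_numpy())
    out = pd.DataFrame(z, columns=cols, index=complete.index)
    if "subject_id" in complete.columns:
        out.insert(0, "subject_id", complete["subject_id"].to_numpy())
    return out, n_dropped


@dataclass(frozen=True)
class ClusterResult:
    """Agglomerative clustering cut at the variance-ratio-optimal k."""

    labels: np.ndarray
    k_selected: int
    k_candidates: tuple[int, ...]
    ch_curve: np.ndarray
    linkage_method: str

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels)[1:]


class CSFClusterer(ClusterMixin, BaseEstimator):
    """Hierarchical clustering with Calinski-Harabasz model selection.

    Ward linkage on Euclidean distance by default. The dendrogram is cut at
    each candidate k; the variance-ratio criterion
    CH(k) = [B/(k-1)] / [W/(n-k)] is evaluated on each cut and the k
    maximizing it is selected (ties to the smallest k). Labels are 1-based.

    Attributes: ``labels_``, ``k_``, ``ch_scores_``, ``k_candidates_``.
    """

    def __init__(self, k_min: int = 2, k_max: int = 10, linkage_method: str = "ward"):
        self.k_min = k_min
        self.k_max = k_max
        self.linkage_method = linkage_method

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (subjects x features)")
        if not np.all(np.isfinite(X)):
            raise ValueError("X must be finite")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError(f"bad k range [{self.k_min}, {self.k_max}]")
        n = X.shape[0]
        if n <= self.k_max:
            raise ValueError(f"need more than k_max={self.k_max} subjects, got {n}")
        if self.linkage_method not in {"ward", "average", "complete"}:
            raise ValueError(f"unsupported linkage {self.linkage_method!r}")
        Z = linkage(X, method=self.linkage_method, metric="euclidean")
        ks = list(range(self.k_min, self.k_max + 1))
        scores = np.empty(len(ks))
        # near-coincident points: the variance ratio is 0/0 at every cut, so
        # the curve is flat and the smallest k wins by the tie rule
        degenerate = float(((X - X.mean(axis=0)) ** 2).sum()) <= 1e-16 * n
        cuts = []
        for i, k in enumerate(ks):
            lab = fcluster(Z, t=k, criterion="maxclust")
            cuts.append(lab)
            if degenerate or len(np.unique(lab)) < 2:
                scores[i] = 0.0 if degenerate else -np.inf
            else:
                scores[i] = calinski_harabasz_score(X, lab)
        best = int(np.argmax(scores))  # first max -> smallest k on ties
        self.k_candidates_ = tuple(ks)
        self.ch_scores_ = scores
        self.k_ = ks[best]
        self.labels_ = cuts[best].astype(int)
        return self

    def result(self) -> ClusterResult:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "labels_")
        return ClusterResult(
            labels=self.labels_,
            k_selected=self.k_,
            k_candidates=self.k_candidates_,
            ch_curve=self.ch_scores_,
            linkage_method=self.linkage_method,
        )


def hierarchical_cluster(
    z_matrix, k_min: int = 2, k_max: int = 10, linkage_method: str = "ward"
) -> ClusterResult:
    """Functional wrapper over :class:`CSFClusterer`."""
    est = CSFClusterer(k_min=k_min, k_max=k_max, linkage_method=linkage_method)
    return est.fit(z_matrix).result()


def compare_groups(values, labels=None, test: str = "kruskal_wallis"):
    """Nonparametric group comparison; returns (statistic, p_value).

    ``kruskal_wallis`` across >= 2 groups, ``wilcoxon_ranksum`` for exactly
    two, and ``chi_square`` on a contingency table passed as ``values``
    (no continuity correction). P-values are two-sided and uncorrected.
    """
    if test == "chi_square":
        table = np.asarray(values, dtype=float)
        if table.ndim != 2:
            raise ValueError("chi_square expects a 2-D contingency table")
        res = chi2_contingency(table, correction=False)
        return float(res.statistic), float(res.pvalue)
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if labels.shape != values.shape:
        raise ValueError("labels must match values in length")
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    if test == "kruskal_wallis":
        res = kruskal(*groups)
    elif test == "wilcoxon_ranksum":
        if len(groups) != 2:
            raise ValueError(
                f"wilcoxon_ranksum compares exactly 2 groups, got {len(groups)}"
            )
        res = ranksums(groups[0], groups[1])
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


def select_atrophy_regions(
    case_volumes: pd.DataFrame, control_volumes: pd.DataFrame, k: int = 10
) -> list[str]:
    """The k most atrophied regions by independent two-sided t-tests.

    Columns are regions, rows subjects. Regions are ranked by the most
    negative t-statistic (cases minus controls: greatest volume deficit
    first); ties keep column order.
    """
    if list(case_volumes.columns) != list(control_volumes.columns):
        raise ValueError("case and control tables must cover identical regions")
    if len(case_volumes) < 2 or len(control_volumes) < 2:
        raise ValueError("need >= 2 subjects in each cohort")
    regions = list(case_volumes.columns)
    if k > len(regions):
        warnings.warn(
            f"k={k} exceeds {len(regions)} regions; returning all", stacklevel=2
        )
        k = len(regions)
    tstats = np.empty(len(regions))
    for i, r in enumerate(regions):
        a = case_volumes[r].to_numpy(dtype=float)
        b = control_volumes[r].to_numpy(dtype=float)
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            if a[0] == b[0]:
                tstats[i] = 0.0  # identical constants: no deficit signal
                continue
            raise ValueError(f"zero pooled variance in region {r!r}")
        tstats[i] = ttest_ind(a, b).statistic
    order = np.argsort(tstats, kind="stable")  # stable -> ties by column order
    return [regions[i] for i in order[:k]]


@dataclass(frozen=True)
class RegressionReport:
    """OLS fit summary: R^2, coefficients, p-values, complete-case count."""

    r_squared: float
    coefficients: pd.Series = field(repr=False)
    p_values: pd.Series = field(repr=False)
    n_used: int


def predict_ppr_baseline(features: pd.DataFrame, outcome) -> RegressionReport:
    """Multivariate OLS of an outcome (the fitted beta, or the global atrophy
    rate) on baseline predictors, with intercept.

    Complete cases only. A rank-deficient design raises an error naming the
    collinear columns.
    """
    y = pd.Series(np.asarray(outcome, dtype=float), index=features.index, name="y")
    df = features.astype(float).join(y)
    df = df.dropna()
    n, p = len(df), features.shape[1]
    if n <= p + 1:
        raise ValueError(f"need more than {p + 1} complete cases, got {n}")
    X = sm.add_constant(df[features.columns], has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify dependent columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(X.to_numpy(), pivoting=True, mode="economic")
        dep = sorted(X.columns[piv[rank:]])
        raise ValueError(f"rank-deficient design; collinear columns: {dep}")
    fit = sm.OLS(df["y"], X).fit()
    return RegressionReport(
        r_squared=float(fit.rsquared),
        coefficients=fit.params,
        p_values=fit.pvalues,
        n_used=n,
    )


def atrophy_from_volumes(
    volumes: pd.DataFrame, control_volumes: pd.DataFrame
) -> pd.DataFrame:
    """Reference atrophy recipe: z-score of volume deficit vs controls, floored at 0.

    atrophy_r = max(0, (control_mean_r - volume_r) / control_sd_r). Columns
    are regions, rows subjects.
    """
    if list(volumes.columns) != list(control_volumes.columns):
        raise ValueError("volume tables must cover identical regions")
    mu = control_volumes.mean(axis=0)
    sd = control_volumes.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        bad = list(sd.index[sd <= 0])
        raise ValueError(f"zero control volume variance in region(s) {bad}")
    z = (mu - volumes) / sd
    return z.clip(lower=0.0)
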