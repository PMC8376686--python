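"""Self-contained synthetic inputs with known ground truth.

Generates (i) connectome-like graphs — symmetric, nonnegative, connected,
~85% sparse; (ii) longitudinal atrophy cohorts driven by the forward
network-diffusion model with Gaussian observation noise; and (iii) CSF
biomarker profiles drawn around three cluster centroids ordered from
control-like to an Alzheimer-like signature (low amyloid-beta, high
tau/pTau). Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from ._labels import dk86_labels, generic_labels
from .connectome import Connectome, Laplacian, threshold_connectome
from .ndm import accumulate
from .ppr import AtrophyTrajectory

__all__ = [
    "SyntheticCohortSpec",
    "synth_connectome",
    "seed_vector",
    "synth_subject",
    "synth_cohort",
    "synth_csf",
    "DEFAULT_SEED_REGIONS",
]

#: canonical early-Alzheimer seeding sites (bilateral entorhinal + hippocampus)
DEFAULT_SEED_REGIONS = (
    "lh_entorhinal",
    "rh_entorhinal",
    "lh_hippocampus",
    "rh_hippocampus",
)

#: control CSF analyte distributions, pg/ml: (mean, sd)
CSF_CONTROL = {"abeta": (1100.0, 180.0), "tau": (240.0, 60.0), "ptau": (22.0, 6.0)}

#: cluster centroids on the raw pg/ml scale, least to most pathogenic
CSF_CENTROIDS = (
    {"abeta": 1050.0, "tau": 260.0, "ptau": 24.0},
    {"abeta": 800.0, "tau": 330.0, "ptau": 33.0},
    {"abeta": 580.0, "tau": 430.0, "ptau": 45.0},
)

#: within-cluster sd per analyte, pg/ml
CSF_WITHIN_SD = {"abeta": 80.0, "tau": 35.0, "ptau": 3.5}


def synth_connectome(
    n_regions: int = 86,
    target_sparsity: float = 0.85,
    seed: int = 0,
    weight_sigma: float = 1.0,
) -> Connectome:
    """Random connected weighted graph with connectome-like sparsity.

    Log-normal edge weights on the complete graph are thresholded to the
    target sparsity; if thresholding disconnects the graph, the strongest
    removed edges bridging components are restored (the final off-diagonal
    zero fraction stays within 0.01 of the target).
    """
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    if not 0.0 <= target_sparsity <= 1.0:
        raise ValueError(f"target_sparsity must be in [0, 1], got {target_sparsity}")
    rng = np.random.default_rng(seed)
    W = np.zeros((n_regions, n_regions))
    iu, ju = np.triu_indices(n_regions, k=1)
    w = rng.lognormal(mean=0.0, sigma=weight_sigma, size=iu.size)
    W[iu, ju] = w
    W += W.T
    labels = dk86_labels() if n_regions == 86 else generic_labels(n_regions)
    conn = Connectome(W, tuple(labels))
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # reconnection handled below
        thin = threshold_connectome(conn, target_sparsity)
    C = thin.C.copy()
    # restore the strongest removed edge between components until connected
    for _ in range(n_regions):
        ncomp, comp = connected_components(C > 0, directed=False)
        if ncomp == 1:
            break
        bridge = (comp[iu] != comp[ju]) & (C[iu, ju] == 0)
        if not np.any(bridge):
            raise ValueError("cannot connect graph at requested sparsity")
        cand = np.flatnonzero(bridge)
        best = cand[np.argmax(W[iu[cand], ju[cand]])]
        C[iu[best], ju[best]] = C[ju[best], iu[best]] = W[iu[best], ju[best]]
    else:
        raise ValueError("cannot connect graph at requested sparsity")
    return Connectome(C, tuple(labels))


def seed_vector(
    labels, seed_regions=DEFAULT_SEED_REGIONS, total_mass: float = 1.0
) -> np.ndarray:
    """Initial pathology x0 concentrated uniformly on named seed regions."""
    labels = list(labels)
    idx = []
    for r in seed_regions:
        if r not in labels:
            raise ValueError(f"seed region {r!r} not among the graph labels")
        idx.append(labels.index(r))
    x0 = np.zeros(len(labels))
    x0[idx] = total_mass / len(idx)
    return x0


def synth_subject(
    L: Laplacian,
    beta: float,
    t_base: float,
    visit_times=(0.0, 1.0, 2.0, 3.0),
    noise_sd: float = 0.0,
    seed=0,
    x0: np.ndarray | None = None,
    subject_id: str = "synthetic",
) -> tuple[AtrophyTrajectory, dict]:
    """Forward-simulate one subject's longitudinal atrophy.

    Atrophy at visit times t_base + tau is the accumulation integral of the
    diffusion model from the seeded x0; observation noise is additive
    Gaussian with sd = noise_sd x RMS of the clean signal, and observed
    atrophy is floored at 0. Returns the trajectory plus a ground-truth
    record (beta, t_base, x0).
    """
    if beta <= 0 or t_base <= 0:
        raise ValueError("beta and t_base must be > 0")
    visit_times = np.asarray(visit_times, dtype=float)
    if visit_times.size < 2:
        raise ValueError("need at least two visits")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if x0 is None:
        x0 = seed_vector(L.labels)
    phi = np.stack([accumulate(L, x0, beta, t_base + tau) for tau in visit_times])
    if noise_sd > 0:
        scale = noise_sd * float(np.sqrt(np.mean(phi**2)))
        phi = phi + rng.normal(0.0, scale, size=phi.shape)
        phi = np.clip(phi, 0.0, None)
    traj = AtrophyTrajectory(
        subject_id=subject_id,
        t_long=visit_times - visit_times[0],
        phi=phi,
        region_labels=L.labels,
    )
    truth = {
        "subject_id": subject_id,
        "beta_true": float(beta),
        "tbase_true": float(t_base),
        "x0": x0.copy(),
    }
    return traj, truth


def synth_csf(
    n_per_cluster=(50, 50, 50), n_controls: int = 100, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Draw raw CSF profiles around the three cluster centroids.

    Returns (patients, controls, true_cluster_labels). Patients are drawn
    cluster by cluster; labels are 1-based, least (1) to most (3) pathogenic.
    """
    rng = np.random.default_rng(seed)
    pat_rows, labels = [], []
    i = 0
    for c, n in enumerate(n_per_cluster, start=1):
        centroid = CSF_CENTROIDS[c - 1]
        for _ in range(n):
            row = {"subject_id": f"P_{i:03d}"}
            for m in ("abeta", "tau", "ptau"):
                row[m] = float(max(1.0, rng.normal(centroid[m], CSF_WITHIN_SD[m])))
            pat_rows.append(row)
            labels.append(c)
            i += 1
    ctrl_rows = []
    for j in range(n_controls):
        row = {"subject_id": f"CON_{j:03d}"}
        for m in ("abeta", "tau", "ptau"):
            mu, sd = CSF_CONTROL[m]
            row[m] = float(max(1.0, rng.normal(mu, sd)))
        ctrl_rows.append(row)
    return pd.DataFrame(pat_rows), pd.DataFrame(ctrl_rows), np.asarray(labels)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Study conditions for a synthetic cohort.

    Group diffusivity medians are ordered EMCI < LMCI < AD; betas are
    log-normal around the group median with log-scale dispersion
    ``beta_log_sd``. Onset-to-baseline intervals are uniform over
    ``tbase_range``. Observation noise sd is a fraction of the clean-signal
    RMS. CSF profiles are drawn around one of three centroids; cluster
    membership is sampled from group-specific mixing probabilities.
    """

    n_per_group: dict = field(
        default_factory=lambda: {"EMCI": 30, "LMCI": 30, "AD": 30}
    )
    beta_medians: dict = field(
        default_factory=lambda: {"EMCI": 0.05, "LMCI": 0.10, "AD": 0.15}
    )
    beta_log_sd: float = 0.3
    tbase_range: tuple = (5.0, 20.0)
    n_visits: int = 4
    visit_spacing: float = 1.0
    seed_regions: tuple = DEFAULT_SEED_REGIONS
    noise_sd: float = 0.10
    cluster_mixing: dict = field(
        default_factory=lambda: {
            "EMCI": (0.70, 0.25, 0.05),
            "LMCI": (0.20, 0.60, 0.20),
            "AD": (0.05, 0.25, 0.70),
        }
    )
    n_controls: int = 100
    seed: int = 0

    def __post_init__(self):
        if any(n < 1 for n in self.n_per_group.values()):
            raise ValueError("need >= 1 subject per group")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        meds = [self.beta_medians[g] for g in self.n_per_group]
        if any(b <= 0 for b in meds):
            raise ValueError("beta medians must be > 0")
        for g, probs in self.cluster_mixing.items():
            if len(probs) != 3 or abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"cluster mixing for {g!r} must be 3 probs summing to 1")


def synth_cohort(spec: SyntheticCohortSpec, L: Laplacian) -> dict:
    """Generate a full cohort keyed by subject_id.

    Returns a dict of DataFrames: ``trajectories`` (long format),
    ``csf`` / ``csf_controls`` (raw pg/ml), ``covariates`` (diagnosis,
    apoe4_count, mmse, faq), ``volumes`` / ``volumes_controls`` (baseline
    regional volumes consistent with baseline atrophy), and
    ``ground_truth`` (beta, t_base, assigned CSF cluster).
    """
    rng = np.random.default_rng(spec.seed)
    labels = list(L.labels)
    x0 = seed_vector(labels, spec.seed_regions)
    visit_times = spec.visit_spacing * np.arange(spec.n_visits)

    traj_rows, truth_rows, csf_rows, cov_rows, vol_rows = [], [], [], [], []
    betas = []
    subjects = []
    for group in spec.n_per_group:
        for i in range(spec.n_per_group[group]):
            sid = f"{group}_{i:03d}"
            beta = float(
                np.exp(rng.normal(np.log(spec.beta_medians[group]), spec.beta_log_sd))
            )
            tbase = float(rng.uniform(*spec.tbase_range))
            traj, truth = synth_subject(
                L,
                beta,
                tbase,
                visit_times=visit_times,
                noise_sd=spec.noise_sd,
                seed=rng,
                x0=x0,
                subject_id=sid,
            )
            cluster = 1 + int(
                rng.choice(3, p=np.asarray(spec.cluster_mixing[group]))
            )
            subjects.append((sid, group, traj, cluster))
            betas.append(beta)
            truth_rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "beta_true": beta,
                    "tbase_true": tbase,
                    "csf_cluster_true": cluster,
                }
            )
            for vi, tau in enumerate(traj.t_long):
                for r, lab in enumerate(labels):
                    traj_rows.append(
                        {
                            "subject_id": sid,
                            "region": lab,
                            "t_years": float(tau),
                            "atrophy": float(traj.phi[vi, r]),
                        }
                    )

    betas = np.asarray(betas)
    ranks = (np.argsort(np.argsort(betas)) + 0.5) / betas.size
    for (sid, group, traj, cluster), rank in zip(subjects, ranks):
        centroid = CSF_CENTROIDS[cluster - 1]
        row = {"subject_id": sid}
        for m in ("abeta", "tau", "ptau"):
            row[m] = float(
                max(1.0, rng.normal(centroid[m], CSF_WITHIN_SD[m]))
            )
        csf_rows.append(row)
        # APOE4 allele count correlated with the subject's beta rank
        apoe4 = int(rng.binomial(2, 0.1 + 0.4 * rank))
        mmse = float(np.clip(rng.normal(29.0 - 14.0 * rank, 1.5), 0.0, 30.0))
        faq = float(np.clip(rng.normal(1.0 + 14.0 * rank, 2.0), 0.0, 30.0))
        cov_rows.append(
            {
                "subject_id": sid,
                "diagnosis": group,
                "apoe4_count": apoe4,
                "mmse": mmse,
                "faq": faq,
            }
        )

    # control CSF draws
    csf_ctrl_rows = []
    for i in range(spec.n_controls):
        row = {"subject_id": f"CON_{i:03d}"}
        for m in ("abeta", "tau", "ptau"):
            mu, sd = CSF_CONTROL[m]
            row[m] = float(max(1.0, rng.normal(mu, sd)))
        csf_ctrl_rows.append(row)

    # baseline regional volumes consistent with baseline atrophy:
    # volume = control_mean - atrophy_z * control_sd + measurement noise
    vol_mu = rng.uniform(2000.0, 12000.0, size=len(labels))
    vol_sd = 0.08 * vol_mu
    vol_ctrl_rows = []
    for i in range(spec.n_controls):
        vols = rng.normal(vol_mu, vol_sd)
        vol_ctrl_rows.append(
            {"subject_id": f"CON_{i:03d}", **dict(zip(labels, vols))}
        )
    for sid, group, traj, cluster in subjects:
        vols = vol_mu - traj.phi_base * vol_sd + rng.normal(0, 0.2 * vol_sd)
        vol_rows.append({"subject_id": sid, **dict(zip(labels, vols))})

    return {
        "trajectories": pd.DataFrame(traj_rows),
        "csf": pd.DataFrame(csf_rows),
        "csf_controls": pd.DataFrame(csf_ctrl_rows),
        "covariates": pd.DataFrame(cov_rows),
        "volumes": pd.DataFrame(vol_rows),
        "volumes_controls": pd.DataFrame(vol_ctrl_rows),
        "ground_truth": pd.DataFrame(truth_rows),
    }
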