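# Methods

## Model

Pathology burden `x(t)` on an `n`-region structural connectome follows
linear diffusion, `dx/dt = −βHx`, solved spectrally as
`x(t) = U diag(e^{−λᵢβt}) Uᵀ x₀` from the cached eigendecomposition
`H = U Λ Uᵀ`. Two Laplacian variants are provided: the unnormalized
`H = D − C` (mass-conserving: the zero mode is the constant vector, so
`Σx(t) = Σx₀`) and the symmetric-normalized `H = I − D^{−1/2} C D^{−1/2}`
(the default; the convention most common in the network-diffusion
literature — the source work does not state which it used, so both are
exposed and the choice is logged in run provenance). Eigenvalues are clipped
at zero from below; a mode counts as "zero" below `1e-8` relative to the
largest eigenvalue, and the zero-mode count must match the number of
connected components (fitting requires exactly one).

Measured atrophy is the accumulated pathology
`Φ(t) = U diag(gᵢ) Uᵀ x₀`, `gᵢ = (1 − e^{−λᵢβt})/(λᵢβ)` (and `gᵢ = t` on
zero modes), so `Φ` is componentwise nondecreasing for nonnegative seeds —
hypertrophy/compensation is outside the model. The proportionality constant
between accumulated pathology and the atrophy statistic is absorbed into the
scale of `β`; atrophy units are therefore arbitrary, and the reference
recipe `atrophy = max(0, z-score of volume deficit vs controls)` is provided
in `pprkit.cohort.atrophy_from_volumes`.

The baseline-slope operator
`H̃(s) = U diag(1/s, λᵢe^{−λᵢs}/(1−e^{−λᵢs})) Uᵀ` links the baseline pattern
to its exact instantaneous rate of change,
`dΦ/dt|_base = β H̃(βt_base) Φ_base`. Nonzero-mode weights are computed as
`λᵢ/expm1(λᵢs)` to avoid cancellation for `λᵢs ≪ 1`; for `λᵢs > 700` the
weight underflows to 0. Because all three operators share one
eigendecomposition, the identity `β H̃(βt) Φ(t) = x(t)` holds to round-off
by construction and is verified to `1e-8` relative over random graphs.

## Rate estimation

Per subject: (1) per-region OLS of atrophy on `[1, t]` via pseudoinverse;
negative slopes are zeroed and counted (cortical thickening is treated as
measurement error). (2) With `β` pinned at `β₀ = 0.05`/yr, `t_base` is
chosen on a grid (default 0.25–50 yr, step 0.25, both bounds configurable)
to maximize the Pearson correlation between `β₀H̃(β₀t)Φ_base` and the
measured slopes; ties break to the smallest `t`, fits at either boundary are
flagged, and an everywhere-undefined correlation (zero-variance slopes)
yields a flagged zero-rate fit. (3) `β̂` is the scalar least-squares
projection `⟨v, slopes⟩/⟨v, v⟩` with `v = H̃(β₀t̂)Φ_base`, clipped at zero
(negative diffusivity has no meaning). Steps 2–3 run once; an opt-in
`iterate` flag repeats them with `β₀ := β̂`.

Identifiability: `H̃` depends on `β` and `t` only through their product, so
only `β₀·t̂_base` is identified — `t̂_base` itself is a nuisance and is not
interpretable unless `β₀` happens to equal the subject's true rate.
Correlation in step 2 is scale-invariant and the projection in step 3 is
linear, so `β̂` scales linearly with the slopes while `t̂` is unchanged.

Accuracy regimes, measured in the test suite: with slopes computed
analytically from the model, recovery of `β` is exact up to grid
quantization (below `1e-3` relative on a 0.01-yr grid). With slopes
estimated by OLS from discrete visits, the slope is a secant reflecting
mid-window pathology rather than the instantaneous baseline rate; the
resulting bias is O(visit spacing) — about 19% at 0.12/yr with yearly
visits, 1% at 0.05-yr spacing — and is the accuracy floor of the
longitudinal design, consistent with the method's stated
linear-change-within-window assumption.

Cohort post-processing flags `β̂` outliers per diagnostic group with Tukey
fences `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`; quartiles use linear interpolation of
order statistics at index `(n−1)p` (the convention is unstated in the source
work; this one is fixed for reproducibility). Groups smaller than 4 get no
flags, with a warning.

## Cohort statistics

CSF z-scores standardize the six features (Aβ, tau, pTau and the ratios
Aβ/tau, Aβ/pTau, pTau/tau, ratios recomputed from raw values) against the
control cohort's mean and sample sd (ddof = 1); incomplete six-feature cases
are dropped and counted, never imputed. Clustering is agglomerative (Ward on
Euclidean distance by default; average/complete available) cut at each
candidate `k` in 2–10; the Calinski–Harabasz variance ratio
`[B/(k−1)]/[W/(n−k)]` selects `k`, ties to the smallest. Near-coincident
inputs (total dispersion ≈ 0) give a flat curve and the smallest `k`. Group
comparisons use Kruskal–Wallis (≥2 groups), Wilcoxon rank-sum (exactly 2),
and chi-square without continuity correction; p-values are two-sided and
deliberately uncorrected for multiple comparisons. Atrophied-region
selection ranks regions by the most negative independent-t statistic (cases
vs controls), ties by column order. The baseline regression is OLS with
intercept on 13 predictors (10 regional volumes + 3 CSF analytes),
complete cases only; rank-deficient designs raise an error naming the
collinear columns (found by pivoted QR).

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, not
real MRI: (i) connectome-like graphs — log-normal edge weights thresholded
to ~85% off-diagonal sparsity, reconnected by restoring the strongest
bridging edges, with an 86-region Desikan-Killiany-style label set
(34 cortical structures per hemisphere plus 9 subcortical per hemisphere);
(ii) subjects forward-simulated from a seed pattern on bilateral entorhinal
cortex + hippocampus (configurable), with group log-normal diffusivities
(medians 0.05/0.10/0.15 per EMCI-/LMCI-/AD-like group, log-sd 0.3 — chosen
to give separable groups at desk scale), onset-to-baseline intervals uniform
on 5–20 yr, four yearly visits, and additive Gaussian observation noise
(sd = 10% of the clean-signal RMS by default, floored at 0); (iii) CSF
profiles drawn around three centroids on ADNI-like pg/ml scales ordered from
control-like (Aβ 1050, tau 260, pTau 24) to an Alzheimer-like signature
(Aβ 580, tau 430, pTau 45) against controls at (1100, 240, 22), with
group-dependent cluster mixing; covariates (APOE4 count, MMSE, FAQ) are
correlated with the subject's diffusivity rank. Everything is deterministic
given the seed.

What passing tests on these data do **not** show: robustness to real
segmentation error structure (noise here is i.i.d. Gaussian), to
misspecified connectomes, to non-diffusive spread, or to demographic
confounding — the generator has none of these.

## Numerical and design choices

- Evolution, accumulation and the baseline-slope operator always use the
  one cached eigendecomposition; no generic `expm` path exists, so the
  operators cannot drift apart numerically.
- `1 − e^{−λs}` is always evaluated via `expm1`.
- The `t_base` grid search is vectorized across the grid through the shared
  eigenbasis (one projection of `Φ_base`, one weight matrix, one
  back-projection), making 10⁴-point grids cheap.
- Asymmetric input connectivity is averaged with its transpose (tractography
  counts both directions); nonzero diagonals are zeroed; both with warnings.
- Thresholding removes the smallest off-diagonal entries symmetrically and
  minimally; disconnection warns rather than fails (construction is allowed,
  fitting is not).
- Problem sizes in the test suite and acceptance script (86-region graphs,
  200-subject recovery cohorts, 1000-replicate calibration nulls, 20
  clustering seeds) were chosen as the smallest sizes at which the measured
  quantities are stable to well within their asserted tolerances.

## Known limitations

- A single global `β` per subject; no regional heterogeneity, no estimation
  of the seed pattern `x₀`, no longitudinal change of the connectome.
- The secant bias above means absolute `β̂` values depend on visit spacing;
  comparisons across subjects with similar schedules (the intended use) are
  rank-stable under noise (Spearman > 0.9 at 10% slope noise) but absolute
  rates should not be compared across different visit designs.
- `t̂_base` is reported for completeness but is not an estimate of disease
  duration.
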