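# pprkit

Network-diffusion modelling of neurodegenerative pathology spread, and
estimation of a per-subject **pathology progression rate (PPR)** from
longitudinal regional brain atrophy.

## The problem and who this is for

In Alzheimer's disease and related dementias, misfolded-protein pathology is
thought to spread along white-matter fibre tracts, so the *network topology*
of the brain — not just local biology — shapes where and how fast
degeneration appears. `pprkit` is for computational neuroscientists and
biomarker researchers who want to (i) simulate this trans-network spread on
a structural connectome, (ii) fit each subject's spread *rate* from two or
more volumetric MRI visits, and (iii) relate that rate to baseline CSF
biomarker profiles (amyloid-β, tau, pTau) at cohort level.

## The model

Pathology on an `n`-region connectome evolves as heat-like diffusion
governed by a graph Laplacian `H` of the connectivity matrix `C`:

    x(t) = exp(−βHt) · x₀

with diffusivity `β` (1/year) — the PPR. Measured atrophy is the running
integral of pathology, `Φ(t) = ∫₀ᵗ x(τ) dτ`, and the baseline atrophy
pattern `Φ_base` determines its own instantaneous rate of change exactly:

    dΦ/dt |_base = β · H̃(β t_base) · Φ_base,
    H̃(s) = U diag(1/s, λᵢ e^{−λᵢ s}/(1 − e^{−λᵢ s})) Uᵀ

where `H = U Λ Uᵀ` and `t_base` is the unobserved interval between pathology
onset and the baseline scan. Fitting proceeds in three steps:

1. per-region OLS atrophy slopes across visits (negative slopes clipped to 0);
2. grid search over `t_base` maximizing the Pearson correlation between
   `β₀·H̃(β₀t)·Φ_base` and the measured slopes, with the reference rate
   `β₀ = 0.05`/yr — only the product `β₀·t̂_base` is identified;
3. scalar least squares for `β̂` in `slopes = β·H̃(β₀t̂_base)·Φ_base`.

Cohort-level tools: Tukey-fence outlier flagging per diagnostic group,
control-standardized CSF z-scores, Ward hierarchical clustering with
Calinski–Harabasz model selection, Kruskal–Wallis / rank-sum / chi-square
comparisons, top-k atrophied-region selection by t-test, and a 13-variable
baseline regression predicting `β`.

## Worked example

```python
from pprkit import build_laplacian, synth_connectome
from pprkit.synthetic import synth_subject
from pprkit.ppr import PPREstimator

conn = synth_connectome(n_regions=86, target_sparsity=0.85, seed=1)
L = build_laplacian(conn, kind="normalized")

# forward-simulate one subject: beta = 0.12/yr, onset 10 yr before baseline,
# 4 yearly visits, no observation noise
traj, truth = synth_subject(L, beta=0.12, t_base=10.0, noise_sd=0.0, seed=1)

est = PPREstimator(laplacian=L, t_grid_stop=200.0).fit(traj.phi, traj.t_long)
print(f"beta_hat = {est.beta_:.4f} /yr")
print(f"tbase_hat = {est.tbase_:.2f} yr; product beta0*tbase = {est.betat_:.4f}")
print(f"peak Pearson r = {est.peak_correlation_:.4f}; clipped: {est.n_clipped_}")
```

prints

```
beta_hat = 0.1430 /yr
tbase_hat = 29.00 yr; product beta0*tbase = 1.4500
peak Pearson r = 1.0000; clipped: 0
```

The fitted rate overshoots the generating 0.12/yr by ~19%: with yearly
visits the OLS slope is a secant that reflects the *mid-window* pathology,
not the instantaneous baseline rate, an O(Δt) bias inherent to the
longitudinal design (see `docs/methods.md`). With analytically computed
baseline slopes the estimator recovers `β` to machine precision, and `t̂_base`
is meaningful only through the product `β₀·t̂_base ≈ β*·t*` (here 1.45 vs the
effective mid-window product 0.12 × 12 ≈ 1.44).

## Command line

```sh
pprkit simulate --seed 3 --out sim/ --n-per-group 20
pprkit fit --connectome sim/connectome.csv --atrophy sim/atrophy_long.csv \
           --covariates sim/covariates.csv --tgrid 0.25:200:0.25 --out fit/
pprkit cluster-report --ppr fit/ppr.csv --csf sim/csf_patients.csv \
           --csf-controls sim/csf_controls.csv --covariates sim/covariates.csv \
           --volumes sim/volumes_patients.csv \
           --volumes-controls sim/volumes_controls.csv --out report/
```

All inputs and outputs are plain delimited text; output tables carry
provenance headers (tool version, config hash, seed) and identically seeded
runs are hash-identical up to timestamps.

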