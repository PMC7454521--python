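# Methods

This note documents the models, numerical choices and known limitations of
each stage, and what the synthetic-data generator does and does not emulate.

## Three-state equilibrium unfolding

Model: N ⇌ I ⇌ U with linear extrapolation of both free-energy differences,
ΔG_X(u) = ΔG°_X − m_X·u (kcal/mol; m in kcal/(mol·M); u = molar urea);
K_X = exp(−ΔG_X/RT); populations from the partition function
1 + K_NI + K_NI·K_IU, evaluated through a log-sum-exp normalization so fully
folded/unfolded limits cannot overflow. RT uses T = 303.15 K (30 °C, the
equilibration temperature of the assays) and R = 0.0019872 kcal/(mol·K).

The observed signal at each wavelength is the population-weighted sum of
linear baselines. The global fit shares the four thermodynamic parameters
across wavelengths and gives each wavelength its own baselines; because
baselines enter linearly they are solved exactly by least squares inside
every residual evaluation (variable projection), reducing the nonlinear
search to four dimensions. Rank-deficient baseline designs (a species never
populated, as in a two-state limit) fall back to the minimum-norm solution,
which leaves the identifiable parameters untouched.

Defaults and rationale:

- **I baseline constant in urea.** The intermediate is populated over a
  narrow window, so a free slope is poorly determined; a slope can be
  enabled per config (`i_baseline_slope=True`).
- **Initialization** from the two steepest regions of a smoothed
  apparent-fraction proxy (per-wavelength normalized signal averaged over
  wavelengths); m-value starts 1.5 and 1.0 kcal/(mol·M); 10 jittered
  multi-starts from a seeded generator, best SSE wins. Bounds: ΔG° ∈
  [−12, 25], m ∈ [0.02, 6].
- **Errors** by residual-resampling bootstrap (default B = 200, seeded),
  refitting from the point estimate; SEs are bootstrap SDs, CIs are
  percentile intervals. Bootstrap is distribution-free and captures the
  strong ΔG–m correlation that a curvature-based covariance understates.
- Non-finite signal rows are dropped with a logged count, never imputed.
- Fewer than 8 distinct urea concentrations is an error; incomplete
  coverage of either transition at the fitted optimum is recorded as a
  warning on the fit object.

**Identifiability caveat.** ΔG° and m are ~0.99 correlated in any
linear-extrapolation fit (the midpoint Cm = ΔG°/m is what the data pin
down; ΔG° is an extrapolation to zero denaturant). With free per-wavelength
linear baselines and noise at 2% of the signal range, the information bound
on SE(ΔG°) for a single melt is ≈ 0.35–0.45 kcal/mol across realistic
parameter values — so single-melt ΔG° values carry a few-tenths-kcal
uncertainty however good the optimizer, and differences (ΔΔG°) should
always be quoted with the bootstrap error. At 0.5% noise (averaged CD
spectra) SE(ΔG°) drops to ≈ 0.1 kcal/mol.

Out of scope by design: thermal melts, kinetic folding data, SVD spectral
preprocessing, four-state models, baselines shared across variants (config
hooks exist for per-variant analyses only).

## Michaelis–Menten kinetics and barrier perturbations

v₀ = V_max[S]/([S]+K_m) fit by `scipy` nonlinear least squares with
positivity bounds; starts V_max = max v₀, K_m = median [S]. A K_m above 5×
the highest substrate level is flagged as poorly constrained. Errors by
seeded bootstrap over replicate groups when replicate labels exist
(mirroring biological-replicate error propagation), else over observations.
k_cat = V_max/[E]₀ (default [E]₀ = 1 μM); K_eff = k_cat/K_m in s⁻¹·μM⁻¹
(×10⁶ for s⁻¹·M⁻¹).

ΔΔG‡ = −RT·ln(k_mut/k_ref): antisymmetric, additive over composition, and
independent of the unknown transition-state prefactor. Applied to k_cat
(ΔΔG‡_kcat) and K_eff (ΔΔG‡_Keff). A fluorescence→concentration calibration
(RFU per μM product) is a config input; without it fits are reported in
relative units and flagged, and comparing a calibrated against a relative
fit is an error.

Initial velocities from progress curves use the OLS slope over an early
window: the first 10% of total amplitude or the first 15 points, whichever
is larger (configurable). An OLS line over the first fraction f of a
saturating trace underestimates the true initial slope by ≈ f/2 (≈5% at
f = 0.10); the window fraction should be chosen with that bias in mind.
Substrate/product inhibition and pre-steady-state kinetics are not modeled.

## Competition fitness

Exponential growth makes log2(mutant:WT) linear in time with slope
w = (k_MT − k_WT)/ln 2 per hour. Slopes are fit per replicate and averaged
(SE = SD/√n over the default three biological replicates). The normalized
selection coefficient is the affine map anchored at the two controls:
s = (w_i − w_WT)/|w_vector − w_WT|, so WT-like → 0 and the vector-only
null → −1 exactly, at any input scale, and s is strictly increasing in w_i.

Two definitions of s circulate for this assay — the anchored slope form and
the rate-ratio form s = log₂(k_MT/k_WT). They are not the same function:
for a lethal vector control the anchored form equals k_MT/k_WT − 1, which
matches log₂(k_MT/k_WT) to first order near s = 0 and compresses larger
effects. The package implements the anchored form as primary (its 0/−1
semantics are the assay's stated ground truth), exposes
`selection_from_rates` and `rate_from_slope` for the rate-ratio path, and
the two agree exactly on noiseless exponential data when the slope is first
converted back to a rate ratio. They are never silently blended. The WT
doubling time (default 4.5 hr) only rescales slopes to per-doubling units.

## Double-mutant cycles and additivity calls

δ = ΔP_DM − (ΔP_M1 + ΔP_M2) with SE by quadrature over the three stage SEs
(fit/bootstrap errors; replicate scatter enters through the stage SEs, not
a second time). The call is three-way: **nonadditive** if |δ| > z·SE
(default z = 1.96), otherwise **inconclusive** if |δ| exceeds an absolute
floor (default 0.1 kcal/mol), else **additive**. The floor prevents a noisy
measurement from being read as positive evidence of additivity. Both knobs
are exposed; no multiple-testing correction is applied across cycles (n is
small and the calls are descriptive). Monte-Carlo checks place the
false-nonadditivity rate on Gaussian nulls at the nominal ~5%.

Abundance: per-replicate band ratio (target/loading control), fold =
mean ratio / mean WT ratio, SE combining both relative SEMs in quadrature.

Flux model: s = a·[E]ᵢ·k_cat/(b + k_cat), fit by bounded least squares
(b > 0), covariance from the Gauss–Newton approximation at the optimum, and
a positive-trend check of s against capacity [E]ᵢ·k_cat. When every k_cat
in the panel is well below b the model degenerates to the linear regime and
only a/b is determined; the fit reports large SEs rather than failing.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical structure each fitting stage
assumes: melts are exactly the three-state population-weighted baselines
plus additive Gaussian noise; velocities carry multiplicative Gaussian
noise (constant CV); log2 competition trajectories are linear with additive
Gaussian noise and always include a vector-control track; blot intensities
are lognormal around the true fold with an independent lognormal loading
control. All randomness flows through explicit integer seeds; identical
seeds give byte-identical tables.

Default ground truth describes a moderately stable thermophilic TIM-barrel
enzyme at 30 °C: ΔG°_NI = 5.5, m_NI = 1.8, ΔG°_IU = 5.0, m_IU = 1.0
(midpoints ≈ 3.1 and 5.0 M on a 0–9 M, 0.25 M-step grid — a three-state
melt with a visible intermediate plateau); five CD wavelengths at
218–230 nm whose intermediate baseline shifts across the band (what makes
a multi-wavelength fit informative); k_cat = 9.5 s⁻¹, K_m = 359 μM at 1 μM
enzyme over 0–1500 μM substrate; WT doubling time 4.5 hr with 8 timepoints
over ~7 doublings; abundance folds in the 1–2.5× range.

Cycle scenarios state effects in the downstream perturbation convention
(positive = destabilized / higher barrier), so an injected δ is recovered
with the same sign and magnitude by the cycle stage; a zero injected δ
yields an exactly additive double mutant.

Not emulated: CD band shapes and instrument drift, aggregation or
irreversibility in melts, substrate depletion in progress curves, lag and
stationary phases in growth, plate effects, blot saturation. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated noise models, not robustness to those real-data pathologies.

## Pipeline determinism and I/O

Stage seeds derive deterministically from the config seed; CSVs are written
with fixed float formatting, so a (config, seed) pair reproduces
byte-identical outputs. Tables are plain UTF-8 CSV with a
`# allokit:<schema>/<version>` comment line; missing required columns raise
a schema error naming the column; unknown columns round-trip. The run log
records the seed, a config hash and per-stage warnings.
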