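# Methods

## The infection model

The model is a deterministic mass-action compartment model of a
well-mixed culture. Bacteria are sensitive (W), CRISPR-resistant (R) or
immunosuppressed (S); free phage are Acr-positive (V₁) or Acr-negative
(V₂). All five equations are printed in the README. The assumptions worth
keeping in mind:

- **Mass action, no space.** Adsorption is proportional to the product of
  phage and cell densities, with a single rate `a` for every cell type.
  Every adsorption removes the free phage particle (the −aN V terms),
  whether or not the infection is productive.
- **Instantaneous lysis.** There is no latent period: a productive
  infection immediately releases `B` particles. Burst size is the same on
  every host type.
- **No free-phage decay.** In a cell-free system phage densities are
  exactly conserved; extinction can only happen through unproductive
  adsorption.
- **Resistance is acquired, not pre-existing.** A sensitive cell survives
  infection with probability `A` and becomes resistant; resistance is
  never lost except transiently through immunosuppression.
- **The Acr acts in two places.** On a resistant cell, an Acr-positive
  phage escapes destruction with probability 1−ρ; it then either lyses
  (probability φ) or immunosuppresses the cell (probability 1−φ), which
  reverts at rate γ. Immunosuppressed cells are fully permissive to both
  phage types — this is the "public good" an Acr-positive phage produces
  for its Acr-negative competitors.
- **Deterministic densities.** Extinction is an operational label (a
  density below a threshold, default 10⁻³, read as "less than one
  particle per notional culture volume"), not an absorbing state; the ODE
  keeps integrating the raw value.

## Parameters and defaults

| symbol | meaning | default |
|---|---|---|
| a | adsorption rate (per phage per cell-density per time) | 0.001 |
| A | P(sensitive cell acquires resistance on infection) | 0.2 |
| B | burst size | 5 |
| ρ | P(Acr⁺ genome destroyed before acr expression on R) | 0.5 |
| φ | P(lysis given Acr expression succeeds on R) | 0.3 |
| γ | reversion rate of immunosuppression (γ⁻¹ = duration) | 1.0 |
| r | maximal bacterial growth rate (per time) | 1.0 |
| k | density-dependence intensity (inverse density) | 10⁻⁶ |
| m | bacterial mortality rate (per time) | 0.1 |

a, A, B, ρ and the (φ, γ) pair are the reference infection-biology
constants; r, k, m, the initial host density W(0) = 10³, the 100:100
phage inoculum and the horizon t_end = 30 are package choices, selected
once so that an uninfected culture grows logistically to a carrying
density of (1−m/r)/k = 9×10⁵ and an infected one runs through the full
epidemic (phage bloom, resistance sweep, immunosuppression) within the
horizon. Time is in arbitrary model units; no mapping to hours is
asserted. All defaults are overridable in config files and echoed into
every output file and manifest, so runs are self-describing. ρ presets
`bim1` = 0.5 and `bim2` = 0.9 encode hosts with one or two targeting
spacers (resistance grows with spacer number); only the one-spacer value
is a reference constant.

## Numerical choices

- Integration uses `scipy.integrate.solve_ivp` (LSODA, stiff-capable)
  with rtol = 10⁻⁸, atol = 10⁻¹⁰ and an analytic Jacobian; user sample
  times are read off the dense output. The suite verifies agreement with
  an independently coded fixed-step RK4 at h = 10⁻⁴ to better than 10⁻⁴
  relative (measured ≈ 5×10⁻⁹).
- Post-step densities in (−b, 0) with b = max(10⁻⁹, 10·atol) are clipped
  to zero as round-off; anything at or below −b aborts the run as an
  integrator failure carrying the last valid state. Zero is an exact
  fixed point of every compartment's equation, so analytic-limit suites
  (A = 0 ⇒ R ≡ S ≡ 0, φ = 1 ⇒ S ≡ 0) check residuals against round-off
  tolerances rather than literal zeros.
- Serial transfers are an optional event schedule multiplying every
  compartment by a dilution factor in (0, 1]; the reference experiment
  presets run without transfers, matching the continuous model. A sample
  requested exactly at a transfer time reflects the pre-transfer state.
- Sweep results map extinction sentinels onto the extended real line
  (+∞ when only the Acr-negative phage is extinct, −∞ when only the
  Acr-positive is) so monotonicity is well defined across extinctions.

## Measuring the immunosuppressed pool

Sweeps report two summaries of S: its peak density and its time
integral. They move in opposite directions along the γ⁻¹ grid: longer
immunosuppression accumulates a larger standing pool (peak S grows),
but fast reversion keeps the resistant pool R topped up, sustaining the
a(1−ρ)(1−φ)V₁R influx for longer, so total S person-time is larger when
reversion is fast. "More immunosuppressed cells accumulate with longer
immunosuppression" is therefore a statement about the standing density,
and the accumulation checks in the tests and acceptance script use peak
S; the integral is reported alongside for completeness.

## Assay statistics

Relative fitness is the odds ratio of the focal competitor's fraction
between two timepoints. Fitness tests default to the log scale (vs
log 1 = 0): the ratio is symmetric under label swap only on logs. The
tail of a one-sample test must be stated explicitly by the caller;
confidence intervals are Student-t at 95% on the analysis scale,
back-transformed for reporting. A fraction of exactly 0 or 1 means a
competitor below the detection limit; such values are returned as
flagged 0/∞ sentinels naming the boundary and are excluded from t tests
with a logged warning. A Shapiro–Wilk check is available as an advisory
(logged) diagnostic and never branches the analysis. Zero variance
across replicates takes a flagged exact-equality fast path.

## Synthetic data

The generators emulate the structure of the bench assays, not any
particular dataset:

- **Competition assays**: six biological replicates by default, sampled
  at days 0, 1 and 3; the focal competitor's odds grow by the true
  fitness factor per day; measured quantities get mean-zero Gaussian
  noise on logs (σ_log = 0.2 by default, a typical titre/qPCR
  coefficient of variation) and optionally Poisson plate-count noise
  after a simulated dilution. With log-normal noise the log-scale t test
  is exactly calibrated, which the 1000-experiment type-I error study
  confirms empirically.
- **Centre-of-infection assays**: pre-adsorbed cells challenged at
  MOI 1; centres are Poisson with expectation ECOI × cells × MOI, with
  ECOI = 0.8 on the knockout host and φ × 0.8 on the resistant host.
- **Noisy trajectories**: the ODE solution observed at the
  bench-observable aggregates only (N, V₁, V₂ — the W/R/S split needs
  clone typing), log-transformed with a detection floor of 10⁻³ and
  i.i.d. Gaussian noise. Everything is a pure function of (truth, noise
  model, seed).

What passing these tests does **not** show about real data: real assays
have shared batch effects across replicates, qPCR efficiency drift,
adsorption losses in washing steps, and biological replicate-to-replicate
variation in the dynamics themselves, none of which the noise model
contains. The calibration result says the statistics are internally
consistent under the stated noise model, not that the model is correct
for any particular bench dataset.

## Fitting φ and γ

`fit_phi_gamma` minimises squared error of log densities (with the same
detection floor applied to data and prediction — without it, collapsed
compartments dominate the loss with meaningless log-residuals) over
(φ, γ) ∈ (0,1) × (0, 100], all other parameters known. A 5×5 coarse grid
(φ linear, γ log-spaced) screens for identifiability — a parameter whose
axis leaves the grid loss unchanged to within 10⁻⁹ relative is flagged
non-identifiable, as happens for both parameters when A = 0 and no
resistant cells ever exist — then L-BFGS-B refines from the two best
grid points in (φ, log γ), with a boundary solution also flagged. The
objective integrates at rtol 10⁻⁶ (the loss surface is smooth well below
that scale, and it keeps a 100-replicate recovery study to minutes);
noise-free self-consistency recovers (0.3, 1.0) to ~10⁻⁶ relative, and
at σ_log = 0.1 the median errors are ≈ 0.01 in φ and ≈ 0.1 in log γ.

## Known limitations

- No stochastic (demographic-noise) formulation, no latent period, no
  spatial structure, no phage escape mutants, no surface-mutant host
  compartment.
- Only (φ, γ) are estimable in the fitting layer; the remaining seven
  parameters must be supplied.
- Monotonicity of the sweeps is established numerically on the default
  grids and reference constants, not proven analytically.
- Time units are arbitrary; comparisons with bench time courses are
  qualitative.
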