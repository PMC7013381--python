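# acrdyn

Population dynamics and assay statistics of anti-CRISPR (Acr) phages.

Bacteria defend against phage with CRISPR-Cas adaptive immunity; many
phages retaliate with anti-CRISPR proteins that block it. An Acr has two
distinct "strength" components: a selfish one — the probability φ that the
phage neutralises immunity and lyses a resistant cell — and a cooperative
one — the duration γ⁻¹ of the immunosuppressed state a failed infection
leaves behind, during which *any* phage (including Acr-negative
competitors) can exploit the cell. This package implements an
epidemiological model of these dynamics, the measurement statistics of the
competition and centre-of-infection assays used to study them, and
synthetic-data generators so every analysis layer can be exercised and
validated end to end without external data. It is written for
microbial-ecology and phage-biology researchers who want to explore how
Acr strength shapes phage competition, and for methodologists who need a
tested reference implementation of the assay arithmetic.

## The model

Five compartments: sensitive bacteria W, CRISPR-resistant bacteria R,
immunosuppressed bacteria S, free Acr-positive phage V₁ and free
Acr-negative phage V₂. With N = W + R + S and V = V₁ + V₂:

```
Ẇ  = r W (1 − kN) − (aV₁ + aV₂ + m) W
Ṙ  = A a V W + r R (1 − kN) − (a(1−ρ)V₁ + m) R + γS
Ṡ  = a(1−ρ)(1−φ) V₁ R − (aV + m + γ) S
V̇₁ = a(1−ρ)φB V₁ R + aB V₁ (S + (1−A)W) − aN V₁
V̇₂ = aB V₂ (S + (1−A)W) − aN V₂
```

Phages adsorb at rate a; a sensitive cell acquires CRISPR resistance with
probability A (otherwise it is lysed, releasing B particles); on a
resistant cell an Acr-positive phage genome is destroyed with probability
ρ, lyses with probability (1−ρ)φ, and otherwise leaves the cell
immunosuppressed, reverting at rate γ. Bacteria grow logistically (r, k)
and die at rate m. See `docs/methods.md` for assumptions, defaults and
numerical choices.

On top of the model sit the assay statistics: competitor fractions
q₁/(q₁+q₂), relative fitness in odds-ratio form
[f_x(1−f₀)]/[f₀(1−f_x)], the efficiency of centres of infection
ECOI = centres/(cells × MOI) with φ ≈ ECOI_resistant/ECOI_knockout, one-
and two-tailed one-sample t tests (optionally on the log scale) with 95%
CIs, and Bonferroni-corrected thresholds α/a.

## Worked example

```python
from acrdyn import ModelParameters, mixed_infection_design, run_design, final_phage_ratio

traj = run_design(mixed_infection_design(ModelParameters(phi=0.3, gamma=1.0)))
ratio = final_phage_ratio(traj)
print(f"V1 -> {traj.final_state.V1:.0f}, V2 -> {traj.final_state.V2:.0f}, "
      f"ratio {ratio.value:.3f}")
```

prints

```
V1 -> 4305, V2 -> 2490, ratio 1.729
```

an equal 100:100 phage mix on 10³ initially sensitive hosts ends with
both phage types persisting and the Acr-positive phage ahead 1.73:1 —
carrying the Acr pays even though its immunosuppression also feeds the
competitor. The numbered scripts under `analysis/` walk through the full
set of analyses (clonal infections and extinction, the φ and γ⁻¹ strength
sweeps, assay statistics on synthetic data, test calibration, parameter
recovery), each printing its findings and writing tables under
`results/`. The same experiments are available from a shell:

```sh
acrdyn simulate --config cfg.yaml --out traj.csv
acrdyn sweep --vary gamma_inv --out sweep.csv
acrdyn fitness --in competition.csv --null 1 --tail greater
```

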