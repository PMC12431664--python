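# filament-kinetics

Exact statistics of actin filament length under multicomponent regulation.

Actin filaments grow and shrink one subunit at a time while actin-binding
proteins (ABPs) — elongators such as formin, cappers such as capping protein,
depolymerases such as twinfilin — bind and unbind their ends. A filament
therefore switches stochastically between discrete states, each with its own
polymerization rate *r*ᵢ or depolymerization rate *γ*ⱼ, and the observable in
a TIRF microscopy experiment is the change in length ΔL<sub>t</sub> = L<sub>t</sub> − L₀
of each filament in a population. This package is for modellers and
experimentalists who want to turn measured length-change distributions into
statements about the underlying regulatory scheme.

## The model

The joint law of (state *i*, length change ΔL) obeys a master equation

```
d/dt P(ΔL, t) = (K − R) P(ΔL, t) + R↑ P(ΔL − 1, t) + R↓ P(ΔL + 1, t)
```

where `K` is the N×N switching-rate generator (`K[i, j]`, i≠j, the j→i rate;
columns sum to zero) and `R = R↑ + R↓` the diagonal matrix of per-state step
rates. Multiplying by ΔLⁿ and summing closes the partial-moment vectors
`M⁽ˣ⁾ᵢ(t) = Σ ΔLˣ Pᵢ(ΔL, t)` into a block-triangular linear ODE solved exactly
by a matrix exponential, giving ⟨ΔL<sub>t</sub>ⁿ⟩ without simulation:

* **transient** moments from any initial state occupancy, and
* **long-time window** moments ⟨ΔL<sub>τ</sub>ⁿ⟩ — the same propagation
  started from the stationary occupancy π (Kπ = 0), modelling a window of
  length τ opened after the switching has equilibrated.

The headline statistic is the Fano factor, variance/mean of ΔL in subunits:
exactly 1 for single-state (Poisson) growth, and pushed above 1 by switching
between states with different rates — how far above, and how it varies with
regulator concentration, discriminates between regulatory mechanisms (e.g.
mutually exclusive vs simultaneous binding of a formin and a capper).

Provided alongside the engine:

* closed-form mean/variance for the two-state elongator and capper schemes
  (`closed_forms`), parameterized by D = k⁺ + k⁻ and A = k⁻/D;
* an exact stochastic simulator producing TIRF-like trajectory ensembles
  (`simulate_ensemble`, `to_microscopy_like`);
* ensemble statistics: time-resolved Fano factor with percentile-bootstrap
  confidence bands, and the sample-size rule
  N = (1/ε²)(2 + 0.0027·F/μ) for planning experiments (`ensemble_stats`);
* a CLI: `filament {moments|sweep|simulate|fano|samplesize}`.

## Worked example

Formin mDia1 at 5 nM with the kinetics that describe the mF-TIRF dataset
(r₁ = 6, r₂ = 16 subunits/s, k̃⁺ = 8.8 µM⁻¹s⁻¹, k⁻ = 1.47×10⁻⁴ s⁻¹):

```python
import numpy as np
import filament_kinetics as fk
from filament_kinetics import reference as ref

model = fk.build_two_state_elongator(
    ref.BARE_RATE, ref.TIRF_FORMIN_BOUND_RATE, ref.tirf_formin()
)
frames = np.arange(0.0, 201.0, 2.0)
theory = fk.moment_summary(model, "transient", frames)
peak = np.nanargmax(theory.fano)
print(f"analytic Fano peak: {theory.fano[peak]:.1f} subunits at t = {frames[peak]:.0f} s")

ens = fk.simulate_ensemble(model, "B", 37, frames, seed=1)
fs = fk.fano_series(ens, n_boot=1000, seed=1)
k = np.searchsorted(frames, 50.0)
print(f"simulated 37-filament Fano at t = 50 s: {fs.fano[k]:.1f} "
      f"(95% CI {fs.ci_low[k]:.1f}-{fs.ci_high[k]:.1f})")

est = fk.required_sample_size(epsilon=0.33, fano_subunits=fs.fano[k],
                              mean_growth_um=fs.mean[k] * 0.0027)
print(f"filaments needed for 33% relative error: {est.n_ceiling}")
```

```
analytic Fano peak: 44.3 subunits at t = 52 s
simulated 37-filament Fano at t = 50 s: 57.2 (95% CI 37.4-73.0)
filaments needed for 33% relative error: 20
```

The analytic curve rises from the Poisson value 1, peaks near 44 subunits
around 50 s — the signature of a mixed population of bare and formin-bound
filaments — and decays back toward 1 as the population homogenizes. A
37-filament ensemble estimates that peak only coarsely (here 57 with a wide
bootstrap band covering the theory), which is exactly what the sample-size
rule quantifies.

The same from the shell:

```sh
filament simulate --builder elongator --r2 16 --kf-on 8.8 --kf-off 14.7e-5 \
    --F 5nM --n 37 --tmax 200 --dt 2 --seed 1 --out traj.csv
filament fano --input traj.csv --out fano.csv
filament samplesize --epsilon 0.1 --fano 1000 --mu 10 --dominant   # N = 200
```

## Layout

| module | contents |
| --- | --- |
| `model` | `StateSpec`, `RegulatorKinetics`, `KineticModel`, builders, YAML/JSON configs |
| `moments` | stationary occupancies, transient / windowed moments, Fano summaries |
| `closed_forms` | analytic two-state mean/variance expressions |
| `simulate` | event-driven SSA, exact ensemble sampler, µm conversion, trajectory CSV I/O |
| `ensemble_stats` | empirical moments, bootstrap Fano series, sample-size formula |
| `reference` | literature kinetic constants for formin and capping protein |
| `cli` | the `filament` command |

See `docs/methods.md` for the mathematical details, numerical choices and
limitations.
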