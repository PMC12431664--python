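# Methods

## Model

A filament is a continuous-time Markov jump process on two coupled
coordinates: a discrete regulatory state *i* ∈ {1…N} and an integer length
change ΔL (subunits). Each state is either polymerizing (unit steps +1 at
rate rᵢ ≥ 0; capped states are polymerizing states with rᵢ = 0) or
depolymerizing (unit steps −1 at rate γᵢ). State switching is governed by a
generator K with off-diagonal entries K[i,j] = k_{ij} (rate j→i) and
column sums zero, so occupancy probability is conserved. The model is
deliberately agnostic to which filament end a protein binds and to nucleotide
state; length is a single scalar coordinate.

Regulator binding enters through pseudo-first-order kinetics: a regulator at
concentration [X] (µM) with on-rate constant k̃⁺ (µM⁻¹s⁻¹) binds at
k⁺ = k̃⁺[X] and unbinds at k⁻ (s⁻¹). Builders cover the canonical schemes:

* one-state growth/shrinkage;
* two-state elongator B(r₁) ⇌ BF(r₂) and capper B(r₁) ⇌ BC(0);
* three-state competitive binding (B ⇌ BF, B ⇌ BC, no BF⇌BC) — mutually
  exclusive occupancy of the end;
* four-state simultaneous binding adding the dual-bound BFC state, with
  separate "primed" constants for binding to an already-occupied end
  (BF ⇌ BFC governed by the capper's primed leg, BC ⇌ BFC by the
  elongator's);
* fully custom N-state models from labelled states and transitions, covering
  e.g. elongator + capper + depolymerase schemes.

A note on the three-state scheme: the elongator-bound state carries the fast
rate r₂ and the capper-bound state rate 0, matching the four-state scheme's
assignments and the biochemistry (a capped end cannot elongate).

## Moment computation

Let M⁽ˣ⁾ᵢ(t) = Σ_ΔL ΔLˣ Pᵢ(ΔL, t). Multiplying the master equation by ΔLˣ
and summing telescopes the shift terms into binomial expansions, giving the
closed block-lower-triangular hierarchy

  dM⁽ˣ⁾/dt = K M⁽ˣ⁾ + Σ_{y<x} C(x,y) [R↑ + (−1)^{x−y} R↓] M⁽ʸ⁾,

with M⁽⁰⁾(0) the initial occupancy and M⁽ˣ≥¹⁾(0) = 0. The n-th moment is
⟨ΔLⁿ⟩ = Σᵢ M⁽ⁿ⁾ᵢ. The augmented (n+1)N system is propagated with
`scipy.linalg.expm` (scaling-and-squaring), which is exact up to
floating-point rounding, handles the stiff rate separations that arise here
(switching rates from 10⁻⁵ to 10⁵ s⁻¹ in the concentration sweeps) without
step-size control, and has no discretization error to tune. Against the
analytic two-state expressions the engine agrees to ≲10⁻⁹ relative error
over t, τ ∈ [1, 1000] s and concentrations spanning [0, 10⁻¹] µM.

Transient moments default to starting wholly in the first (bare) state for
the canonical builders, matching the convention of the analytic transient
expressions, and accept any initial distribution. Moment order is soft-capped
at 4 (a warning beyond): higher-order partial moments mix terms of very
different magnitude and lose digits.

**Stationary occupancy.** π solves Kπ = 0, Σπ = 1, computed by SVD null
space with a residual check at 10⁻¹⁰ relative to the largest rate. A unique
π exists iff the switching graph has exactly one *closed* communicating
class; this is checked explicitly (strongly connected components plus an
out-edge scan) and violated models raise, never fall back to a
pseudo-inverse. Transient states are allowed and get zero mass — important
because a regulator at concentration 0 makes its bound state unreachable,
and all zero-concentration limits must still evaluate.

**Long-time window statistics** ⟨ΔL_τⁿ⟩ are transient moments started from
π: the experimental protocol is to let filaments equilibrate among states,
then record length changes over a window τ. For n = 1 this reduces to
Σᵢ (signed rate)ᵢ πᵢ τ, exactly linear in τ.

**Fano factor.** variance/mean of ΔL, reported in subunits (variance and
mean are both computed on the subunit scale before the ratio, even when
traces are stored in µm). Where the mean vanishes — e.g. a balanced
polymerizing/depolymerizing random walk — the ratio is undefined and
reported as NaN, never silently 0 or ∞.

## Closed forms

The two-state transient and windowed mean/variance expressions are evaluated
directly, parameterized by D = k⁺ + k⁻ and the stationary bare-state
occupancy A = k⁻/D. Numerical care: `expm1` for 1 − e^{−Dt}; D = 0 (and D
whose square underflows) short-circuits to the pure one-state Poisson limit
(mean = variance = r₁t) instead of dividing by zero. The transient variance
expressions cancel terms of magnitude (Δr/D)², which bounds their attainable
absolute accuracy near t = 0 to that scale times machine epsilon; the test
tolerances account for this. The transcription of the transient variances
was validated three ways: variance(0) = 0 symbolically, the linear-in-t
coefficients match the windowed expressions' slopes, and the engine and
stochastic simulation reproduce them numerically to 10⁻⁶ relative and 3
Monte-Carlo SE respectively.

## Stochastic simulation

`simulate_trajectory` is a plain event-driven SSA over the joint process: in
state i, competing exponential clocks for each outgoing switch and for a
unit length step; every event is kept, and sampling a path at arbitrary
times is piecewise-constant interpolation of the exact event sequence. A
state with zero total rate is a valid absorbing configuration and is flagged,
not raised.

`simulate_ensemble` exploits the structure of the process for population
work: conditional on the switching path, the length steps are a piecewise
homogeneous Poisson process, so the step counts on the constant-state
intervals between consecutive frame/switch breakpoints are independent
Poisson draws. Sampling the switching path event-by-event and then drawing
those counts yields frame-time lengths with exactly the joint distribution
of the full SSA — no approximation — at ~10³× less work when step rates are
of order 10 s⁻¹ and switching rates of order 10⁻³ s⁻¹ (10⁴ filaments × 100 s
in well under a second). The two routes are cross-validated statistically in
the test suite. The cost of the shortcut is that within-frame event times are
not materialized; analyses needing them should use `simulate_trajectory`.

Reproducibility: one integer seed determines an ensemble via
`numpy.random.SeedSequence.spawn`, one child stream per filament; stationary
initial states are drawn inside each filament's own stream.

`to_microscopy_like` converts subunit counts to µm traces (1 subunit =
0.0027 µm) with an optional common initial length and optional i.i.d.
Gaussian per-frame measurement noise. The noise model is an emulation
convenience, off by default — real TIRF length extraction has correlated,
intensity-dependent errors that this does not attempt to capture.

## What the synthetic ensembles do and do not show

The generator reproduces the statistical structure the analysis assumes:
Markovian state switching, unit-step length kinetics, independent filaments,
a common frame grid, ΔL measured from observation start. It does not emulate
finite filament-detection length, photobleaching, drift, tracking errors,
filament loss/censoring, or inter-filament heterogeneity in rates. Agreement
of the estimators with theory on these ensembles therefore validates the
estimators and the analytic machinery, not the fidelity of any particular
experimental pipeline.

## Ensemble statistics

Empirical moments are the standard unbiased cross-sectional estimators
(variance with n−1), computed on ΔL = L_t − L_(first frame) in subunits.
Using ΔL rather than absolute length matters when initial lengths vary
across filaments; this is the definition used throughout.

The bootstrap resamples whole filaments with replacement (preserving
within-trajectory correlation) and takes percentile intervals per time
point; defaults n_boot = 1000, 95% level, both configurable, deterministic
given a seed. At small n (tens of filaments) percentile intervals undercover
somewhat, and band membership is strongly correlated across time points
within one ensemble — an outlying ensemble misses at most time points at
once. The replicated-recovery test therefore summarizes five replicate
ensembles by their median per-replicate coverage.

The sample-size rule N = (1/ε²)(2 + 0.0027·F/μ) takes F in subunits and μ
in µm (the 0.0027 is the subunit length that converts between them) and
returns both the real value and its ceiling; the dominant-term variant keeps
only the constant 2, appropriate when 0.0027·F/μ ≪ 2.

## Problem sizes used in validation

The stochastic cross-checks run 10⁴-filament ensembles per canonical model
(five models, transient and windowed), chosen so that 3 Monte-Carlo standard
errors resolve the analytic mean and variance to a few percent; the bootstrap
recovery test uses the experimentally motivated 37 filaments × 101 frames ×
5 replicates; the bootstrap coverage study uses 200 replicate ensembles of
200 filaments. The whole suite completes in well under a minute.

## Known limitations

* No spatial or structural filament model, no two-ended kinetics, no
  nucleotide (ATP/ADP-Pi) state, no filament-age effects, no bursty
  multi-subunit steps.
* Moments only; the full distribution P(ΔL, t) is not reconstructed.
* No closed forms for the 3- and 4-state schemes (the engine covers them
  numerically).
* The competitive scheme's Fano factor approaches the Poisson value only
  slowly with elongator concentration (Fano − 1 ∝ 1/[F] at fixed capper
  level); at 1 µM elongator with nanomolar capper it is still well above 1.
* Concentrations are constant parameters: no regulator depletion, no
  time-varying concentrations.
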