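# Methods

This note records the model conventions, measurement definitions, numerical
choices and known limitations of `hybridrx`.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The hybrid model

Gene expression is modeled by rate equations whose synthesis terms are gated
by right-closed unit steps, `s⁺(x, θ) = 1` iff `x ≥ θ`.  The boundary
convention matters only on measure-zero surfaces; fixing it right-closed
makes event handling deterministic and matches the integrator's restart
logic (after locating a crossing, the state is nudged ~1e−10 past the
surface in the crossing direction so the restarted right-hand side sees a
definite step value).  No sliding-mode (Filippov) treatment is attempted:
the model class studied here does not chatter, and a detector aborts with a
diagnostic if the same surface fires three times within 1e−6 time units
rather than guessing.

Absent thresholds are represented by `None` (collapsing the step factor to a
constant), never by floating-point infinities in configuration files.
Unswitched linear cross terms (`+η·x_j`, used by the positive-feedback
networks) are a first-class network field rather than encoded as degenerate
step terms.  Activating drug couplings (`+effect`) are implemented for
completeness alongside the repressing form (`−effect·x`); all benchmark
systems use the repressing form.

## PK conventions

Within each dosing period the concentration follows rise / plateau / decay.
Two conventions deserve emphasis because they are easy to get wrong:

* **`p1` and `p2` are stage-boundary times since the dose**, not stage
  durations: the rise ends at `p1`, the plateau ends at `p2` (its duration
  is `p2 − p1`), and elimination runs from `p2` to the period end.  This is
  the reading of the stage markers on a concentration–time profile axis, and
  it is the convention under which the benchmark dosing-regimen outcomes
  (11.5 / 8.8 / 12.1 for τ = 7 / 12 / 22 at α = 0.4) are reproduced to
  better than 0.1; the duration reading (`plateau ends at p1+p2`) misses
  them by up to 2 units.
* **The absorption quotient is not free**: continuity of the concentration
  at the rise/plateau junction forces `λ_a = ln(1+ζ)/p1`.  A user-supplied
  conflicting value triggers a warning and the derived value wins.
* **No inter-dose accumulation**: the profile restarts from zero (three-stage)
  or from the peak (decay-only) at every dose instant.  This is a property
  of the model, implemented literally.
* The peak concentration ζ is identified with the unit dose
  (proportionality constant 1), so stated dose values are usable directly.

`decay_only` is a separate profile, not a limiting case of the three-stage
profile, because fast-absorbing experiments specify `u(kτ) = ζ` exactly.

## PD conventions

The piecewise-linear effect map is zero below MinED θ̲, has slope `q`
between MinED and MaxED θ̄, and saturates above.  Built from a Hill curve
via `q = m·Emax/(4·EC50)` with the linear range centered on EC50 and the
swing pinned to Emax, the approximation's worst-case deviation sits at the
MaxED corner and equals `Emax·(1 − (3/2)^m/(1+(3/2)^m))` — about 0.165·Emax
for m = 4.  If the implied MinED would be negative (m < 2) it is clipped at
zero with the range width preserved, with a warning.

Benchmarks whose parameterization gives a slope but no effective-dose
thresholds use the **unsaturated linear PD** `γᵘ = q·u` (θ̲ = 0, θ̄ = ∞).
This applies to the 2-gene mutual-repression and 3-gene benchmarks.  The
saturated PD is used wherever thresholds are part of the parameterization (the one-gene efficacy
benchmark, the 2-gene positive-feedback benchmark).

## What "settles at" means

`end_of_period_series` reports the pre-dose samples `x(kτ⁻)` and flags
settling when successive values differ by less than `settle_eps`
(default 0.01).  The **reported settled level of a dosing regimen, however,
is the peak of the settled limit cycle**: after the concentration drops
below MinED the gene rebounds, and the rebound continues briefly past the
next dose until the concentration re-crosses MinED (time `t1` of the
period).  That rebound peak — the rightmost excursion of the cycle in the
expression–concentration plane, located analytically by root-finding on
`dx/dt = 0` and numerically by dense sampling — is the level a clinician
would read off a trace as "where treatment holds the gene", and it is the
definition under which the three benchmark regimens settle at 11.48, 8.81
and 12.17 (within 0.07 of the reference values 11.5, 8.8, 12.1).  The
pre-dose fixed points (10.999, 8.361, 11.904) are also exposed.

Percent reduction is measured against the *initial* disease level `x(0)`
(default 20), not against the drug-free steady state β₁/γ₁ = 25; the
drug-free limit therefore reads −25% (expression rises).

## Numerical choices

* Default integrator tolerances rel 1e−8 / abs 1e−10; `max_step ≤ τ/20` so
  no PK stage is stepped over; every PK stage boundary and PD crossing is a
  hard integrator restart, and gene-threshold crossings are located by
  `solve_ivp` event root-finding with restart.
* Stage-wise one-gene solutions use the exact integrating factor; the
  non-elementary convolution integrals of the rise and decay stages are
  evaluated by adaptive quadrature (tolerance 1e−10) with the exponent
  written as `G(s) − G(t) ≤ 0` so the integrand cannot overflow.
* The cycle-map fixed point is obtained by plain iteration to |Δ| < 1e−8
  (≤ 500 iterations, geometric convergence since the map is an affine
  contraction), mirroring the settling process rather than root-finding.
* The two-gene second-order solution uses the full form
  `x₁ = d/b + k₁e^{λ₁t} + k₂e^{λ₂t}` — the constant particular term is
  required for the forced equation — and switches to the resonant form with
  a `(d/a)·t` particular term at the marginal case b = 0, which is reported
  as `marginal`, not as an error.
* All numerics are double precision; outputs are printed at 12 significant
  digits; the entire pipeline is deterministic (no randomness anywhere).

## The 3-gene network and initial-condition bistability

With the benchmark parameters, the literal hybrid dynamics from the
late-disease start `x₁(0) = 40` are *not* bistable: the drug term
(≈ 5·x₁ at the dose instant) pulls x₁ below the gate threshold θ₁₃ = 21
within ~0.15 time units, the x₃ degradation gate re-engages, and the
trajectory converges to the same cycle as the early-disease start.  The
often-quoted divergence of late-stage disease emerges only under the
**regime-frozen approximation** — analyzing the affine system whose step
factors are pinned at their initial values, so a start above θ₁₃ never
re-engages x₃ degradation and the x₁–x₃ positive loop runs away.  The
package implements the literal semantics in the simulator and ships
`freeze_regime(network, x0)` as an explicit, documented analysis device;
the regime-frozen run from x₁(0) = 40 does diverge past 100 (unit-tested),
the literal run does not, and the corresponding acceptance check of the
literal claim is intentionally left failing rather than silently switching
semantics.

## NF-κB case study

Parameters are the published mass-action constants (µM, minutes) with the
lumped release rate `r4+d4 = 11.1`/min split into a catalytic part
`r4 = 11.07` and the dissociation `d4 = 0.03` so proteasome inhibition can
scale only the catalytic part.  Choices the source leaves open:

* **Stimulus** `k(t)`: constant, default `1e−4` µM/min.  Selected by
  scanning constant stimuli downward in order of magnitude with the default
  initial condition: at `1e−3`–`1e−2` the IKK steady state `k0/k02 ≥ 0.5` µM
  destroys IκBα faster than the delayed feedback can act and nuclear NF-κB
  saturates after ≤ 2 peaks, while at `1e−4` the system sustains ≥ 5
  oscillation peaks over 600 min with period ≈ 110 min, consistent with
  reported nuclear NF-κB oscillation timescales.
* **Initial condition**: total NF-κB 0.1 µM placed entirely in the
  cytoplasmic IκBα:NF-κB complex, all other species zero, constant history
  on `[−τ_delay, 0]` (resting cell).
* **Delay integration**: method of steps with step length `τ_delay = 40`
  min and dense interpolation of the lagged nuclear NF-κB; `τ_delay = 0`
  falls back to a plain ODE, and the method-of-steps solution converges to
  it as the delay shrinks (tested at `τ_delay = 1e−3` min).
* The published equations leave total NF-κB slightly non-conserved (a binding
  sink without a matching source, and release/loss coefficients differing
  by `d4 − d1`); they are implemented verbatim by default, and a
  `strict_balance` flag restores exact conservation for comparison.  The
  IKK branch obeys `d/dt(x7+x8+x9+x10) = k(t) − k02·x7` exactly in both
  variants, drug X included.

## What the fixtures do and do not emulate

The packaged fixtures are fully parameterized idealizations: step-function
regulation, a single effect-site compartment, no inter-individual PK
variability, no stochastic gene expression, and drug toxicity summarized
entirely by the intake density α.  Passing tests therefore demonstrate the
internal consistency of the hybrid framework and the reproducibility of its
benchmark analyses — not the calibration of any fixture against measured
biology.  Fitting the network form or the NF-κB model to real time courses
is out of scope.

## Problem sizes

Settled levels are measured from 40–50 simulated periods (settling is
detected after ~10–30), efficacy sweeps use 20-point period grids across
five intake densities, the eigen-analysis property checks use 1000 random
parameter draws, and NF-κB runs cover 600 min (15 delay steps).  These
sizes were chosen so every quantity is visibly converged (halving
integrator tolerances moves settled values by < 1e−4 relative).
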