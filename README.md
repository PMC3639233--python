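# hybridrx

Hybrid-systems modeling of gene regulatory networks under periodic drug
dosing.

Many drug-development questions are scheduling questions: given a drug that
represses a disease gene, is it better to give small doses often or large
doses rarely?  `hybridrx` answers this inside an explicit dynamical model
that couples three layers:

* **a threshold-switched gene network** — each gene's synthesis rate is a
  maximal rate gated by unit-step functions of its regulators,

  `dx_i/dt = Σ_k β_ik · Π Ω_ij · (1 − Π Ξ_ij) − γ_i x_i + (drug terms)`,

  with `Ω_ij = s⁺(x_j, θ⁺) s⁻(x_j, θ⁻)` so the state space is carved into
  regions with affine dynamics;
* **pharmacokinetics (PK)** — periodic intake with an effect-site
  concentration that rises exponentially (`e^{λ_a s} − 1`), holds at the peak
  ζ, and decays (`ζ e^{−λ_d (s−p2)}`) within each dosing period τ, or a pure
  decay profile for fast-absorbing drugs;
* **pharmacodynamics (PD)** — a piecewise-linear approximation of the
  sigmoidal Emax (Hill) curve, zero below the minimum effective dose θ̲,
  slope `q = m·Emax/(4·EC50)` between θ̲ and the maximum effective dose θ̄,
  saturated above.  The drug contributes an extra degradation term
  `−γᵘ(u(t))·x` on its target gene.

On top of the simulator the package provides exact stage-wise solutions of
the one-gene disease model (closed forms where the effect is constant,
integrating-factor quadrature where it tracks the concentration), the
per-period cycle map `x(kτ) ↦ x((k+1)τ)` whose fixed point is the settled
treatment outcome, efficacy-region sweeps at fixed intake density
`α = dose/τ`, a two-gene positive-feedback eigen-analysis (stability flips
exactly at `(γ₁+γᵘ)γ₂ = η₁η₂`), and a nine-species NF-κB pathway
delay-differential case study with single and combination drug
perturbations.

It is intended for systems-pharmacology and computational-biology work where
regimen structure (period, dose, stage boundaries) matters more than
molecular detail.

## Worked example

```python
import hybridrx as hx

bundle = hx.benchmark_fixture("one_gene")     # β₁=1, γ₁=0.04, q=0.1, θ̲=2, θ̄=10
params = hx.OneGeneParams(1.0, 0.04, bundle.pd, bundle.regimen)

fp = hx.one_gene_fixed_point(params, x0=20.0)   # τ=12, dose=4.8 (α=0.4)
print(fp.x_star, fp.peak, fp.converged)
```

prints

```
8.36101008182986 8.813718851113602 True
```

i.e. starting from the elevated disease level 20, the per-period map
converges: the pre-dose expression settles at **8.36** and the limit cycle
peaks at **8.81** — a 56% reduction of the disease-gene level, against a
drug-free steady state of β₁/γ₁ = 25.  Sweeping the period at the same
intake density shows why this regimen is a *sweet spot*:

```bash
hybridrx sweep --alpha 0.4 --tau-min 6 --tau-max 25 --tau-step 1 --out der.csv
```

gives a U-shaped reduction curve: 42.6% at τ=7 (doses too small — the
concentration barely clears θ̲), a maximum of 56.2% near τ=11–12, and 39.2%
at τ=22 (long drug-free windows let the gene rebound).  The same CLI exposes
`simulate` (labeled trajectories for any packaged or user-written network
spec), `stages` (stage times and fixed point as JSON), `eigen`, `nfkb`
and `fixtures`.

The NF-κB case study runs the delayed-feedback pathway model under a
kinase inhibitor ("drug X", competitive IKK binding), a proteasome
inhibitor (rate scaling by the inhibition fraction), and their combination:

```python
traj, m = hx.simulate_nfkb(hx.NFkBParams(), hx.DrugScenario())
print(m.n_peaks, round(m.period, 1), round(m.mean_x4, 4))   # 5 112.7 0.0482
```

Nuclear NF-κB oscillates with a ~110-minute period under constant stimulus;
0.2 µM of drug X drops its time average to 0.0097, 1.0 µM to 0.0045, 65%
proteasome inhibition alone barely moves it (0.0408), and the
0.2 µM + 65% combination reaches 0.0063 — lower than either single agent.

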