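name: two_gene_repression
description: >
  Mutually repressing gene pair; x1 is the disease gene (no self-degradation)
  and the drug adds concentration-proportional degradation to it.  Decay-only
  dosing, unsaturated linear PD.
genes: [x1, x2]
synthesis:
  x1:
    - beta: 1.0
      activators:
        - {gene: x2, theta_minus: 2.0}
  x2:
    - beta: 1.0
      activators:
        - {gene: x1, theta_minus: 10.0}
gamma:
  x1: 0.0
  x2: 1.0
drug_couplings:
  - target: x1
    mode: repressing
regimen:
  profile: decay_only
  tau: 8.0
  dose: 24.0
  lambda_d: 0.5
pd:
  q: 0.21
x0:
  x1: 20.0
  x2: 0.7
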