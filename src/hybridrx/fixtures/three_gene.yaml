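name: three_gene
description: >
  Three-gene network with multiple feedback loops: mutual repression between
  x1 and x2, x3 activated by low x2 and degraded only while x1 is below
  theta13, and a linear x3 -> x1 perturbation closing a conditional positive
  feedback loop.  Decay-only dosing on x1, unsaturated linear PD.
genes: [x1, x2, x3]
synthesis:
  x1:
    - beta: 1.0
      activators:
        - {gene: x2, theta_minus: 2.0}
  x2:
    - beta: 1.0
      activators:
        - {gene: x1, theta_minus: 10.0}
  x3:
    - beta: 4.0
      activators:
        - {gene: x2, theta_minus: 10.0}
gamma:
  x1: 0.0
  x2: 1.0
  x3: 0.0
switched_degradation:
  - gene: x3
    rate: 1.0
    gate: {gene: x1, theta_minus: 21.0}
feedback:
  - {from: x3, to: x1, eta: 0.1}
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
  x3: 0.5
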