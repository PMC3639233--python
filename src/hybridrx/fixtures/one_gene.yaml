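name: one_gene
description: >
  Single disease gene with impaired self-regulation under periodic three-stage
  dosing with a saturated piecewise-linear PD curve (the dosing-regimen
  efficacy benchmark).
genes: [x1]
synthesis:
  x1:
    - beta: 1.0
gamma:
  x1: 0.04
drug_couplings:
  - target: x1
    mode: repressing
regimen:
  profile: three_stage
  tau: 12.0
  dose: 4.8
  lambda_d: 0.3
  p1: 1.0
  p2: 5.0
pd:
  q: 0.1
  theta_lower: 2.0
  theta_upper: 10.0
x0:
  x1: 20.0
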