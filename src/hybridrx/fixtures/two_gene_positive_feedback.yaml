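name: two_gene_positive_feedback
description: >
  Gene pair coupled by an unswitched positive feedback loop (eta1, eta2); the
  drug represses x1.  Without the drug the loop gain exceeds the degradation
  product and expression grows without bound.  Three-stage dosing, saturated
  PD.
genes: [x1, x2]
synthesis:
  x1:
    - beta: 0.1
  x2:
    - beta: 0.1
gamma:
  x1: 0.2
  x2: 1.0
feedback:
  - {from: x2, to: x1, eta: 1.0}
  - {from: x1, to: x2, eta: 1.0}
drug_couplings:
  - target: x1
    mode: repressing
regimen:
  profile: three_stage
  tau: 20.0
  dose: 16.0
  lambda_d: 0.3
  p1: 1.0
  p2: 15.0
pd:
  q: 2.0
  theta_lower: 3.0
  theta_upper: 8.0
x0:
  x1: 1.0
  x2: 1.0
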