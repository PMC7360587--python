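# The 14 branch models of the selection analysis and the nested LRT ladder.
# Each model maps clade/branch labels to an omega-class index; unlisted edges
# share the background class 0 (omega_0). Model A is the one-ratio null.
# `lrt` and `p` carry the published statistic and p-value for each
# comparison ("<0.05" where only significance was printed).
models:
  A: {}
  B: {A1: 1, BranchA1: 1}
  C: {A2: 1}
  D: {A3: 1}
  E: {B1: 1, BranchB1: 1}
  F: {B2: 1}
  G: {BranchA1: 1}
  H: {BranchB1: 1}
  I: {C1: 1}
  J: {D1: 1}
  K: {A1: 1, BranchA1: 1, B1: 1, BranchB1: 1}
  L: {A1: 1, BranchA1: 1, B1: 2, BranchB1: 2}
  M: {A1: 1, B1: 1, BranchB1: 2, BranchA1: 3}
  N: {A1: 1, BranchA1: 2, B1: 3, BranchB1: 4}
ladder:
  - {"null": A, alt: B, df: 1, lrt: 30.4, p: "<0.05"}
  - {"null": A, alt: C, df: 1, lrt: 0.68, p: "0.41"}
  - {"null": A, alt: D, df: 1, lrt: 0.36, p: "0.55"}
  - {"null": A, alt: E, df: 1, lrt: 35.0, p: "<0.05"}
  - {"null": A, alt: F, df: 1, lrt: 0.98, p: "0.32"}
  - {"null": A, alt: G, df: 1, lrt: 3.56, p: "0.06"}
  - {"null": A, alt: H, df: 1, lrt: 0.06, p: "0.81"}
  - {"null": A, alt: I, df: 1, lrt: 0.47, p: "0.49"}
  - {"null": A, alt: J, df: 1, lrt: 1.83, p: "0.18"}
  - {"null": A, alt: K, df: 1, lrt: 67.07, p: "<0.05"}
  - {"null": A, alt: L, df: 2, lrt: 67.76, p: "<0.05"}
  - {"null": A, alt: M, df: 3, lrt: 74.62, p: "<0.05"}
  - {"null": A, alt: N, df: 4, lrt: 74.62, p: "<0.05"}
  - {"null": K, alt: L, df: 1, lrt: 0.70, p: "0.40"}
  - {"null": K, alt: M, df: 2, lrt: 7.56, p: "<0.05"}
  - {"null": K, alt: N, df: 3, lrt: 7.56, p: "0.06"}
  - {"null": M, alt: N, df: 1, lrt: 0.00, p: "1.00"}
# omega estimates of the best-supported model M
best_model: M
omegas_best:
  A1: 1.033
  B1: 1.033
  BranchA1: 1.726
  BranchB1: 0.322
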