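# Kinase autophosphorylation with positive feedback and a saturable
# phosphatase: bistable in the deterministic limit, stochastically
# switching between the two steady states at particle numbers.
# SYNTHETIC desk-scale rates (ms dynamics); per-pair rates divided by the
# 0.25 um box volume are the BNG-unit bimolecular constants below.
begin model
begin parameters
  V      0.015625      # um^3 (0.25 um box)
  kauto  3000*V        # trans-autophosphorylation, um^3/N/s
  kbase  1200          # basal phosphorylation, 1/s
  kon    1.2e5*V       # phosphatase binding, um^3/N/s
  koff   3e4           # 1/s
  kcat   1.2e6         # dephosphorylation in complex, 1/s
  n_K    120
  n_P    7
  MCELL_DIFFUSION_CONSTANT_3D_K 1e-5
  MCELL_DIFFUSION_CONSTANT_3D_P 1e-5
end parameters
begin molecule types
  K(p~0~1,b)
  P(b)
end molecule types
begin compartments
  CP 3 V
end compartments
begin seed species
  @CP:K(p~0,b) n_K
  @CP:P(b) n_P
end seed species
begin observables
  Molecules Kp K(p~1)
  Molecules K0 K(p~0)
  Molecules P_free P(b)
end observables
begin reaction rules
  auto:    K(p~0,b) + K(p~1,b) -> K(p~1,b) + K(p~1,b) kauto
  basal:   K(p~0,b) -> K(p~1,b) kbase
  p_bind:  P(b) + K(p~1,b) -> P(b!1).K(p~1,b!1) kon
  p_off:   P(b!1).K(p~1,b!1) -> P(b) + K(p~1,b) koff
  p_cat:   P(b!1).K(p~1,b!1) -> P(b) + K(p~0,b) kcat
end reaction rules
end model
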