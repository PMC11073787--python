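# Activator-repressor circadian clock (Vilar-type), pure particle form.
# One gene copy each for activator A and repressor R; A enhances both
# promoters; R sequesters A into an inert complex C; mRNAs are explicit.
# Desk-scale parameterization: concentrations reduced (s=30), promoter
# and sequestration kinetics slowed 3x relative to production, and time
# compressed so one oscillation lasts ~5 ms (see docs/methods.md).
begin model
begin parameters
  V        0.015625        # um^3 (0.25 um box)
  F        3611.1          # time compression: 1/h -> 1/s * 1.3e7/3600
  s        30              # concentration reduction
  slow     3               # promoter/sequestration slowdown
  alphaA   50/s*F          # basal activator transcription, 1/s
  alphaAp  500/s*F         # activated
  alphaR   0.01/s*F
  alphaRp  50/s*F
  betaA    50*F            # translation, 1/s
  betaR    5*F
  deltaMA  10*F
  deltaMR  0.5*F
  deltaA   1*F
  deltaR   0.2*F
  gammaA   1*s/slow*F*V    # promoter binding, um^3/N/s
  gammaR   1*s/slow*F*V
  gammaC   2*s/slow*F*V    # A+R sequestration, um^3/N/s
  thetaA   50/slow*F       # promoter unbinding, 1/s
  thetaR   100/slow*F
  MCELL_DIFFUSION_CONSTANT_3D_GA 0
  MCELL_DIFFUSION_CONSTANT_3D_GR 0
  MCELL_DIFFUSION_CONSTANT_3D_MA 1e-5
  MCELL_DIFFUSION_CONSTANT_3D_MR 1e-5
  MCELL_DIFFUSION_CONSTANT_3D_A 1e-5
  MCELL_DIFFUSION_CONSTANT_3D_R 1e-5
  MCELL_DIFFUSION_CONSTANT_3D_C 1e-5
end parameters
begin molecule types
  GA(p~0~1)
  GR(p~0~1)
  MA()
  MR()
  A()
  R()
  C()
end molecule types
begin compartments
  CP 3 V
end compartments
begin seed species
  @CP:GA(p~0) 1
  @CP:GR(p~0) 1
end seed species
begin observables
  Molecules A_count A()
  Molecules R_count R()
  Molecules C_count C()
  Molecules MA_count MA()
  Molecules MR_count MR()
end observables
begin reaction rules
  ga_bind:   GA(p~0) + A() -> GA(p~1) gammaA
  ga_unbind: GA(p~1) -> GA(p~0) + A() thetaA
  gr_bind:   GR(p~0) + A() -> GR(p~1) gammaR
  gr_unbind: GR(p~1) -> GR(p~0) + A() thetaR
  tx_a0:     GA(p~0) -> GA(p~0) + MA() alphaA
  tx_a1:     GA(p~1) -> GA(p~1) + MA() alphaAp
  tx_r0:     GR(p~0) -> GR(p~0) + MR() alphaR
  tx_r1:     GR(p~1) -> GR(p~1) + MR() alphaRp
  tl_a:      MA() -> MA() + A() betaA
  tl_r:      MR() -> MR() + R() betaR
  dMA:       MA() -> 0 deltaMA
  dMR:       MR() -> 0 deltaMR
  dA:        A() -> 0 deltaA
  dR:        R() -> 0 deltaR
  seq:       A() + R() -> C() gammaC
  c_to_r:    C() -> R() deltaA
end reaction rules
end model
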