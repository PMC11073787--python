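# Hybrid form of the activator-repressor clock: repressor R is tracked
# as a continuous copy number updated by explicit-Euler finite
# differences outside the particle engine; everything else is particles.
# The bimolecular sequestration A + R -> C becomes the pseudo-first-order
# rule A_to_C whose rate (gammaC_pair * R) is set before each iteration;
# C -> R becomes C_decay, with R incremented by the event count.
begin model
begin parameters
  V        0.015625
  F        3611.1
  s        30
  slow     3
  slowC    90             # extra slowdown of A+R sequestration (Euler stability)
  alphaA   50/s*F
  alphaAp  500/s*F
  alphaR   0.01/s*F
  alphaRp  50/s*F
  betaA    50*F
  betaR    5*F            # enters the Euler update of R (not a rule here)
  deltaMA  10*F
  deltaMR  0.5*F
  deltaA   1*F
  deltaR   0.2*F          # enters the Euler update of R
  gammaA   1*s/slow*F*V
  gammaR   1*s/slow*F*V
  gammaC   2*s/slowC*F*V  # divided by V at runtime for the A_to_C rate
  thetaA   50/slow*F
  thetaR   100/slow*F
  MCELL_DIFFUSION_CONSTANT_3D_GA 0
  MCELL_DIFFUSION_CONSTANT_3D_GR 0
  MCELL_DIFFUSION_CONSTANT_3D_MA 1e-5
  MCELL_DIFFUSION_CONSTANT_3D_MR 1e-5
  MCELL_DIFFUSION_CONSTANT_3D_A 1e-5
  MCELL_DIFFUSION_CONSTANT_3D_C 1e-5
end parameters
begin molecule types
  GA(p~0~1)
  GR(p~0~1)
  MA()
  MR()
  A()
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
  dMA:       MA() -> 0 deltaMA
  dMR:       MR() -> 0 deltaMR
  dA:        A() -> 0 deltaA
  A_to_C:    A() -> C() 0
  C_decay:   C() -> 0 deltaA
end reaction rules
end model
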