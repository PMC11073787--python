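# Well-mixed irreversible association A + B -> C in a 0.5 um box.
# Calibration fixture: with D = 1e-5 cm^2/s the box is well mixed and the
# mean trajectory must follow the mass-action ODE.
begin model
begin parameters
  kon 1.66      # um^3/N/s (~1e9 M^-1 s^-1)
  n0 100
  MCELL_DIFFUSION_CONSTANT_3D_A 1e-5
  MCELL_DIFFUSION_CONSTANT_3D_B 1e-5
  MCELL_DIFFUSION_CONSTANT_3D_C 1e-5
end parameters
begin molecule types
  A()
  B()
  C()
end molecule types
begin compartments
  CP 3 0.125
end compartments
begin seed species
  @CP:A() n0
  @CP:B() n0
end seed species
begin observables
  Molecules A_free A()
  Molecules B_free B()
  Molecules C_made C()
end observables
begin reaction rules
  bind: A() + B() -> C() kon
end reaction rules
end model
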