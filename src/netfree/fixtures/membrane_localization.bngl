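# Membrane localization stabilizes protein-protein interaction: volume
# partners A and B bind a membrane lipid M; membrane-bound MA and MB then
# dimerize in 2D far faster than A and B do in 3D.
# Desk-scale geometry: 0.47 x 0.47 x 0.5 um box, M released on the -z
# face with reflective 2D edges (configured by the fixture loader).
# SYNTHETIC rates of plausible magnitude; BNG units.
begin model
begin parameters
  ka_m   0.8      # A + M binding, um^3/N/s
  kd_m   1000     # unbinding, 1/s
  ka_d   0.5      # MA + MB dimerization (thin-volume rate), um^3/N/s
  kd_d   200      # dimer dissociation, 1/s
  ka_v   0.005    # A + B in solution, um^3/N/s
  kd_v   2000     # 1/s
  n_m    80
  n_a    80
  n_b    80
  MCELL_DIFFUSION_CONSTANT_3D_A 1e-5
  MCELL_DIFFUSION_CONSTANT_3D_B 1e-5
  MCELL_DIFFUSION_CONSTANT_2D_M 1e-8
end parameters
begin molecule types
  A(m,b)
  B(m,a)
  M(l)
end molecule types
begin compartments
  PM 2 0.2209
  CP 3 0.11045 PM
end compartments
begin seed species
  @PM:M(l) n_m
  @CP:A(m,b) n_a
  @CP:B(m,a) n_b
end seed species
begin observables
  Molecules MA M(l!1).A(m!1)
  Molecules MB M(l!1).B(m!1)
  Molecules AB_3d A(m,b!1).B(m,a!1)
  Molecules MAB M(l!1).A(m!1,b!2).B(a!2)
end observables
begin reaction rules
  a_mem: A(m,b) + M(l)@PM <-> A(m!1,b).M(l!1) ka_m, kd_m
  b_mem: B(m,a) + M(l)@PM <-> B(m!1,a).M(l!1) ka_m, kd_m
  dimer2d: A(m!+,b) + B(m!+,a) <-> A(m!+,b!1).B(m!+,a!1) ka_d, kd_d
  dimer3d: A(m,b) + B(m,a) <-> A(m,b!1).B(m,a!1) ka_v, kd_v
end reaction rules
end model
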