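# Reduced dendritic-spine fixture: kinase K and calcium in a spine head
# with a PSD subcompartment whose walls are reflective to K but
# transparent to Ca (species-selective surface classes, configured by
# the fixture loader).  SYNTHETIC rates.
begin parameters
  k_bind 0.2
  k_unbind 5000
  MCELL_DIFFUSION_CONSTANT_3D_K 2e-6
  MCELL_DIFFUSION_CONSTANT_3D_Ca 2e-5
end parameters
begin molecule types
  K(c)
  Ca(k)
end molecule types
begin seed species
end seed species
begin observables
  Molecules KCa K(c!1).Ca(k!1)
  Molecules Ca_free Ca(k)
end observables
begin reaction rules
  bind: K(c) + Ca(k) <-> K(c!1).Ca(k!1) k_bind, k_unbind
end reaction rules
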