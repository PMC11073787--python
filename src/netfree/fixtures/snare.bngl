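# Dual-calcium-sensor model of vesicle release at a SNARE complex.
# One membrane-bound sensor complex carries a synchronous site binding up
# to 5 Ca (component s), an asynchronous site binding up to 2 Ca
# (component a), and a docked-vesicle flag dv.  Release (spontaneous,
# synchronous from s~5, asynchronous from a~2) undocks the vesicle and
# emits a dummy V_release molecule that timestamps the event.
#
# SYNTHETIC rate constants: plausible dual-sensor magnitudes in BNG units
# (bimolecular um^3.N^-1.s^-1, unimolecular s^-1); the state and reaction
# counts of this model do not depend on them.
begin model
begin parameters
  alpha    0.102      # sync Ca on-rate per free site
  beta     2320       # sync Ca off-rate per bound ion
  b        0.25       # sync unbinding cooperativity
  chi      0.00634    # async Ca on-rate per free site
  delta    13         # async Ca off-rate per bound ion
  g_spont  2e-4       # spontaneous release
  g_sync   2000       # synchronous release from s~5
  g_async  50         # asynchronous release from a~2
  n_snare  70
  n_ca     1000
  MCELL_DIFFUSION_CONSTANT_2D_snare 1e-8
  MCELL_DIFFUSION_CONSTANT_3D_Ca 6e-6
  MCELL_DIFFUSION_CONSTANT_3D_V_release 1e-6
end parameters
begin molecule types
  snare(s~0~1~2~3~4~5,a~0~1~2,dv~0~1)
  Ca()
  V_release()
end molecule types
begin compartments
  PM 2 0.375
  CP 3 0.0156 PM
end compartments
begin seed species
  @PM:snare(s~0,a~0,dv~1) n_snare
  @CP:Ca() n_ca
end seed species
begin observables
  Molecules Ca_free Ca
  Molecules docked snare(dv~1)
  Molecules sync_ready snare(s~5)
  Molecules async_ready snare(a~2)
  Molecules released V_release()
end observables
begin reaction rules
  sync1:  snare(s~0) + Ca@CP <-> snare(s~1)  5*alpha, beta
  sync2:  snare(s~1) + Ca@CP <-> snare(s~2)  4*alpha, 2*beta*b
  sync3:  snare(s~2) + Ca@CP <-> snare(s~3)  3*alpha, 3*beta*b^2
  sync4:  snare(s~3) + Ca@CP <-> snare(s~4)  2*alpha, 4*beta*b^3
  sync5:  snare(s~4) + Ca@CP <-> snare(s~5)  alpha,   5*beta*b^4
  async1: snare(a~0) + Ca@CP <-> snare(a~1)  2*chi, delta
  async2: snare(a~1) + Ca@CP <-> snare(a~2)  chi,   2*delta
  spont:  snare(dv~1) -> snare(dv~0) + V_release()@CP  g_spont
  sync:   snare(s~5,dv~1) -> snare(s~5,dv~0) + V_release()@CP  g_sync
  async:  snare(a~2,dv~1) -> snare(a~2,dv~0) + V_release()@CP  g_async
end reaction rules
end model
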