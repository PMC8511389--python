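"""Simulate one pure stand and print its three season-level outputs.

N_ears  — surviving axes (ears) per plant at maturity;
L_perc  — mean fraction of incident light intercepted by the canopy;
F_tot   — total plot fitness, the sum over surviving axes of intercepted
          PAR per unit thermal time over the 45 days around flowering.
"""

from canomix import Genotype, build_pure_plot, generate_climate, simulate_stand

climate = generate_climate(360, seed=1)
genotype = Genotype(h_ms=100.0, phi_b=40.0, lmax_b=21.5, gai_c=0.55, par_t=0.4)

plot = build_pure_plot(genotype, n_plants=24, density=200.0, seed=7)
out = simulate_stand(plot, climate, seed=7)

print(f"N_ears = {out.n_ears:.3f} ears per plant")
print(f"L_perc = {out.l_perc:.3f}")
print(f"F_tot  = {out.f_tot:.3f} mol m-2 (degC d)-1 summed over axes")
print(f"max axes per plant over the season: {out.tillering_dynamics.max()}")
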