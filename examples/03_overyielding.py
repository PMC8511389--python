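"""Overyielding of a binary mixture against its seed-matched pure stands.

A mixture is parameterized by reference values (the mixture mean) and
differentials (variety 1 minus variety 2) for the five plant parameters.
Overyielding OY = output_mixture / mean(output_pure1, output_pure2); with
zero differentials the three stands are identical and OY = 1 exactly.
"""

from canomix import MixtureSpec, generate_climate, overyielding, run_with_pures

climate = generate_climate(360, seed=1)
ref = {"h_ms": 100.0, "phi_b": 40.0, "lmax_b": 21.5, "gai_c": 0.55, "par_t": 0.4}

for label, diff in [
    ("zero differential", dict.fromkeys(ref, 0.0)),
    ("height contrast  ", {**dict.fromkeys(ref, 0.0), "h_ms": 40.0}),
    ("blade contrast   ", {**dict.fromkeys(ref, 0.0), "lmax_b": 10.0}),
]:
    spec = MixtureSpec(ref=ref, diff=diff)
    mix, p1, p2 = run_with_pures(spec, climate, seed=7, n_plants=24)
    oy = overyielding(mix.f_tot, p1.f_tot, p2.f_tot)
    print(f"{label}: F_tot mix={oy.out_mix:.3f} "
          f"pures=({oy.out_pure1:.3f}, {oy.out_pure2:.3f})  OY={oy.oy:.3f}")
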