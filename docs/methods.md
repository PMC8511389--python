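# Methods

This document describes the model implemented by `canomix`: the synthetic
climate generator, the individual-based stand simulator, the analysis
stack, the numerical choices, and the known limitations.

## 1. Synthetic climate

`generate_climate(n_days, seed, params)` produces a daily series of mean
air temperature (°C) and incident photosynthetically active radiation
(PAR, mol m⁻² d⁻¹), starting at a late-autumn sowing date (day of year
295 by default) so a full season fits in ~360 days.

- Temperature: sinusoidal annual course (mean 11 °C, amplitude 8 °C, peak
  at midsummer) plus AR(1) day-to-day noise (autocorrelation 0.7,
  innovation sd 0.8 °C).
- PAR: seasonal sinusoid between 5 and 55 mol m⁻² d⁻¹ with multiplicative
  lognormal noise (σ = 0.1), truncated at 0.

All defaults live in `ClimateConfig`; CSV round trips through
`ClimateSeries.to_frame()/from_frame()` with columns
`day, temp_c, par_mol_m2_d`.

## 2. Plant development and morphology

Development runs on thermal time *tt* (°Cd, base 0 °C, daily increments
`max(0, T_mean)`). Constants are collected in `DevConstants`:

| constant | default | meaning |
|---|---|---|
| phyllochron | 110 °Cd | thermal time between successive leaves |
| n_leaves | 11 | final main-stem leaf number |
| flowering_tt | 1650 °Cd | flowering (anthesis) |
| maturity_tt | 2350 °Cd | physiological maturity |
| elongation | 900–1500 °Cd | stem extension window |
| leaf_lifespan | 5 phyllochrons | lower-leaf senescence (top 3 persistent) |
| max_tiller_ranks | 6 | potential tillers per plant |
| emergence_probs | 0.95…0.10 | per-rank emission probability |

A genotype is five parameters: `h_ms` (final main-stem height, cm),
`phi_b` (blade erectness angle, deg; light-extinction coefficient
`k = sin(phi_b)`), `lmax_b` (maximal blade length, cm), `gai_c` and
`par_t` (tillering thresholds, §4).

Each axis (main stem or tiller) carries a vertical green-area profile on
2 cm layers. Blade *n* of *N* reaches final length
`lmax_b · (0.25 + 0.75 · n/N)`, grows over one phyllochron, and its area
is `0.74 · length · width` with `width = 0.08 ·` final length. Leaves
senesce after five phyllochrons (fading over one phyllochron), except the
top three which persist until the global senescence ramp between
flowering and maturity. Stems elongate on the *plant* clock between 900
and 1500 °Cd; a rank-*r* tiller reaches `h_ms · max(1 − 0.05·r, 0.5)`.
Green stem area is a cylinder (diameter 0.4 cm) distributed along the
current height. Ligule heights sit at fraction `n/N` of current height,
anchoring each blade's area in the profile.

## 3. Light partitioning

Light competition uses a multilayer turbid-medium model over the whole
periodic plot (no ray tracing). The diffuse sky is discretized into 16
directions (1 zenith + rings of 5 at 15°, 45° and 75°), each weighted by
the standard-overcast-sky radiance `(1 + 2 cos θ)/3` integrated over its
zenith band; a 46-direction discretization is also available. For each
direction, every layer has optical depth
`Σ_axes k_axis · area_axis / (ground_area · cos θ)`; flux decays by
Beer–Lambert from the top, and each layer's absorbed fraction is shared
among axes in proportion to their `k · area` contribution. Interception
plus transmission equals incidence exactly (telescoping sum); the test
suite enforces conservation to 1e-9 relative.

## 4. Tillering plasticity

Three rules, evaluated daily per plant:

1. **Emission** — tiller of rank *r* becomes eligible when the main stem
   has `r + 3` leaves; it emerges with probability `emergence_probs[r]`
   (one draw per rank per plant).
2. **Cessation** — emission stops permanently once the green area index
   within 0.15 m of the plant (minimum-image periodic distances, focal
   plant included) reaches `gai_c`.
3. **Regression** — an axis (never the main stem) dies when the 7-day
   running mean of its intercepted PAR per unit axis green area per
   degree-day falls below `par_t` (mol m⁻² °Cd⁻¹). A regressing axis
   fades linearly over 5 days.

**Unit note.** `par_t` thresholds are expressed per m² of axis green
area. With daily incident PAR of order tens of mol m⁻² and canopy-level
interception fractions, per-axis interception per unit area per °Cd lands
in the range ~0.05–1, so thresholds of 0.2–0.6 discriminate between
genotypes. Per cm² the same quantity would be ~10⁻⁴ and no threshold in
that numeric range could ever trigger.

## 5. Stand simulation and outputs

`simulate_stand(plot, climate, config, seed)` steps the plot one day at a
time: morphology update, light partitioning, GAI bookkeeping, tillering
rules. Default plots hold 110 plants at 200 plants m⁻² on a near-square
grid with spacing `1/√density` and periodic boundaries. Outputs at
maturity:

- `n_ears` — mean number of surviving axes per plant (each bears an ear);
  always ≥ 1 (main stems never regress).
- `l_perc` — mean daily fraction of incident light intercepted from day
  100 to maturity; in [0, 1].
- `f_tot` — total plot fitness: for each surviving axis the mean
  intercepted PAR over the 45 days up to flowering divided by the mean
  temperature over the same window (a photothermal quotient), summed over
  axes.

## 6. Mixtures and overyielding

A binary mixture is a `MixtureSpec` of five reference values and five
differentials; variety *i* is `ref ± diff/2`. Exploration ranges and
plant-scale bounds:

| parameter | ref range | diff range | plant bounds |
|---|---|---|---|
| H_MS (cm) | 65–135 | ±50 | 40–160 |
| phi_B (deg) | 30–50 | ±40 | 10–70 |
| LmaxB (cm) | 16–27 | ±16 | 8–35 |
| GAI_c | 0.4–0.7 | ±0.6 | 0.1–1.0 |
| PAR_t | 0.3–0.5 | ±0.2 | 0.2–0.6 |

Any ref/diff combination inside the exploration box splits within the
plant-scale bounds. `run_with_pures` simulates the 50/50 mixture and both
pure stands with the *same* plot geometry, climate and master seed; the
random substreams (plot placement, emergence delays, tiller draws) are
keyed by plant index only, so a zero-differential mixture reproduces its
pure references bit-for-bit and `OY = 1` exactly.

## 7. Analysis stack

- **Designs** — maximin Latin hypercubes by best-of-20 candidates
  (`scipy.stats.qmc.LatinHypercube`), seeded and prefix-stable.
- **Kriging** — `sklearn` Gaussian process: constant trend
  (`normalize_y`), anisotropic Matérn 5/2 kernel, optional white-noise
  nugget (estimated or fixed), inputs normalized to the unit cube.
  Models serialize to JSON and reload with frozen hyperparameters.
- **Sobol indices** — pick-freeze Saltelli sampling (A, B, AB_i) with
  Jansen estimators for first-order and total-order indices, replicated
  over independent sub-seeds to report a Monte-Carlo spread. Indices are
  always computed on a metamodel, never on the raw simulator. The
  overyielding predictor composes a 10-D mixture metamodel with a 5-D
  pure-stand metamodel evaluated at both split genotypes.
- **EGO** — Expected-Improvement enrichment: refit the metamodel each
  iteration, pick the EI argmax over a fresh seeded LHS pool, run the
  simulator there; failures are recorded and skipped.
- **Campaigns** — per-row seeds derived from the campaign seed and row
  index (`SeedSequence`-based, < 2³¹), so results are independent of
  worker count and execution order; failed rows are flagged, not fatal.

## 8. Limitations

- The light model is a layered turbid medium, not 3-D ray tracing: plants
  in the same layer shade each other only through the plot-level optical
  depth, so spatial detail within a layer is averaged out.
- At desk scale (24–110 plants, this light model) the simulated `n_ears`
  range is compressed (roughly 1–3.5 across the exploration box) relative
  to what finer-grained architectural models produce; directional
  responses (e.g. fewer ears and higher interception with larger blades)
  are reproduced and tested, absolute magnitudes are not calibrated.
- Total green area is *not* monotone in `lmax_b` day-by-day once
  tillering feedback operates: larger blades raise GAI sooner, stop
  tiller emission earlier, and the stand can transiently carry less area.
  Monotonicity holds (and is tested) with a fixed axis population.
- Morphology is deliberately simple: no leaf curvature, no azimuthal
  anisotropy, single-ear axes, no grain filling; `f_tot` is a
  light-capture proxy for fitness, not a yield model.
- The climate generator is a statistical sketch for experimentation, not
  a weather reconstruction.
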