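import numpy as np
import pytest

import canomix as cm
from canomix.canopy import Axis, DevConstants
from canomix.stand import Plant, Plot, StandSimulator, surrounding_gai


def plot_with_one_plant(area_cm2: float) -> Plot:
    g = cm.Genotype(h_ms=100, phi_b=40, lmax_b=20, gai_c=0.5, par_t=0.3)
    ax = Axis(rank=0, emergence_tt=0.0, green_area_by_layer=np.array([area_cm2]))
    plant = Plant(position=(0.5, 0.5), genotype_id=0, axes=[ax])
    return Plot(plants=[plant], genotypes=[g], density=1.0, domain=(1.0, 1.0))


class TestSurroundingGai:
    def test_bare_plot_is_zero(self):
        plot = plot_with_one_plant(0.0)
        assert surrounding_gai(plot, 0, radius=0.1) == 0.0

    def test_single_plant_arithmetic(self):
        plot = plot_with_one_plant(100.0)
        gai = surrounding_gai(plot, 0, radius=0.1)
        assert gai == pytest.approx(0.01 / (np.pi * 0.01), rel=1e-12)

    def test_periodic_edge_equals_interior(self):
        # uniform 4x4 grid: a corner plant must see the same neighborhood as
        # a central plant thanks to minimum-image wrapping
        g = cm.Genotype(h_ms=100, phi_b=40, lmax_b=20, gai_c=0.5, par_t=0.3)
        plants = []
        for r in range(4):
            for c in range(4):
                ax = Axis(
                    rank=0, emergence_tt=0.0, green_area_by_layer=np.array([50.0])
                )
                plants.append(
                    Plant(position=(0.125 + c * 0.25, 0.125 + r * 0.25),
                          genotype_id=0, axes=[ax])
                )
        plot = Plot(plants=plants, genotypes=[g], density=16.0, domain=(1.0, 1.0))
        corner = surrounding_gai(plot, 0, radius=0.3)
        center = surrounding_gai(plot, 5, radius=0.3)
        assert corner == pytest.approx(center, rel=1e-12)

    def test_oversized_radius_rejected(self):
        plot = plot_with_one_plant(10.0)
        with pytest.raises(ValueError):
            surrounding_gai(plot, 0, radius=5.0)


class TestTilleringRules:
    def test_saturated_emission_gives_exact_ear_count(self, climate):
        # certain emission, no cessation, no regression, 3 tiller ranks:
        # every plant keeps main stem + 3 tillers
        dev = DevConstants(max_tiller_ranks=3, emergence_probs=(1.0, 1.0, 1.0))
        g = cm.Genotype(h_ms=100, phi_b=40, lmax_b=22, gai_c=1e9, par_t=0.0, dev=dev)
        out = cm.simulate_stand(
            cm.build_pure_plot(g, 24, 200.0, 3), climate, seed=3
        )
        assert out.n_ears == 4.0

    def test_immediate_cessation_means_no_tillers(self, climate):
        # gai_c below any attainable surrounding GAI: emission ceases before
        # the first tiller becomes eligible
        g = cm.Genotype(h_ms=100, phi_b=40, lmax_b=22, gai_c=1e-6, par_t=0.0)
        out = cm.simulate_stand(
            cm.build_pure_plot(g, 24, 200.0, 3), climate, seed=3
        )
        assert out.n_ears == 1.0
        assert out.tillering_dynamics.max() == 1

    def test_zero_threshold_means_no_regression(self, climate):
        g = cm.Genotype(h_ms=100, phi_b=40, lmax_b=22, gai_c=0.7, par_t=0.0)
        out = cm.simulate_stand(
            cm.build_pure_plot(g, 24, 200.0, 3), climate, seed=3
        )
        # per-plant axis counts never decrease: nothing ever regresses
        assert np.all(np.diff(out.tillering_dynamics, axis=0) >= 0)

    def test_positive_threshold_causes_regression(self, climate):
        g = cm.Genotype(h_ms=100, phi_b=40, lmax_b=22, gai_c=0.7, par_t=0.6)
        out = cm.simulate_stand(
            cm.build_pure_plot(g, 24, 200.0, 3), climate, seed=3
        )
        assert out.tillering_dynamics.max() > out.tillering_dynamics[-1].max()


class TestSimulateStand:
    def test_deterministic_given_seed(self, climate, genotype):
        runs = [
            cm.simulate_stand(
                cm.build_pure_plot(genotype, 24, 200.0, 9), climate, seed=9
            )
            for _ in range(2)
        ]
        assert runs[0].n_ears == runs[1].n_ears
        assert runs[0].l_perc == runs[1].l_perc
        assert runs[0].f_tot == runs[1].f_tot

    def test_seed_changes_trajectory(self, climate, genotype):
        a = cm.simulate_stand(cm.build_pure_plot(genotype, 24, 200.0, 1), climate, seed=1)
        b = cm.simulate_stand(cm.build_pure_plot(genotype, 24, 200.0, 2), climate, seed=2)
        assert (a.n_ears, a.l_perc, a.f_tot) != (b.n_ears, b.l_perc, b.f_tot)

    def test_output_invariants(self, small_pure_outputs):
        out = small_pure_outputs
        assert out.n_ears >= 1.0
        assert 0.0 <= out.l_perc <= 1.0
        assert out.f_tot >= 0.0
        assert np.all(out.interception_dynamics >= 0.0)
        assert np.all(out.interception_dynamics <= 1.0)

    def test_dark_season_yields_zero_light_outputs(self, genotype):
        dark = cm.ClimateSeries(
            day_index=np.arange(360),
            temp_mean=np.full(360, 12.0),
            par_incident=np.zeros(360),
        )
        out = cm.simulate_stand(
            cm.build_pure_plot(genotype, 24, 200.0, 3), dark, seed=3
        )
        assert out.f_tot == 0.0
        assert out.l_perc == 0.0
        assert out.n_ears >= 1.0

    def test_short_climate_rejected_with_shortfall_message(self, genotype):
        short = cm.generate_climate(60, seed=1)
        with pytest.raises(ValueError, match="climate too short"):
            cm.simulate_stand(cm.build_pure_plot(genotype, 24, 200.0, 3), short, seed=3)

    def test_green_area_monotone_in_lmax_b_with_fixed_axes(self, climate):
        # with emission saturated and regression off the axis population is
        # identical, and larger blades can only add area — every day
        dev = DevConstants(max_tiller_ranks=3, emergence_probs=(1.0, 1.0, 1.0))

        def daily_total(lmax):
            g = cm.Genotype(
                h_ms=100, phi_b=40, lmax_b=lmax, gai_c=1e9, par_t=0.0, dev=dev
            )
            sim = StandSimulator(cm.build_pure_plot(g, 24, 200.0, 3), climate, seed=3)
            totals = []
            while sim.maturity_day < 0:
                sim.step_day()
                totals.append(sim._areas.sum())
            return np.array(totals)

        small, large = daily_total(16.0), daily_total(27.0)
        n = min(len(small), len(large))
        assert np.all(large[:n] >= small[:n])

    def test_directional_effects_of_leaf_size(self, climate):
        """Larger blades: more light intercepted, fewer surviving tillers."""
        results = {}
        for lmax in (16.0, 27.0):
            ne, lp = [], []
            for seed in (11, 12, 13):
                g = cm.Genotype(
                    h_ms=100, phi_b=40, lmax_b=lmax, gai_c=0.55, par_t=0.35
                )
                out = cm.simulate_stand(
                    cm.build_pure_plot(g, 24, 200.0, seed), climate, seed=seed
                )
                ne.append(out.n_ears)
                lp.append(out.l_perc)
            results[lmax] = (np.mean(ne), np.mean(lp))
        assert results[27.0][1] > results[16.0][1]  # higher interception
        assert results[27.0][0] <= results[16.0][0]  # fewer or equal ears
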