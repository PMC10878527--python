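"""Transport rates, half-lives, coupling equilibria, CHQ estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vegfr_trafficking import (
    PerturbationSpec,
    compute_fluxes,
    equilibrium_coupled,
    equilibrium_dimer_fraction,
    equilibrium_hetero_fraction,
    estimate_chq_inhibition,
    expand_reactions,
    recycling_degradation_ratio,
    reference_parameters,
    simulate,
    simulate_chq_series,
    steady_state,
    surface_residence_half_life,
    whole_cell_fold_change,
)
from vegfr_trafficking.parameters import Compartments
from vegfr_trafficking.receptors import species_index
from vegfr_trafficking.simulate import half_life_from_series


class TestHalfLife:
    def test_measured_vegfr1_internalization_rate_gives_53_seconds(self):
        assert surface_residence_half_life(1.3e-2) == pytest.approx(53.3, abs=0.05)

    def test_ln2_rate_gives_one_second(self):
        assert surface_residence_half_life(np.log(2.0)) == pytest.approx(1.0)

    @given(st.floats(min_value=1e-6, max_value=1e-1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_doubling_rate_halves_half_life(self, k):
        assert surface_residence_half_life(2 * k) == pytest.approx(
            surface_residence_half_life(k) / 2
        )

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            surface_residence_half_life(0.0)


class TestRatio:
    def test_rate_constant_ratio(self):
        params = reference_parameters(
            trafficking={"k_rec4_R1": 2e-3, "k_4to11_R1": 4.5e-4, "k_deg_R1": 5e-4}
        )
        assert recycling_degradation_ratio(params, "R1") == pytest.approx(4.9)

    def test_zero_recycling_gives_zero(self):
        params = reference_parameters(
            trafficking={"k_rec4_R2": 0.0, "k_4to11_R2": 0.0}
        )
        assert recycling_degradation_ratio(params, "R2") == 0.0

    def test_flux_weighted_matches_rate_ratio_at_steady_state(
        self, network, reference_params, reference_steady_state
    ):
        """Recycling and degradation both drain the same Rab4a pool, so for
        receptors whose complexes all share their own rate constants
        (VEGFR1, VEGFR2) the flux ratio equals the rate-constant ratio.
        NRP1's complexed fraction moves at VEGFR1 rates, so its flux ratio
        legitimately differs."""
        for rec in ("R1", "R2"):
            assert recycling_degradation_ratio(
                reference_params, rec, flux_weighted=True,
                network=network, state=reference_steady_state,
            ) == pytest.approx(recycling_degradation_ratio(reference_params, rec))
        n1_flux = recycling_degradation_ratio(
            reference_params, "N1", flux_weighted=True,
            network=network, state=reference_steady_state,
        )
        assert n1_flux != pytest.approx(
            recycling_degradation_ratio(reference_params, "N1"), rel=0.01
        )


class TestFluxes:
    def test_zero_state_has_only_production_flux(self, network, reference_params):
        ft = compute_fluxes(reference_params, network, np.zeros(32))
        for rec in ("R1", "R2", "N1"):
            assert ft.rate(rec, "production") == pytest.approx(
                reference_params[f"k_prod_{rec}"]
            )
            for p in ("internalization", "recycle4", "transfer4to11",
                      "recycle11", "degradation"):
                assert ft.rate(rec, p) == 0.0

    def test_net_compartment_rates_vanish_at_steady_state(
        self, network, reference_params, reference_steady_state
    ):
        ft = compute_fluxes(reference_params, network, reference_steady_state)
        prod = {r: ft.rate(r, "production") for r in ("R1", "R2", "N1")}
        for row in ft.net.itertuples():
            assert abs(row.net_rate_per_s) < 1e-6 * prod[row.receptor]

    def test_rab11_inflow_balances_recycle11_outflow(
        self, network, reference_params, reference_steady_state
    ):
        ft = compute_fluxes(reference_params, network, reference_steady_state)
        for rec in ("R1", "R2", "N1"):
            assert ft.rate(rec, "transfer4to11") == pytest.approx(
                ft.rate(rec, "recycle11"), rel=1e-6
            )

    def test_surface_balance_identity(
        self, network, reference_params, reference_steady_state
    ):
        """Internalization off the surface balances production plus both
        recycling inflows, per receptor."""
        ft = compute_fluxes(reference_params, network, reference_steady_state)
        for rec in ("R1", "R2", "N1"):
            inflow = (
                ft.rate(rec, "production")
                + ft.rate(rec, "recycle4")
                + ft.rate(rec, "recycle11")
            )
            assert ft.rate(rec, "internalization") == pytest.approx(
                inflow, rel=1e-6
            )

    def test_whole_cell_chx_half_life_exceeds_surface_residence(
        self, network, reference_params, reference_steady_state
    ):
        times = np.linspace(0.0, 16 * 3600.0, 200)
        fc = whole_cell_fold_change(
            reference_params, network, PerturbationSpec.chx(), times,
            initial=reference_steady_state,
        )
        for rec in ("R1", "R2"):
            t_cell = half_life_from_series(fc.time_s.to_numpy(), fc[rec].to_numpy())
            t_surf = surface_residence_half_life(reference_params[f"k_int_{rec}"])
            assert t_cell > t_surf


class TestEquilibria:
    def test_zero_coupling_gives_zero_dimer_fraction(self):
        assert equilibrium_dimer_fraction(1e4, 0.0, 0.01) == 0.0

    def test_saturation_limit(self):
        assert equilibrium_dimer_fraction(1e12, 1e-5, 0.01) > 0.999

    @given(
        st.floats(min_value=1e2, max_value=1e6),
        st.floats(min_value=1e-9, max_value=1e-4),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_dimer_fraction_satisfies_equilibrium_quadratic(self, r_t, kc):
        kd = 0.01
        frac = equilibrium_dimer_fraction(r_t, kc, kd)
        m = (1.0 - frac) * r_t
        d = frac * r_t / 2.0
        assert kc * m * m == pytest.approx(kd * d, rel=1e-9)

    def test_dimer_fraction_matches_trafficking_off_ode(self):
        """Simulation oracle: with trafficking off, the ODE relaxes to the
        closed-form dimer equilibrium to 1e-6 relative."""
        compartments = Compartments(surface_area=1000.0)
        net = expand_reactions(compartments)
        params = reference_parameters(
            trafficking={n: 0.0 for n in
                         [f"{p}_{r}" for r in ("R1", "R2", "N1")
                          for p in ("k_int", "k_rec4", "k_4to11",
                                    "k_rec11", "k_deg")]},
            coupling={"kc_R1N1": 0.0, "kc_R1R1": 1e-4, "kc_R2R2": 2e-4},
        )
        x0 = np.zeros(32)
        r_t = {"R1": 20000.0, "R2": 50000.0}
        for rec, v in r_t.items():
            x0[species_index(rec, "surface")] = v
        traj = simulate(params, net, x0, None, (0.0, 5e4), rtol=1e-11, atol=1e-9)
        final = traj.states[-1]
        for rec, dimer in (("R1", "R1R1"), ("R2", "R2R2")):
            kc_eff = params[f"kc_{dimer}"] / 1000.0
            expected = equilibrium_dimer_fraction(
                r_t[rec], kc_eff, params[f"kd_{dimer}"]
            )
            got = 2 * final[species_index(dimer, "surface")] / r_t[rec]
            assert got == pytest.approx(expected, rel=1e-6)

    def test_full_coupling_equilibrium_detailed_balance_vs_ode(self):
        """With trafficking off, the full VEGFR1/NRP1 coupling network must
        relax to the closed-form detailed-balance equilibrium."""
        compartments = Compartments(surface_area=1000.0)
        net = expand_reactions(compartments)
        traff_off = {
            f"{p}_{r}": 0.0
            for r in ("R1", "R2", "N1")
            for p in ("k_int", "k_rec4", "k_4to11", "k_rec11", "k_deg")
        }
        params = reference_parameters(trafficking=traff_off)
        x0 = np.zeros(32)
        x0[species_index("R1", "surface")] = 15000.0
        x0[species_index("N1", "surface")] = 60000.0
        traj = simulate(params, net, x0, None, (0.0, 1e5), rtol=1e-11, atol=1e-9)
        final = traj.states[-1]
        eq = equilibrium_coupled(
            15000.0, 60000.0,
            params["kc_R1R1"] / 1000.0, params["kd_R1R1"],
            params["kc_R1N1"] / 1000.0, params["kd_R1N1"],
        )
        for label in ("R1", "N1", "R1R1", "R1N1", "R1R1N1", "R1R1N1N1"):
            got = final[species_index(label, "surface")]
            assert got == pytest.approx(eq.species[label], rel=1e-5, abs=1e-6)

    def test_hetero_1to1_matches_quadratic(self):
        """S3-style 1:1 coupling: with K_d 12,500/cell, R_T 1800, N_T 68000
        the bound fraction follows the standard binding quadratic."""
        frac_r, frac_n = equilibrium_hetero_fraction(1800.0, 68000.0, 8e-7, 0.01)
        k_eq = 0.01 / 8e-7
        b = 1800 + 68000 + k_eq
        c = (b - np.sqrt(b * b - 4 * 1800 * 68000)) / 2
        assert frac_r == pytest.approx(c / 1800)
        assert frac_n == pytest.approx(c / 68000)


class TestChqEstimation:
    def test_flat_series_gives_zero_inhibition(
        self, network, reference_params
    ):
        times_h = (2.0, 4.0, 8.0)
        f = estimate_chq_inhibition(
            times_h, np.ones(3), reference_params, network
        )
        assert f == pytest.approx(0.0, abs=1e-3)

    def test_round_trip_recovery_of_42_percent(self, network, reference_params):
        times_h = (1.0, 2.0, 4.0, 8.0, 18.0)
        series = simulate_chq_series(reference_params, network, 0.42, times_h)
        f = estimate_chq_inhibition(times_h, series, reference_params, network)
        assert f == pytest.approx(0.42, abs=0.01)

    def test_full_inhibition_boundary_round_trip(self, network, reference_params):
        times_h = (1.0, 2.0, 4.0, 8.0, 18.0)
        series = simulate_chq_series(reference_params, network, 1.0, times_h)
        f = estimate_chq_inhibition(times_h, series, reference_params, network)
        assert f == pytest.approx(1.0, abs=0.01)

    def test_decaying_series_clips_to_zero_with_flag(
        self, network, reference_params
    ):
        times_h = (2.0, 4.0)
        f, info = estimate_chq_inhibition(
            times_h, [0.8, 0.6], reference_params, network, full_output=True
        )
        assert f == 0.0
        assert info["flagged_at_zero"]
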