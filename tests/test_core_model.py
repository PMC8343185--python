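"""Kinetic model: geometry, rate constants, ODE solver vs analytic oracles."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from gelwell import (
    AnnealingSchedule,
    GelParams,
    InterfaceModel,
    MotifSpec,
    PhysicalParams,
    closed_form_unbound,
    collision_rate,
    cooling_profile,
    diffusion_coefficient,
    final_gel_count,
    gel_radius,
    make_well_geometry,
    rate_constants,
    run_annealing,
    solve_kinetics,
    solve_to_steady_state,
    sweep_model,
)
from gelwell.units import AVOGADRO, molar_concentration, motif_count


class TestGeometry:
    @pytest.mark.parametrize(
        "diameter,depth,volume,area",
        [
            (50e-6, 100e-6, 1.9635e-13, 1.9635e-9),
            (100e-6, 100e-6, 7.854e-13, 7.854e-9),
        ],
    )
    def test_disc_interface_volume_and_area(self, diameter, depth, volume, area):
        geom = make_well_geometry(diameter, depth)
        assert geom.volume == pytest.approx(volume, rel=1e-4)
        assert geom.interface_area == pytest.approx(area, rel=1e-4)

    @pytest.mark.parametrize("bad", [{"diameter": 0}, {"depth": -1e-6}, {"interface_thickness": 0}])
    def test_nonpositive_dimension_rejected(self, bad):
        kwargs = {"diameter": 50e-6, "depth": 100e-6, "interface_thickness": 4e-8}
        kwargs.update(bad)
        with pytest.raises(ValueError):
            make_well_geometry(**kwargs)

    def test_spherical_cap_reduces_to_disc_at_small_angle(self):
        flat = make_well_geometry(100e-6, 100e-6)
        cap = make_well_geometry(
            100e-6, 100e-6, interface_model=InterfaceModel.SPHERICAL_CAP, contact_angle=1e-4
        )
        assert cap.interface_area == pytest.approx(flat.interface_area, rel=1e-6)

    def test_hemispherical_cap_doubles_the_mouth_area(self):
        cap = make_well_geometry(
            100e-6, 100e-6, interface_model="spherical_cap", contact_angle=math.pi / 2
        )
        assert cap.interface_area == pytest.approx(2 * math.pi * (50e-6) ** 2, rel=1e-12)


class TestRateConstants:
    def test_stokes_einstein_value(self, phys, motif):
        assert diffusion_coefficient(phys, motif) == pytest.approx(4.366e-12, rel=1e-3)

    def test_diffusion_scaling_in_viscosity_and_radius(self, phys, motif):
        d0 = diffusion_coefficient(phys, motif)
        assert diffusion_coefficient(PhysicalParams(viscosity=2e-2), motif) == pytest.approx(d0 / 2)
        assert diffusion_coefficient(phys, MotifSpec(hydrodynamic_radius=1e-8)) == pytest.approx(d0 / 2)

    def test_brownian_kernel_value_and_scalings(self, phys):
        assert collision_rate(phys) == pytest.approx(1.097e-18, rel=1e-3)
        assert collision_rate(PhysicalParams(temperature=596)) == pytest.approx(
            2 * collision_rate(phys)
        )
        a1 = collision_rate(PhysicalParams(viscosity=1e-2)) * 1e-2
        a2 = collision_rate(PhysicalParams(viscosity=5e-2)) * 5e-2
        assert a1 == pytest.approx(a2)

    def test_lumped_coefficients_for_50um_well(self, rates50):
        assert rates50.loss_rate_a == pytest.approx(1.091, rel=1e-3)
        assert rates50.coalescence_rate_b == pytest.approx(2.794e-6, rel=1e-3)

    def test_disc_interface_loss_rate_is_D_over_h_w(self, phys, motif):
        # cylindrical well + disc interface: A/V = 1/h exactly
        for depth in (50e-6, 100e-6, 200e-6):
            geom = make_well_geometry(80e-6, depth)
            rc = rate_constants(phys, motif, geom)
            expected = rc.diffusion_coefficient / (depth * geom.interface_thickness)
            assert rc.loss_rate_a == pytest.approx(expected, rel=1e-12)

    def test_thick_interface_kills_diffusive_loss(self, phys, motif):
        # a ~ 1/w, so the loss rate vanishes as the interface thickens
        a_ref = rate_constants(phys, motif, make_well_geometry(50e-6, 100e-6)).loss_rate_a
        a_thick = rate_constants(
            phys, motif, make_well_geometry(50e-6, 100e-6, interface_thickness=4e4)
        ).loss_rate_a
        assert a_thick == pytest.approx(a_ref * 1e-12, rel=1e-9)


class TestClosedFormOracle:
    """The analytic Riccati solution is verified by substitution into the ODE
    before it is trusted as the oracle for the numeric solver."""

    @pytest.mark.parametrize(
        "a,b,N0",
        [(1.091, 2.794e-6, 9.46e8), (0.01, 1e-9, 1e6), (5.0, 1e-3, 1e4), (0.0, 2.794e-6, 9.46e8), (2.0, 0.0, 1e8)],
    )
    def test_satisfies_the_ode_by_central_difference(self, a, b, N0):
        ts = np.linspace(0.05, 3.0, 25)
        h = 1e-6
        nu = closed_form_unbound(a, b, N0, ts)
        deriv = (closed_form_unbound(a, b, N0, ts + h) - closed_form_unbound(a, b, N0, ts - h)) / (2 * h)
        rhs = -a * nu - b * nu**2
        assert np.allclose(deriv, rhs, rtol=1e-5, atol=1e-5 * N0)

    def test_initial_condition(self):
        assert closed_form_unbound(1.0, 1e-6, 1e8, 0.0) == pytest.approx(1e8)

    def test_pure_diffusion_limit_is_exponential(self):
        t = np.linspace(0, 5, 11)
        assert np.allclose(closed_form_unbound(0.7, 0.0, 1e8, t), 1e8 * np.exp(-0.7 * t), rtol=1e-12)

    def test_pure_coalescence_half_decay(self):
        b, N0 = 3e-7, 1e7
        assert closed_form_unbound(0.0, b, N0, 1.0 / (b * N0)) == pytest.approx(N0 / 2)

    def test_no_dynamics_when_both_rates_vanish(self):
        assert closed_form_unbound(0.0, 0.0, 1e8, 100.0) == pytest.approx(1e8)

    def test_large_at_does_not_overflow(self):
        assert closed_form_unbound(10.0, 1e-6, 1e9, 1e4) == 0.0


class TestFinalGelCount:
    def test_agrees_with_quadrature_of_coalescence_flux(self):
        # brute-force oracle: N_g(inf) = int_0^inf b * N_u(t)^2 dt over the
        # verified closed-form trajectory
        rng = np.random.default_rng(42)
        for _ in range(10):
            a = 10.0 ** rng.uniform(-2, 1)
            b = 10.0 ** rng.uniform(-9, -4)
            N0 = 10.0 ** rng.uniform(4, 9)
            integral, _ = quad(
                lambda t: b * closed_form_unbound(a, b, N0, t) ** 2, 0, np.inf, limit=200
            )
            assert final_gel_count(a, b, N0) == pytest.approx(integral, rel=1e-6)

    def test_limits(self):
        assert final_gel_count(1e-12, 1e-6, 1e8) == pytest.approx(1e8, rel=1e-3)
        assert final_gel_count(10.0, 1e-15, 1e3) == pytest.approx(0.0, abs=1e-3)
        assert final_gel_count(1.0, 0.0, 1e8) == 0.0
        assert final_gel_count(0.0, 1e-6, 1e8) == 1e8

    def test_paper_geometry_gelled_fraction(self, rates50, n0_8uM_50):
        frac = final_gel_count(rates50.loss_rate_a, rates50.coalescence_rate_b, n0_8uM_50) / n0_8uM_50
        assert frac == pytest.approx(0.9968, abs=1e-3)


class TestSolveKinetics:
    def test_null_input_stays_at_zero(self, rates50):
        traj = solve_kinetics(rates50, 0.0, 10.0)
        assert np.all(traj.N_u == 0) and np.all(traj.N_g == 0) and np.all(traj.N_lost == 0)

    def test_gelled_fraction_matches_closed_form(self, rates50, n0_8uM_50):
        traj = solve_kinetics(rates50, n0_8uM_50, 10.0)
        assert traj.final_gelled / n0_8uM_50 == pytest.approx(0.9968, abs=1e-3)

    def test_oracle_equivalence_over_random_parameters(self):
        # >= 20 (a, b, N0) triples spanning six orders of magnitude
        rng = np.random.default_rng(7)
        for _ in range(25):
            a = 10.0 ** rng.uniform(-3, 3)
            b = 10.0 ** rng.uniform(-9, -3)
            N0 = 10.0 ** rng.uniform(3, 9)
            t_end = 5.0 / a
            t_eval = np.geomspace(t_end * 1e-3, t_end, 40)
            traj = solve_kinetics(
                _rates(a, b), N0, t_end, rel_tol=1e-12, abs_tol=1e-14 * N0, t_eval=t_eval
            )
            exact = closed_form_unbound(a, b, N0, traj.times)
            err = np.abs(traj.N_u - exact) / np.maximum(exact, 1e-300)
            assert err.max() <= 1e-6

    def test_conservation_and_monotonicity(self, rates50, n0_8uM_50):
        traj = solve_kinetics(rates50, n0_8uM_50, 20.0, rel_tol=1e-9)
        balance = traj.N_u + traj.N_g + traj.N_lost
        assert np.max(np.abs(balance - n0_8uM_50)) / n0_8uM_50 <= 1e-8
        assert np.all(np.diff(traj.N_g) >= -1e-6 * n0_8uM_50)
        assert np.all(np.diff(traj.N_lost) >= -1e-6 * n0_8uM_50)

    def test_pure_loss_limit_is_exponential(self):
        traj = solve_kinetics(_rates(0.5, 0.0), 1e8, 10.0, t_eval=np.linspace(0.1, 10, 30))
        assert np.allclose(traj.N_u, 1e8 * np.exp(-0.5 * traj.times), rtol=1e-6)

    def test_pure_coalescence_limit_is_hyperbolic(self):
        b, N0 = 1e-7, 1e8
        traj = solve_kinetics(_rates(0.0, b), N0, 10.0, t_eval=np.linspace(0.1, 10, 30))
        assert np.allclose(traj.N_u, N0 / (1 + b * N0 * traj.times), rtol=1e-6)

    def test_steady_state_matches_final_gel_count(self, rates50, n0_8uM_50):
        traj = solve_to_steady_state(rates50, n0_8uM_50)
        exact = final_gel_count(rates50.loss_rate_a, rates50.coalescence_rate_b, n0_8uM_50)
        assert traj.final_gelled == pytest.approx(exact, rel=1e-4)

    def test_invalid_arguments(self, rates50):
        with pytest.raises(ValueError):
            solve_kinetics(rates50, -1.0, 1.0)
        with pytest.raises(ValueError):
            solve_kinetics(rates50, 1.0, 0.0)


def _rates(a, b):
    from gelwell import RateConstants

    return RateConstants(diffusion_coefficient=0.0, collision_rate=0.0, loss_rate_a=a, coalescence_rate_b=b)


class TestGelRadius:
    def test_zero_count_zero_radius(self, gel):
        assert gel_radius(0.0, gel) == 0.0

    def test_paper_parameter_point(self, gel):
        # all motifs from 8 uM in a 50-um well, rho_g = 14 uM, lambda = 5
        assert gel_radius(9.459e8, gel) * 1e6 == pytest.approx(5.99, abs=0.02)

    def test_cube_root_law(self, gel):
        assert gel_radius(8e8, gel) == pytest.approx(2 * gel_radius(1e8, gel), rel=1e-12)

    def test_unit_roundtrip_via_moles(self, gel):
        # brute-force unit check: compute gel volume in moles/liters instead of counts
        n_g = 5e8
        moles = n_g / AVOGADRO
        volume_L = moles / gel.gel_motif_concentration
        r_uncompacted = (3 * volume_L * 1e-3 / (4 * math.pi)) ** (1 / 3)
        assert gel_radius(n_g, gel) == pytest.approx(r_uncompacted / gel.compaction_factor, rel=1e-12)

    def test_concentration_count_conversion_inverts(self, well50):
        n = motif_count(8e-6, well50.volume)
        assert molar_concentration(n, well50.volume) == pytest.approx(8e-6, rel=1e-12)


class TestAnnealing:
    def test_single_round_equals_plain_solve(self, rates50, n0_8uM_50):
        one = run_annealing(rates50, n0_8uM_50, AnnealingSchedule(n_rounds=1))
        plain = solve_to_steady_state(rates50, n0_8uM_50)
        assert one.final_gelled == pytest.approx(plain.final_gelled, rel=1e-9)

    def test_lossless_rounds_conserve_everything(self, n0_8uM_50):
        rates = _rates(0.0, 1e-7)
        traj = run_annealing(rates, n0_8uM_50, AnnealingSchedule(n_rounds=3, round_duration=100.0))
        # a = 0: nothing ever leaves, so after long rounds nearly all motifs gel
        assert traj.N_u[-1] + traj.final_gelled == pytest.approx(n0_8uM_50, rel=1e-6)
        assert np.all(traj.N_lost == 0)

    def test_extra_rounds_shrink_the_final_aggregate(self, rates50, n0_8uM_50):
        g1 = run_annealing(rates50, n0_8uM_50, AnnealingSchedule(n_rounds=1)).final_gelled
        g2 = run_annealing(rates50, n0_8uM_50, AnnealingSchedule(n_rounds=2)).final_gelled
        g3 = run_annealing(rates50, n0_8uM_50, AnnealingSchedule(n_rounds=3)).final_gelled
        assert g3 < g2 < g1

    def test_times_are_monotone_across_rounds(self, rates50, n0_8uM_50):
        traj = run_annealing(rates50, n0_8uM_50, AnnealingSchedule(n_rounds=2))
        assert np.all(np.diff(traj.times) >= 0)

    def test_invalid_schedule(self):
        with pytest.raises(ValueError):
            AnnealingSchedule(n_rounds=0)


class TestSweep:
    def test_grid_cardinality_and_columns(self, phys, motif, gel, well50, well100):
        table = sweep_model([1e-6, 4e-6, 8e-6], [well50, well100], phys, motif, gel)
        assert len(table) == 6
        assert list(table.columns) == [
            "concentration_M", "well_diameter_m", "a_per_s", "b_per_s_count", "N0", "Ng_final", "r_g_m",
        ]

    def test_radius_monotone_in_concentration_and_volume(self, phys, motif, gel, well50, well100):
        table = sweep_model([1e-6, 2e-6, 4e-6, 8e-6], [well50, well100], phys, motif, gel)
        for _, grp in table.groupby("well_diameter_m"):
            r = grp.sort_values("concentration_M")["r_g_m"].to_numpy()
            assert np.all(np.diff(r) > 0)
        for _, grp in table.groupby("concentration_M"):
            r = grp.sort_values("well_diameter_m")["r_g_m"].to_numpy()
            assert np.all(np.diff(r) > 0)

    def test_cube_root_concentration_scaling_when_loss_negligible(self, motif, gel):
        # shrink the loss term so essentially every motif gels
        geom = make_well_geometry(50e-6, 100e-6, interface_thickness=1.0)
        table = sweep_model(list(np.geomspace(1e-6, 1e-5, 6)), [geom], PhysicalParams(), motif, gel)
        r = table["r_g_m"].to_numpy()
        c = table["concentration_M"].to_numpy()
        predicted = r[0] * (c / c[0]) ** (1 / 3)
        assert np.allclose(r, predicted, rtol=1e-2)

    def test_8uM_50um_row_reproduces_the_reference_radius(self, phys, motif, gel, well50):
        table = sweep_model([8e-6], [well50], phys, motif, gel)
        assert table.loc[0, "r_g_m"] * 1e6 == pytest.approx(5.98, abs=0.02)

    def test_empty_input_rejected(self, phys, motif, gel, well50):
        with pytest.raises(ValueError):
            sweep_model([], [well50], phys, motif, gel)


class TestCoolingProfile:
    def test_endpoints_and_time_constant(self):
        sched = AnnealingSchedule(hot_temperature=348.15, ambient_temperature=298.0, cooling_time_constant=30.0)
        assert cooling_profile(sched, 0.0) == pytest.approx(348.15)
        assert cooling_profile(sched, 1e6) == pytest.approx(298.0)
        assert cooling_profile(sched, 30.0) == pytest.approx(298.0 + (348.15 - 298.0) / math.e)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            cooling_profile(AnnealingSchedule(), -1.0)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            AnnealingSchedule(cooling_time_constant=0.0)
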