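"""Single-grain flow and reactive-transport solver."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import solve_bvp

import sanddbl
from sanddbl import transport as tr


@pytest.fixture(scope="module")
def default_config():
    return sanddbl.GrainModelConfig(inflow_velocity_um_s=100.0, inflow_o2_umol_L=50.0)


class TestGrid:
    def test_rim_aligned_with_radial_faces(self, default_config):
        grid = tr.build_grid(default_config)
        a = default_config.grain_radius_m
        rim_edge = a + default_config.rim_thickness_um * 1e-6
        assert grid.r_faces[0] == pytest.approx(a)
        assert grid.r_faces[grid.rim_cells] == pytest.approx(rim_edge, rel=1e-12)
        assert grid.r_faces[-1] == pytest.approx(default_config.outer_radius_m)

    def test_rim_resolution_enforced(self):
        with pytest.raises(ValueError):
            sanddbl.GrainModelConfig(rim_cells=1)


class TestFlow:
    def test_stagnant_water_is_at_rest(self):
        cfg = sanddbl.GrainModelConfig(inflow_velocity_um_s=0.0)
        flow = sanddbl.solve_flow(cfg)
        grid = tr.build_grid(cfg)
        u_r, u_t = flow.velocity(grid.r_centers[:, None], grid.theta_centers[None, :])
        assert np.max(np.abs(u_r)) == 0.0
        assert np.max(np.abs(u_t)) == 0.0

    def test_no_slip_on_grain_surface(self, default_config):
        flow = sanddbl.solve_flow(default_config)
        theta = np.linspace(0, 2 * np.pi, 64)
        u_r, u_t = flow.velocity(np.full_like(theta, flow.a), theta)
        assert np.max(np.abs(u_r)) < 1e-18
        assert np.max(np.abs(u_t)) < 1e-18

    def test_small_grain_limit_approaches_uniform_stream(self):
        cfg = sanddbl.GrainModelConfig(
            grain_radius_um=10.0, rim_thickness_um=2.0,
            consumer_arc_um=2.0, producer_arc_um=1.0,
            inflow_velocity_um_s=100.0, outer_radius_factor=64.0,
        )
        flow = sanddbl.solve_flow(cfg)
        r = 0.95 * cfg.outer_radius_m
        u_r, u_t = flow.velocity(np.array([r, r]), np.array([0.0, np.pi / 2]))
        assert u_r[0] == pytest.approx(flow.U, rel=0.05)      # along-stream
        assert -u_t[1] == pytest.approx(flow.U, rel=0.05)     # cross-stream

    def test_inflow_flux_balances_outflow(self, default_config):
        flow = sanddbl.solve_flow(default_config)
        grid = tr.build_grid(default_config)
        Fr, _ = tr._face_fluxes(flow, grid)
        outer = Fr[-1, :]
        inflow = -outer[outer < 0].sum()
        outflow = outer[outer > 0].sum()
        assert abs(inflow - outflow) / inflow < 1e-3

    def test_discrete_divergence_free(self, default_config):
        flow = sanddbl.solve_flow(default_config)
        grid = tr.build_grid(default_config)
        assert tr.divergence_norm(flow, grid) < 1e-12


class TestReactionField:
    def test_extrema_at_arc_centres(self, default_config):
        cfg = default_config
        r_mid = cfg.grain_radius_m + 2.5e-6
        rc_consumer = tr.surface_reaction_field(cfg, r_mid, np.pi)
        rc_producer = tr.surface_reaction_field(cfg, r_mid, 1.25 * np.pi)
        assert rc_consumer == pytest.approx(-955.0 / 3.6e3, rel=1e-9)
        assert rc_producer == pytest.approx(514.0 / 3.6e3, rel=1e-9)

    def test_arc_lengths_from_sign_integral(self, default_config):
        cfg = default_config
        theta = np.linspace(0, 2 * np.pi, 200_000, endpoint=False)
        rc = tr.surface_reaction_field(cfg, cfg.grain_radius_m + 2.5e-6, theta)
        perim_um = 2 * np.pi * cfg.grain_radius_um
        consumer_um = np.mean(rc < 0) * perim_um
        producer_um = np.mean(rc > 0) * perim_um
        assert consumer_um == pytest.approx(4 * 76.0, rel=0.01)
        assert producer_um == pytest.approx(4 * 38.0, rel=0.01)

    def test_zero_outside_rim(self, default_config):
        cfg = default_config
        assert tr.surface_reaction_field(cfg, cfg.grain_radius_m + 1e-5, np.pi) == 0.0


class TestSolutes:
    def test_no_reaction_gives_uniform_o2_and_no_n2(self):
        cfg = sanddbl.GrainModelConfig(
            r_c_min_mmol_L_h=0.0, r_c_max_mmol_L_h=0.0,
            inflow_velocity_um_s=100.0, inflow_o2_umol_L=50.0,
        )
        sol = sanddbl.solve_solutes(cfg)
        np.testing.assert_allclose(sol.c_o2_umol_L, 50.0, rtol=1e-9)
        np.testing.assert_allclose(sol.c_n2, 0.0, atol=1e-15)

    def test_zero_inflow_o2_full_strength_n2_source(self):
        cfg = sanddbl.GrainModelConfig(
            inflow_velocity_um_s=50.0, inflow_o2_umol_L=0.0, production_on=False,
        )
        sol = sanddbl.solve_solutes(cfg)
        assert np.max(sol.c_o2) < 1e-12
        # f_N(0) = 1: the N2 source equals 1/10 of the potential consumption
        sink = np.maximum(-sol.reaction_o2, 0.0)
        mask = sink > 0
        np.testing.assert_allclose(sol.source_n2[mask], 0.1 * sink[mask], rtol=1e-9)

    def test_steady_state_flux_balance(self, default_config, anoxic_solution):
        sol = sanddbl.solve_solutes(default_config)
        assert tr.mass_balance_error(default_config, sol, "o2") < 0.01
        assert tr.mass_balance_error(default_config, sol, "n2") < 0.01
        cfg2, sol2, _ = anoxic_solution
        assert tr.mass_balance_error(cfg2, sol2, "o2") < 0.01

    def test_concentrations_non_negative(self, anoxic_solution):
        _, sol, _ = anoxic_solution
        assert sol.c_o2.min() >= 0.0
        assert sol.c_n2.min() >= 0.0

    def test_stagnant_uniform_rim_matches_1d_diffusion_oracle(self):
        """U = 0 with an axisymmetric rim sink reduces to radial
        diffusion-consumption, solvable independently as a two-point BVP."""
        cfg = sanddbl.GrainModelConfig(
            inflow_velocity_um_s=0.0, inflow_o2_umol_L=100.0,
            uniform_consumption_mmol_L_h=-50.0, n_radial=128,
        )
        sol = sanddbl.solve_solutes(cfg)
        profile = sol.c_o2.mean(axis=1)  # axisymmetric: theta-average

        # nondimensional rim BVP, c'' + c'/x = phi c/(kappa + c), closed by the
        # analytic Laplace solution of the reaction-free outer annulus
        # (Robin condition at the rim edge; C0 scaled to 1)
        a, b = cfg.grain_radius_m, cfg.outer_radius_m
        c0 = cfg.inflow_o2_umol_L * 1e-3
        x_i = 1.0 + cfg.rim_thickness_um * 1e-6 / a
        beta = b / a
        kappa = cfg.k_m_umol_L * 1e-3 / c0
        phi = (50.0 / 3.6e3) * a**2 / (cfg.d_o2_m2_s * c0)

        def ode(x, y):
            c, dc = y
            return np.vstack([dc, phi * c / (kappa + c) - dc / x])

        def bc(ya, yb):
            robin = yb[1] - (1.0 - yb[0]) / (x_i * np.log(beta / x_i))
            return np.array([ya[1], robin])

        x_mesh = np.linspace(1.0, x_i, 50)
        y0 = np.vstack([np.ones_like(x_mesh), np.zeros_like(x_mesh)])
        res = solve_bvp(ode, bc, x_mesh, y0, tol=1e-8, max_nodes=10000)
        assert res.success

        xc = sol.grid.r_centers / a
        rim = xc <= x_i
        oracle = np.empty_like(xc)
        oracle[rim] = res.sol(xc[rim])[0]
        c_i = res.sol(x_i)[0].item()
        oracle[~rim] = c_i + (1.0 - c_i) * np.log(xc[~rim] / x_i) / np.log(beta / x_i)
        np.testing.assert_allclose(profile, oracle * c0, rtol=0.05)


class TestSummaryAndEnsemble:
    def test_consumption_disabled_means_no_anoxia_no_n2(self):
        cfg = sanddbl.GrainModelConfig(
            r_c_min_mmol_L_h=0.0, inflow_velocity_um_s=100.0, inflow_o2_umol_L=50.0
        )
        summ = sanddbl.summarize(cfg, sanddbl.solve_solutes(cfg))
        assert summ.anoxic_rim_volume_fraction == 0.0
        assert summ.n2_per_grain_nmol_d == 0.0

    def test_per_grain_n2_sums_over_colonies(self, anoxic_solution):
        _, _, summ = anoxic_solution
        assert summ.n2_per_grain_nmol_d == pytest.approx(
            summ.n2_per_colony_nmol_d.sum()
        )
        assert summ.anoxic_colony_count == 4

    def test_oxic_regime_has_no_anoxic_colonies(self):
        cfg = sanddbl.GrainModelConfig(
            inflow_velocity_um_s=500.0, inflow_o2_umol_L=100.0
        )
        summ = sanddbl.summarize(cfg, sanddbl.solve_solutes(cfg))
        assert summ.anoxic_rim_volume_fraction < 0.05
        assert summ.anoxic_colony_count == 0

    def test_empty_grid_gives_empty_table(self):
        df = sanddbl.run_ensemble(sanddbl.GrainModelConfig(), [], [])
        assert len(df) == 0

    def test_anoxic_fraction_monotone_in_o2_and_velocity(self, default_ensemble):
        df = default_ensemble
        for u, grp in df.groupby("u_um_s"):
            fr = grp.sort_values("c0_umol_L").anoxic_fraction.to_numpy()
            assert np.all(np.diff(fr) <= 1e-9)
        # in U: away from the degenerate case C0 == anoxia threshold
        for c0, grp in df[df.c0_umol_L > 1.0].groupby("c0_umol_L"):
            fr = grp.sort_values("u_um_s").anoxic_fraction.to_numpy()
            assert np.all(np.diff(fr) <= 0.01)

    def test_photosynthesis_has_minor_effect_on_anoxia(self, default_ensemble):
        cfg = sanddbl.GrainModelConfig()
        deltas = []
        for u, c0 in [(0.0, 50.0), (100.0, 50.0), (100.0, 10.0)]:
            on = sanddbl.run_ensemble(cfg, [u], [c0], production_on=True)
            off = sanddbl.run_ensemble(cfg, [u], [c0], production_on=False)
            deltas.append(abs(on.anoxic_fraction[0] - off.anoxic_fraction[0]))
        # largest near the anoxia transition, small elsewhere
        assert max(deltas) < 0.2
        assert np.mean(deltas) < 0.15

    def test_grid_refinement_stable_within_five_percent(self):
        cfg = sanddbl.GrainModelConfig(inflow_velocity_um_s=100.0,
                                       inflow_o2_umol_L=10.0)
        coarse = sanddbl.summarize(cfg, sanddbl.solve_solutes(cfg))
        fine_cfg = dataclasses.replace(cfg, n_theta=384, n_radial=192, rim_cells=8)
        fine = sanddbl.summarize(fine_cfg, sanddbl.solve_solutes(fine_cfg))
        assert fine.anoxic_rim_volume_fraction == pytest.approx(
            coarse.anoxic_rim_volume_fraction, rel=0.05
        )
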