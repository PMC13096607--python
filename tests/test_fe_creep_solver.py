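"""FE creep solver: mesh construction, verification against the linear
biphasic closed form, conservation and convergence properties."""

import numpy as np
import pytest

import cartifls as cf
from cartifls.fe_creep_solver import (
    Geometry,
    LoadingProtocol,
    SolverError,
    SolverOptions,
    build_mesh,
    run_creep,
)

HEALTHY_GEO = Geometry(radius=3.5, thickness=1.7, n_r=15, n_z=10)


class TestMesh:
    def test_default_mesh_has_2400_elements(self):
        mesh = build_mesh(Geometry())
        assert mesh.n_elements == 2400
        assert mesh.n_nodes == 61 * 41

    def test_single_element(self):
        mesh = build_mesh(Geometry(n_r=1, n_z=1))
        assert mesh.n_elements == 1
        assert mesh.n_nodes == 4

    def test_boundary_tags(self):
        g = Geometry(radius=2.0, thickness=1.0, n_r=3, n_z=2)
        mesh = build_mesh(g)
        assert len(mesh.axis_nodes) == 3
        assert len(mesh.outer_nodes) == 3
        assert len(mesh.bottom_nodes) == 4
        assert len(mesh.top_nodes) == 4
        assert np.allclose(mesh.coords[mesh.axis_nodes, 0], 0.0)
        assert np.allclose(mesh.coords[mesh.outer_nodes, 0], 2.0e-3)
        assert np.allclose(mesh.coords[mesh.top_nodes, 1], 1.0e-3)
        # element corners span the full domain
        assert mesh.coords[:, 0].max() == pytest.approx(2.0e-3)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            Geometry(radius=-1.0)
        with pytest.raises(ValueError):
            Geometry(n_r=0)


class TestOracleLimit:
    def test_matches_linear_biphasic_series(self, oracle_pair):
        """No fibrils, constant permeability, small strain: the FE creep
        curve must track the closed-form Bessel series within 2% from
        10 s to equilibrium."""
        sol, oracle = oracle_pair
        mask = sol.times >= 10.0
        eps_fe = sol.axial_strain[mask]
        eps_series = cf.biphasic_unconfined_creep(oracle, sol.times[mask])
        assert np.max(np.abs(eps_fe / eps_series - 1.0)) < 0.02

    def test_equilibrium_strain_is_drained_uniaxial(self, oracle_pair):
        sol, oracle = oracle_pair
        assert sol.axial_strain[-1] == pytest.approx(
            oracle.eps_equilibrium, rel=0.01)


class TestCreepSolution:
    def test_displacement_nondecreasing_during_hold(self, healthy_solution):
        sol = healthy_solution
        hold = sol.times > sol.protocol.ramp_duration
        assert np.all(np.diff(sol.axial_displacement[hold]) >= -1e-9)

    def test_ifls_bounded_and_nonincreasing_after_ramp(self,
                                                       healthy_solution):
        sol = healthy_solution
        assert np.all(sol.ifls >= -1e-12)
        assert np.all(sol.ifls <= 1.02)
        hold = sol.times > sol.protocol.ramp_duration
        assert np.all(np.diff(sol.ifls[hold]) <= 1e-3)

    def test_ifls_decays_to_drained_equilibrium(self, healthy_solution):
        assert healthy_solution.ifls[-1] < 0.02

    def test_ifls_high_shortly_after_ramp(self, healthy_solution):
        sol = healthy_solution
        i = np.searchsorted(sol.times, sol.protocol.ramp_duration * 1.2)
        assert sol.ifls[i] >= 0.7

    def test_load_balance_during_hold(self, healthy_solution):
        sol = healthy_solution
        applied = (sol.protocol.applied_stress * 1e6
                   * np.pi * (sol.geometry.radius * 1e-3) ** 2)
        hold = sol.times > sol.protocol.ramp_duration
        assert np.max(np.abs(sol.reaction_force[hold] / applied - 1.0)) \
            < 0.005

    def test_dataframe_export(self, healthy_solution):
        df = healthy_solution.to_dataframe()
        assert list(df.columns) == ["time_s", "displacement_mm", "strain",
                                    "por_MPa", "ifls", "reaction_N"]
        assert len(df) == len(healthy_solution.times)

    def test_interpolation_outside_span_rejected(self, healthy_solution):
        with pytest.raises(ValueError):
            healthy_solution.strain_at(healthy_solution.times[-1] * 2.0)

    def test_output_times_resampling(self, healthy_params):
        ot = np.array([1.0, 10.0, 100.0, 500.0])
        proto = LoadingProtocol(hold_duration=600.0, output_times=ot)
        sol = run_creep(healthy_params, HEALTHY_GEO, proto)
        assert np.array_equal(sol.times, ot)
        assert sol.pore_pressure_field.shape == (4, build_mesh(
            HEALTHY_GEO).n_nodes)


class TestConservationAndConvergence:
    def test_fluid_mass_conservation_small_strain(self):
        """Volume change per step equals the Darcy outflow through the
        free-draining edge (post-processed from the pressure gradient)
        once the pressure boundary layer spans several elements."""
        p = cf.MaterialParams(E_nf=0.5, E_f0=0.0, E_feps=0.0, k0=1e-14,
                              M=0.0, nu=0.1)
        geo = Geometry(radius=3.5, thickness=1.75, n_r=30, n_z=6)
        proto = LoadingProtocol(applied_stress=0.005, ramp_duration=0.05,
                                hold_duration=10_000.0)
        sol = run_creep(p, geo, proto,
                        SolverOptions(frictionless_base=True,
                                      small_strain=True, max_dt=1e9))
        d = sol.diagnostics
        dV = np.diff(np.concatenate([[0.0], d["volume_change"]]))
        outflow = d["edge_outflow"] * d["step_dt"]
        t = sol.times[1:]
        mask = t > 100.0   # boundary layer resolved (t >> h^2 / c)
        rel = np.abs(-dV[mask] - outflow[mask]) / np.abs(dV[mask])
        assert rel.max() < 0.01

    def test_mesh_refinement_converges(self, healthy_params):
        proto = LoadingProtocol(hold_duration=5000.0)
        e = {}
        for n_r, n_z in [(15, 10), (30, 20)]:
            geo = Geometry(radius=3.5, thickness=1.7, n_r=n_r, n_z=n_z)
            e[n_r] = run_creep(healthy_params, geo, proto).axial_strain[-1]
        assert abs(e[15] / e[30] - 1.0) < 0.01

    def test_time_step_refinement(self, healthy_params):
        proto = LoadingProtocol(hold_duration=2000.0)
        base = run_creep(healthy_params, HEALTHY_GEO, proto,
                         SolverOptions(dt0=0.0025,
                                       dt_growth=np.sqrt(1.15)))
        half = run_creep(healthy_params, HEALTHY_GEO, proto,
                         SolverOptions(dt0=0.00125,
                                       dt_growth=np.sqrt(np.sqrt(1.15))))
        tt = np.geomspace(0.1, 2000.0, 120)
        rel = np.abs(base.displacement_at(tt) / half.displacement_at(tt)
                     - 1.0)
        assert rel.max() < 0.005

    def test_aspect_ratio_permutation(self, healthy_params):
        proto = LoadingProtocol(hold_duration=2000.0)
        a = run_creep(healthy_params,
                      Geometry(radius=3.5, thickness=1.7, n_r=15, n_z=10),
                      proto)
        b = run_creep(healthy_params,
                      Geometry(radius=3.5, thickness=1.7, n_r=10, n_z=15),
                      proto)
        assert abs(a.axial_strain[-1] / b.axial_strain[-1] - 1.0) < 0.005

    def test_stabilization_halving_negligible(self, healthy_params):
        proto = LoadingProtocol(hold_duration=1000.0)
        a = run_creep(healthy_params, HEALTHY_GEO, proto,
                      SolverOptions(stab_alpha=1.0))
        b = run_creep(healthy_params, HEALTHY_GEO, proto,
                      SolverOptions(stab_alpha=0.5))
        tt = np.geomspace(1.0, 1000.0, 60)
        da = np.interp(tt, a.times, a.ifls)
        db = np.interp(tt, b.times, b.ifls)
        assert np.max(np.abs(da - db)) < 0.005


class TestFailureModes:
    def test_step_budget_exhaustion_raises(self, healthy_params):
        with pytest.raises(SolverError):
            run_creep(healthy_params, HEALTHY_GEO,
                      LoadingProtocol(hold_duration=5000.0),
                      SolverOptions(max_steps=5))

    def test_crushing_load_fails_with_diagnostic(self):
        soft = cf.MaterialParams(E_nf=0.02, E_f0=0.0, E_feps=0.0,
                                 k0=1e-14, M=0.0)
        proto = LoadingProtocol(applied_stress=5.0, hold_duration=100.0)
        with pytest.raises(SolverError):
            run_creep(soft, Geometry(n_r=6, n_z=4), proto,
                      SolverOptions(max_step_halvings=4,
                                    newton_max_iter=12, max_steps=60))
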