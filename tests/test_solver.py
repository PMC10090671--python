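"""Wire-network mechanics, contact law and dynamic relaxation."""

import numpy as np
import pytest

from braidsim.kinematics import CrimpSpec, crimp_displacements, rotation_matrix
from braidsim.solver import (
    SolverSettings,
    assemble_model,
    build_wire_model,
    compute_forces,
    contact_nodal_force,
    relax_to_equilibrium,
    run_deployment,
    strain_energy,
)
from braidsim.dataset import crimped_segment_length
from braidsim.stent import StentParameters, build_stent_mesh
from braidsim.vessel import SignedDistanceGrid, VesselParameters, vessel_sdf


def flat_wall_grid(extent=1.0, spacing=0.1):
    """SDF of the half-space z > 0 (value = z, positive inside)."""
    ax = np.arange(-extent, extent + 1e-9, spacing)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    return SignedDistanceGrid(
        origin=np.array([-extent] * 3), spacing=spacing, values=Z.copy()
    )


def single_node_model(k_node=10.0, R_w=0.1):
    from braidsim.solver import StructuralModel

    return StructuralModel(
        x0=np.array([[0.0, 0.0, 0.05]]),
        beams=np.empty((0, 2), np.int64), k_axial=np.empty(0), L0=np.empty(0),
        triples=np.empty((0, 3), np.int64), k_bend=np.empty(0),
        theta0=np.empty(0),
        scissors=np.empty((0, 2), np.int64), k_scissor=np.empty(0),
        d0_scissor=np.empty(0),
        pairs=np.empty((0, 2), np.int64), k_pair=0.0,
        node_stiffness=np.array([k_node]), R_w=R_w, EA=1.0, EI=1.0,
    )


class TestAssembleModel:
    def test_reference_configuration_stress_free(self):
        mesh = build_stent_mesh(StentParameters(N_w=8, N_cells=4))
        model = assemble_model(mesh)
        F = compute_forces(model, mesh.nodes)
        assert np.abs(F).max() < 1e-10

    def test_axial_element_response(self):
        EA = 138.0
        pts = np.array([[0, 0, 0], [0, 0, 2.0]])
        model = build_wire_model(pts, EA=EA, EI=1.0)
        eps = 1e-6
        x = pts.copy()
        x[1, 2] += 2.0 * eps  # uniform strain eps
        F = compute_forces(model, x)
        assert np.isclose(F[1, 2], -EA * eps, rtol=1e-6)

    def test_rigid_rotation_objectivity(self):
        mesh = build_stent_mesh(StentParameters(N_w=8, N_cells=4))
        model = assemble_model(mesh)
        R = rotation_matrix(np.array([1.0, 2.0, 3.0]) / np.sqrt(14), 0.7)
        x = mesh.nodes @ R.T + np.array([1.0, -2.0, 0.5])
        F = compute_forces(model, x)
        assert np.abs(F).max() < 1e-8

    def test_rigid_translation_zero_force(self):
        mesh = build_stent_mesh(StentParameters(N_w=6, N_cells=3))
        model = assemble_model(mesh)
        F = compute_forces(model, mesh.nodes + np.array([0.3, -0.7, 1.1]))
        assert np.abs(F).max() < 1e-10

    def test_cantilever_tip_deflection(self):
        # 10 collinear elements, clamped start, small tip load:
        # Euler-Bernoulli closed form P L^3 / (3 EI) within 5%
        EA, EI, L0, n = 1000.0, 10.0, 1.0, 10
        pts = np.column_stack(
            [np.arange(n + 1) * L0, np.zeros(n + 1), np.zeros(n + 1)]
        )
        model = build_wire_model(pts, EA=EA, EI=EI, clamp_start=True)
        mask = np.zeros((len(model.x0), 3), bool)
        mask[0] = True
        mask[1] = True
        P = 0.003
        ext = np.zeros_like(model.x0)
        ext[-1, 1] = P
        s = SolverSettings(force_tol=1e-8)
        x, rec = relax_to_equilibrium(
            model, constraints=(mask, model.x0.copy()), settings=s,
            ext_force=ext,
        )
        assert rec["converged"]
        exact = P * (n * L0) ** 3 / (3 * EI)
        assert abs(x[-1, 1] - exact) / exact < 0.05

    def test_zero_length_beam_rejected(self):
        pts = np.array([[0, 0, 0], [0, 0, 0], [0, 0, 1.0]])
        with pytest.raises(ValueError, match="zero-length"):
            build_wire_model(pts, EA=1.0, EI=1.0)


class TestContactLaw:
    def test_linear_penalty_arithmetic(self):
        s = SolverSettings(k_n=10.0, c_n=0.0)
        f = contact_nodal_force(
            distance=0.0, normal=np.array([0, 0, 1.0]),
            velocity=np.zeros(3), settings=s, R_w=0.01,
        )
        assert np.allclose(f, [0, 0, 0.1])

    def test_no_force_without_penetration(self):
        s = SolverSettings()
        f = contact_nodal_force(1.0, np.array([0, 0, 1.0]), np.zeros(3), s, 0.014)
        assert np.allclose(f, 0.0)

    def test_never_adhesive(self):
        s = SolverSettings(k_n=10.0, c_n=100.0)
        # separating fast: viscous term only acts on growing penetration
        f = contact_nodal_force(
            0.005, np.array([0, 0, 1.0]), np.array([0, 0, 1e3]), s, 0.01
        )
        assert np.dot(f, [0, 0, 1.0]) >= 0.0

    def test_friction_ratio_speed_sweep(self):
        s = SolverSettings(k_n=10.0, c_n=0.0, mu_f=0.3, v_reg=1.0)
        n = np.array([0.0, 0.0, 1.0])
        for speed in (0.01, 0.3, 1.0, 10.0, 1000.0):
            v = np.array([speed, 0.0, 0.0])
            f = contact_nodal_force(0.0, n, v, s, 0.01)
            fn = np.dot(f, n)
            ft = np.linalg.norm(f - fn * n)
            assert np.isclose(ft / fn, 0.3 * np.tanh(speed / 1.0), rtol=1e-9)
            assert ft / fn <= 0.3 + 1e-12
        # high slip speed approaches the Coulomb limit
        f = contact_nodal_force(0.0, n, np.array([1e4, 0, 0]), s, 0.01)
        fn = np.dot(f, n)
        assert np.isclose(np.linalg.norm(f - fn * n) / fn, 0.3, rtol=1e-6)


class TestRelaxation:
    def test_point_mass_on_wall_force_balance(self):
        # constant push F against a flat wall: penetration delta = F/k_n
        model = single_node_model()
        s = SolverSettings(k_n=10.0, mu_f=0.0, force_tol=1e-9, max_steps=50000)
        ext = np.array([[0.0, 0.0, -0.1]])
        x, rec = relax_to_equilibrium(
            model, sdf=flat_wall_grid(), settings=s, ext_force=ext,
        )
        assert rec["converged"]
        # wall distance = z; contact at z < R_w; delta = R_w - z = F/k_n
        assert np.isclose(model.R_w - x[0, 2], 0.1 / 10.0, atol=1e-6)

    def test_free_crimped_stent_recovers_reference(self):
        # the stress-free helix is the unique equilibrium: released without
        # a wall, the crimped braid must return to it (tight residual
        # tolerance resolves the very soft torsional end modes)
        params = StentParameters(N_w=8, N_cells=4)
        mesh = build_stent_mesh(params)
        settings = SolverSettings(force_tol=1e-8)
        model = assemble_model(mesh, settings=settings)
        cf = crimp_displacements(mesh, CrimpSpec(R_crimped=1.2))
        x_start = mesh.nodes + cf.displacements
        x, rec = relax_to_equilibrium(model, settings=settings, x_init=x_start)
        assert rec["converged"]
        dev = np.linalg.norm(x - mesh.nodes, axis=1)
        assert dev.max() < 1e-3

    def test_crimp_elongation_matches_inextensible_helix(self):
        params = StentParameters(N_w=8, N_cells=4)
        mesh = build_stent_mesh(params)
        settings = SolverSettings()
        model = assemble_model(mesh, settings=settings)
        crimp = CrimpSpec(R_crimped=1.0)
        cf = crimp_displacements(mesh, crimp)
        mask = np.zeros(mesh.nodes.shape, bool)
        mask[:, :2] = True
        vals = np.zeros_like(mesh.nodes)
        vals[:, :2] = mesh.nodes[:, :2] + cf.displacements[:, :2]
        x, rec = relax_to_equilibrium(
            model, constraints=(mask, vals), settings=settings
        )
        assert rec["converged"]
        z_extent = x[:, 2].max() - x[:, 2].min()
        free_extent = params.L_s
        assert z_extent > free_extent  # crimping elongates the braid
        predicted = crimped_segment_length(params, crimp) * params.N_cells
        assert abs(z_extent - predicted) / predicted < 0.02

    def test_energy_nonincreasing_across_restarts(self):
        # restart relaxation in zero-velocity segments: the stored strain
        # energy at the segment boundaries must decrease monotonically
        params = StentParameters(N_w=8, N_cells=4)
        mesh = build_stent_mesh(params)
        settings = SolverSettings(max_steps=1500, check_every=1500)
        model = assemble_model(mesh, settings=settings)
        cf = crimp_displacements(mesh, CrimpSpec(R_crimped=1.2))
        x = mesh.nodes + cf.displacements
        energies = [strain_energy(model, x)]
        for _ in range(6):
            x, _ = relax_to_equilibrium(model, settings=settings, x_init=x)
            energies.append(strain_energy(model, x))
        assert all(b <= a * (1 + 1e-9) for a, b in zip(energies, energies[1:]))
        assert energies[-1] < 0.01 * energies[0]

    def test_non_convergence_is_flagged(self):
        model = single_node_model()
        s = SolverSettings(max_steps=2, mu_f=0.0)
        ext = np.array([[0.0, 0.0, -0.1]])
        _, rec = relax_to_equilibrium(
            model, sdf=flat_wall_grid(), settings=s, ext_force=ext,
        )
        assert rec["converged"] is False

    def test_determinism(self):
        params = StentParameters(N_w=8, N_cells=4)
        mesh = build_stent_mesh(params)
        settings = SolverSettings(max_steps=3000)
        model = assemble_model(mesh, settings=settings)
        cf = crimp_displacements(mesh, CrimpSpec(R_crimped=1.2))
        x0 = mesh.nodes + cf.displacements
        x1, _ = relax_to_equilibrium(model, settings=settings, x_init=x0)
        x2, _ = relax_to_equilibrium(model, settings=settings, x_init=x0)
        assert np.array_equal(x1, x2)

    def test_dt_invariance(self):
        # stiffness-proportional masses make dt a gauge parameter
        params = StentParameters(N_w=8, N_cells=3)
        mesh = build_stent_mesh(params)
        results = []
        for dt in (1.0, 0.5):
            settings = SolverSettings(dt=dt)
            model = assemble_model(mesh, settings=settings)
            cf = crimp_displacements(mesh, CrimpSpec(R_crimped=1.5))
            x, rec = relax_to_equilibrium(
                model, settings=settings, x_init=mesh.nodes + cf.displacements
            )
            assert rec["converged"]
            results.append(x)
        assert np.abs(results[0] - results[1]).max() < 1e-3


class TestRunDeployment:
    @pytest.fixture(scope="class")
    def narrow_vessel_run(self):
        stent = StentParameters(N_w=16, N_cells=6)
        vessel = VesselParameters(y_P1=0.0, z_P1=30.0, D_v=3.0, D_a=7.0,
                                  y_Ca=2.0)
        res = run_deployment(stent, vessel, eta=0.42, sdf_spacing=0.2)
        return stent, vessel, res

    def test_converged_kinetic_energy_below_threshold(self, narrow_vessel_run):
        _, _, res = narrow_vessel_run
        assert res.converged
        assert res.final_kinetic_energy < 1e-12

    def test_no_wall_violation(self, narrow_vessel_run):
        stent, vessel, res = narrow_vessel_run
        d = vessel_sdf(res.positions, vessel)
        delta_tol = 2e-3  # penalty penetration + SDF interpolation slack
        assert d.min() >= stent.R_w - delta_tol

    def test_stent_expands_to_wall(self, narrow_vessel_run):
        stent, vessel, res = narrow_vessel_run
        # in a 3 mm vessel the 2.6 mm stent is wall-apposed: wire centres
        # sit within a couple voxels of the wall offset D_v/2 - R_w
        from braidsim.vessel import centerline_polyline, polyline_distance

        poly = centerline_polyline(vessel)
        r = polyline_distance(res.positions, poly)
        mid = (res.positions[:, 2] > 25) & (res.positions[:, 2] < 35)
        assert np.median(r[mid]) > 1.0  # expanded well beyond crimp (0.914)

    def test_u_h_layout(self, narrow_vessel_run):
        stent, _, res = narrow_vessel_run
        n_n = 16 * 7
        assert res.u_h.shape == (3 * n_n,)
        assert np.allclose(
            res.u_h.reshape(-1, 3), res.positions - res.reference
        )

    def test_wide_vessel_recovers_free_radius(self):
        # small stent in a much wider tube: free expansion, no contact
        stent = StentParameters(N_w=8, R_s=1.2, N_cells=4, L_s=8.0)
        vessel = VesselParameters(y_P1=0.0, z_P1=30.0, D_v=3.0, D_a=7.0,
                                  y_Ca=2.0)
        res = run_deployment(
            stent, vessel, eta=0.05, crimp=CrimpSpec(R_crimped=0.5),
            settings=SolverSettings(force_tol=1e-8), sdf_spacing=0.2,
        )
        assert res.converged
        # radial distance from the (straight) vessel axis
        r = np.hypot(res.positions[:, 0], res.positions[:, 1])
        assert np.abs(r - (stent.R_s + stent.R_w)).max() < 1e-3

    def test_crossing_pairs_stay_tied(self, narrow_vessel_run):
        stent, _, res = narrow_vessel_run
        mesh = build_stent_mesh(stent)
        pairs = mesh.crossing_pairs
        gap = np.linalg.norm(
            res.positions[pairs[:, 0]] - res.positions[pairs[:, 1]], axis=1
        )
        assert gap.max() < 5e-3
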