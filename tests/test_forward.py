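"""Forward diffusion model: coefficients, P1 assembly, solves, measurements."""

import numpy as np
import pytest

from fmtwave import (
    DetectorSet,
    InvalidParameterError,
    Mesh,
    SourceSet,
    TissueProperties,
    assemble,
    build_cylinder_mesh,
    build_disc_mesh,
    derive_coefficients,
    forward_map,
    solve_emission,
    solve_excitation,
    source_vector,
)
from fmtwave.forward import DerivedCoefficients, weighted_mass_matrix

from conftest import tissue


class TestDeriveCoefficients:
    def test_cw_background_band_x(self):
        p = TissueProperties(
            n_nodes=1, mu_axi=0.03, mu_axf=0.06, mu_sx_prime=4.0,
            mu_ami=0.02, mu_amf=0.005, mu_sm_prime=3.0, eta=0.2, tau=0.6,
        )
        co = derive_coefficients(p, 0.0)
        assert co.D_x[0] == pytest.approx(1.0 / (3 * 4.09), rel=1e-12)
        assert co.k_x[0] == pytest.approx(0.09, rel=1e-12)

    def test_cw_alpha(self):
        p = TissueProperties(
            n_nodes=1, mu_axi=0.03, mu_axf=0.4, mu_sx_prime=4.0, eta=0.2, tau=0.6
        )
        assert derive_coefficients(p, 0.0).alpha[0] == pytest.approx(0.08, rel=1e-12)

    def test_rf_alpha_magnitude(self):
        # f = 100 MHz -> omega = 2*pi*0.1 rad/ns; omega*tau = 0.37699
        p = TissueProperties(
            n_nodes=1, mu_axi=0.03, mu_axf=0.4, mu_sx_prime=4.0, eta=0.2, tau=0.6
        )
        co = derive_coefficients(p, 2 * np.pi * 0.1)
        assert abs(co.alpha[0]) == pytest.approx(0.08 / np.sqrt(1 + 0.37699**2), rel=1e-4)
        assert co.k_x[0].imag > 0

    def test_zero_attenuation_names_node(self):
        p = TissueProperties(n_nodes=3, mu_axi=[0.01, 0.0, 0.01], mu_sx_prime=[0.1, 0.0, 0.1])
        with pytest.raises(InvalidParameterError, match="node 1"):
            derive_coefficients(p, 0.0)

    def test_cw_coefficients_are_real(self):
        p = TissueProperties(n_nodes=2, mu_axi=0.01, mu_sx_prime=1.0, eta=0.1, tau=0.5)
        co = derive_coefficients(p, 0.0)
        for arr in (co.k_x, co.k_m, co.alpha):
            assert not np.iscomplexobj(arr)


def unit_triangle():
    return Mesh(
        2,
        np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
        np.array([[0, 1, 2]]),
        np.array([[0, 1]]),
    )


def coeffs(n, D=0.0, k=0.0, b=0.0):
    return DerivedCoefficients(
        D_x=np.full(n, float(D)), D_m=np.full(n, float(D)),
        k_x=np.full(n, float(k)), k_m=np.full(n, float(k)),
        alpha=np.zeros(n), omega=0.0, robin_b_x=b, robin_b_m=b,
    )


class TestAssembly:
    def test_p1_stiffness_unit_triangle(self):
        A = assemble(unit_triangle(), coeffs(3, D=1.0), "x").A.toarray()
        expect = np.array([[1.0, -0.5, -0.5], [-0.5, 0.5, 0.0], [-0.5, 0.0, 0.5]])
        np.testing.assert_allclose(A, expect, atol=1e-14)

    def test_p1_mass_unit_triangle(self):
        A = assemble(unit_triangle(), coeffs(3, k=1.0), "x").A.toarray()
        expect = np.array([[2, 1, 1], [1, 2, 1], [1, 1, 2]]) / 24.0
        np.testing.assert_allclose(A, expect, atol=1e-14)

    def test_robin_edge_matrix(self):
        A = assemble(unit_triangle(), coeffs(3, b=1.0), "x").A.toarray()
        expect = np.zeros((3, 3))
        expect[:2, :2] = [[1 / 3, 1 / 6], [1 / 6, 1 / 3]]
        np.testing.assert_allclose(A, expect, atol=1e-14)

    def test_assembled_matrix_symmetric(self, disc_setup):
        mesh, props, _, _ = disc_setup
        co = derive_coefficients(props, 2 * np.pi * 0.1)
        A = assemble(mesh, co, "x").A
        d = abs(A - A.T).max()
        assert d < 1e-12 * abs(A).max()

    def test_spd_at_cw(self, disc_setup):
        mesh, props, _, _ = disc_setup
        A = assemble(mesh, derive_coefficients(props, 0.0), "x").A.toarray()
        assert np.linalg.eigvalsh(A).min() > 0


class TestSourcesAndSolves:
    def test_source_at_node_single_entry(self, small_disc):
        n = 5
        rhs = source_vector(small_disc, small_disc.nodes[n], amplitude=2.0)
        assert rhs[n] == pytest.approx(2.0)
        assert np.count_nonzero(np.abs(rhs) > 1e-12) <= 3

    def test_zero_amplitude(self, small_disc):
        assert not source_vector(small_disc, [1.0, 1.0], amplitude=0.0).any()

    def test_partition_of_unity(self, small_disc):
        rhs = source_vector(small_disc, [2.3, -1.7], amplitude=0.7)
        assert rhs.sum() == pytest.approx(0.7, abs=1e-12)

    def test_zero_rhs_zero_field(self, disc_setup):
        mesh, props, _, _ = disc_setup
        sys_x = assemble(mesh, derive_coefficients(props, 0.0), "x")
        assert not solve_excitation(sys_x, np.zeros(mesh.N)).any()

    def test_positive_field_decays_from_source(self, disc_setup):
        mesh, props, _, _ = disc_setup
        sys_x = assemble(mesh, derive_coefficients(props, 0.0), "x")
        k = int(np.argmin(np.linalg.norm(mesh.nodes, axis=1)))
        phi = solve_excitation(sys_x, source_vector(mesh, mesh.nodes[k]))
        assert (phi > 0).all()
        r = np.linalg.norm(mesh.nodes - mesh.nodes[k], axis=1)
        far, near = phi[r > 6.0].max(), phi[(r > 2.0) & (r < 4.0)].min()
        assert far < near

    def test_emission_zero_without_fluorophore(self, disc_setup):
        mesh, props, srcs, dets = disc_setup
        from dataclasses import replace

        p0 = replace(props, eta=np.zeros(mesh.N))
        y = forward_map(mesh, p0, srcs, dets)
        np.testing.assert_allclose(y, 0.0, atol=1e-18)

    def test_emission_linear_in_eta(self, disc_setup):
        mesh, props, srcs, dets = disc_setup
        from dataclasses import replace

        y1 = forward_map(mesh, props, srcs, dets)
        y2 = forward_map(mesh, replace(props, eta=2 * props.eta), srcs, dets)
        np.testing.assert_allclose(y2, 2 * y1, rtol=1e-12)

    def test_emission_source_support(self, disc_setup):
        mesh, props, _, _ = disc_setup
        co = derive_coefficients(props, 0.0)
        alpha = np.zeros(mesh.N)
        alpha[3] = 1.0
        M = weighted_mass_matrix(mesh, alpha)
        touching = np.unique(mesh.elements[(mesh.elements == 3).any(axis=1)])
        phi_x = np.ones(mesh.N)
        s_m = M @ phi_x
        assert set(np.nonzero(np.abs(s_m) > 1e-15)[0]) <= set(touching)


class TestForwardMap:
    def test_amplitude_linearity(self, disc_setup):
        mesh, props, srcs, dets = disc_setup
        from dataclasses import replace

        y1 = forward_map(mesh, props, srcs, dets)
        y2 = forward_map(mesh, props, replace(srcs, amplitude=2.0), dets)
        np.testing.assert_allclose(y2, 2 * y1, rtol=1e-12)

    def test_detector_permutation(self, disc_setup):
        mesh, props, srcs, dets = disc_setup
        y = forward_map(mesh, props, srcs, dets)
        perm = np.array([3, 1, 5, 0, 2, 4])
        from dataclasses import replace

        dets_p = replace(dets, angles_deg=dets.angles_deg[perm])
        y_p = forward_map(mesh, props, srcs, dets_p)
        n_det = len(dets)
        for s in range(len(srcs)):
            np.testing.assert_allclose(
                y_p[s * n_det : (s + 1) * n_det],
                y[s * n_det : (s + 1) * n_det][perm],
                rtol=1e-12,
            )

    def test_reciprocity_cw(self, disc_setup):
        mesh, props, _, _ = disc_setup
        sys_x = assemble(mesh, derive_coefficients(props, 0.0), "x")
        b = np.unique(mesh.boundary_facets)
        p, q = int(b[0]), int(b[len(b) // 2])
        e_p = np.zeros(mesh.N); e_p[p] = 1.0
        e_q = np.zeros(mesh.N); e_q[q] = 1.0
        a = solve_excitation(sys_x, e_p)[q]
        bb = solve_excitation(sys_x, e_q)[p]
        assert abs(a - bb) <= 1e-8 * abs(a)

    def test_grid_convergence_on_disc(self):
        """Boundary fluence differences shrink monotonically under refinement."""
        ys = []
        srcs = SourceSet(angles_deg=[0.0], boundary_radius_mm=10.0, offset_depth_mm=2.5)
        dets = DetectorSet(angles_deg=np.arange(0, 360, 45) + 22.5, boundary_radius_mm=10.0)
        for edge in (4.0, 2.0, 1.0, 0.5):
            mesh = build_disc_mesh(10.0, edge)
            props = tissue(mesh)
            ys.append(forward_map(mesh, props, srcs, dets))
        diffs = [np.linalg.norm(ys[i + 1] - ys[i]) for i in range(3)]
        assert diffs[0] > diffs[1] > diffs[2]


class TestGreensFunctionOracle:
    def test_matches_infinite_medium_solution(self):
        """Interior FEM fluence vs analytic point-source Green's function.

        Homogeneous cylinder, source at the centre; nodes at least 3 mm from
        the source and 5 mm from the boundary agree with
        exp(-mu_eff r) / (4 pi D r) within 10%.
        """
        mesh = build_cylinder_mesh(10.0, 20.0, 0.6)
        mu_a, mu_s = 0.05, 2.0
        props = TissueProperties(n_nodes=mesh.N, mu_axi=mu_a, mu_sx_prime=mu_s)
        sys_x = assemble(mesh, derive_coefficients(props, 0.0), "x")
        k = int(np.argmin(np.linalg.norm(mesh.nodes - [0, 0, 10.0], axis=1)))
        rhs = np.zeros(mesh.N)
        rhs[k] = 1.0
        phi = solve_excitation(sys_x, rhs)
        D = 1 / (3 * (mu_a + mu_s))
        mu_eff = np.sqrt(mu_a / D)
        r = np.linalg.norm(mesh.nodes - mesh.nodes[k], axis=1)
        rho = np.linalg.norm(mesh.nodes[:, :2], axis=1)
        d_bnd = np.minimum(10 - rho, np.minimum(mesh.nodes[:, 2], 20 - mesh.nodes[:, 2]))
        sel = (r >= 3.0) & (d_bnd >= 5.0)
        assert sel.sum() > 500
        G = np.exp(-mu_eff * r[sel]) / (4 * np.pi * D * r[sel])
        assert (np.abs(phi[sel] - G) / G).max() < 0.10
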