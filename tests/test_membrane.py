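import numpy as np
import pytest

from hemoflow.membrane import (CellTopology, MembraneParams,
                               SpringWienerIncrement, area_volume_forces,
                               bending_forces, build_rbc_mesh, elastic_forces,
                               membrane_viscous_forces, mesh_area, mesh_volume,
                               total_energy, wlc_triangle_constant)


def _params_for(x, topo, **overrides):
    edges = np.linalg.norm(x[topo.springs[:, 0]] - x[topo.springs[:, 1]], axis=1)
    return MembraneParams.reference(float(edges.mean()), **overrides)


@pytest.fixture(params=[12, 100])
def mesh(request):
    return build_rbc_mesh(request.param, area=4 * np.pi)


class TestParams:
    def test_x0_in_unit_interval(self):
        with pytest.raises(ValueError):
            MembraneParams(l0=1.0, lm=0.9, p=0.01)

    def test_random_force_realisability(self):
        # 3 gamma_c >= gamma_t required for a real amplitude
        with pytest.raises(ValueError, match="gamma_c"):
            MembraneParams(l0=0.5, lm=1.1, p=0.01, gamma_t=3.1, gamma_c=1.0)

    def test_reference_set_valid(self):
        p = MembraneParams.reference(0.5)
        assert 0 < p.x0 < 1 and 3 * p.gamma_c >= p.gamma_t


class TestMeshConstruction:
    def test_icosahedron_combinatorics(self):
        x, topo = build_rbc_mesh(12, area=4 * np.pi)
        assert topo.n_springs == 30
        assert topo.n_triangles == 20
        # Euler characteristic V - E + F = 2
        assert 12 - topo.n_springs + topo.n_triangles == 2

    @pytest.mark.parametrize("n_v", [12, 60, 100, 500])
    def test_closed_triangulation_identities(self, n_v):
        x, topo = build_rbc_mesh(n_v, area=4 * np.pi)
        assert topo.n_springs == 3 * (n_v - 2)
        assert topo.n_triangles == 2 * (n_v - 2)

    def test_volume_against_divergence_theorem_oracle(self, mesh):
        x, topo = mesh
        # independent oracle: sum signed tetrahedra vertex-by-vertex in
        # straight Python
        vol = 0.0
        for (a, b, c) in topo.triangles:
            vol += np.dot(x[a], np.cross(x[b], x[c])) / 6.0
        np.testing.assert_allclose(mesh_volume(x, topo.triangles), vol,
                                   rtol=1e-12)
        assert vol > 0  # outward orientation

    def test_area_and_volume_targets(self):
        area = 30.0
        vol = 0.75 * (area / (4 * np.pi)) ** 1.5 * 4 * np.pi / 3
        x, topo = build_rbc_mesh(200, area=area, volume=vol)
        assert topo.A0 == pytest.approx(area, rel=0.02)
        assert topo.V0 == pytest.approx(vol, rel=0.05)

    def test_minimum_vertex_count(self):
        with pytest.raises(ValueError):
            build_rbc_mesh(11, area=1.0)

    def test_center_and_orientation(self):
        c = np.array([1.0, 2.0, 3.0])
        x, _ = build_rbc_mesh(42, area=4 * np.pi, center=c)
        np.testing.assert_allclose(x.mean(axis=0), c, atol=0.05)


class TestForceGradients:
    """Analytic forces must equal the exact negative energy gradients."""

    def _check(self, x, topo, params, force_fn, energy_fn, num_grad,
               tol=1e-6):
        f = force_fn(x)
        g = num_grad(energy_fn, x)
        scale = np.abs(f).max()
        assert np.abs(f + g).max() / scale < tol

    @pytest.fixture
    def perturbed(self, mesh, rng):
        x, topo = mesh
        return x + 0.02 * rng.normal(size=x.shape), topo

    def test_elastic(self, perturbed, num_grad):
        x, topo = perturbed
        params = _params_for(x, topo)
        self._check(x, topo, params,
                    lambda X: elastic_forces(X, topo, params)[0],
                    lambda X: elastic_forces(X, topo, params)[1], num_grad)

    def test_bending(self, perturbed, num_grad):
        x, topo = perturbed
        params = _params_for(x, topo, theta0=0.15)
        self._check(x, topo, params,
                    lambda X: bending_forces(X, topo, params)[0],
                    lambda X: bending_forces(X, topo, params)[1], num_grad)

    def test_area_volume(self, perturbed, num_grad):
        x, topo = perturbed
        params = _params_for(x, topo)
        self._check(x, topo, params,
                    lambda X: area_volume_forces(X, topo, params)[0],
                    lambda X: sum(area_volume_forces(X, topo, params)[1:]),
                    num_grad)

    def test_total_is_sum_of_terms(self, perturbed):
        x, topo = perturbed
        params = _params_for(x, topo)
        e = total_energy(x, topo, params)
        assert e["V"] == pytest.approx(e["Vs"] + e["Vb"] + e["Va"] + e["Vv"])


class TestElastic:
    def test_wlc_divergence_near_max_extension(self):
        x, topo = build_rbc_mesh(12, area=4 * np.pi)
        params = _params_for(x, topo)
        energies = []
        for scale in (1.0, 1.2, 1.4):
            xs = x * scale
            if np.linalg.norm(xs[topo.springs[:, 0]] - xs[topo.springs[:, 1]],
                              axis=1).max() / params.lm < 1.0:
                energies.append(elastic_forces(xs, topo, params)[1])
        assert all(np.diff(energies) > 0)

    def test_overextension_error(self):
        x, topo = build_rbc_mesh(12, area=4 * np.pi)
        params = _params_for(x, topo)
        with pytest.raises(ValueError, match="overextension"):
            elastic_forces(x * 5.0, topo, params)

    def test_triangle_constant_value(self):
        # C = 3 sqrt(3) kBT lm^3 x0^4 (4 x0^2 - 9 x0 + 6) / (64 p (1-x0)^2)
        p = MembraneParams(l0=0.5, lm=1.0, p=0.01, kBT=0.2)
        x0 = 0.5
        expected = (3 * np.sqrt(3) * 0.2 * 1.0 * x0 ** 4
                    * (4 * 0.25 - 4.5 + 6) / (64 * 0.01 * 0.25))
        assert wlc_triangle_constant(p) == pytest.approx(expected)

    def test_per_triangle_term_scales_inverse_area(self):
        x, topo = build_rbc_mesh(12, area=4 * np.pi)
        params = _params_for(x, topo)
        C = wlc_triangle_constant(params)
        areas = mesh_area(x, topo.triangles)
        e_tri = (C / areas).sum()
        e_tri_scaled = (C / mesh_area(1.1 * x, topo.triangles)).sum()
        assert e_tri_scaled == pytest.approx(e_tri / 1.1 ** 2)

    def test_regular_mesh_near_equilibrium(self):
        # all springs at l0: residual per-vertex elastic force small vs kBT/p
        x, topo = build_rbc_mesh(12, area=4 * np.pi)
        params = _params_for(x, topo)
        f, _ = elastic_forces(x, topo, params)
        scale = params.kBT / params.p
        assert np.linalg.norm(f, axis=1).max() < 1e-2 * scale


class TestBending:
    def test_zero_at_spontaneous_angle(self):
        x, topo = build_rbc_mesh(12, area=4 * np.pi)
        # icosahedron: all dihedral angles equal; set theta0 to that angle
        params = _params_for(x, topo)
        from hemoflow.membrane import _dihedral_angles_and_grads
        theta, _ = _dihedral_angles_and_grads(x, topo.dihedrals)
        params = _params_for(x, topo, theta0=float(theta[0]))
        f, e = bending_forces(x, topo, params)
        assert e == pytest.approx(0.0, abs=1e-10)
        assert np.abs(f).max() < 1e-8

    def test_flat_patch_restoring_force(self):
        x = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                      [0.5, 0.8, 0.0], [0.5, -0.8, 0.0]])
        topo = CellTopology(springs=np.array([[0, 1]]),
                            triangles=np.array([[0, 1, 2], [1, 0, 3]]),
                            dihedrals=np.array([[0, 1, 2, 3]]),
                            A0=1.0, V0=1.0, n_verts=4)
        params = MembraneParams(l0=0.5, lm=1.2, p=0.01, kb=1.0, theta0=0.0)
        f, e = bending_forces(x, topo, params)
        assert e == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(f, 0.0, atol=1e-12)
        xp = x.copy()
        xp[2, 2] = 0.05  # push one off-edge vertex out of plane
        f, e = bending_forces(xp, topo, params)
        assert e > 0
        assert f[2, 2] < 0  # restoring toward the plane


class TestAreaVolume:
    def test_zero_at_reference(self, mesh):
        x, topo = mesh
        params = _params_for(x, topo)
        f, va, vv = area_volume_forces(x, topo, params)
        assert va == pytest.approx(0.0, abs=1e-9)
        assert vv == pytest.approx(0.0, abs=1e-9)
        assert np.abs(f).max() < 1e-6

    def test_quadratic_growth(self, mesh):
        x, topo = mesh
        params = _params_for(x, topo)
        ratios = []
        for eps in (1e-2, 1e-3):
            scale = (1 + eps) ** (1 / 3)
            _, _, vv = area_volume_forces(x * scale, topo, params)
            ratios.append(vv / eps ** 2)
        # V = V0 (1 + eps): energy grows as eps^2
        assert ratios[0] == pytest.approx(ratios[1], rel=0.05)

    def test_inverted_mesh_error(self, mesh):
        x, topo = mesh
        params = _params_for(x, topo)
        flipped = topo.triangles[:, [0, 2, 1]]
        bad = CellTopology(springs=topo.springs, triangles=flipped,
                           dihedrals=topo.dihedrals, A0=topo.A0, V0=topo.V0,
                           n_verts=topo.n_verts)
        with pytest.raises(ValueError, match="inverted"):
            area_volume_forces(x, bad, params)


class TestViscousForces:
    def test_zero_relative_velocity(self, mesh):
        x, topo = mesh
        params = _params_for(x, topo)
        f = membrane_viscous_forces(x, np.zeros_like(x), topo, params, dt=0.01)
        np.testing.assert_array_equal(f, 0.0)

    def test_parallel_velocity_magnitude(self):
        # v_ij parallel to e_ij: |F| = (gamma_t + gamma_c) |v_ij|
        x = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.5, 1.0, 0.0],
                      [0.5, -1.0, 0.0]])
        topo = CellTopology(springs=np.array([[0, 1]]),
                            triangles=np.array([[0, 1, 2], [1, 0, 3]]),
                            dihedrals=np.array([[0, 1, 2, 3]]),
                            A0=1.0, V0=1.0, n_verts=4)
        params = MembraneParams(l0=0.5, lm=1.2, p=0.01, gamma_t=0.7,
                                gamma_c=0.9)
        v = np.zeros_like(x)
        v[0, 0] = 0.25
        f = membrane_viscous_forces(x, v, topo, params, dt=0.01)
        np.testing.assert_allclose(np.linalg.norm(f[0]),
                                   (0.7 + 0.9) * 0.25, rtol=1e-12)
        np.testing.assert_allclose(f[0], -f[1], rtol=1e-12)

    def test_wiener_increment_traceless_symmetric(self, rng):
        inc = SpringWienerIncrement.draw(40, dt=0.01, rng=rng)
        np.testing.assert_allclose(
            np.trace(inc.dW_bar_s, axis1=1, axis2=2), 0.0, atol=1e-14)
        np.testing.assert_allclose(
            inc.dW_bar_s, np.transpose(inc.dW_bar_s, (0, 2, 1)), atol=1e-14)

    def test_random_force_momentum_free(self, mesh, rng):
        x, topo = mesh
        params = _params_for(x, topo)
        inc = SpringWienerIncrement.draw(topo.n_springs, dt=0.01, rng=rng)
        f = membrane_viscous_forces(x, rng.normal(size=x.shape), topo, params,
                                    dt=0.01, increments=inc)
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-10)


class TestGlobalInvariants:
    def test_internal_forces_momentum_and_torque_free(self, mesh, rng):
        x, topo = mesh
        x = x + 0.02 * rng.normal(size=x.shape)
        params = _params_for(x, topo)
        f = (elastic_forces(x, topo, params)[0]
             + bending_forces(x, topo, params)[0]
             + area_volume_forces(x, topo, params)[0])
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(np.cross(x, f).sum(axis=0), 0.0, atol=1e-10)
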