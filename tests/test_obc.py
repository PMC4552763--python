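import numpy as np
import pytest

from hemoflow.core import (ParticleSystem, Region, SimClock, Simulation,
                           Species)
from hemoflow.geometry import OutletPlane
from hemoflow.membrane import build_rbc_mesh, MembraneParams
from hemoflow.obc import (CellManager, ObcLayout, OutflowController,
                          one_way_weights, outflow_membrane,
                          regenerate_ghosts, update_outflow_probability)


class TestLayout:
    def test_copy_border_at_generating_face(self):
        lay = ObcLayout(gen_len=10.0, zone_width=1.5)
        assert lay.copy_border == 10.0

    def test_too_short_generating_region(self):
        with pytest.raises(ValueError, match="twice the zone width"):
            ObcLayout(gen_len=2.0, zone_width=1.5)


class TestController:
    def test_dp_formula_exact(self):
        # dP = h |rho - rho_t| / rho_t = 0.05 * 0.30 / 2.96
        dP = 0.05 * abs(2.66 - 2.96) / 2.96
        P = update_outflow_probability(0.5, 2.66, 2.96, h=0.05)
        # below-target density: retain more, so removal probability drops
        assert P == pytest.approx(0.5 - dP)
        assert dP == pytest.approx(0.0050675675675675, rel=1e-10)

    def test_above_target_raises_P(self):
        P = update_outflow_probability(0.5, 3.26, 2.96, h=0.05)
        assert P == pytest.approx(0.5 + 0.05 * 0.30 / 2.96)

    def test_at_target_unchanged(self):
        assert update_outflow_probability(0.37, 2.96, 2.96) == 0.37

    def test_monotone_drop_until_clamped(self):
        # persistently half-target density: P falls monotonically to 0
        P = 0.9
        values = []
        for _ in range(500):
            P = update_outflow_probability(P, 1.48, 2.96)
            values.append(P)
        assert all(np.diff(values) <= 0)
        assert values[-1] == 0.0

    def test_clamped_to_unit_interval(self):
        assert update_outflow_probability(0.999, 29.6, 2.96) == 1.0

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            update_outflow_probability(0.5, 1.0, 0.0)
        with pytest.raises(ValueError):
            OutflowController(rho_target=-1.0)

    def test_smoothing_window(self):
        ctl = OutflowController(rho_target=2.96, window=3)
        for rho in (1.0, 2.0, 3.0, 4.0):
            ctl.smoothed(rho)
        assert ctl.smoothed(5.0) == pytest.approx(4.0)  # mean of (3,4,5)


class TestOutflowMembrane:
    def _system(self, z_values):
        pos = np.zeros((len(z_values), 3))
        pos[:, 2] = z_values
        return ParticleSystem(pos)

    def test_P_one_removes_every_crossing(self, rng):
        ps = self._system([5.1, 5.2, 4.9])
        plane = OutletPlane((0, 0, 5.0), (0, 0, 1))
        removed, nref = outflow_membrane(ps, plane, 1.0, rng,
                                         np.ones(3, dtype=bool))
        assert sorted(removed.tolist()) == [0, 1]
        assert nref == 0

    def test_P_zero_reflects_all(self, rng):
        ps = self._system([5.25])
        ps.vel[0] = [0.3, 0.1, 1.0]
        plane = OutletPlane((0, 0, 5.0), (0, 0, 1))
        removed, nref = outflow_membrane(ps, plane, 0.0, rng,
                                         np.ones(1, dtype=bool))
        assert len(removed) == 0 and nref == 1
        # specular: position mirrored, normal velocity negated
        np.testing.assert_allclose(ps.pos[0, 2], 4.75)
        np.testing.assert_allclose(ps.vel[0], [0.3, 0.1, -1.0])

    def test_binomial_removal_fraction(self, rng):
        n = 10_000
        ps = self._system(np.full(n, 5.5))
        plane = OutletPlane((0, 0, 5.0), (0, 0, 1))
        removed, _ = outflow_membrane(ps, plane, 0.5, rng,
                                      np.ones(n, dtype=bool))
        frac = len(removed) / n
        assert abs(frac - 0.5) < 0.015  # 3 sigma of Binomial(1e4, 0.5)

    def test_ineligible_untouched(self, rng):
        ps = self._system([5.5])
        plane = OutletPlane((0, 0, 5.0), (0, 0, 1))
        removed, nref = outflow_membrane(ps, plane, 1.0, rng,
                                         np.zeros(1, dtype=bool))
        assert len(removed) == 0 and nref == 0


class TestOneWayCoupling:
    def test_cross_border_pair(self):
        wi, wj = one_way_weights(np.array([True]), np.array([False]))
        assert wi[0] == 0.0 and wj[0] == 1.0  # generating member gets nothing

    def test_same_side_pairs_symmetric(self):
        for side in (True, False):
            wi, wj = one_way_weights(np.array([side]), np.array([side]))
            assert wi[0] == 1.0 and wj[0] == 1.0

    def test_net_force_on_generating_region_zero(self):
        # directly from the masking definition: every cross pair applies
        # zero force to the generating member
        gi = np.array([True, True, False, False])
        gj = np.array([False, True, True, False])
        wi, wj = one_way_weights(gi, gj)
        assert np.all(wi[gi & ~gj] == 0.0)
        assert np.all(wj[gj & ~gi] == 0.0)


class _NullForce:
    def __call__(self, sim):
        return np.zeros_like(sim.system.pos)


def _make_sim(ps):
    return Simulation(ps, _NullForce(), clock=SimClock(dt=0.01, seed=5))


class TestGhostRegeneration:
    def test_images_placed_in_A1_A4(self):
        lay = ObcLayout(gen_len=10.0, zone_width=1.5)
        pos = np.array([[0.0, 0.0, 0.4],    # zone A2 -> ghost at z + 10
                        [0.0, 0.0, 9.2],    # zone A3 -> ghost at z - 10
                        [0.0, 0.0, 5.0]])   # interior -> no ghost
        ps = ParticleSystem(pos, region=np.full(3, Region.GENERATING))
        ps.vel[0] = [1.0, 2.0, 3.0]
        sim = _make_sim(ps)
        n_new = regenerate_ghosts(sim, lay)
        assert n_new == 2
        ghosts = ps.species == Species.GHOST
        zs = sorted(ps.pos[ghosts, 2].tolist())
        assert zs == pytest.approx([-0.8, 10.4])
        # ghost carries the source velocity
        g4 = np.nonzero(ghosts & (ps.pos[:, 2] > 10))[0][0]
        np.testing.assert_array_equal(ps.vel[g4], [1.0, 2.0, 3.0])

    def test_empty_zones_no_ghosts(self):
        lay = ObcLayout(gen_len=10.0, zone_width=1.5)
        ps = ParticleSystem(np.array([[0, 0, 5.0]]),
                            region=[Region.GENERATING])
        assert regenerate_ghosts(_make_sim(ps), lay) == 0

    def test_old_ghosts_replaced(self):
        lay = ObcLayout(gen_len=10.0, zone_width=1.5)
        ps = ParticleSystem(np.array([[0, 0, 0.4]]),
                            region=[Region.GENERATING])
        sim = _make_sim(ps)
        regenerate_ghosts(sim, lay)
        regenerate_ghosts(sim, lay)
        assert int((ps.species == Species.GHOST).sum()) == 1


class TestCellManager:
    def _cell_system(self, center_z, Lg=10.0):
        x, topo = build_rbc_mesh(12, area=4.0)
        x = x + [0.0, 0.0, center_z]
        xw = x.copy()
        xw[:, 2] = np.mod(xw[:, 2], Lg)
        ps = ParticleSystem(xw, species=np.full(12, Species.MEMBRANE),
                            cell_id=np.full(12, 1),
                            region=np.full(12, Region.GENERATING))
        params = MembraneParams.reference(0.7)
        mgr = CellManager(params, period_z=Lg)
        mgr.add_cell(topo, np.arange(12), periodic=True, cell_id=1)
        mgr.cells[1].com_z = center_z % Lg
        return ps, mgr, topo

    def test_minimum_image_spring_lengths_across_seam(self):
        # cell straddling the periodic seam: unwrapped geometry must equal
        # the explicitly unwrapped coordinates
        x, topo = build_rbc_mesh(12, area=4.0)
        x_true = x + [0.0, 0.0, 9.95]
        ps, mgr, _ = self._cell_system(9.95)
        xu = mgr.unwrapped(ps, mgr.cells[1])
        li_u = np.linalg.norm(xu[topo.springs[:, 0]] - xu[topo.springs[:, 1]],
                              axis=1)
        li_t = np.linalg.norm(
            x_true[topo.springs[:, 0]] - x_true[topo.springs[:, 1]], axis=1)
        np.testing.assert_allclose(li_u, li_t, rtol=1e-12)

    def test_com_tracking_and_crossing(self):
        ps, mgr, _ = self._cell_system(9.0)
        # advect the cell across the border
        crossed_at = None
        for step in range(30):
            ps.pos[:, 2] = np.mod(ps.pos[:, 2] + 0.1, 10.0)
            crossed = mgr.track_coms(ps)
            if crossed:
                crossed_at = step
                break
        assert crossed_at is not None
        assert mgr.cells[1].com_z < 1.0  # wrapped back

    def test_dissolution_keeps_particles_in_place(self):
        ps, mgr, topo = self._cell_system(5.0)
        n_before = ps.n
        pos_before = ps.pos.copy()
        verts = mgr.dissolve(ps, 1)
        assert ps.n == n_before
        np.testing.assert_array_equal(ps.pos, pos_before)
        assert np.all(ps.species[verts] == Species.FLUID)
        assert np.all(ps.cell_id[verts] == -1)
        assert 1 not in mgr.cells
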