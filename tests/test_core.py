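import numpy as np
import pytest

from hemoflow.core import (ParticleSystem, Region, SimClock, Simulation,
                           Species, build_neighbor_pairs)
from hemoflow.dpd import DPDParams
from hemoflow.forces import ForceModel


class TestNeighborPairs:
    def test_two_particles_within_cutoff(self):
        pos = np.array([[0.0, 0.0, 0.0], [0.9, 0.0, 0.0]])
        i, j, dr = build_neighbor_pairs(pos, cutoff=1.0)
        assert len(i) == 1
        np.testing.assert_allclose(np.linalg.norm(dr[0]), 0.9)

    def test_two_particles_beyond_cutoff(self):
        pos = np.array([[0.0, 0.0, 0.0], [1.1, 0.0, 0.0]])
        i, j, dr = build_neighbor_pairs(pos, cutoff=1.0)
        assert len(i) == 0

    def test_empty_system(self):
        i, j, dr = build_neighbor_pairs(np.empty((0, 3)), cutoff=1.0)
        assert len(i) == 0 and dr.shape == (0, 3)

    def test_periodic_image_pair(self):
        box = np.array([10.0, 10.0, 10.0])
        pos = np.array([[0.2, 5.0, 5.0], [9.9, 5.0, 5.0]])
        i, j, dr = build_neighbor_pairs(pos, 1.0, box=box,
                                        periodic=(True, False, False))
        assert len(i) == 1
        np.testing.assert_allclose(np.linalg.norm(dr[0]), 0.3, atol=1e-12)
        # same configuration, periodicity off: no pair
        i, j, _ = build_neighbor_pairs(pos, 1.0)
        assert len(i) == 0

    @pytest.mark.parametrize("periodic", [(True, True, True),
                                          (False, False, True)])
    def test_against_brute_force(self, rng, periodic):
        box = np.array([5.0, 6.0, 7.0])
        pos = rng.uniform(0, 1, (50, 3)) * box
        cutoff = 1.6
        i, j, dr = build_neighbor_pairs(pos, cutoff, box=box, periodic=periodic)
        got = set(zip(np.minimum(i, j).tolist(), np.maximum(i, j).tolist()))
        expected = set()
        for a in range(50):
            for b in range(a + 1, 50):
                d = pos[a] - pos[b]
                for k in range(3):
                    if periodic[k]:
                        d[k] -= box[k] * np.round(d[k] / box[k])
                if np.linalg.norm(d) < cutoff:
                    expected.add((a, b))
        assert got == expected
        assert np.all(np.linalg.norm(dr, axis=1) < cutoff)

    def test_cutoff_exceeding_half_box_rejected(self):
        pos = np.zeros((3, 3))
        with pytest.raises(ValueError, match="half the periodic box"):
            build_neighbor_pairs(pos, 3.0, box=[5.0, 5.0, 5.0],
                                 periodic=(True, True, True))


class TestParticleSystem:
    def test_membrane_requires_cell_id(self):
        with pytest.raises(ValueError, match="cell id"):
            ParticleSystem(np.zeros((1, 3)),
                           species=[Species.MEMBRANE], cell_id=[-1])

    def test_add_remove_with_remap(self):
        ps = ParticleSystem(np.zeros((3, 3)))
        ps.add(np.ones((2, 3)), species=Species.WALL)
        remap = ps.remove([1])
        assert ps.n == 4
        assert remap[0] == 0 and remap[1] == -1 and remap[2] == 1

    def test_clock_validation(self):
        with pytest.raises(ValueError):
            SimClock(dt=0.0)


def _free_sim(pos, vel, dt=0.01, force=None):
    ps = ParticleSystem(pos, vel=vel)
    if force is None:
        def force(sim):
            return np.zeros_like(sim.system.pos)
    return Simulation(ps, force, clock=SimClock(dt=dt, seed=0))


class TestVelocityVerlet:
    def test_free_flight_displacement(self):
        v = np.array([[0.3, -0.2, 0.5]])
        sim = _free_sim(np.zeros((1, 3)), v, dt=0.01)
        sim.run(7)
        np.testing.assert_allclose(sim.system.pos, 7 * 0.01 * v, rtol=1e-14)

    def test_constant_force_closed_form(self):
        f = np.array([[0.0, 0.0, 2.5]])
        sim = _free_sim(np.zeros((1, 3)), np.zeros((1, 3)), dt=0.02,
                        force=lambda s: f)
        k = 25
        sim.run(k)
        t = k * 0.02
        np.testing.assert_allclose(sim.system.pos[0, 2], 0.5 * 2.5 * t * t,
                                   rtol=1e-12)
        np.testing.assert_allclose(sim.system.vel[0, 2], 2.5 * t, rtol=1e-12)

    def test_harmonic_oscillator_energy_drift(self):
        # omega = 1, dt = 0.01: symplectic integrator keeps energy bounded
        sim = _free_sim(np.array([[1.0, 0.0, 0.0]]), np.zeros((1, 3)), dt=0.01,
                        force=lambda s: -s.system.pos)
        e0 = 0.5
        for _ in range(100):
            sim.run(100)
            e = 0.5 * np.sum(sim.system.vel ** 2) + 0.5 * np.sum(sim.system.pos ** 2)
            assert abs(e - e0) / e0 < 1e-4

    def test_wall_particles_not_integrated(self):
        ps = ParticleSystem(np.zeros((1, 3)), vel=[[1.0, 0, 0]],
                            species=[Species.WALL])
        sim = Simulation(ps, lambda s: np.ones((1, 3)),
                         clock=SimClock(dt=0.01, seed=0))
        sim.run(5)
        np.testing.assert_array_equal(ps.pos, np.zeros((1, 3)))

    def test_nonfinite_state_aborts(self):
        sim = _free_sim(np.zeros((1, 3)), np.zeros((1, 3)),
                        force=lambda s: np.full((1, 3), np.nan))
        with pytest.raises(FloatingPointError, match="non-finite"):
            sim.step()


class TestConservationAndDeterminism:
    def test_momentum_conserved_conservative_periodic(self, rng):
        edge = 5.0
        params = DPDParams(g=0.0)
        n = int(params.n * edge ** 3)
        pos = rng.uniform(0, edge, (n, 3))
        vel = rng.normal(0, 0.1, (n, 3))
        vel -= vel.mean(axis=0)
        ps = ParticleSystem(pos, vel=vel, box=[edge] * 3,
                            periodic=(True, True, True))
        fm = ForceModel(params, one_way=False, thermostat=False)
        sim = Simulation(ps, fm, clock=SimClock(dt=0.005, seed=3))
        sim.add_hook(lambda s: np.mod(s.system.pos, edge, out=s.system.pos))
        p0 = ps.vel.sum(axis=0)
        sim.run(1000)
        np.testing.assert_allclose(ps.vel.sum(axis=0), p0, atol=1e-9)

    def test_bitwise_reproducibility(self, rng):
        edge = 4.0
        params = DPDParams()

        def make():
            r = np.random.default_rng(77)
            pos = r.uniform(0, edge, (int(params.n * edge ** 3), 3))
            ps = ParticleSystem(pos, box=[edge] * 3, periodic=(True,) * 3)
            sim = Simulation(ps, ForceModel(params, one_way=False),
                             clock=SimClock(dt=0.005, seed=42))
            sim.add_hook(lambda s: np.mod(s.system.pos, edge,
                                          out=s.system.pos))
            sim.run(50)
            return ps

        a, b = make(), make()
        np.testing.assert_array_equal(a.pos, b.pos)
        np.testing.assert_array_equal(a.vel, b.vel)
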