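"""Particle state container, neighbor search and velocity-Verlet integration.

All quantities are in reduced (DPD) units with unit particle mass.  The
:class:`ParticleSystem` is a structure-of-arrays container shared by every
other module; forces are recomputed from scratch each step by a force model
callable, and open-boundary bookkeeping runs as post-drift hooks in a fixed
order (see :mod:`hemoflow.obc`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Species",
    "Region",
    "ParticleSystem",
    "SimClock",
    "Simulation",
    "build_neighbor_pairs",
    "minimum_image",
]


class Species(IntEnum):
    """Particle species tags."""

    FLUID = 0
    WALL = 1
    MEMBRANE = 2
    GHOST = 3
    SLAVED = 4


class Region(IntEnum):
    """Region tags relative to the open-boundary layout."""

    GENERATING = 0
    MAIN = 1
    DELETION = 2


#: species that are advanced by the integrator
MOVABLE = (Species.FLUID, Species.MEMBRANE)


class ParticleSystem:
    """Structure-of-arrays particle container.

    Parameters
    ----------
    pos, vel : (N, 3) float arrays
    species : (N,) int array of :class:`Species` values
    cell_id : (N,) int array, ``-1`` for particles not belonging to a cell
    region : (N,) int array of :class:`Region` values
    box : (3,) float array or None
        Edge lengths of the bounding box used for periodic wrapping.
    periodic : (3,) bool array
        Which dimensions are treated periodically.
    """

    def __init__(self, pos, vel=None, species=None, cell_id=None, region=None,
                 box=None, periodic=(False, False, False)):
        pos = np.atleast_2d(np.asarray(pos, dtype=np.float64))
        n = len(pos)
        self.pos = pos.copy()
        self.vel = (np.zeros((n, 3)) if vel is None
                    else np.asarray(vel, dtype=np.float64).copy())
        self.force = np.zeros((n, 3))
        self.species = (np.full(n, Species.FLUID, dtype=np.int8) if species is None
                        else np.asarray(species, dtype=np.int8).copy())
        self.cell_id = (np.full(n, -1, dtype=np.int32) if cell_id is None
                        else np.asarray(cell_id, dtype=np.int32).copy())
        self.region = (np.full(n, Region.MAIN, dtype=np.int8) if region is None
                       else np.asarray(region, dtype=np.int8).copy())
        self.box = None if box is None else np.asarray(box, dtype=np.float64)
        self.periodic = np.asarray(periodic, dtype=bool)
        self._validate()

    def _validate(self):
        n = self.n
        for name in ("vel", "force"):
            if getattr(self, name).shape != (n, 3):
                raise ValueError(f"{name} has wrong shape")
        for name in ("species", "cell_id", "region"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} has wrong length")
        if np.any((self.species == Species.MEMBRANE) & (self.cell_id < 0)):
            raise ValueError("membrane vertices must carry a cell id")

    @property
    def n(self) -> int:
        return len(self.pos)

    def movable_mask(self) -> np.ndarray:
        return (self.species == Species.FLUID) | (self.species == Species.MEMBRANE)

    def add(self, pos, vel=None, species=Species.FLUID, cell_id=-1,
            region=Region.MAIN) -> np.ndarray:
        """Append particles; returns the indices of the new particles."""
        pos = np.atleast_2d(np.asarray(pos, dtype=np.float64))
        k = len(pos)
        if k == 0:
            return np.empty(0, dtype=np.int64)
        vel = np.zeros((k, 3)) if vel is None else np.atleast_2d(np.asarray(vel, float))
        start = self.n
        self.pos = np.concatenate([self.pos, pos])
        self.vel = np.concatenate([self.vel, vel])
        self.force = np.concatenate([self.force, np.zeros((k, 3))])
        self.species = np.concatenate(
            [self.species, np.broadcast_to(np.int8(species), k)])
        self.cell_id = np.concatenate(
            [self.cell_id, np.broadcast_to(np.int32(cell_id), k)])
        self.region = np.concatenate(
            [self.region, np.broadcast_to(np.int8(region), k)])
        return np.arange(start, start + k)

    def remove(self, idx) -> np.ndarray:
        """Delete particles by index.

        Returns an (N_old,) remap array: old index -> new index, -1 for
        removed particles.  Callers holding particle indices (cell
        topologies, slaved-duplicate maps) must apply the remap.
        """
        idx = np.asarray(idx, dtype=np.int64)
        keep = np.ones(self.n, dtype=bool)
        keep[idx] = False
        remap = np.full(self.n, -1, dtype=np.int64)
        remap[keep] = np.arange(int(keep.sum()))
        for name in ("pos", "vel", "force", "species", "cell_id", "region"):
            setattr(self, name, getattr(self, name)[keep])
        return remap


@dataclass
class SimClock:
    """Timestep, step counter and master seed (reproducibility contract)."""

    dt: float = 0.005
    step: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def time(self) -> float:
        return self.step * self.dt


def minimum_image(dr: np.ndarray, box, periodic) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors in place."""
    if box is None or not np.any(periodic):
        return dr
    for d in range(3):
        if periodic[d]:
            dr[:, d] -= box[d] * np.round(dr[:, d] / box[d])
    return dr


def build_neighbor_pairs(pos, cutoff, box=None, periodic=(False, False, False),
                         origin=(0.0, 0.0, 0.0)):
    """All unordered particle pairs with separation below ``cutoff``.

    Periodicity is honoured (minimum image) only in the flagged dimensions.
    Implemented with a k-d tree over the real particles plus halo images of
    particles within ``cutoff`` of a periodic face.

    Returns ``(i, j, dr)`` where ``dr = pos[i] - pos[j]`` is the
    minimum-image displacement.
    """
    pos = np.asarray(pos, dtype=np.float64)
    periodic = np.asarray(periodic, dtype=bool)
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = len(pos)
    if n < 2:
        e = np.empty(0, dtype=np.int64)
        return e, e.copy(), np.empty((0, 3))
    if np.any(periodic):
        box = np.asarray(box, dtype=np.float64)
        for d in np.nonzero(periodic)[0]:
            if cutoff > 0.5 * box[d]:
                raise ValueError(
                    f"cutoff {cutoff} exceeds half the periodic box edge {box[d]}")
        origin = np.asarray(origin, dtype=np.float64)
        pts = [pos]
        src = [np.arange(n)]
        # halo images: replicate particles near periodic faces by every
        # combination of +/- box shifts in the periodic dimensions
        shifts = [np.zeros(3)]
        for d in np.nonzero(periodic)[0]:
            new = []
            for s in shifts:
                for sign in (-1.0, 1.0):
                    sh = s.copy()
                    sh[d] += sign * box[d]
                    new.append(sh)
            shifts.extend(new)
        lo = np.where(periodic, origin - cutoff, -np.inf)
        hi = np.where(periodic, origin + box + cutoff, np.inf)
        for sh in shifts[1:]:
            img = pos + sh
            inside = np.all((img > lo) & (img < hi), axis=1)
            # only keep images that can reach a real particle
            if np.any(inside):
                pts.append(img[inside])
                src.append(np.nonzero(inside)[0])
        allpts = np.concatenate(pts)
        allsrc = np.concatenate(src)
        tree = cKDTree(allpts)
        raw = tree.query_pairs(cutoff, output_type="ndarray")
        if len(raw) == 0:
            e = np.empty(0, dtype=np.int64)
            return e, e.copy(), np.empty((0, 3))
        # Every minimum-image pair has a representation with at least one
        # real member, so image-image pairs are dropped.  A cross pair
        # (real i, image of j) also appears as (real j, image of i); keep
        # only the orientation where the real member's source index is the
        # smaller, which selects exactly one of the two.
        t0, t1 = raw[:, 0], raw[:, 1]
        real0, real1 = t0 < n, t1 < n
        s0, s1 = allsrc[t0], allsrc[t1]
        both = real0 & real1
        mixed = real0 ^ real1
        real_src = np.where(real0, s0, s1)
        img_src = np.where(real0, s1, s0)
        keep = both | (mixed & (real_src < img_src))
        t0, t1 = t0[keep], t1[keep]
        i, j = allsrc[t0], allsrc[t1]
        dr = allpts[t0] - allpts[t1]
        return i.astype(np.int64), j.astype(np.int64), dr
    tree = cKDTree(pos)
    raw = tree.query_pairs(cutoff, output_type="ndarray")
    if len(raw) == 0:
        e = np.empty(0, dtype=np.int64)
        return e, e.copy(), np.empty((0, 3))
    i, j = raw[:, 0].astype(np.int64), raw[:, 1].astype(np.int64)
    return i, j, pos[i] - pos[j]


class Simulation:
    """Velocity-Verlet driver with a fixed post-drift hook pipeline.

    ``force_model(sim)`` must return an ``(N, 3)`` force array for the
    current particle set.  Hooks are callables ``hook(sim)`` executed after
    the drift, in the order they were registered; the open-boundary modules
    register themselves here (integrate -> bounce-back -> dissolution ->
    outflow membrane -> controller -> duplication -> ghost regeneration).
    Wall, ghost and slaved particles are never integrated.
    """

    def __init__(self, system: ParticleSystem, force_model,
                 clock: SimClock | None = None, seed: int = 0, dt: float = 0.005):
        self.system = system
        self.force_model = force_model
        self.clock = clock if clock is not None else SimClock(dt=dt, seed=seed)
        ss = np.random.SeedSequence(self.clock.seed)
        kids = ss.spawn(4)
        # independent streams so toggling one subsystem leaves the others'
        # draws untouched
        self.rng = {
            "thermostat": np.random.Generator(np.random.Philox(kids[0])),
            "membrane": np.random.Generator(np.random.Philox(kids[1])),
            "outflow": np.random.Generator(np.random.Philox(kids[2])),
            "packing": np.random.Generator(np.random.Philox(kids[3])),
        }
        self.hooks: list[Callable[["Simulation"], None]] = []
        self.prev_pos: np.ndarray | None = None
        self._forces_valid = False

    def add_hook(self, hook) -> None:
        self.hooks.append(hook)

    def compute_forces(self) -> None:
        self.system.force = self.force_model(self)
        self._forces_valid = True

    def step(self) -> None:
        ps = self.system
        if not self._forces_valid:
            self.compute_forces()
        mov = ps.movable_mask()
        dt = self.clock.dt
        ps.vel[mov] += 0.5 * dt * ps.force[mov]
        self.prev_pos = ps.pos.copy()
        ps.pos[mov] += dt * ps.vel[mov]
        for hook in self.hooks:
            hook(self)
        self.compute_forces()
        mov = ps.movable_mask()  # hooks may have added/removed particles
        ps.vel[mov] += 0.5 * dt * ps.force[mov]
        self.clock.step += 1
        if not (np.all(np.isfinite(ps.pos[mov])) and np.all(np.isfinite(ps.vel[mov]))):
            bad = np.nonzero(~np.isfinite(ps.pos).all(axis=1)
                             | ~np.isfinite(ps.vel).all(axis=1))[0]
            raise FloatingPointError(
                f"non-finite state at step {self.clock.step} "
                f"(first bad particle {bad[0] if len(bad) else '?'}; "
                "timestep too large or overlapping particles)")

    def run(self, nsteps: int, callback=None, callback_every: int = 1) -> None:
        for k in range(nsteps):
            self.step()
            if callback is not None and (self.clock.step % callback_every == 0):
                callback(self)
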