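"""Open boundary conditions: generating region, copy-border duplication,
adaptive probabilistic outflow membrane and cell dissolution.

The flow axis of the generating region is z.  The generating region
occupies ``z in [0, gen_len)`` and runs as an independent periodic
subsystem: its z-periodicity is realised with ghost particles (zones A1/A4
hold images of zones A3/A2), and one-way coupling removes every force a
main-domain particle would exert on a generating-region particle while
keeping the reverse.  Particles crossing the copy border (``z = gen_len``)
are duplicated into the main domain; whole cells are duplicated once their
center of mass crosses, and the duplicate is slaved to the original until it
lies fully inside the main domain.  At each outlet an adaptive reflecting
membrane removes crossing particles with probability ``P`` (reflecting them
otherwise), with ``P`` driven toward the target density by the increment
``dP = h |rho - rho_target| / rho_target``.
"""

from __future__ import annotations

import logging
import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .core import ParticleSystem, Region, Simulation, Species, minimum_image
from .geometry import OutletPlane, WallGeometry, bounce_back
from .membrane import (CellTopology, MembraneParams, SpringWienerIncrement,
                       area_volume_forces, bending_forces, elastic_forces,
                       membrane_viscous_forces, mesh_volume)

log = logging.getLogger(__name__)

__all__ = ["ObcLayout", "OutflowController", "SlavedDuplicate", "CellManager",
           "ObcPipeline", "update_outflow_probability", "outflow_membrane",
           "one_way_weights", "regenerate_ghosts"]


@dataclass
class ObcLayout:
    """Geometric planes and zones of the open-boundary decomposition.

    ``zone_width`` is the maximum of all interaction cutoffs; the copy
    border coincides with the downstream face of the generating region.

    Each outlet consists of a particle-deletion (drain) region of length
    ``drain_len`` ending at the outflow-membrane plane (``outlets``).  The
    drain keeps the membrane's contact-density artifact and the cell
    dissolution zone outside the measured main domain: fluid crossing into
    the drain still interacts normally and supplies conservative
    back-pressure at the main-domain boundary (``main_planes``), which a
    bare reflecting membrane cannot (it only returns the kinetic momentum
    flux, a small fraction of the DPD fluid's pressure).
    """

    gen_len: float
    zone_width: float
    outlets: list[OutletPlane] = field(default_factory=list)
    drain_len: float = 6.0

    def __post_init__(self):
        if self.gen_len < 2.0 * self.zone_width:
            raise ValueError("generating region shorter than twice the zone width")
        if self.drain_len < 0:
            raise ValueError("drain length must be non-negative")
        self.main_planes = [
            OutletPlane(o.origin - self.drain_len * o.normal, o.normal,
                        branch=o.branch)
            for o in self.outlets]

    @property
    def copy_border(self) -> float:
        return self.gen_len


@dataclass
class OutflowController:
    """Per-outlet adaptive removal probability.

    ``P`` is the *removal* probability (particles are reflected with
    probability ``1 - P``), updated each step by
    ``dP = h |rho_current - rho_target| / rho_target`` toward the sign that
    restores the target density, and clamped to [0, 1].  The measured
    density is smoothed over ``window`` steps before use.
    """

    rho_target: float
    h: float = 0.05
    P: float = 0.5
    window: int = 100
    update_every: int = 1
    _hist: deque = field(default_factory=deque, repr=False)
    _calls: int = field(default=0, repr=False)

    def __post_init__(self):
        if self.rho_target <= 0:
            raise ValueError("rho_target must be positive")
        if self.h <= 0:
            raise ValueError("gain h must be positive")
        if self.update_every < 1:
            raise ValueError("update_every must be >= 1")
        self.P = float(np.clip(self.P, 0.0, 1.0))

    def smoothed(self, rho_current: float) -> float:
        self._hist.append(rho_current)
        while len(self._hist) > self.window:
            self._hist.popleft()
        return float(np.mean(self._hist))

    def update(self, rho_current: float) -> float:
        """Record a density sample; apply the dP rule every
        ``update_every`` samples (one controller iteration = one control
        interval; desk-scale domains need intervals >> 1 step or the
        controller traverses its whole authority range far faster than the
        density can respond and bang-bangs)."""
        rho = self.smoothed(rho_current)
        self._calls += 1
        if self._calls % self.update_every == 0:
            self.P = update_outflow_probability(self.P, rho, self.rho_target,
                                                self.h)
        return self.P


def update_outflow_probability(P: float, rho_current: float, rho_target: float,
                               h: float = 0.05) -> float:
    """One controller update with increment ``dP = h |rho - rho_t| / rho_t``.

    ``P`` is the removal probability; when the measured density is at or
    below target the membrane must retain more particles, so ``P``
    decreases by ``dP`` (equivalently: the reflection probability ``1 - P``
    increases by ``dP``), and vice versa.  The result is clamped to [0, 1].
    """
    if rho_target <= 0:
        raise ValueError("rho_target must be positive")
    dP = h * abs(rho_current - rho_target) / rho_target
    P = P - dP if rho_current <= rho_target else P + dP
    return float(np.clip(P, 0.0, 1.0))


def outflow_membrane(system: ParticleSystem, plane: OutletPlane, P: float,
                     rng: np.random.Generator, eligible: np.ndarray):
    """Probabilistic membrane at an outflow plane.

    Eligible particles beyond the plane are removed with probability ``P``
    and specularly reflected back (position mirrored, normal velocity
    negated) otherwise.  Returns ``(removed_indices, n_reflected)``; the
    caller performs the actual deletion.
    """
    idx = np.nonzero(eligible)[0]
    if len(idx) == 0:
        return np.empty(0, dtype=np.int64), 0
    s = plane.signed(system.pos[idx])
    crossing = idx[s > 0.0]
    if len(crossing) == 0:
        return np.empty(0, dtype=np.int64), 0
    u = rng.random(len(crossing))
    remove = crossing[u < P]
    reflect = crossing[u >= P]
    if len(reflect):
        sr = plane.signed(system.pos[reflect])
        system.pos[reflect] -= 2.0 * sr[:, None] * plane.normal
        vn = system.vel[reflect] @ plane.normal
        system.vel[reflect] -= 2.0 * vn[:, None] * plane.normal
    return remove, int(len(reflect))


def one_way_weights(gen_side_i: np.ndarray, gen_side_j: np.ndarray):
    """Force-application weights implementing one-way coupling.

    For a pair crossing the copy border the force is applied only to the
    main-domain member; the generating-region member receives nothing.
    """
    wi = np.where(gen_side_i & ~gen_side_j, 0.0, 1.0)
    wj = np.where(gen_side_j & ~gen_side_i, 0.0, 1.0)
    return wi, wj


@dataclass
class SlavedDuplicate:
    """Bookkeeping for a copy-border cell duplicate slaved to its original."""

    master_id: int
    dup_id: int
    offset: np.ndarray
    active: bool = True


class _Cell:
    """A managed cell: local-topology mesh + global particle indices."""

    def __init__(self, topo: CellTopology, verts: np.ndarray, periodic: bool):
        self.topo = topo
        self.verts = np.asarray(verts, dtype=np.int64)
        self.periodic = periodic          # lives in the periodic generating region
        self.com_z = 0.0                  # unwrapped COM (periodic cells only)
        self.slaved: SlavedDuplicate | None = None   # set on the *duplicate*


class CellManager:
    """Owns every cell mesh, computes membrane forces, tracks duplications.

    ``period_z`` is the z-period of the periodic subdomain (the generating
    region length, or the box length for a fully periodic run).  Cells
    flagged periodic have their bonded geometry evaluated on coordinates
    unwrapped with the minimum-image convention along z.
    """

    def __init__(self, params: MembraneParams, period_z: float | None = None):
        self.params = params
        self.period_z = period_z
        self.cells: dict[int, _Cell] = {}
        self._next = 0

    def new_id(self) -> int:
        self._next += 1
        return self._next

    def add_cell(self, topo: CellTopology, verts: np.ndarray,
                 periodic: bool = False, cell_id: int | None = None) -> int:
        cid = self.new_id() if cell_id is None else cell_id
        if cid in self.cells:
            raise ValueError(f"cell id {cid} already in use")
        self._next = max(self._next, cid)  # keep new_id() collision-free
        cell = _Cell(topo, verts, periodic)
        self.cells[cid] = cell
        return cid

    def unwrapped(self, ps: ParticleSystem, cell: _Cell) -> np.ndarray:
        x = ps.pos[cell.verts].copy()
        if cell.periodic and self.period_z:
            Lz = self.period_z
            dz = x[:, 2] - cell.com_z
            x[:, 2] = cell.com_z + dz - Lz * np.round(dz / Lz)
        return x

    def track_coms(self, ps: ParticleSystem) -> list[int]:
        """Update unwrapped COMs of periodic cells; return ids that crossed
        the downstream period boundary this step (copy-border crossings)."""
        crossed = []
        for cid, cell in self.cells.items():
            if not cell.periodic or cell.slaved is not None:
                continue
            x = self.unwrapped(ps, cell)
            com = float(x[:, 2].mean())
            if com >= self.period_z:
                com -= self.period_z
                crossed.append(cid)
            elif com < 0.0:
                com += self.period_z
            cell.com_z = com
        return crossed

    def compute_forces(self, sim: Simulation, out: np.ndarray) -> None:
        ps = sim.system
        dt = sim.clock.dt
        rng = sim.rng["membrane"]
        for cid in sorted(self.cells):
            cell = self.cells[cid]
            if cell.slaved is not None:
                continue  # slaved duplicates mirror their master; no dynamics
            x = self.unwrapped(ps, cell)
            v = ps.vel[cell.verts]
            f, _ = elastic_forces(x, cell.topo, self.params)
            fb, _ = bending_forces(x, cell.topo, self.params)
            fav, _, _ = area_volume_forces(x, cell.topo, self.params)
            inc = SpringWienerIncrement.draw(cell.topo.n_springs, dt, rng)
            fv = membrane_viscous_forces(x, v, cell.topo, self.params, dt,
                                         increments=inc)
            np.add.at(out, cell.verts, f + fb + fav + fv)

    def remap(self, remap: np.ndarray) -> None:
        for cell in self.cells.values():
            new = remap[cell.verts]
            if np.any(new < 0):
                raise RuntimeError("a membrane vertex was deleted")
            cell.verts = new

    def dissolve(self, ps: ParticleSystem, cid: int) -> np.ndarray:
        """Destroy a cell's topology, leaving its particles in place as fluid."""
        cell = self.cells.pop(cid)
        ps.species[cell.verts] = Species.FLUID
        ps.cell_id[cell.verts] = -1
        return cell.verts


class ObcPipeline:
    """Post-drift hook implementing the full open-boundary step.

    Order: bounce-back -> backflow cleanup/region retag -> cell dissolution
    -> outflow membrane -> controller update -> fluid/cell duplication ->
    ghost regeneration.
    """

    def __init__(self, geometry: WallGeometry, layout: ObcLayout,
                 controllers: list[OutflowController],
                 cell_manager: CellManager | None = None,
                 main_volume: float | None = None):
        self.geometry = geometry
        self.layout = layout
        self.controllers = controllers
        self.cells = cell_manager
        if len(controllers) != len(layout.outlets):
            raise ValueError("one controller per outlet required")
        if main_volume is None:
            main_volume = self._measure_main_volume()
        self.main_volume = main_volume
        self.slaved: list[SlavedDuplicate] = []
        # diagnostics
        self.inserted = 0
        self.removed = [0] * len(layout.outlets)
        self.backflow_absorbed = 0
        self.exit_log: list[tuple[int, int, int]] = []  # (step, branch, cell_id)
        self.controller_log: list[tuple] = []
        self.rho_current = float("nan")

    def _measure_main_volume(self) -> float:
        geo, lay = self.geometry, self.layout
        rng = np.random.Generator(np.random.Philox(11))
        lo, hi = geo.bounds()
        lo = lo.copy()
        lo[2] = max(lo[2], lay.gen_len)
        n = 200_000
        pts = rng.uniform(lo, hi, size=(n, 3))
        inside = geo.sdf(pts) > 0
        for plane in lay.main_planes:
            inside &= plane.signed(pts) <= 0
        return float(np.mean(inside)) * float(np.prod(hi - lo))

    # -- individual stages ------------------------------------------------

    def retag(self, ps: ParticleSystem) -> None:
        mov = ps.movable_mask() | (ps.species == Species.SLAVED)
        not_gen = mov & (ps.region != Region.GENERATING)
        idx = np.nonzero(not_gen)[0]
        if len(idx) == 0:
            return
        region = np.full(len(idx), Region.MAIN, dtype=np.int8)
        for plane in self.layout.main_planes:
            region[plane.signed(ps.pos[idx]) > 0] = Region.DELETION
        ps.region[idx] = region

    def remove_particles(self, sim: Simulation, idx: np.ndarray) -> None:
        if len(idx) == 0:
            return
        remap = sim.system.remove(idx)
        if self.cells is not None:
            self.cells.remap(remap)
        if sim.prev_pos is not None and len(sim.prev_pos) == len(remap):
            keep = remap >= 0
            sim.prev_pos = sim.prev_pos[keep]

    def backflow_absorb(self, sim: Simulation) -> None:
        """Delete main-domain fluid that crosses upstream of the copy border.

        The copy border is a flux-exchange surface with the generating
        region acting as an infinite reservoir: every downstream crossing
        of a generating particle inserts a duplicate (thermal crossings
        included), so the matching upstream thermal flux of main-domain
        particles must be absorbed, or the border would inject roughly
        twice the physical net flux into the main domain."""
        ps = sim.system
        bad = ((ps.species == Species.FLUID) & (ps.region != Region.GENERATING)
               & (ps.pos[:, 2] < self.layout.copy_border))
        if np.any(bad):
            self.backflow_absorbed += int(bad.sum())
            self.remove_particles(sim, np.nonzero(bad)[0])

    def dissolve_cells(self, sim: Simulation) -> None:
        if self.cells is None:
            return
        ps = sim.system
        for cid, cell in list(self.cells.cells.items()):
            if cell.periodic or cell.slaved is not None:
                continue
            pos = ps.pos[cell.verts]
            for plane in self.layout.main_planes:
                if np.all(plane.signed(pos) > 0.0):
                    self.cells.dissolve(ps, cid)
                    self.exit_log.append((sim.clock.step, plane.branch, cid))
                    break

    def apply_outflow(self, sim: Simulation) -> None:
        ps = sim.system
        eligible = (ps.species == Species.FLUID) & (ps.region != Region.GENERATING)
        for k, (outlet, ctl) in enumerate(zip(self.layout.outlets,
                                              self.controllers)):
            removed, _ = outflow_membrane(ps, outlet, ctl.P,
                                          sim.rng["outflow"], eligible)
            if len(removed):
                self.removed[k] += len(removed)
                self.remove_particles(sim, removed)
                eligible = ((ps.species == Species.FLUID)
                            & (ps.region != Region.GENERATING))

    def update_controllers(self, sim: Simulation) -> None:
        """Measure the main-domain number density (particles positioned
        between the copy border and the main-domain boundary planes) and
        update every outlet controller."""
        ps = sim.system
        inside = (((ps.species == Species.FLUID)
                   | (ps.species == Species.MEMBRANE))
                  & (ps.pos[:, 2] >= self.layout.copy_border))
        for plane in self.layout.main_planes:
            inside &= plane.signed(ps.pos) <= 0
        self.rho_current = int(inside.sum()) / self.main_volume
        row = [sim.clock.step, self.rho_current]
        for ctl in self.controllers:
            row.append(ctl.update(self.rho_current))
        self.controller_log.append(tuple(row))

    def duplicate_fluid(self, sim: Simulation) -> None:
        ps = sim.system
        Lg = self.layout.gen_len
        gen = ps.region == Region.GENERATING
        gen_fluid = gen & (ps.species == Species.FLUID)
        crossing = gen_fluid & (ps.pos[:, 2] >= Lg)
        idx = np.nonzero(crossing)[0]
        if len(idx):
            ps.add(ps.pos[idx], vel=ps.vel[idx], species=Species.FLUID,
                   region=Region.MAIN)
            self.inserted += len(idx)
        # periodic wrap of every generating-region mover (membrane vertices wrap
        # individually; their bonded terms use minimum-image coordinates)
        gen_mov = (ps.region == Region.GENERATING) & ps.movable_mask()
        z = ps.pos[gen_mov, 2]
        ps.pos[gen_mov, 2] = np.mod(z, Lg)

    def duplicate_cells(self, sim: Simulation) -> None:
        if self.cells is None:
            return
        ps = sim.system
        Lg = self.layout.gen_len
        crossed = self.cells.track_coms(ps)
        for cid in crossed:
            # release-or-warn if a previous duplicate of this master is still slaved
            for sl in self.slaved:
                if sl.active and sl.master_id == cid:
                    warnings.warn("new transit before previous duplicate was "
                                  "released; forcing release", RuntimeWarning)
                    self._release(ps, sl)
            cell = self.cells.cells[cid]
            x = self.cells.unwrapped(ps, cell)
            offset = np.array([0.0, 0.0, Lg])
            dup_id = self.cells.new_id()
            verts = ps.add(x + offset, vel=ps.vel[cell.verts],
                           species=Species.SLAVED, cell_id=dup_id,
                           region=Region.MAIN)
            topo = CellTopology(springs=cell.topo.springs,
                                triangles=cell.topo.triangles,
                                dihedrals=cell.topo.dihedrals,
                                A0=cell.topo.A0, V0=cell.topo.V0,
                                n_verts=cell.topo.n_verts)
            self.cells.add_cell(topo, verts, periodic=False, cell_id=dup_id)
            sl = SlavedDuplicate(master_id=cid, dup_id=dup_id, offset=offset)
            self.cells.cells[dup_id].slaved = sl
            self.slaved.append(sl)

    def _release(self, ps: ParticleSystem, sl: SlavedDuplicate) -> None:
        dup = self.cells.cells[sl.dup_id]
        ps.species[dup.verts] = Species.MEMBRANE
        dup.slaved = None
        sl.active = False

    def update_slaved(self, sim: Simulation) -> None:
        if self.cells is None:
            return
        ps = sim.system
        for sl in self.slaved:
            if not sl.active:
                continue
            master = self.cells.cells.get(sl.master_id)
            dup = self.cells.cells[sl.dup_id]
            x = self.cells.unwrapped(ps, master)
            ps.pos[dup.verts] = x + sl.offset
            ps.vel[dup.verts] = ps.vel[master.verts]
            if np.all(ps.pos[dup.verts, 2] > self.layout.copy_border):
                self._release(ps, sl)
        self.slaved = [sl for sl in self.slaved if sl.active]

    def regenerate_ghosts(self, sim: Simulation) -> None:
        regenerate_ghosts(sim, self.layout, self)

    # -- the hook ---------------------------------------------------------

    def __call__(self, sim: Simulation) -> None:
        ps = sim.system
        bounce_back(ps, sim.prev_pos, self.geometry)
        self.backflow_absorb(sim)
        self.retag(ps)
        self.dissolve_cells(sim)
        self.apply_outflow(sim)
        self.update_controllers(sim)
        self.duplicate_fluid(sim)
        self.duplicate_cells(sim)
        self.update_slaved(sim)
        self.regenerate_ghosts(sim)


def regenerate_ghosts(sim: Simulation, layout: ObcLayout,
                      pipeline: ObcPipeline | None = None) -> int:
    """Rebuild the ghost images of the generating region's periodic seam.

    Particles in zone A2 (``z in [0, w)``) are imaged into zone A4
    (``z in [gen_len, gen_len + w)``) and particles in zone A3
    (``z in [gen_len - w, gen_len)``) into zone A1 (``z in [-w, 0)``).
    Ghosts carry the source velocity and cell id, exert forces on
    generating-region particles only, and are never integrated.
    """
    ps = sim.system
    old = np.nonzero(ps.species == Species.GHOST)[0]
    if len(old):
        remap = ps.remove(old)
        if pipeline is not None and pipeline.cells is not None:
            pipeline.cells.remap(remap)
        if sim.prev_pos is not None and len(sim.prev_pos) == len(remap):
            sim.prev_pos = sim.prev_pos[remap >= 0]
    w = layout.zone_width
    Lg = layout.gen_len
    gen_mov = (ps.region == Region.GENERATING) & ps.movable_mask()
    z = ps.pos[:, 2]
    n_new = 0
    for sel, shift in (((gen_mov & (z < w)), Lg),
                       ((gen_mov & (z >= Lg - w)), -Lg)):
        idx = np.nonzero(sel)[0]
        if len(idx) == 0:
            continue
        pos = ps.pos[idx].copy()
        pos[:, 2] += shift
        new = ps.add(pos, vel=ps.vel[idx], species=Species.GHOST,
                     region=Region.GENERATING)
        ps.cell_id[new] = ps.cell_id[idx]
        n_new += len(idx)
    return n_new
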