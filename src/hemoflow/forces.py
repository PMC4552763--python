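"""Composition of all force contributions into one force model.

Pair interactions (DPD) are computed over a single neighbor-pair list and
filtered by species/region masks:

* wall-wall and ghost-ghost pairs are dropped;
* ghost particles interact with generating-region particles only (they
  realise the generating region's internal periodicity);
* same-cell membrane vertex pairs are excluded (bonded terms cover them);
* cross-cell membrane contacts use the conservative repulsion only;
* pairs crossing the copy border apply force to the main-domain member
  only (one-way coupling).

Membrane bonded forces come from the :class:`~hemoflow.obc.CellManager`;
the body force drives fluid and membrane particles along the local flow
axis with optional per-branch multipliers.
"""

from __future__ import annotations

import numpy as np

from .core import Region, Simulation, Species, build_neighbor_pairs
from .dpd import DPDParams, pair_forces_arrays
from .geometry import WallGeometry
from .kernels import pair_forces_fused
from .obc import CellManager, one_way_weights

__all__ = ["ForceModel", "BodyForce"]


class BodyForce:
    """Constant per-particle driving force of magnitude ``g`` along the
    geometry's local flow axis, with optional per-branch multipliers.

    ``z_max`` restricts the drive to particles with ``z < z_max`` (used to
    drive only the generating region, leaving the main domain
    pressure-fed by the inflow, which reproduces the analytic
    ``dP/dz = 16 v_max eta / d^2 = n g`` pressure profile downstream).
    """

    def __init__(self, g: float, geometry: WallGeometry | None = None,
                 branch_factors: dict[int, float] | None = None,
                 z_max: float | None = None):
        self.g = g
        self.geometry = geometry
        self.branch_factors = dict(branch_factors or {})
        self.z_max = z_max

    def __call__(self, ps) -> np.ndarray:
        f = np.zeros_like(ps.pos)
        if self.g == 0.0:
            return f
        mov = ps.movable_mask()
        if self.z_max is not None:
            mov &= ps.pos[:, 2] < self.z_max
        if self.geometry is None:
            f[mov, 2] = self.g
            return f
        dirs = self.geometry.drive_direction(ps.pos[mov])
        mag = np.full(int(mov.sum()), self.g)
        if self.branch_factors and hasattr(self.geometry, "branch_id"):
            bid = self.geometry.branch_id(ps.pos[mov])
            for b, fac in self.branch_factors.items():
                mag[bid == b] *= fac
        f[mov] = mag[:, None] * dirs
        return f


class ForceModel:
    """Callable returning the total force array for the current particle set."""

    def __init__(self, params: DPDParams, cell_manager: CellManager | None = None,
                 body_force: BodyForce | None = None, thermostat: bool = True,
                 one_way: bool = True):
        self.params = params
        self.cells = cell_manager
        self.body_force = body_force
        self.thermostat = thermostat
        self.one_way = one_way
        self._wall_cache = None

    def _wall_pairs(self, ps, mov_idx: np.ndarray):
        """Mover-wall pairs against a cached static wall tree.

        Wall particles never move, are created before all other particles
        and are never deleted, so their indices and the tree stay valid for
        the lifetime of a scenario.  Under z-periodicity the tree includes
        wall images within one cutoff of the periodic faces.
        """
        from scipy.spatial import cKDTree

        wall_idx = np.nonzero(ps.species == Species.WALL)[0]
        if len(wall_idx) == 0:
            e = np.empty(0, dtype=np.int64)
            return e, e.copy(), np.empty((0, 3))
        cache = self._wall_cache
        if cache is None or cache["n"] != len(wall_idx):
            wpts = ps.pos[wall_idx]
            wsrc = wall_idx.copy()
            if ps.box is not None and ps.periodic[2]:
                Lz = ps.box[2]
                for shift in (Lz, -Lz):
                    z = wpts[: len(wall_idx), 2] + shift
                    sel = (z > -self.params.r_c) & (z < Lz + self.params.r_c)
                    if np.any(sel):
                        img = ps.pos[wall_idx[sel]].copy()
                        img[:, 2] += shift
                        wpts = np.concatenate([wpts, img])
                        wsrc = np.concatenate([wsrc, wall_idx[sel]])
            cache = self._wall_cache = {
                "n": len(wall_idx), "tree": cKDTree(wpts),
                "pts": wpts, "src": wsrc}
        tm = cKDTree(ps.pos[mov_idx])
        hits = tm.sparse_distance_matrix(cache["tree"], self.params.r_c,
                                         output_type="ndarray")
        i = mov_idx[hits["i"]]
        j = cache["src"][hits["j"]]
        dr = ps.pos[i] - cache["pts"][hits["j"]]
        return i, j, dr

    def _kernel_supported(self, ps) -> bool:
        if pair_forces_fused is None:
            return False
        if ps.box is None or not np.any(ps.periodic):
            return True
        if ps.periodic[0] or ps.periodic[1]:
            return False
        # periodic z needs at least 3 cell-list layers for the half stencil
        return int(ps.box[2] / self.params.r_c) >= 3

    def __call__(self, sim: Simulation) -> np.ndarray:
        ps = sim.system
        if self._kernel_supported(ps):
            seed = int(sim.rng["thermostat"].integers(2 ** 31))
            f = pair_forces_fused(ps, self.params, sim.clock.dt, seed,
                                  self.one_way, self.thermostat)
            if self.cells is not None:
                self.cells.compute_forces(sim, f)
            if self.body_force is not None:
                f += self.body_force(ps)
            return f
        return self._numpy_forces(sim)

    def _numpy_forces(self, sim: Simulation) -> np.ndarray:
        ps = sim.system
        p = self.params
        mov_idx = np.nonzero(ps.species != Species.WALL)[0]
        im, jm, drm = build_neighbor_pairs(ps.pos[mov_idx], p.r_c, box=ps.box,
                                           periodic=ps.periodic)
        iw, jw, drw = self._wall_pairs(ps, mov_idx)
        i = np.concatenate([mov_idx[im], iw])
        j = np.concatenate([mov_idx[jm], jw])
        dr = np.concatenate([drm, drw])
        f = np.zeros_like(ps.pos)
        if len(i):
            sp_i, sp_j = ps.species[i], ps.species[j]
            wall_j = sp_j == Species.WALL
            ghost_i = sp_i == Species.GHOST
            ghost_j = sp_j == Species.GHOST
            gen_i = (ps.region[i] == Region.GENERATING) | ghost_i
            gen_j = (ps.region[j] == Region.GENERATING) | ghost_j
            ci, cj = ps.cell_id[i], ps.cell_id[j]
            keep = ~(ghost_i & ghost_j)
            keep &= ~((ci == cj) & (ci >= 0))          # same-cell: bonded only
            # ghosts never touch the main domain (walls aside)
            keep &= ~(ghost_i & ~gen_j & ~wall_j)
            keep &= ~(ghost_j & ~gen_i)
            i, j, dr = i[keep], j[keep], dr[keep]
            if len(i):
                sp_i, sp_j = ps.species[i], ps.species[j]
                ci, cj = ps.cell_id[i], ps.cell_id[j]
                v_rel = ps.vel[i] - ps.vel[j]
                xi = (sim.rng["thermostat"].normal(size=len(i))
                      if self.thermostat else None)
                cons_only = (ci >= 0) & (cj >= 0) & (ci != cj)
                fp = pair_forces_arrays(dr, v_rel, p, sim.clock.dt, xi=xi,
                                        conservative_only=cons_only)
                wi = np.ones(len(i))
                wj = np.ones(len(i))
                if self.one_way:
                    gi = (ps.region[i] == Region.GENERATING) | (sp_i == Species.GHOST)
                    gj = (ps.region[j] == Region.GENERATING) | (sp_j == Species.GHOST)
                    wall = (sp_i == Species.WALL) | (sp_j == Species.WALL)
                    wi_, wj_ = one_way_weights(gi, gj)
                    wi = np.where(wall, 1.0, wi_)
                    wj = np.where(wall, 1.0, wj_)
                for d in range(3):
                    f[:, d] += np.bincount(i, weights=wi * fp[:, d],
                                           minlength=ps.n)
                    f[:, d] -= np.bincount(j, weights=wj * fp[:, d],
                                           minlength=ps.n)
        if self.cells is not None:
            self.cells.compute_forces(sim, f)
        if self.body_force is not None:
            f += self.body_force(ps)
        return f
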