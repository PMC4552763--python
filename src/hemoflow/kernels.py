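"""Numba-accelerated fused neighbor-search + DPD pair-force kernel.

Implements exactly the pair interaction rules of :class:`hemoflow.forces.
ForceModel` (species/region masking, one-way coupling, conservative-only
membrane contact, per-pair symmetric random term) in a single cell-list
pass.  The pure-numpy route remains available as a fallback and serves as
the independent oracle in the test-suite.

Set ``HEMOFLOW_NO_NUMBA=1`` to disable this backend.
"""

from __future__ import annotations

import os

import numpy as np

HAVE_NUMBA = False
if not os.environ.get("HEMOFLOW_NO_NUMBA"):
    try:
        from numba import njit
        HAVE_NUMBA = True
    except ImportError:  # pragma: no cover
        pass

if HAVE_NUMBA:

    # species / region codes (must match core.Species / core.Region)
    _FLUID, _WALL, _MEMBRANE, _GHOST, _SLAVED = 0, 1, 2, 3, 4
    _GEN = 0

    @njit(cache=True, fastmath=False)
    def _pair_forces_numba(pos, vel, species, region, cell_id,
                           rc, a, gamma, sigma, s_exp, dt, seed,
                           Lz, periodic_z, one_way, thermostat):
        np.random.seed(seed)
        n = pos.shape[0]
        f = np.zeros((n, 3))
        if n < 2:
            return f
        rc2 = rc * rc
        inv_sqrt_dt = 1.0 / np.sqrt(dt)
        # --- cell list ----------------------------------------------------
        xmin = np.empty(3)
        xmax = np.empty(3)
        for d in range(3):
            lo = pos[0, d]
            hi = pos[0, d]
            for k in range(1, n):
                if pos[k, d] < lo:
                    lo = pos[k, d]
                if pos[k, d] > hi:
                    hi = pos[k, d]
            xmin[d] = lo
            xmax[d] = hi + 1e-9
        if periodic_z:
            xmin[2] = 0.0
            xmax[2] = Lz
        nc = np.empty(3, dtype=np.int64)
        edge = np.empty(3)
        for d in range(3):
            nc[d] = max(int((xmax[d] - xmin[d]) / rc), 1)
            edge[d] = (xmax[d] - xmin[d]) / nc[d]
        cid = np.empty(n, dtype=np.int64)
        for k in range(n):
            cx = int((pos[k, 0] - xmin[0]) / edge[0])
            cy = int((pos[k, 1] - xmin[1]) / edge[1])
            cz = int((pos[k, 2] - xmin[2]) / edge[2])
            if cx < 0:
                cx = 0
            if cx >= nc[0]:
                cx = nc[0] - 1
            if cy < 0:
                cy = 0
            if cy >= nc[1]:
                cy = nc[1] - 1
            if periodic_z:
                cz = cz % nc[2]
            else:
                if cz < 0:
                    cz = 0
                if cz >= nc[2]:
                    cz = nc[2] - 1
            cid[k] = (cx * nc[1] + cy) * nc[2] + cz
        ncell = nc[0] * nc[1] * nc[2]
        count = np.zeros(ncell + 1, dtype=np.int64)
        for k in range(n):
            count[cid[k] + 1] += 1
        for c in range(ncell):
            count[c + 1] += count[c]
        order = np.empty(n, dtype=np.int64)
        fill = count[:-1].copy()
        for k in range(n):
            order[fill[cid[k]]] = k
            fill[cid[k]] += 1
        # half stencil: self + 13 neighbors
        offs = np.array([
            (0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 0),
            (1, 0, 1), (0, 1, 1), (1, 1, 1), (1, -1, 0), (1, 0, -1),
            (0, 1, -1), (1, -1, 1), (1, 1, -1), (1, -1, -1)],
            dtype=np.int64)
        for cx in range(nc[0]):
            for cy in range(nc[1]):
                for cz in range(nc[2]):
                    c1 = (cx * nc[1] + cy) * nc[2] + cz
                    for o in range(offs.shape[0]):
                        gx = cx + offs[o, 0]
                        gy = cy + offs[o, 1]
                        gz = cz + offs[o, 2]
                        if gx < 0 or gx >= nc[0] or gy < 0 or gy >= nc[1]:
                            continue
                        if periodic_z:
                            gz = gz % nc[2]
                        elif gz < 0 or gz >= nc[2]:
                            continue
                        c2 = (gx * nc[1] + gy) * nc[2] + gz
                        same = c1 == c2
                        if same and o != 0:
                            continue
                        for p1 in range(count[c1], count[c1 + 1]):
                            i = order[p1]
                            start = p1 + 1 if same else count[c2]
                            for p2 in range(start, count[c2 + 1]):
                                j = order[p2]
                                sp_i = species[i]
                                sp_j = species[j]
                                if sp_i == _WALL and sp_j == _WALL:
                                    continue
                                if sp_i == _GHOST and sp_j == _GHOST:
                                    continue
                                ci = cell_id[i]
                                cj = cell_id[j]
                                if ci >= 0 and ci == cj:
                                    continue
                                gen_i = region[i] == _GEN or sp_i == _GHOST
                                gen_j = region[j] == _GEN or sp_j == _GHOST
                                if sp_i == _GHOST and not gen_j and sp_j != _WALL:
                                    continue
                                if sp_j == _GHOST and not gen_i and sp_i != _WALL:
                                    continue
                                dx = pos[i, 0] - pos[j, 0]
                                dy = pos[i, 1] - pos[j, 1]
                                dz = pos[i, 2] - pos[j, 2]
                                if periodic_z:
                                    dz -= Lz * np.round(dz / Lz)
                                r2 = dx * dx + dy * dy + dz * dz
                                if r2 >= rc2 or r2 <= 0.0:
                                    continue
                                r = np.sqrt(r2)
                                ex = dx / r
                                ey = dy / r
                                ez = dz / r
                                wc = 1.0 - r / rc
                                mag = a * wc
                                cons_only = ci >= 0 and cj >= 0 and ci != cj
                                if not cons_only:
                                    w_d = wc ** s_exp
                                    ve = (ex * (vel[i, 0] - vel[j, 0])
                                          + ey * (vel[i, 1] - vel[j, 1])
                                          + ez * (vel[i, 2] - vel[j, 2]))
                                    mag -= gamma * w_d * ve
                                    if thermostat:
                                        xi = np.random.normal()
                                        mag += (sigma * np.sqrt(w_d)
                                                * xi * inv_sqrt_dt)
                                wi = 1.0
                                wj = 1.0
                                if one_way and sp_i != _WALL and sp_j != _WALL:
                                    if gen_i and not gen_j:
                                        wi = 0.0
                                    elif gen_j and not gen_i:
                                        wj = 0.0
                                f[i, 0] += wi * mag * ex
                                f[i, 1] += wi * mag * ey
                                f[i, 2] += wi * mag * ez
                                f[j, 0] -= wj * mag * ex
                                f[j, 1] -= wj * mag * ey
                                f[j, 2] -= wj * mag * ez
        return f

    def pair_forces_fused(ps, params, dt, seed, one_way, thermostat):
        """Total DPD pair forces for the current particle state."""
        periodic_z = bool(ps.box is not None and ps.periodic[2])
        Lz = float(ps.box[2]) if periodic_z else 1.0
        return _pair_forces_numba(
            ps.pos, ps.vel, ps.species.astype(np.int8),
            ps.region.astype(np.int8), ps.cell_id.astype(np.int64),
            float(params.r_c), float(params.a), float(params.gamma),
            float(params.sigma), float(params.s), float(dt),
            int(seed) & 0x7FFFFFFF, Lz, periodic_z, bool(one_way),
            bool(thermostat))
else:  # pragma: no cover
    pair_forces_fused = None
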