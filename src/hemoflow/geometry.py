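"""Wall construction and scenario geometries.

Solid walls are frozen layers of particles (copies of an equilibrated fluid
slab, so the wall density matches the fluid) combined with bounce-back
reflection of any particle that penetrates the lumen boundary.  Geometries
are described by a signed-distance function of the wetted domain: positive
inside the lumen, negative inside the wall.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .core import ParticleSystem, Region, Species, build_neighbor_pairs
from .dpd import DPDParams, pair_forces_arrays

log = logging.getLogger(__name__)

__all__ = ["WallGeometry", "TubeGeometry", "BifurcationGeometry",
           "BifurcationSpec", "OutletPlane", "build_tube",
           "build_bifurcation", "bounce_back"]


@dataclass
class OutletPlane:
    """Outflow plane: particles at ``(x - origin) . normal > 0`` have crossed."""

    origin: np.ndarray
    normal: np.ndarray
    branch: int = 0

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        self.normal = n / np.linalg.norm(n)

    def signed(self, pts: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(pts) - self.origin) @ self.normal


@lru_cache(maxsize=8)
def _equilibrated_cube(edge: float, density: float, seed: int, steps: int = 400):
    """Periodic cube of DPD fluid equilibrated in place (for wall stamping)."""
    from .core import SimClock, Simulation
    from .forces import ForceModel

    rng = np.random.Generator(np.random.Philox(seed))
    n = int(round(density * edge ** 3))
    pos = rng.uniform(0.0, edge, size=(n, 3))
    ps = ParticleSystem(pos, box=np.array([edge] * 3),
                        periodic=(True, True, True))
    sim = Simulation(ps, ForceModel(DPDParams(), one_way=False),
                     clock=SimClock(dt=0.005, seed=seed))
    sim.add_hook(lambda s: np.mod(s.system.pos, edge, out=s.system.pos))
    sim.run(steps)
    return np.mod(ps.pos, edge).copy()


class WallGeometry:
    """Base class: signed-distance lumen description + frozen wall particles."""

    #: shell thickness of frozen particles (>= interaction cutoff)
    thickness: float = 1.5

    def sdf(self, pts: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def normal(self, pts: np.ndarray, h: float = 1e-5) -> np.ndarray:
        """Outward-from-wall (into-lumen) unit normal via sdf gradient."""
        pts = np.atleast_2d(pts)
        g = np.zeros_like(pts, dtype=float)
        for d in range(3):
            dp = np.zeros(3)
            dp[d] = h
            g[:, d] = (self.sdf(pts + dp) - self.sdf(pts - dp)) / (2 * h)
        nrm = np.linalg.norm(g, axis=1)
        nrm[nrm == 0] = 1.0
        return g / nrm[:, None]

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:  # pragma: no cover
        raise NotImplementedError

    def drive_direction(self, pts: np.ndarray) -> np.ndarray:
        """Unit vector of the local flow axis (body-force direction)."""
        return np.broadcast_to(np.array([0.0, 0.0, 1.0]), np.atleast_2d(pts).shape)

    @property
    def outlets(self) -> list[OutletPlane]:
        return getattr(self, "_outlets", [])

    def build_wall_particles(self, density: float, seed: int = 1234,
                             z_range=None) -> np.ndarray:
        """Frozen wall particles: equilibrated-fluid copies in the wall shell.

        ``z_range`` restricts particles to ``z0 <= z < z1`` (periodic pilot
        boxes must not carry wall padding beyond the period).
        """
        lo, hi = self.bounds()
        lo = lo - self.thickness
        hi = hi + self.thickness
        edge = 6.0
        cube = _equilibrated_cube(edge, density, seed)
        pts = []
        nx, ny, nz = [int(np.ceil((hi[d] - lo[d]) / edge)) for d in range(3)]
        for ix in range(nx):
            for iy in range(ny):
                for iz in range(nz):
                    off = lo + edge * np.array([ix, iy, iz], dtype=float)
                    p = cube + off
                    s = self.sdf(p)
                    sel = (s <= 0.0) & (s >= -self.thickness)
                    sel &= np.all(p < hi, axis=1)
                    if z_range is not None:
                        sel &= (p[:, 2] >= z_range[0]) & (p[:, 2] < z_range[1])
                    if np.any(sel):
                        pts.append(p[sel])
        return np.concatenate(pts) if pts else np.empty((0, 3))

    def lumen_volume_mc(self, z_range=None, n_samples: int = 200_000,
                        seed: int = 7) -> float:
        """Monte-Carlo lumen volume, optionally restricted to a z interval."""
        rng = np.random.Generator(np.random.Philox(seed))
        lo, hi = self.bounds()
        lo, hi = lo.copy(), hi.copy()
        if z_range is not None:
            lo[2], hi[2] = z_range
        pts = rng.uniform(lo, hi, size=(n_samples, 3))
        frac = float(np.mean(self.sdf(pts) > 0))
        return frac * float(np.prod(hi - lo))


class TubeGeometry(WallGeometry):
    """Straight cylindrical lumen of diameter ``d`` along z over ``[0, L]``."""

    def __init__(self, d: float, L: float, thickness: float = 1.5):
        if d <= 0 or L <= 0:
            raise ValueError("diameter and length must be positive")
        self.d = float(d)
        self.L = float(L)
        self.thickness = thickness
        self._outlets = [OutletPlane(origin=(0, 0, L), normal=(0, 0, 1), branch=0)]

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return self.d / 2.0 - np.hypot(pts[:, 0], pts[:, 1])

    def bounds(self):
        r = self.d / 2.0
        return (np.array([-r, -r, 0.0]), np.array([r, r, self.L]))

    def lumen_volume(self, z_range=None) -> float:
        z0, z1 = (0.0, self.L) if z_range is None else z_range
        return np.pi * (self.d / 2.0) ** 2 * (z1 - z0)


@dataclass
class BifurcationSpec:
    """Bifurcation: parent along z splitting into two coplanar daughters.

    ``theta`` is the full angle between the daughter axes; ``phi_d`` is the
    diagnostic target flow-rate ratio (branch 1 : branch 2).  By default the
    daughters are symmetric about the parent axis (each at ``theta/2``);
    with ``straight_main=True`` daughter 1 continues along the parent axis
    (the "main" branch) and daughter 2 leaves at ``theta`` (the "side"
    branch) — the configuration of the bifurcation-angle study.
    """

    d_parent: float = 13.3
    d_daughter1: float = 11.0
    d_daughter2: float = 11.0
    theta: float = 78.0
    L_parent: float = 15.0
    L_daughter: float = 12.0
    phi_d: float = 1.0
    straight_main: bool = False

    def __post_init__(self):
        if min(self.d_parent, self.d_daughter1, self.d_daughter2) <= 0:
            raise ValueError("diameters must be positive")
        if not (0.0 < self.theta < 180.0):
            raise ValueError("bifurcation angle must be in (0, 180) degrees")


class BifurcationGeometry(WallGeometry):
    """Union of a parent tube (along z) and two half-infinite daughter tubes."""

    def __init__(self, spec: BifurcationSpec, thickness: float = 1.5):
        self.spec = spec
        self.thickness = thickness
        self.junction = np.array([0.0, 0.0, spec.L_parent])
        if spec.straight_main:
            th = np.deg2rad(spec.theta)
            self.axis1 = np.array([0.0, 0.0, 1.0])
            self.axis2 = np.array([-np.sin(th), 0.0, np.cos(th)])
        else:
            th = np.deg2rad(spec.theta) / 2.0
            self.axis1 = np.array([np.sin(th), 0.0, np.cos(th)])
            self.axis2 = np.array([-np.sin(th), 0.0, np.cos(th)])
        o1 = self.junction + spec.L_daughter * self.axis1
        o2 = self.junction + spec.L_daughter * self.axis2
        if np.linalg.norm(o1 - o2) < (spec.d_daughter1 + spec.d_daughter2) / 2.0:
            raise ValueError("outlet regions overlap: increase angle or lengths")
        self._outlets = [OutletPlane(origin=o1, normal=self.axis1, branch=1),
                         OutletPlane(origin=o2, normal=self.axis2, branch=2)]

    def _branch_sdfs(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        sp = self.spec
        # parent: capped at the junction plane
        rho_p = np.hypot(pts[:, 0], pts[:, 1])
        s_parent = np.minimum(sp.d_parent / 2.0 - rho_p,
                              self.junction[2] - pts[:, 2])
        out = [s_parent]
        pad = self.thickness + 1.0  # daughters extend past the outlet plane
        for ax, dd, Ld in ((self.axis1, sp.d_daughter1, sp.L_daughter),
                           (self.axis2, sp.d_daughter2, sp.L_daughter)):
            rel = pts - self.junction
            s_ax = rel @ ax
            rho = np.linalg.norm(rel - s_ax[:, None] * ax, axis=1)
            s = np.minimum(dd / 2.0 - rho, s_ax)
            s = np.minimum(s, Ld + pad - s_ax)
            out.append(s)
        return np.stack(out, axis=1)

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        return self._branch_sdfs(pts).max(axis=1)

    def branch_id(self, pts: np.ndarray) -> np.ndarray:
        """0 = parent, 1/2 = daughters (nearest-lumen assignment)."""
        return self._branch_sdfs(pts).argmax(axis=1)

    def drive_direction(self, pts: np.ndarray) -> np.ndarray:
        bid = self.branch_id(pts)
        axes = np.stack([np.array([0.0, 0.0, 1.0]), self.axis1, self.axis2])
        return axes[bid]

    def bounds(self):
        sp = self.spec
        pad = self.thickness + 1.0
        ends = np.stack([o.origin + o.normal * pad for o in self._outlets])
        rmax = max(sp.d_daughter1, sp.d_daughter2) / 2.0
        lo = np.minimum(ends.min(axis=0) - rmax,
                        np.array([-sp.d_parent / 2, -sp.d_parent / 2, 0.0]))
        hi = np.maximum(ends.max(axis=0) + rmax,
                        np.array([sp.d_parent / 2, sp.d_parent / 2, sp.L_parent]))
        return lo, hi

    def lumen_volume(self, z_range=None) -> float:
        return self.lumen_volume_mc(z_range=z_range)


def build_tube(d: float, L: float, thickness: float = 1.5) -> TubeGeometry:
    """Cylindrical lumen along z with a frozen-particle wall shell."""
    return TubeGeometry(d, L, thickness=thickness)


def build_bifurcation(spec: BifurcationSpec, thickness: float = 1.5
                      ) -> BifurcationGeometry:
    return BifurcationGeometry(spec, thickness=thickness)


def bounce_back(system: ParticleSystem, prev_pos: np.ndarray,
                geometry: WallGeometry, max_depth_warn: float | None = None
                ) -> int:
    """Bounce-back reflection of particles that crossed the lumen boundary.

    The position is reflected across the crossing point along the incoming
    trajectory and the full velocity vector is negated (no-slip).  Particles
    found deeper than one step-length inside the wall are clamped to the
    surface with a warning.  Returns the number of reflected particles.
    """
    mov = system.movable_mask()
    idx = np.nonzero(mov)[0]
    if len(idx) == 0:
        return 0
    s_new = geometry.sdf(system.pos[idx])
    bad = s_new < 0.0
    if not np.any(bad):
        return 0
    bi = idx[bad]
    p0 = prev_pos[bi]
    p1 = system.pos[bi]
    s0 = geometry.sdf(p0)
    step_len = np.linalg.norm(p1 - p0, axis=1)
    deep = (-s_new[bad]) > np.maximum(step_len, 1e-12)
    if max_depth_warn is None and np.any(deep):
        warnings.warn(f"{int(deep.sum())} particle(s) deeper than one step "
                      "inside the wall; clamped to surface", RuntimeWarning)
    # bisection for the crossing point on segments with a valid outside start
    t_lo = np.zeros(len(bi))
    t_hi = np.ones(len(bi))
    started_inside = s0 < 0.0
    for _ in range(20):
        t_mid = 0.5 * (t_lo + t_hi)
        pm = p0 + t_mid[:, None] * (p1 - p0)
        sm = geometry.sdf(pm)
        out = sm >= 0.0
        t_lo = np.where(out, t_mid, t_lo)
        t_hi = np.where(out, t_hi, t_mid)
    t_c = 0.5 * (t_lo + t_hi)
    xc = p0 + t_c[:, None] * (p1 - p0)
    newp = 2.0 * xc - p1
    system.pos[bi] = newp
    system.vel[bi] = -system.vel[bi]
    # clamp stragglers (deep penetration, started inside, or reflected into
    # the far wall at a corner) onto the lumen side
    for _ in range(4):
        s = geometry.sdf(system.pos[bi])
        stuck = s < 0.0
        if not np.any(stuck):
            break
        sb = bi[stuck]
        nrm = geometry.normal(system.pos[sb])
        system.pos[sb] += (1e-3 - s[stuck])[:, None] * nrm
    if np.any(started_inside):
        log.debug("%d particle(s) began the step inside the wall",
                  int(started_inside.sum()))
    return int(bad.sum())
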