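"""Coarse-grained red-blood-cell membrane: triangulated mesh + force terms.

The cell membrane is a closed 2D triangulated network whose vertices are
particles.  Its potential energy is the sum of four terms:

* in-plane elasticity: a worm-like-chain (WLC) term per spring plus a
  repulsive ``C / A_alpha`` term per triangle, with ``C`` fixed by the
  zero-tension condition at the equilibrium spring length,
* bending: ``k_b [1 - cos(theta - theta_0)]`` per adjacent-triangle pair,
* global area and volume constraints, quadratic in ``A - A_0`` and
  ``V - V_0``.

Membrane viscosity is a per-spring dissipative force with a matched random
force built from the traceless-symmetric part and trace of a 3x3 Wiener
increment (fluctuation--dissipation pair).

All force routines return exact analytic negative gradients of the stated
energies; the test-suite checks them against central differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import ConvexHull

__all__ = [
    "MembraneParams", "CellTopology", "SpringWienerIncrement",
    "build_rbc_mesh", "elastic_forces", "bending_forces",
    "area_volume_forces", "membrane_viscous_forces", "total_energy",
    "wlc_triangle_constant", "mesh_volume", "mesh_area",
]



def _cross(a, b):
    """Row-wise cross product without np.cross's axis-handling overhead."""
    out = np.empty(np.broadcast(a, b).shape)
    out[..., 0] = a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1]
    out[..., 1] = a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2]
    out[..., 2] = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    return out

@dataclass
class MembraneParams:
    """Membrane model parameters (reduced units).

    ``x0 = l0/lm`` must lie in (0, 1); ``3*gamma_c >= gamma_t`` is required
    for the random-force amplitude to be real.
    """

    l0: float
    lm: float
    p: float
    kBT: float = 0.0945
    gamma_t: float = 0.5
    gamma_c: float = 1.0
    kb: float = 1.0
    theta0: float = 0.0
    ka: float = 5000.0
    kv: float = 5000.0

    def __post_init__(self):
        if not (self.lm > self.l0 > 0):
            raise ValueError("require lm > l0 > 0")
        if not (0.0 < self.x0 < 1.0):
            raise ValueError("x0 = l0/lm must be in (0, 1)")
        if self.p <= 0:
            raise ValueError("persistence length must be positive")
        if self.gamma_t <= 0:
            raise ValueError("gamma_t must be positive")
        if 3.0 * self.gamma_c < self.gamma_t:
            raise ValueError("need 3*gamma_c >= gamma_t (random force amplitude)")

    @property
    def x0(self) -> float:
        return self.l0 / self.lm

    @classmethod
    def reference(cls, l0: float, kBT: float = 0.0945, x0: float = 0.45,
                  **overrides) -> "MembraneParams":
        """Documented reference set yielding a stable deformable cell.

        ``x0`` sets the extension margin (``lm = l0/x0``); the default
        persistence length gives a WLC force scale of a few DPD force
        units at the rest length.  Fast-transport runs should lower ``x0``
        (more headroom before the WLC divergence) and/or ``p`` (stiffer
        springs).
        """
        x0 = overrides.pop("x0", x0)
        defaults = dict(l0=l0, lm=l0 / x0, p=0.02, kBT=kBT,
                        gamma_t=0.5, gamma_c=1.0, kb=1.0, theta0=0.0,
                        ka=5000.0, kv=5000.0)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class CellTopology:
    """Per-cell mesh connectivity in local vertex indices.

    ``verts`` maps local indices to :class:`~hemoflow.core.ParticleSystem`
    indices (or is None for a free-standing mesh).  ``springs`` (S, 2),
    ``triangles`` (T, 3) with consistent outward orientation, ``dihedrals``
    (D, 4) as ``(i, j, k, l)`` where ``(i, j)`` is the shared edge and
    ``k``/``l`` the opposite vertices of the two adjacent triangles.
    """

    springs: np.ndarray
    triangles: np.ndarray
    dihedrals: np.ndarray
    A0: float
    V0: float
    n_verts: int
    verts: np.ndarray | None = None

    def __post_init__(self):
        self.springs = np.asarray(self.springs, dtype=np.int64)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.dihedrals = np.asarray(self.dihedrals, dtype=np.int64)
        if self.verts is not None:
            self.verts = np.asarray(self.verts, dtype=np.int64)

    @property
    def n_springs(self) -> int:
        return len(self.springs)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)


class SpringWienerIncrement:
    """Per-spring 3x3 Wiener increments with derived traceless symmetric part.

    Entries of ``dW`` are independent N(0, dt); ``dW_bar_s`` is the
    traceless symmetric part and ``trace`` the matrix trace.
    """

    def __init__(self, dW: np.ndarray):
        dW = np.asarray(dW, dtype=float)
        if dW.ndim != 3 or dW.shape[1:] != (3, 3):
            raise ValueError("dW must have shape (S, 3, 3)")
        self.dW = dW
        sym = 0.5 * (dW + np.transpose(dW, (0, 2, 1)))
        tr = np.trace(sym, axis1=1, axis2=2)
        self.dW_bar_s = sym - tr[:, None, None] * np.eye(3) / 3.0
        self.trace = np.trace(dW, axis1=1, axis2=2)

    @classmethod
    def draw(cls, n_springs: int, dt: float, rng: np.random.Generator
             ) -> "SpringWienerIncrement":
        return cls(rng.normal(0.0, np.sqrt(dt), size=(n_springs, 3, 3)))


# ---------------------------------------------------------------------------
# mesh construction

def _icosahedron():
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=float)
    v /= np.linalg.norm(v, axis=1)[:, None]
    return v


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n, dtype=float)
    ga = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    th = ga * k
    return np.stack([r * np.cos(th), r * np.sin(th), z], axis=1)


def _orient_outward(points, tris):
    """Flip triangles so the signed normal points away from the centroid."""
    c = points.mean(axis=0)
    a, b, d = points[tris[:, 0]], points[tris[:, 1]], points[tris[:, 2]]
    nrm = _cross(b - a, d - a)
    flip = np.einsum("ij,ij->i", nrm, (a + b + d) / 3.0 - c) < 0
    tris = tris.copy()
    tris[flip] = tris[flip][:, [0, 2, 1]]
    return tris


def _edges_and_dihedrals(tris):
    """Unique edges and (i, j, k, l) dihedrals of a closed triangulation.

    For the dihedral of edge (i, j), ``k`` is the opposite vertex of the
    triangle traversing the edge as i->j and ``l`` of the one traversing it
    j->i; with consistently outward-oriented triangles this fixes the sign
    of the dihedral angle.
    """
    directed: dict[tuple[int, int], int] = {}
    for a, b, c in tris:
        for (i, j, k) in ((a, b, c), (b, c, a), (c, a, b)):
            if (i, j) in directed:
                raise ValueError("mesh is not a consistently oriented manifold")
            directed[(int(i), int(j))] = int(k)
    springs, dihedrals = [], []
    for (i, j), k in sorted(directed.items()):
        if i > j:
            continue
        if (j, i) not in directed:
            raise ValueError("mesh is not a closed 2-manifold")
        springs.append((i, j))
        dihedrals.append((i, j, k, directed[(j, i)]))
    return np.array(springs, dtype=np.int64), np.array(dihedrals, dtype=np.int64)


def mesh_area(x: np.ndarray, tris: np.ndarray):
    a, b, c = x[tris[:, 0]], x[tris[:, 1]], x[tris[:, 2]]
    areas = 0.5 * np.linalg.norm(_cross(b - a, c - a), axis=1)
    return areas


def mesh_volume(x: np.ndarray, tris: np.ndarray) -> float:
    """Signed volume by summing signed tetrahedra against the origin."""
    a, b, c = x[tris[:, 0]], x[tris[:, 1]], x[tris[:, 2]]
    return float(np.einsum("ij,ij->i", a, _cross(b, c)).sum() / 6.0)


def _oblate_aspect(reduced_volume: float) -> float:
    """Aspect ratio c/a of an oblate spheroid with the given reduced volume.

    Reduced volume = 6 sqrt(pi) V / A^(3/2); equals 1 for a sphere.
    """
    def rv(e):  # e = c/a in (0, 1]
        if e >= 1.0:
            return 1.0
        ecc = np.sqrt(1.0 - e * e)
        area = 2 * np.pi * (1.0 + (e * e / ecc) * np.arctanh(ecc))  # a = 1
        vol = 4.0 * np.pi * e / 3.0
        return 6.0 * np.sqrt(np.pi) * vol / area ** 1.5
    if reduced_volume >= 1.0:
        return 1.0
    return brentq(lambda e: rv(e) - reduced_volume, 1e-3, 1.0 - 1e-9)


def build_rbc_mesh(n_v: int, area: float, volume: float | None = None,
                   center=(0.0, 0.0, 0.0), orientation=None):
    """Closed triangulated cell mesh with ``n_v`` vertices.

    The mesh starts from a near-uniform point distribution on the unit
    sphere (exact icosahedron for ``n_v = 12``), triangulated by its convex
    hull, then squashed to an oblate spheroid so that total area and
    enclosed volume match the targets (``volume=None`` keeps a sphere of
    the requested area).  ``A0``/``V0`` recorded on the topology are those
    of the built mesh.

    Returns ``(positions, CellTopology)``.
    """
    if n_v < 12:
        raise ValueError("need at least 12 vertices")
    pts = _icosahedron() if n_v == 12 else _fibonacci_sphere(n_v)
    hull = ConvexHull(pts)
    tris = _orient_outward(pts, hull.simplices.astype(np.int64))
    if len(np.unique(tris)) != n_v:
        raise ValueError("degenerate point distribution: hull dropped vertices")
    # squash to oblate spheroid matching the target reduced volume, then
    # scale uniformly to the target area
    if volume is not None:
        rv = 6.0 * np.sqrt(np.pi) * volume / area ** 1.5
        e = _oblate_aspect(rv)
        pts = pts * np.array([1.0, 1.0, e])
    A_now = mesh_area(pts, tris).sum()
    pts = pts * np.sqrt(area / A_now)
    if orientation is not None:
        pts = pts @ np.asarray(orientation, dtype=float).T
    pts = pts + np.asarray(center, dtype=float)
    springs, dihedrals = _edges_and_dihedrals(tris)
    topo = CellTopology(springs=springs, triangles=tris, dihedrals=dihedrals,
                        A0=float(mesh_area(pts, tris).sum()),
                        V0=float(_volume_about_centroid(pts, tris)),
                        n_verts=n_v)
    return pts, topo


def _volume_about_centroid(x, tris) -> float:
    return mesh_volume(x - x.mean(axis=0), tris)


# ---------------------------------------------------------------------------
# energies and analytic forces (local coordinates, one cell or a batch with
# concatenated topology arrays)

def wlc_triangle_constant(params: MembraneParams) -> float:
    """Per-triangle coefficient C of the ``C/A_alpha`` term.

    Chosen so the network tension vanishes at spring length ``l0``::

        C = 3 sqrt(3) kBT lm^3 x0^4 (4 x0^2 - 9 x0 + 6) / (64 p (1 - x0)^2)
    """
    x0 = params.x0
    return (3.0 * np.sqrt(3.0) * params.kBT * params.lm ** 3 * x0 ** 4
            * (4.0 * x0 ** 2 - 9.0 * x0 + 6.0)
            / (64.0 * params.p * (1.0 - x0) ** 2))


def _triangle_area_gradients(x, tris):
    """Areas and dA/dx for each corner of each triangle."""
    a, b, c = x[tris[:, 0]], x[tris[:, 1]], x[tris[:, 2]]
    nrm = _cross(b - a, c - a)
    n2 = np.linalg.norm(nrm, axis=1)
    if np.any(n2 <= 0):
        raise ValueError("zero-area triangle")
    areas = 0.5 * n2
    nhat = nrm / n2[:, None]
    ga = 0.5 * _cross(b - c, nhat)
    gb = 0.5 * _cross(c - a, nhat)
    gc = 0.5 * _cross(a - b, nhat)
    return areas, ga, gb, gc


def elastic_forces(x: np.ndarray, topo: CellTopology, params: MembraneParams):
    """In-plane elastic (WLC + per-triangle) forces and energy.

    Raises if any spring reaches its maximum extension ``lm``.
    """
    i, j = topo.springs[:, 0], topo.springs[:, 1]
    d = x[i] - x[j]
    li = np.linalg.norm(d, axis=1)
    xi = li / params.lm
    if np.any(xi >= 1.0):
        raise ValueError("spring overextension (x >= 1): reduce dt or raise lm")
    kBT, p, lm = params.kBT, params.p, params.lm
    e_wlc = kBT * lm / (4.0 * p) * (3.0 * xi ** 2 - 2.0 * xi ** 3) / (1.0 - xi)
    # dU/dl = kBT x (4x^2 - 9x + 6) / (4 p (1-x)^2)
    dudl = kBT * xi * (4.0 * xi ** 2 - 9.0 * xi + 6.0) / (4.0 * p * (1.0 - xi) ** 2)
    f = np.zeros_like(x)
    fpair = -(dudl / li)[:, None] * d
    np.add.at(f, i, fpair)
    np.add.at(f, j, -fpair)
    C = wlc_triangle_constant(params)
    areas, ga, gb, gc = _triangle_area_gradients(x, topo.triangles)
    e_tri = C / areas
    coef = (C / areas ** 2)[:, None]
    np.add.at(f, topo.triangles[:, 0], coef * ga)
    np.add.at(f, topo.triangles[:, 1], coef * gb)
    np.add.at(f, topo.triangles[:, 2], coef * gc)
    return f, float(e_wlc.sum() + e_tri.sum())


def _dihedral_angles_and_grads(x, dihedrals):
    """Signed adjacent-triangle angles and their gradients.

    For a dihedral (i, j, k, l) the angle between the triangle planes is
    computed from the torsion of the chain k-i-j-l about the edge (i, j);
    a flat patch has angle 0.  Gradients follow the standard torsion-angle
    gradient formulas.
    """
    pi_, pj, pk, pl = x[dihedrals[:, 0]], x[dihedrals[:, 1]], \
        x[dihedrals[:, 2]], x[dihedrals[:, 3]]
    b1 = pi_ - pk
    b2 = pj - pi_
    b3 = pl - pj
    m = _cross(b1, b2)
    n = _cross(b2, b3)
    m2 = np.einsum("ij,ij->i", m, m)
    n2 = np.einsum("ij,ij->i", n, n)
    if np.any(m2 <= 0) or np.any(n2 <= 0):
        raise ValueError("zero-area triangle in dihedral")
    b2n = np.linalg.norm(b2, axis=1)
    y = np.einsum("ij,ij->i", _cross(m, n), b2) / b2n
    c = np.einsum("ij,ij->i", m, n)
    phi = np.arctan2(y, c)
    # angle between triangle planes, positive for a convex (outward-bulging)
    # dihedral, zero for a flat patch
    theta = phi - np.pi
    theta = np.where(theta <= -np.pi, theta + 2.0 * np.pi, theta)
    dphi_d1 = -(b2n / m2)[:, None] * m          # d phi / d pk
    dphi_d4 = (b2n / n2)[:, None] * n           # d phi / d pl
    c1 = (np.einsum("ij,ij->i", b1, b2) / b2n ** 2)[:, None]
    c3 = (np.einsum("ij,ij->i", b3, b2) / b2n ** 2)[:, None]
    dphi_d2 = -(1.0 + c1) * dphi_d1 + c3 * dphi_d4     # d phi / d pi
    dphi_d3 = c1 * dphi_d1 - (1.0 + c3) * dphi_d4      # d phi / d pj
    # d theta = d phi
    return theta, (dphi_d2, dphi_d3, dphi_d1, dphi_d4)


def bending_forces(x: np.ndarray, topo: CellTopology, params: MembraneParams):
    """Bending forces and energy ``sum kb [1 - cos(theta - theta0)]``."""
    theta, grads = _dihedral_angles_and_grads(x, topo.dihedrals)
    energy = params.kb * (1.0 - np.cos(theta - params.theta0))
    dedt = params.kb * np.sin(theta - params.theta0)
    f = np.zeros_like(x)
    for col, g in zip(range(4), grads):
        np.add.at(f, topo.dihedrals[:, col], -dedt[:, None] * g)
    return f, float(energy.sum())


def area_volume_forces(x: np.ndarray, topo: CellTopology, params: MembraneParams):
    """Global area/volume constraint forces and energies ``(f, Va, Vv)``.

    ``Va = ka kBT (A - A0)^2 / (2 l0^2 A0)``,
    ``Vv = kv kBT (V - V0)^2 / (2 l0^3 V0)``.
    """
    areas, ga, gb, gc = _triangle_area_gradients(x, topo.triangles)
    A = float(areas.sum())
    ctr = x.mean(axis=0)
    V = mesh_volume(x - ctr, topo.triangles)
    if V < 0:
        raise ValueError("inverted mesh (negative volume)")
    kBT, l0 = params.kBT, params.l0
    va = params.ka * kBT * (A - topo.A0) ** 2 / (2.0 * l0 ** 2 * topo.A0)
    vv = params.kv * kBT * (V - topo.V0) ** 2 / (2.0 * l0 ** 3 * topo.V0)
    dva_dA = params.ka * kBT * (A - topo.A0) / (l0 ** 2 * topo.A0)
    dvv_dV = params.kv * kBT * (V - topo.V0) / (l0 ** 3 * topo.V0)
    f = np.zeros_like(x)
    np.add.at(f, topo.triangles[:, 0], -dva_dA * ga)
    np.add.at(f, topo.triangles[:, 1], -dva_dA * gb)
    np.add.at(f, topo.triangles[:, 2], -dva_dA * gc)
    # dV/dx about the (moving) centroid: centroid terms cancel because the
    # per-triangle gradients of a closed surface sum to the surface normal
    # integral = 0; use coordinates relative to ctr directly.
    xa = x[topo.triangles[:, 0]] - ctr
    xb = x[topo.triangles[:, 1]] - ctr
    xc = x[topo.triangles[:, 2]] - ctr
    np.add.at(f, topo.triangles[:, 0], -dvv_dV / 6.0 * _cross(xb, xc))
    np.add.at(f, topo.triangles[:, 1], -dvv_dV / 6.0 * _cross(xc, xa))
    np.add.at(f, topo.triangles[:, 2], -dvv_dV / 6.0 * _cross(xa, xb))
    return f, float(va), float(vv)


def membrane_viscous_forces(x: np.ndarray, v: np.ndarray, topo: CellTopology,
                            params: MembraneParams, dt: float,
                            increments: SpringWienerIncrement | None = None):
    """Per-spring dissipative + random membrane-viscosity forces.

    Dissipative: ``F^D = -gamma_t v_ij - gamma_c (v_ij . e) e`` on vertex i
    (negated on j).  Random: ``F^R dt = sqrt(2 kBT) (sqrt(2 gamma_t)
    dW_bar_s + sqrt(3 gamma_c - gamma_t) tr[dW]/3 * I) . e``.  Pass
    ``increments=None`` to disable the random part.
    """
    i, j = topo.springs[:, 0], topo.springs[:, 1]
    d = x[i] - x[j]
    li = np.linalg.norm(d, axis=1)
    e = d / li[:, None]
    vij = v[i] - v[j]
    ve = np.einsum("ij,ij->i", vij, e)
    fd = -params.gamma_t * vij - params.gamma_c * ve[:, None] * e
    f = np.zeros_like(x)
    if increments is not None:
        amp_t = np.sqrt(2.0 * params.kBT * 2.0 * params.gamma_t)
        amp_c = np.sqrt(2.0 * params.kBT) * np.sqrt(
            3.0 * params.gamma_c - params.gamma_t)
        mat = (amp_t * increments.dW_bar_s
               + (amp_c * increments.trace / 3.0)[:, None, None] * np.eye(3))
        fr = np.einsum("sab,sb->sa", mat, e) / dt
        fd = fd + fr
    np.add.at(f, i, fd)
    np.add.at(f, j, -fd)
    return f


def total_energy(x: np.ndarray, topo: CellTopology, params: MembraneParams) -> dict:
    """All four potential-energy terms of a cell; total under key ``'V'``."""
    _, vs = elastic_forces(x, topo, params)
    _, vb = bending_forces(x, topo, params)
    _, va, vv = area_volume_forces(x, topo, params)
    return {"Vs": vs, "Vb": vb, "Va": va, "Vv": vv, "V": vs + vb + va + vv}
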