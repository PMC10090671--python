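"""Quasi-static stent mechanics: wire-network elasticity, SDF penalty
contact and dynamic relaxation.

The braided stent is modelled as a simplified elastic wire network:

* axial springs along every wire segment (stiffness ``EA / L0``),
* angle springs at interior wire nodes penalising the change of the
  included angle between consecutive segments from its stress-free value
  (stiffness ``EI / l_v`` with ``l_v`` the Voronoi length, i.e. the mean of
  the adjacent segment lengths; a clamped end uses half an edge),
* scissor springs at every braid crossing: distance springs (stiffness
  ``EI / l^3``) between the wire successors, and between the wire
  predecessors, of each coincident node pair.  They penalise the change
  of the local braid (scissor) angle between the two wire families - the
  collective degree of freedom that sets the braid radius - so the
  crimped braid stores the energy that drives radial re-expansion, and
  the helical free shape is the unique stress-free state.  With axial and
  turning-angle springs alone the wire twist is unconstrained and a braid
  crimped to a smaller radius would be an equally stress-free state,
* stiff penalty springs tying the coincident node pairs at the braid
  crossings together,
* unilateral viscoelastic penalty contact against the rigid vessel wall
  queried through a signed distance field, with a regularised Coulomb
  friction law; contact activates when the wall distance drops below the
  wire radius (the wire surface, not its centreline, touches the wall).

Rod torsion is deliberately omitted (the scissor springs stand in for the
torsional stiffening of the interlaced families).  Static equilibria are found by dynamic
relaxation: explicit pseudo-time stepping with fictitious
stiffness-proportional nodal masses, light viscous damping and kinetic
damping (velocities reset when the kinetic energy passes a peak).  A state
is converged when the kinetic energy falls below the stop threshold
(default 1e-12 mJ) *and* the largest out-of-balance force on a free node is
below the force tolerance.  Because the fictitious masses scale with
``dt**2`` the trajectory, and hence the converged state, is independent of
the nominal pseudo-time step.

For numerical conditioning the axial stiffness used during relaxation is
capped (default 2 N/mm): braided stents are bending-dominated structures
with quasi-inextensible wires, and the cap bounds axial strains to O(1e-3)
under the sub-millinewton forces of deployment while speeding convergence
of the soft bending modes by orders of magnitude.  ``assemble_model``
called without settings keeps the physical ``EA / L0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from numba import njit

from braidsim.kinematics import (
    CrimpSpec,
    crimp_displacements,
    cumulative_alignment,
    interpolate_configurations,
    map_centerline,
    ring_rotations,
)
from braidsim.stent import StentMesh, StentParameters, assign_rings, build_stent_mesh
from braidsim.vessel import (
    SignedDistanceGrid,
    VesselParameters,
    centerline_polyline,
    vessel_sdf_grid,
)

__all__ = [
    "SolverSettings",
    "StructuralModel",
    "DeploymentResult",
    "assemble_model",
    "build_wire_model",
    "compute_forces",
    "contact_nodal_force",
    "relax_to_equilibrium",
    "run_deployment",
]


@dataclass(frozen=True)
class SolverSettings:
    """Numerical settings of the contact and relaxation scheme.

    Units: forces N, lengths mm, energies mJ, pseudo-time s.
    """

    k_n: float = 10.0  #: normal penalty stiffness, N/mm
    c_n: float = 1e-3  #: normal viscous damping, N*s/mm
    mu_f: float = 0.2  #: Coulomb friction coefficient
    v_reg: float = 1.0  #: friction regularisation slip speed, mm/s
    dt: float = 1.0  #: pseudo-time step (gauge parameter), s
    damping: float = 0.02  #: viscous velocity decay per step
    ke_threshold: float = 1e-12  #: kinetic-energy stop criterion, mJ
    force_tol: float = 5e-6  #: residual force tolerance on free nodes, N
    max_steps: int = 150_000
    check_every: int = 200
    max_step_disp: float = 0.02  #: per-node displacement cap per step, mm
    kinetic_reset_every: int = 500  #: min steps between kinetic-damping resets (0: off)
    pair_stiffness_factor: float = 10.0  #: crossing-pair k / axial k
    axial_stiffness_cap: float = 2.0  #: relaxation axial-stiffness cap, N/mm
    mass_factor: float = 1.0  #: fictitious-mass scaling

    def __post_init__(self) -> None:
        for name in ("k_n", "c_n", "mu_f", "v_reg", "dt", "ke_threshold",
                     "force_tol", "mass_factor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class StructuralModel:
    """Assembled wire-network model (reference configuration ``x0``)."""

    x0: np.ndarray  # (N, 3) reference nodal positions, mm
    beams: np.ndarray  # (B, 2) axial springs
    k_axial: np.ndarray  # (B,) N/mm
    L0: np.ndarray  # (B,) rest lengths, mm
    triples: np.ndarray  # (T, 3) bending joints (a, b, c)
    k_bend: np.ndarray  # (T,) N*mm/rad
    theta0: np.ndarray  # (T,) rest included angles, rad
    scissors: np.ndarray  # (S, 2) braid scissor distance springs
    k_scissor: np.ndarray  # (S,) N/mm
    d0_scissor: np.ndarray  # (S,) rest distances, mm
    pairs: np.ndarray  # (P, 2) crossing-pair penalty springs
    k_pair: float  # N/mm
    node_stiffness: np.ndarray  # (N,) summed incident stiffness, N/mm
    R_w: float  # wire radius used for contact offset, mm
    EA: float  # physical axial rigidity, N
    EI: float  # bending rigidity, N*mm^2

    @property
    def n_nodes(self) -> int:
        return len(self.x0)


@dataclass
class PhaseRecord:
    name: str
    steps: int
    kinetic_energy: float
    residual: float
    converged: bool


@dataclass
class DeploymentResult:
    """Outcome of a three-phase (crimp, position, deploy) simulation.

    ``u_h`` is the nodal displacement vector of length ``3 * N_n`` measured
    from the free reference configuration, ordered
    ``(u_x,1, u_y,1, u_z,1, ..., u_x,Nn, u_y,Nn, u_z,Nn)``.
    """

    positions: np.ndarray
    reference: np.ndarray
    converged: bool
    final_kinetic_energy: float
    phases: list = dc_field(default_factory=list)

    @property
    def u_h(self) -> np.ndarray:
        return (self.positions - self.reference).ravel()


# ---------------------------------------------------------------------------
# Model assembly
# ---------------------------------------------------------------------------


def _bending_triples(beams: np.ndarray, n_nodes: int):
    """Interior-joint triples (a, b, c) from chained beam connectivity."""
    nxt = np.full(n_nodes, -1, dtype=np.int64)
    prv = np.full(n_nodes, -1, dtype=np.int64)
    for a, b in beams:
        nxt[a] = b
        prv[b] = a
    triples = []
    for b in range(n_nodes):
        if prv[b] >= 0 and nxt[b] >= 0:
            triples.append((prv[b], b, nxt[b]))
    if not triples:
        return np.empty((0, 3), dtype=np.int64)
    return np.asarray(triples, dtype=np.int64)


def _included_angles(x: np.ndarray, triples: np.ndarray) -> np.ndarray:
    if len(triples) == 0:
        return np.empty(0)
    u = x[triples[:, 1]] - x[triples[:, 0]]
    v = x[triples[:, 2]] - x[triples[:, 1]]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    c = np.einsum("ij,ij->i", u, v) / (nu * nv)
    s = np.linalg.norm(np.cross(u, v), axis=1) / (nu * nv)
    return np.arctan2(s, np.clip(c, -1.0, 1.0))


def _finish_model(
    x0: np.ndarray,
    beams: np.ndarray,
    pairs: np.ndarray,
    EA: float,
    EI: float,
    R_w: float,
    settings: SolverSettings | None,
    scissors: np.ndarray | None = None,
) -> StructuralModel:
    L0 = np.linalg.norm(x0[beams[:, 1]] - x0[beams[:, 0]], axis=1)
    if np.any(L0 <= 0.0):
        raise ValueError("zero-length beam in assembly")
    k_axial = EA / L0
    if settings is not None and settings.axial_stiffness_cap is not None:
        k_axial = np.minimum(k_axial, settings.axial_stiffness_cap)
    triples = _bending_triples(beams, len(x0))
    # Voronoi lengths: mean of adjacent segment lengths
    seg_len = {tuple(sorted(b)): l for b, l in zip(beams.tolist(), L0)}
    l_v = np.array(
        [
            0.5
            * (
                seg_len[tuple(sorted((a, b)))]
                + seg_len[tuple(sorted((b, c)))]
            )
            for a, b, c in triples
        ]
    ) if len(triples) else np.empty(0)
    k_bend = EI / l_v if len(triples) else np.empty(0)
    theta0 = _included_angles(x0, triples)
    # braid scissor springs: distance springs with EI/l^3 stiffness
    if scissors is not None and len(scissors):
        scissors = np.asarray(scissors, dtype=np.int64)
        l_mean = float(L0.mean())
        k_scissor = np.full(len(scissors), EI / l_mean**3)
        d0_scissor = np.linalg.norm(
            x0[scissors[:, 1]] - x0[scissors[:, 0]], axis=1
        )
        if np.any(d0_scissor <= 0.0):
            raise ValueError("degenerate scissor spring (coincident nodes)")
    else:
        scissors = np.empty((0, 2), dtype=np.int64)
        k_scissor = np.empty(0)
        d0_scissor = np.empty(0)
    pair_factor = (
        settings.pair_stiffness_factor if settings is not None else 100.0
    )
    k_pair = float(pair_factor * k_axial.mean()) if len(pairs) else 0.0

    node_k = np.zeros(len(x0))
    np.add.at(node_k, beams[:, 0], k_axial)
    np.add.at(node_k, beams[:, 1], k_axial)
    if len(triples):
        k_bt = k_bend / np.maximum(l_v.mean() if len(l_v) else 1.0, 1e-12) ** 2
        for col in range(3):
            np.add.at(node_k, triples[:, col], 4.0 * k_bt)
    if len(scissors):
        np.add.at(node_k, scissors[:, 0], k_scissor)
        np.add.at(node_k, scissors[:, 1], k_scissor)
    if len(pairs):
        np.add.at(node_k, pairs[:, 0], k_pair)
        np.add.at(node_k, pairs[:, 1], k_pair)
    kn = settings.k_n if settings is not None else 10.0
    node_k += kn
    return StructuralModel(
        x0=np.ascontiguousarray(x0, dtype=np.float64),
        beams=np.ascontiguousarray(beams, dtype=np.int64),
        k_axial=k_axial,
        L0=L0,
        triples=np.ascontiguousarray(triples, dtype=np.int64),
        k_bend=k_bend,
        theta0=theta0,
        scissors=np.ascontiguousarray(scissors, dtype=np.int64),
        k_scissor=k_scissor,
        d0_scissor=d0_scissor,
        pairs=np.ascontiguousarray(pairs, dtype=np.int64),
        k_pair=k_pair,
        node_stiffness=node_k,
        R_w=R_w,
        EA=EA,
        EI=EI,
    )


def assemble_model(
    mesh: StentMesh,
    material=None,
    settings: SolverSettings | None = None,
) -> StructuralModel:
    """Assemble the wire-network model of a braided stent mesh.

    The model is stress-free in the reference (free) configuration.  With
    ``settings=None`` the axial stiffness is the physical ``EA / L0``;
    passing relaxation settings applies the axial-stiffness cap and the
    crossing-pair stiffness factor documented in the module docstring.
    """
    mat = material if material is not None else mesh.params.material
    E = mat.E * 1e3  # GPa -> N/mm^2
    A = np.pi * mesh.params.R_w**2
    I = np.pi * mesh.params.R_w**4 / 4.0
    # scissor springs between the wire successors (and predecessors) of
    # every coincident crossing pair
    n_nodes = mesh.n_nodes
    nxt = np.full(n_nodes, -1, dtype=np.int64)
    prv = np.full(n_nodes, -1, dtype=np.int64)
    for a, b in mesh.beams:
        nxt[a] = b
        prv[b] = a
    sc = set()
    for a, b in mesh.crossing_pairs:
        if nxt[a] >= 0 and nxt[b] >= 0:
            sc.add((min(nxt[a], nxt[b]), max(nxt[a], nxt[b])))
        if prv[a] >= 0 and prv[b] >= 0:
            sc.add((min(prv[a], prv[b]), max(prv[a], prv[b])))
    scissors = np.asarray(sorted(sc), dtype=np.int64) if sc else None
    return _finish_model(
        mesh.nodes,
        mesh.beams,
        mesh.crossing_pairs,
        EA=E * A,
        EI=E * I,
        R_w=mesh.params.R_w,
        settings=settings,
        scissors=scissors,
    )


def build_wire_model(
    points: np.ndarray,
    EA: float,
    EI: float,
    R_w: float = 0.1,
    clamp_start: bool = False,
    settings: SolverSettings | None = None,
) -> StructuralModel:
    """Model of a single open wire along ``points`` (testing/benchmarks).

    With ``clamp_start=True`` a ghost node is prepended and a half-edge
    angle spring (stiffness ``EI / (L0/2)``) enforces the clamped tangent;
    fix the ghost node and the first real node to realise the clamp.
    """
    points = np.asarray(points, dtype=float)
    if clamp_start:
        ghost = points[0] - (points[1] - points[0])
        points = np.vstack([ghost[None], points])
    n = len(points)
    beams = np.column_stack([np.arange(n - 1), np.arange(1, n)]).astype(np.int64)
    model = _finish_model(
        points,
        beams,
        np.empty((0, 2), dtype=np.int64),
        EA=EA,
        EI=EI,
        R_w=R_w,
        settings=settings,
    )
    if clamp_start:
        # joint at the first real node only integrates half an edge
        L0 = np.linalg.norm(points[1] - points[0])
        idx = np.flatnonzero(model.triples[:, 1] == 1)
        model.k_bend[idx] = EI / (L0 / 2.0)
    return model


# ---------------------------------------------------------------------------
# Reference (numpy) force evaluation
# ---------------------------------------------------------------------------


def contact_nodal_force(
    distance: float,
    normal: np.ndarray,
    velocity: np.ndarray,
    settings: SolverSettings,
    R_w: float,
) -> np.ndarray:
    """Contact force on one node from its SDF query.

    ``distance`` is the signed distance of the node centre to the wall
    (positive inside the lumen) and ``normal`` the unit inward normal.
    Contact activates when the wall distance drops below the wire radius;
    the normal force is the regularised viscoelastic penalty
    ``(k_n*delta + c_n*max(d(delta)/dt, 0))`` clamped non-negative (no
    adhesion), and the tangential force is a regularised Coulomb law
    ``mu_f * |F_n| * tanh(|v_t| / v_reg)`` opposing the tangential
    velocity.
    """
    normal = np.asarray(normal, dtype=float)
    velocity = np.asarray(velocity, dtype=float)
    delta = R_w - distance
    if delta <= 0.0:
        return np.zeros(3)
    ddot = -float(np.dot(velocity, normal))
    fn = settings.k_n * delta + settings.c_n * max(ddot, 0.0)
    fn = max(fn, 0.0)
    force = fn * normal
    vt = velocity - np.dot(velocity, normal) * normal
    speed = np.linalg.norm(vt)
    if speed > 1e-14 and fn > 0.0:
        ft = settings.mu_f * fn * np.tanh(speed / settings.v_reg)
        force -= ft * vt / speed
    return force


def compute_forces(
    model: StructuralModel,
    x: np.ndarray,
    v: np.ndarray | None = None,
    grid: SignedDistanceGrid | None = None,
    settings: SolverSettings | None = None,
    ext_force: np.ndarray | None = None,
) -> np.ndarray:
    """Assembled nodal forces (numpy reference implementation).

    Includes axial, bending and crossing-pair elastic forces, optional SDF
    contact (``grid``) and optional external loads.
    """
    if settings is None:
        settings = SolverSettings()
    if v is None:
        v = np.zeros_like(x)
    F = np.zeros_like(x)

    d = x[model.beams[:, 1]] - x[model.beams[:, 0]]
    L = np.linalg.norm(d, axis=1)
    f_ax = (model.k_axial * (L - model.L0) / np.maximum(L, 1e-30))[:, None] * d
    np.add.at(F, model.beams[:, 0], f_ax)
    np.add.at(F, model.beams[:, 1], -f_ax)

    if len(model.triples):
        a, b, c = model.triples.T
        u = x[b] - x[a]
        w = x[c] - x[b]
        nu = np.linalg.norm(u, axis=1)
        nw = np.linalg.norm(w, axis=1)
        uh = u / nu[:, None]
        wh = w / nw[:, None]
        cos_t = np.clip(np.einsum("ij,ij->i", uh, wh), -1.0, 1.0)
        sin_t = np.linalg.norm(np.cross(uh, wh), axis=1)
        theta = np.arctan2(sin_t, cos_t)
        moment = model.k_bend * (theta - model.theta0)
        pa = wh - cos_t[:, None] * uh
        pc = uh - cos_t[:, None] * wh
        npa = np.linalg.norm(pa, axis=1)
        npc = np.linalg.norm(pc, axis=1)
        ok = (npa > 1e-12) & (npc > 1e-12)
        ga = np.zeros_like(u)
        gc = np.zeros_like(u)
        ga[ok] = pa[ok] / npa[ok, None] / nu[ok, None]
        gc[ok] = -(pc[ok] / npc[ok, None]) / nw[ok, None]
        fa = -moment[:, None] * ga
        fc = -moment[:, None] * gc
        np.add.at(F, a, fa)
        np.add.at(F, c, fc)
        np.add.at(F, b, -(fa + fc))

    if len(model.scissors):
        d = x[model.scissors[:, 1]] - x[model.scissors[:, 0]]
        L = np.linalg.norm(d, axis=1)
        f_sc = (
            model.k_scissor * (L - model.d0_scissor) / np.maximum(L, 1e-30)
        )[:, None] * d
        np.add.at(F, model.scissors[:, 0], f_sc)
        np.add.at(F, model.scissors[:, 1], -f_sc)

    if len(model.pairs):
        dp = x[model.pairs[:, 1]] - x[model.pairs[:, 0]]
        fp = model.k_pair * dp
        np.add.at(F, model.pairs[:, 0], fp)
        np.add.at(F, model.pairs[:, 1], -fp)

    if grid is not None:
        from braidsim.vessel import query_sdf

        dist, normal = query_sdf(grid, x)
        for i in range(len(x)):
            F[i] += contact_nodal_force(
                dist[i], normal[i], v[i], settings, model.R_w
            )

    if ext_force is not None:
        F += ext_force
    return F


def strain_energy(model: StructuralModel, x: np.ndarray) -> float:
    """Elastic strain energy (axial + bending + pair), mJ."""
    d = x[model.beams[:, 1]] - x[model.beams[:, 0]]
    L = np.linalg.norm(d, axis=1)
    e = 0.5 * np.sum(model.k_axial * (L - model.L0) ** 2)
    if len(model.triples):
        theta = _included_angles(x, model.triples)
        e += 0.5 * np.sum(model.k_bend * (theta - model.theta0) ** 2)
    if len(model.scissors):
        d = np.linalg.norm(
            x[model.scissors[:, 1]] - x[model.scissors[:, 0]], axis=1
        )
        e += 0.5 * np.sum(model.k_scissor * (d - model.d0_scissor) ** 2)
    if len(model.pairs):
        dp = x[model.pairs[:, 1]] - x[model.pairs[:, 0]]
        e += 0.5 * model.k_pair * np.sum(dp * dp)
    return float(e)


# ---------------------------------------------------------------------------
# Numba relaxation kernel
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _interp_one(values, ox, oy, oz, h, px, py, pz):
    """Single trilinear interpolation with clamped indices."""
    nx, ny, nz = values.shape
    rx = (px - ox) / h
    ry = (py - oy) / h
    rz = (pz - oz) / h
    if rx < 0.0:
        rx = 0.0
    if ry < 0.0:
        ry = 0.0
    if rz < 0.0:
        rz = 0.0
    if rx > nx - 1.000001:
        rx = nx - 1.000001
    if ry > ny - 1.000001:
        ry = ny - 1.000001
    if rz > nz - 1.000001:
        rz = nz - 1.000001
    i0 = int(rx)
    j0 = int(ry)
    k0 = int(rz)
    fx = rx - i0
    fy = ry - j0
    fz = rz - k0
    c00 = values[i0, j0, k0] * (1 - fx) + values[i0 + 1, j0, k0] * fx
    c10 = values[i0, j0 + 1, k0] * (1 - fx) + values[i0 + 1, j0 + 1, k0] * fx
    c01 = values[i0, j0, k0 + 1] * (1 - fx) + values[i0 + 1, j0, k0 + 1] * fx
    c11 = (
        values[i0, j0 + 1, k0 + 1] * (1 - fx)
        + values[i0 + 1, j0 + 1, k0 + 1] * fx
    )
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    return c0 * (1 - fz) + c1 * fz


@njit(cache=True)
def _interp_grad(values, ox, oy, oz, h, px, py, pz):
    """Trilinear SDF value and half-spacing central-difference gradient."""
    nx, ny, nz = values.shape
    vals = np.empty(7)
    for q in range(7):
        qx, qy, qz = px, py, pz
        hh = 0.5 * h
        if q == 1:
            qx += hh
        elif q == 2:
            qx -= hh
        elif q == 3:
            qy += hh
        elif q == 4:
            qy -= hh
        elif q == 5:
            qz += hh
        elif q == 6:
            qz -= hh
        rx = (qx - ox) / h
        ry = (qy - oy) / h
        rz = (qz - oz) / h
        if rx < 0.0:
            rx = 0.0
        if ry < 0.0:
            ry = 0.0
        if rz < 0.0:
            rz = 0.0
        if rx > nx - 1.000001:
            rx = nx - 1.000001
        if ry > ny - 1.000001:
            ry = ny - 1.000001
        if rz > nz - 1.000001:
            rz = nz - 1.000001
        i0 = int(rx)
        j0 = int(ry)
        k0 = int(rz)
        fx = rx - i0
        fy = ry - j0
        fz = rz - k0
        c00 = values[i0, j0, k0] * (1 - fx) + values[i0 + 1, j0, k0] * fx
        c10 = values[i0, j0 + 1, k0] * (1 - fx) + values[i0 + 1, j0 + 1, k0] * fx
        c01 = values[i0, j0, k0 + 1] * (1 - fx) + values[i0 + 1, j0, k0 + 1] * fx
        c11 = (
            values[i0, j0 + 1, k0 + 1] * (1 - fx)
            + values[i0 + 1, j0 + 1, k0 + 1] * fx
        )
        c0 = c00 * (1 - fy) + c10 * fy
        c1 = c01 * (1 - fy) + c11 * fy
        vals[q] = c0 * (1 - fz) + c1 * fz
    gx = (vals[1] - vals[2]) / h
    gy = (vals[3] - vals[4]) / h
    gz = (vals[5] - vals[6]) / h
    return vals[0], gx, gy, gz


@njit(cache=True)
def _forces_kernel(
    x,
    v,
    F,
    bi,
    bj,
    kax,
    L0,
    ta,
    tb,
    tc,
    kbend,
    theta0,
    si,
    sj,
    ksc,
    d0sc,
    pi_,
    pj_,
    k_pair,
    ext,
    has_grid,
    grid_vals,
    gx0,
    gy0,
    gz0,
    gh,
    R_w,
    k_n,
    c_n,
    mu_f,
    v_reg,
    anchor,
    anchor_active,
):
    n = x.shape[0]
    for i in range(n):
        F[i, 0] = ext[i, 0]
        F[i, 1] = ext[i, 1]
        F[i, 2] = ext[i, 2]
    for e in range(bi.shape[0]):
        i = bi[e]
        j = bj[e]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        L = np.sqrt(dx * dx + dy * dy + dz * dz)
        if L < 1e-30:
            continue
        s = kax[e] * (L - L0[e]) / L
        F[i, 0] += s * dx
        F[i, 1] += s * dy
        F[i, 2] += s * dz
        F[j, 0] -= s * dx
        F[j, 1] -= s * dy
        F[j, 2] -= s * dz
    for t in range(ta.shape[0]):
        a = ta[t]
        b = tb[t]
        c = tc[t]
        ux = x[b, 0] - x[a, 0]
        uy = x[b, 1] - x[a, 1]
        uz = x[b, 2] - x[a, 2]
        wx = x[c, 0] - x[b, 0]
        wy = x[c, 1] - x[b, 1]
        wz = x[c, 2] - x[b, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nw = np.sqrt(wx * wx + wy * wy + wz * wz)
        if nu < 1e-30 or nw < 1e-30:
            continue
        uhx, uhy, uhz = ux / nu, uy / nu, uz / nu
        whx, why, whz = wx / nw, wy / nw, wz / nw
        ct = uhx * whx + uhy * why + uhz * whz
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        cx = uhy * whz - uhz * why
        cy = uhz * whx - uhx * whz
        cz = uhx * why - uhy * whx
        st = np.sqrt(cx * cx + cy * cy + cz * cz)
        theta = np.arctan2(st, ct)
        m = kbend[t] * (theta - theta0[t])
        pax = whx - ct * uhx
        pay = why - ct * uhy
        paz = whz - ct * uhz
        pcx = uhx - ct * whx
        pcy = uhy - ct * why
        pcz = uhz - ct * whz
        npa = np.sqrt(pax * pax + pay * pay + paz * paz)
        npc = np.sqrt(pcx * pcx + pcy * pcy + pcz * pcz)
        if npa < 1e-12 or npc < 1e-12:
            continue
        gax = pax / npa / nu
        gay = pay / npa / nu
        gaz = paz / npa / nu
        gcx = -pcx / npc / nw
        gcy = -pcy / npc / nw
        gcz = -pcz / npc / nw
        fax = -m * gax
        fay = -m * gay
        faz = -m * gaz
        fcx = -m * gcx
        fcy = -m * gcy
        fcz = -m * gcz
        F[a, 0] += fax
        F[a, 1] += fay
        F[a, 2] += faz
        F[c, 0] += fcx
        F[c, 1] += fcy
        F[c, 2] += fcz
        F[b, 0] -= fax + fcx
        F[b, 1] -= fay + fcy
        F[b, 2] -= faz + fcz
    for e in range(si.shape[0]):
        i = si[e]
        j = sj[e]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        L = np.sqrt(dx * dx + dy * dy + dz * dz)
        if L < 1e-30:
            continue
        sfac = ksc[e] * (L - d0sc[e]) / L
        F[i, 0] += sfac * dx
        F[i, 1] += sfac * dy
        F[i, 2] += sfac * dz
        F[j, 0] -= sfac * dx
        F[j, 1] -= sfac * dy
        F[j, 2] -= sfac * dz
    for p in range(pi_.shape[0]):
        i = pi_[p]
        j = pj_[p]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        F[i, 0] += k_pair * dx
        F[i, 1] += k_pair * dy
        F[i, 2] += k_pair * dz
        F[j, 0] -= k_pair * dx
        F[j, 1] -= k_pair * dy
        F[j, 2] -= k_pair * dz
    if has_grid:
        for i in range(n):
            d = _interp_one(
                grid_vals, gx0, gy0, gz0, gh, x[i, 0], x[i, 1], x[i, 2]
            )
            if R_w - d <= 0.0:
                anchor_active[i] = 0
                continue
            d, gx, gy, gz = _interp_grad(
                grid_vals, gx0, gy0, gz0, gh, x[i, 0], x[i, 1], x[i, 2]
            )
            delta = R_w - d
            if delta <= 0.0:
                anchor_active[i] = 0
                continue
            gn = np.sqrt(gx * gx + gy * gy + gz * gz)
            if gn < 1e-30:
                anchor_active[i] = 0
                continue
            nx_, ny_, nz_ = gx / gn, gy / gn, gz / gn
            vn = v[i, 0] * nx_ + v[i, 1] * ny_ + v[i, 2] * nz_
            ddot = -vn
            fn = k_n * delta
            if ddot > 0.0:
                fn += c_n * ddot
            if fn < 0.0:
                fn = 0.0
            F[i, 0] += fn * nx_
            F[i, 1] += fn * ny_
            F[i, 2] += fn * nz_
            if mu_f <= 0.0 or fn <= 0.0:
                anchor_active[i] = 0
                continue
            # slip-stick Coulomb friction via an anchored elastic-slip
            # tangential spring (stiffness k_n), capped at mu_f * fn
            if anchor_active[i] == 0:
                anchor[i, 0] = x[i, 0]
                anchor[i, 1] = x[i, 1]
                anchor[i, 2] = x[i, 2]
                anchor_active[i] = 1
                continue
            tdx = x[i, 0] - anchor[i, 0]
            tdy = x[i, 1] - anchor[i, 1]
            tdz = x[i, 2] - anchor[i, 2]
            tn = tdx * nx_ + tdy * ny_ + tdz * nz_
            tdx -= tn * nx_
            tdy -= tn * ny_
            tdz -= tn * nz_
            td = np.sqrt(tdx * tdx + tdy * tdy + tdz * tdz)
            if td < 1e-30:
                anchor[i, 0] = x[i, 0]
                anchor[i, 1] = x[i, 1]
                anchor[i, 2] = x[i, 2]
                continue
            ft = k_n * td
            cap = mu_f * fn
            if ft > cap:
                ft = cap
                # anchor slides along the slip direction
                slide = td - cap / k_n
                anchor[i, 0] += slide * tdx / td
                anchor[i, 1] += slide * tdy / td
                anchor[i, 2] += slide * tdz / td
            F[i, 0] -= ft * tdx / td
            F[i, 1] -= ft * tdy / td
            F[i, 2] -= ft * tdz / td
            # keep the anchor on the node's tangent plane
            anchor[i, 0] += tn * nx_
            anchor[i, 1] += tn * ny_
            anchor[i, 2] += tn * nz_


@njit(cache=True)
def _relax_kernel(
    x,
    v,
    m,
    bi,
    bj,
    kax,
    L0,
    ta,
    tb,
    tc,
    kbend,
    theta0,
    si,
    sj,
    ksc,
    d0sc,
    pi_,
    pj_,
    k_pair,
    fixed,
    fixed_val,
    ext,
    has_grid,
    grid_vals,
    gx0,
    gy0,
    gz0,
    gh,
    R_w,
    k_n,
    c_n,
    mu_f,
    v_reg,
    dt,
    damping,
    max_disp,
    reset_every,
    ke_threshold,
    force_tol,
    max_steps,
    check_every,
    hist_ke,
    hist_res,
):
    n = x.shape[0]
    F = np.zeros((n, 3))
    anchor = np.zeros((n, 3))
    anchor_active = np.zeros(n, dtype=np.uint8)
    ke_prev = 0.0
    n_checks = 0
    steps = 0
    converged = False
    resid = 1e30
    ke = 0.0
    last_check = -1000000
    last_reset = -1000000
    for step in range(max_steps):
        steps = step + 1
        _forces_kernel(
            x, v, F, bi, bj, kax, L0, ta, tb, tc, kbend, theta0,
            si, sj, ksc, d0sc,
            pi_, pj_, k_pair, ext, has_grid, grid_vals, gx0, gy0, gz0, gh,
            R_w, k_n, c_n, mu_f, v_reg, anchor, anchor_active,
        )
        ke = 0.0
        for i in range(n):
            for d3 in range(3):
                if fixed[i, d3]:
                    v[i, d3] = 0.0
                else:
                    v[i, d3] = (v[i, d3] + dt * F[i, d3] / m[i]) * (1.0 - damping)
            # cap the per-step displacement: keeps the released braid
            # quasi-static instead of flailing into tangled states
            sp2 = (v[i, 0] * v[i, 0] + v[i, 1] * v[i, 1] + v[i, 2] * v[i, 2]) * dt * dt
            if sp2 > max_disp * max_disp:
                sc = max_disp / (np.sqrt(sp2))
                v[i, 0] *= sc
                v[i, 1] *= sc
                v[i, 2] *= sc
            for d3 in range(3):
                if not fixed[i, d3]:
                    ke += 0.5 * m[i] * v[i, d3] * v[i, d3]
        reset = False
        if ke < ke_prev and reset_every > 0 and steps - last_reset >= reset_every:
            # kinetic damping: passed an energy peak.  A refractory period
            # keeps local contact chatter from zeroing the coherent
            # expansion velocity at every step.
            for i in range(n):
                v[i, 0] = 0.0
                v[i, 1] = 0.0
                v[i, 2] = 0.0
            ke = 0.0
            reset = True
            last_reset = steps
        for i in range(n):
            for d3 in range(3):
                if fixed[i, d3]:
                    x[i, d3] = fixed_val[i, d3]
                else:
                    x[i, d3] += dt * v[i, d3]
        ke_prev = ke
        scheduled = steps % check_every == 0 or steps == max_steps
        # kinetic-damping resets are natural quasi-static checkpoints
        if scheduled or (reset and steps - last_check >= check_every // 4):
            last_check = steps
            resid = 0.0
            for i in range(n):
                for d3 in range(3):
                    if not fixed[i, d3]:
                        af = abs(F[i, d3])
                        if af > resid:
                            resid = af
            if scheduled and n_checks < hist_ke.shape[0]:
                hist_ke[n_checks] = ke
                hist_res[n_checks] = resid
                n_checks += 1
            if ke < ke_threshold and resid < force_tol:
                converged = True
                break
    return steps, ke, resid, converged, n_checks


# ---------------------------------------------------------------------------
# Relaxation driver
# ---------------------------------------------------------------------------

_EMPTY_GRID = np.zeros((2, 2, 2))


def relax_to_equilibrium(
    model: StructuralModel,
    sdf: SignedDistanceGrid | None = None,
    constraints=None,
    settings: SolverSettings | None = None,
    x_init: np.ndarray | None = None,
    ext_force: np.ndarray | None = None,
):
    """Relax the model to static equilibrium by damped dynamic relaxation.

    ``constraints`` is an optional ``(mask, values)`` pair of an (N, 3)
    boolean array marking prescribed degrees of freedom and their target
    coordinates.  Returns ``(positions, record)`` where ``record`` is a
    dict with steps, final kinetic energy (mJ), residual force (N),
    convergence flag and per-check histories.  Non-convergence within
    ``max_steps`` is flagged, never silent.
    """
    if settings is None:
        settings = SolverSettings()
    x = np.array(x_init if x_init is not None else model.x0, dtype=np.float64)
    v = np.zeros_like(x)
    if constraints is not None:
        mask, values = constraints
        mask = np.ascontiguousarray(mask, dtype=np.bool_)
        fixed_val = np.ascontiguousarray(values, dtype=np.float64)
        x[mask] = fixed_val[mask]
    else:
        mask = np.zeros(x.shape, dtype=np.bool_)
        fixed_val = np.zeros_like(x)
    ext = (
        np.ascontiguousarray(ext_force, dtype=np.float64)
        if ext_force is not None
        else np.zeros_like(x)
    )
    m = settings.mass_factor * settings.dt**2 * model.node_stiffness
    has_grid = sdf is not None
    gv = np.ascontiguousarray(sdf.values) if has_grid else _EMPTY_GRID
    go = sdf.origin if has_grid else np.zeros(3)
    gh = sdf.spacing if has_grid else 1.0
    n_hist = settings.max_steps // settings.check_every + 1
    hist_ke = np.zeros(n_hist)
    hist_res = np.zeros(n_hist)
    steps, ke, resid, converged, n_checks = _relax_kernel(
        x,
        v,
        m,
        model.beams[:, 0],
        model.beams[:, 1],
        model.k_axial,
        model.L0,
        model.triples[:, 0] if len(model.triples) else np.empty(0, np.int64),
        model.triples[:, 1] if len(model.triples) else np.empty(0, np.int64),
        model.triples[:, 2] if len(model.triples) else np.empty(0, np.int64),
        model.k_bend,
        model.theta0,
        model.scissors[:, 0] if len(model.scissors) else np.empty(0, np.int64),
        model.scissors[:, 1] if len(model.scissors) else np.empty(0, np.int64),
        model.k_scissor,
        model.d0_scissor,
        model.pairs[:, 0] if len(model.pairs) else np.empty(0, np.int64),
        model.pairs[:, 1] if len(model.pairs) else np.empty(0, np.int64),
        model.k_pair,
        mask,
        fixed_val,
        ext,
        has_grid,
        gv,
        float(go[0]),
        float(go[1]),
        float(go[2]),
        float(gh),
        model.R_w,
        settings.k_n,
        settings.c_n,
        settings.mu_f,
        settings.v_reg,
        settings.dt,
        settings.damping,
        settings.max_step_disp,
        settings.kinetic_reset_every,
        settings.ke_threshold,
        settings.force_tol,
        settings.max_steps,
        settings.check_every,
        hist_ke,
        hist_res,
    )
    record = {
        "steps": int(steps),
        "kinetic_energy": float(ke),
        "residual": float(resid),
        "converged": bool(converged),
        "history_ke": hist_ke[:n_checks].copy(),
        "history_residual": hist_res[:n_checks].copy(),
    }
    return x, record


# ---------------------------------------------------------------------------
# Three-phase deployment
# ---------------------------------------------------------------------------


def run_deployment(
    stent: StentParameters,
    vessel: VesselParameters,
    eta: float,
    settings: SolverSettings | None = None,
    crimp: CrimpSpec | None = None,
    sdf: SignedDistanceGrid | None = None,
    sdf_spacing: float = 0.1,
    n_position_steps: int = 20,
    n_release_stages: int = 2,
    stage_max_steps: int = 12_000,
    mesh: StentMesh | None = None,
    model: StructuralModel | None = None,
) -> DeploymentResult:
    """Simulate crimping, positioning and deployment of a stent.

    Phases: (1) crimp - radial displacement ``R_s - R_crimped`` prescribed
    with circumferential DOFs blocked, axial free, relaxed to equilibrium;
    (2) position - the crimped stent is swept kinematically along the
    intermediate centerlines ``C_t`` by rigid per-ring transforms until it
    lies on the target centerline ``C_T`` (first ring at arc fraction
    ``eta``); (3) deploy - constraints released with SDF wall contact
    active and relaxed to equilibrium.  The release is staged through a
    virtual sheath: a coaxial tube around the vessel centerline whose
    radius grows from just above the crimp radius to the vessel radius
    over a few intermediate relaxations (the model has no
    wire-to-wire excluded volume, and an instantaneous release of the
    stored crimping energy can fold the braid through itself into tangled
    local minima; gradual unsheathing keeps the expansion quasi-static and
    ordered, as in clinical practice).  ``u_h`` is measured from the free
    reference configuration.

    A precomputed ``sdf`` can be supplied (skipping the sheath staging);
    otherwise the analytic vessel SDF is voxelised at ``sdf_spacing`` on a
    box around the positioned stent.  A prebuilt ``mesh``/``model`` pair
    may be reused across runs of identical stent parameters.
    """
    if settings is None:
        settings = SolverSettings()
    if crimp is None:
        crimp = CrimpSpec()
    if mesh is None:
        mesh = build_stent_mesh(stent)
    if model is None:
        model = assemble_model(mesh, settings=settings)
    phases: list[PhaseRecord] = []

    # --- phase 1: crimp ---
    cf = crimp_displacements(mesh, crimp)
    crimped_xy = mesh.nodes[:, :2] + cf.displacements[:, :2]
    mask = np.zeros(mesh.nodes.shape, dtype=bool)
    mask[:, 0] = True
    mask[:, 1] = True
    values = np.zeros_like(mesh.nodes)
    values[:, :2] = crimped_xy
    x_crimped, rec = relax_to_equilibrium(
        model, sdf=None, constraints=(mask, values), settings=settings
    )
    phases.append(
        PhaseRecord("crimp", rec["steps"], rec["kinetic_energy"],
                    rec["residual"], rec["converged"])
    )

    # --- phase 2: position (kinematic per-ring rigid sweep) ---
    ring_id, centres = assign_rings(x_crimped, tol=1e-3)
    seg_lengths = np.linalg.norm(np.diff(centres, axis=0), axis=1)
    poly = centerline_polyline(vessel)
    c_t = map_centerline(poly, eta, seg_lengths)
    configs = interpolate_configurations(c_t, n_position_steps)
    rel = x_crimped - centres[ring_id]
    x_pos = x_crimped
    for cfg in configs[1:]:
        path = cumulative_alignment(cfg)
        R = ring_rotations(path)
        x_pos = cfg[ring_id] + np.einsum("nij,nj->ni", R[ring_id], rel)
    phases.append(PhaseRecord("position", n_position_steps, 0.0, 0.0, True))

    # --- phase 3: deploy (staged release with wall contact) ---
    x_release = x_pos
    if sdf is None:
        from braidsim.vessel import vessel_and_centerline_grids

        lo = x_pos.min(axis=0) - 4.0
        hi = x_pos.max(axis=0) + 4.0
        sdf, dist_cl = vessel_and_centerline_grids(
            vessel, spacing=sdf_spacing, bounds=(lo, hi)
        )
        if n_release_stages > 0:
            r_start = crimp.R_crimped + mesh.params.R_w + 0.05
            r_end = vessel.D_v / 2.0
            stage_settings = SolverSettings(
                **{**settings.__dict__, "max_steps": stage_max_steps}
            )
            for r_k in np.linspace(r_start, r_end, n_release_stages + 1)[1:]:
                sheath = SignedDistanceGrid(
                    origin=sdf.origin, spacing=sdf.spacing,
                    values=np.minimum(sdf.values, r_k - dist_cl),
                )
                x_release, _ = relax_to_equilibrium(
                    model, sdf=sheath, constraints=None,
                    settings=stage_settings, x_init=x_release,
                )
    x_final, rec = relax_to_equilibrium(
        model, sdf=sdf, constraints=None, settings=settings, x_init=x_release
    )
    phases.append(
        PhaseRecord("deploy", rec["steps"], rec["kinetic_energy"],
                    rec["residual"], rec["converged"])
    )
    converged = all(p.converged for p in phases)
    return DeploymentResult(
        positions=x_final,
        reference=mesh.nodes,
        converged=converged,
        final_kinetic_energy=rec["kinetic_energy"],
        phases=phases,
    )
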