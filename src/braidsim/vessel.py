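"""Idealised aneurysmal-artery geometry and signed distance fields.

The artery is a constant-diameter tube swept along a planar quadratic
Bezier centerline; a saccular aneurysm is a sphere whose centre sits at a
parametrised y-offset from the arc-length midpoint of the centerline.  The
Boolean union of tube and sphere is realised implicitly: the vessel signed
distance field (SDF) is the pointwise maximum of the tube and sphere
implicit functions under the positive-inside convention (positive values in
the lumen, negative outside).  A triangulated surface is extracted from the
zero level set only for STL export and visualisation; the contact solver
consumes the SDF directly.

The SDF of an arbitrary watertight triangle surface can also be computed
(``compute_sdf``): unsigned distances are exact point-triangle distances and
the inside/outside sign comes from the generalized winding number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.spatial import cKDTree

__all__ = [
    "VesselParameters",
    "TriSurface",
    "SignedDistanceGrid",
    "bezier_point",
    "bezier_arc_length",
    "centerline_polyline",
    "aneurysm_centre",
    "polyline_distance",
    "vessel_sdf",
    "vessel_sdf_grid",
    "extract_surface",
    "build_vessel_surface",
    "compute_sdf",
    "query_sdf",
]


@dataclass(frozen=True)
class VesselParameters:
    """Parametric idealised artery with a saccular aneurysm.

    The centerline is the planar quadratic Bezier curve through control
    points ``P0, P1, P2`` (only the y and z coordinates of ``P1`` vary).
    ``D_v`` is the (constant) vessel diameter, ``D_a`` the aneurysm diameter
    and ``y_Ca`` the y-offset of the aneurysm centre from the arc-length
    midpoint of the centerline.  Diameter ranges follow the sampling plan:
    ``D_v`` in [2, 4] mm, ``D_a`` in [5, 10] mm.
    """

    y_P1: float = 7.5  #: y of the middle Bezier control point, mm
    z_P1: float = 30.0  #: z of the middle Bezier control point, mm
    D_v: float = 3.0  #: vessel diameter, mm
    D_a: float = 7.0  #: aneurysm diameter, mm
    y_Ca: float = 2.5  #: aneurysm-centre y-offset from the centerline midpoint, mm
    P0: tuple = (0.0, 0.0, 0.0)  #: fixed proximal endpoint, mm
    P2: tuple = (0.0, 0.0, 60.0)  #: fixed distal endpoint, mm

    def __post_init__(self) -> None:
        if not (2.0 <= self.D_v <= 4.0):
            raise ValueError(f"D_v must lie in [2, 4] mm, got {self.D_v}")
        if not (5.0 <= self.D_a <= 10.0):
            raise ValueError(f"D_a must lie in [5, 10] mm, got {self.D_a}")
        if np.allclose(self.P0, self.P2):
            raise ValueError("P0 and P2 must differ")

    @property
    def P1(self) -> np.ndarray:
        return np.array([0.0, self.y_P1, self.z_P1])

    @property
    def R_a(self) -> float:
        """Aneurysm radius, mm."""
        return self.D_a / 2.0


@dataclass
class TriSurface:
    """Watertight triangulated surface (vertices in mm)."""

    vertices: np.ndarray
    triangles: np.ndarray

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.triangles, process=False
        )

    @classmethod
    def from_trimesh(cls, mesh) -> "TriSurface":
        return cls(
            vertices=np.asarray(mesh.vertices, dtype=float),
            triangles=np.asarray(mesh.faces, dtype=np.int64),
        )

    @property
    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    @property
    def area(self) -> float:
        return float(self.to_trimesh().area)


@dataclass
class SignedDistanceGrid:
    """Voxelised signed distance field, positive inside the lumen.

    ``values[i, j, k]`` is the signed distance (mm) at
    ``origin + spacing * (i, j, k)``.
    """

    origin: np.ndarray
    spacing: float
    values: np.ndarray

    @property
    def dims(self) -> tuple:
        return self.values.shape

    @property
    def upper(self) -> np.ndarray:
        return self.origin + self.spacing * (np.array(self.dims) - 1)


# ---------------------------------------------------------------------------
# Bezier centerline
# ---------------------------------------------------------------------------


def bezier_point(P0, P1, P2, t):
    """Evaluate the planar quadratic Bezier curve
    ``B(t) = (1-t)^2 P0 + 2 t (1-t) P1 + t^2 P2`` for ``t`` in [0, 1].

    ``t`` may be a scalar or an array; a point (or array of points) in mm is
    returned.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0) or np.any(t > 1.0):
        raise ValueError("Bezier parameter t must lie in [0, 1]")
    P0, P1, P2 = (np.asarray(p, dtype=float) for p in (P0, P1, P2))
    tt = t[..., None] if t.ndim else t
    return (1 - tt) ** 2 * P0 + 2 * tt * (1 - tt) * P1 + tt**2 * P2


def bezier_arc_length(P0, P1, P2, t0: float = 0.0, t1: float = 1.0) -> float:
    """Arc length of the quadratic Bezier curve by adaptive quadrature."""
    P0, P1, P2 = (np.asarray(p, dtype=float) for p in (P0, P1, P2))

    def speed(t):
        d = 2 * (1 - t) * (P1 - P0) + 2 * t * (P2 - P1)
        return np.linalg.norm(d)

    val, _ = quad(speed, t0, t1, limit=200)
    return float(val)


def centerline_polyline(vp: VesselParameters, n: int = 2001) -> np.ndarray:
    """Dense polyline sampling of the vessel centerline (n points)."""
    t = np.linspace(0.0, 1.0, n)
    return bezier_point(vp.P0, vp.P1, vp.P2, t)


def _cumulative_arclength(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def aneurysm_centre(vp: VesselParameters, n: int = 2001) -> np.ndarray:
    """Sphere centre: arc-length midpoint of the centerline plus (0, y_Ca, 0)."""
    pts = centerline_polyline(vp, n)
    s = _cumulative_arclength(pts)
    mid = point_at_arclength(pts, s, s[-1] / 2.0)
    return mid + np.array([0.0, vp.y_Ca, 0.0])


def point_at_arclength(points: np.ndarray, s: np.ndarray, target) -> np.ndarray:
    """Interpolate position(s) at arc length(s) ``target`` along a polyline."""
    target = np.asarray(target, dtype=float)
    out = np.stack(
        [np.interp(target, s, points[:, k]) for k in range(3)], axis=-1
    )
    return out


# ---------------------------------------------------------------------------
# Analytic SDF of the tube + sphere union
# ---------------------------------------------------------------------------


def polyline_distance(points: np.ndarray, poly: np.ndarray, tree: cKDTree | None = None):
    """Distance from each query point to a dense polyline.

    The nearest polyline vertices are found with a KD-tree and the exact
    point-segment distance is evaluated on the segments adjacent to them;
    valid for densely sampled smooth curves.
    """
    points = np.atleast_2d(points)
    if tree is None:
        tree = cKDTree(poly)
    _, idx = tree.query(points, k=2)
    n_seg = len(poly) - 1
    # candidate segments: those adjacent to the two nearest vertices
    cand = np.concatenate(
        [np.clip(idx - 1, 0, n_seg - 1), np.clip(idx, 0, n_seg - 1)], axis=1
    )  # (N, 4)
    a = poly[cand]  # (N, 4, 3)
    b = poly[cand + 1]
    ab = b - a
    ap = points[:, None, :] - a
    denom = np.einsum("ijk,ijk->ij", ab, ab)
    tpar = np.clip(np.einsum("ijk,ijk->ij", ap, ab) / np.maximum(denom, 1e-300), 0, 1)
    closest = a + tpar[..., None] * ab
    d = np.linalg.norm(points[:, None, :] - closest, axis=2)
    return d.min(axis=1)


def vessel_sdf(
    points: np.ndarray, vp: VesselParameters, poly: np.ndarray | None = None,
    tree: cKDTree | None = None,
):
    """Signed distance (positive inside) of points to the tube+sphere union.

    Implicit Boolean union: max of the tube implicit function
    ``D_v/2 - dist(p, centerline)`` and the sphere implicit function
    ``R_a - |p - C_a|``.

    Raises
    ------
    ValueError
        If the sphere is fully inside the tube or fully detached from it
        (degenerate geometry: no two-body union exists).
    """
    if poly is None:
        poly = centerline_polyline(vp)
    c_a = _validated_centre(vp, poly)
    points = np.atleast_2d(points)
    tube = vp.D_v / 2.0 - polyline_distance(points, poly, tree)
    sphere = vp.R_a - np.linalg.norm(points - c_a, axis=1)
    return np.maximum(tube, sphere)


def _validated_centre(vp: VesselParameters, poly: np.ndarray) -> np.ndarray:
    s = _cumulative_arclength(poly)
    mid = point_at_arclength(poly, s, s[-1] / 2.0)
    c_a = mid + np.array([0.0, vp.y_Ca, 0.0])
    d_c = float(polyline_distance(c_a[None], poly)[0])
    r_t = vp.D_v / 2.0
    if d_c + vp.R_a <= r_t:
        raise ValueError("degenerate geometry: aneurysm sphere fully inside the tube")
    if d_c - vp.R_a >= r_t:
        raise ValueError("degenerate geometry: aneurysm sphere detached from the tube")
    return c_a


def vessel_sdf_grid(
    vp: VesselParameters,
    spacing: float = 0.1,
    bounds: tuple | None = None,
    pad: float | None = None,
    include_aneurysm: bool = True,
) -> SignedDistanceGrid:
    """Voxelise the analytic vessel SDF on an isotropic grid.

    If ``bounds`` (min corner, max corner) is omitted, the grid covers the
    tube and sphere padded by ``pad`` (default ``D_a / 2``).
    ``include_aneurysm=False`` gives the bare tube (fixture use).
    """
    poly = centerline_polyline(vp)
    c_a = _validated_centre(vp, poly)
    if bounds is None:
        if pad is None:
            pad = vp.D_a / 2.0
        r_t = vp.D_v / 2.0
        lo = np.minimum(poly.min(axis=0) - r_t, c_a - vp.R_a) - pad
        hi = np.maximum(poly.max(axis=0) + r_t, c_a + vp.R_a) + pad
    else:
        lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    dims = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 2)
    axes = [lo[k] + spacing * np.arange(dims[k]) for k in range(3)]
    tree = cKDTree(poly)
    values = np.empty(dims, dtype=np.float64)
    # chunk over x-slabs to bound memory
    yy, zz = np.meshgrid(axes[1], axes[2], indexing="ij")
    for i, x in enumerate(axes[0]):
        pts = np.column_stack(
            [np.full(yy.size, x), yy.ravel(), zz.ravel()]
        )
        val = vp.D_v / 2.0 - polyline_distance(pts, poly, tree)
        if include_aneurysm:
            sphere = vp.R_a - np.linalg.norm(pts - c_a, axis=1)
            val = np.maximum(val, sphere)
        values[i] = val.reshape(yy.shape)
    return SignedDistanceGrid(origin=np.asarray(lo, dtype=float), spacing=float(spacing), values=values)


# ---------------------------------------------------------------------------
# Surface extraction and mesh-based SDF
# ---------------------------------------------------------------------------


def vessel_and_centerline_grids(
    vp: VesselParameters,
    spacing: float,
    bounds: tuple,
):
    """Vessel SDF grid plus the raw distance-to-centerline field.

    The centerline-distance array (same grid layout) lets a caller build
    auxiliary coaxial tube fields - e.g. the virtual sheath used for
    staged stent release - as ``r_sheath - dist_cl`` without recomputing
    polyline distances.
    """
    poly = centerline_polyline(vp)
    c_a = _validated_centre(vp, poly)
    lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    dims = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 2)
    axes = [lo[k] + spacing * np.arange(dims[k]) for k in range(3)]
    tree = cKDTree(poly)
    values = np.empty(dims, dtype=np.float64)
    dist_cl = np.empty(dims, dtype=np.float64)
    yy, zz = np.meshgrid(axes[1], axes[2], indexing="ij")
    for i, xv in enumerate(axes[0]):
        pts = np.column_stack([np.full(yy.size, xv), yy.ravel(), zz.ravel()])
        dcl = polyline_distance(pts, poly, tree)
        sphere = vp.R_a - np.linalg.norm(pts - c_a, axis=1)
        values[i] = np.maximum(vp.D_v / 2.0 - dcl, sphere).reshape(yy.shape)
        dist_cl[i] = dcl.reshape(yy.shape)
    grid = SignedDistanceGrid(origin=lo, spacing=float(spacing), values=values)
    return grid, dist_cl


def extract_surface(grid: SignedDistanceGrid) -> TriSurface:
    """Extract the zero level set of a positive-inside SDF grid.

    Marching cubes is run on the negated field so that the resulting
    triangles are outward-oriented.  The surface is watertight whenever the
    zero level set does not touch the grid boundary.
    """
    from skimage import measure
    import trimesh

    verts, faces, _, _ = measure.marching_cubes(
        -grid.values, level=0.0, spacing=(grid.spacing,) * 3
    )
    verts = verts + grid.origin
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    return TriSurface.from_trimesh(mesh)


def build_vessel_surface(
    vp: VesselParameters,
    spacing: float = 0.1,
    pad: float | None = None,
    bounds: tuple | None = None,
    include_aneurysm: bool = True,
) -> TriSurface:
    """Extract the triangulated vessel surface from the zero level set.

    ``spacing`` is the voxel size used for extraction; it must resolve at
    least 16 circumferential segments of the tube (``spacing <= pi*D_v/16``).
    The result is a watertight, outward-oriented surface of the tube+sphere
    union suitable for STL export.
    """
    if spacing > np.pi * vp.D_v / 16.0:
        raise ValueError(
            "spacing too coarse: fewer than 16 circumferential tube segments"
        )
    grid = vessel_sdf_grid(
        vp, spacing=spacing, bounds=bounds, pad=pad,
        include_aneurysm=include_aneurysm,
    )
    return extract_surface(grid)


def _point_triangle_distance(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact min distance from each point to a set of triangles (vectorised)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    best = np.full(len(points), np.inf)
    # process triangles in blocks
    block = max(1, int(4e6 // max(len(points), 1)))
    for s in range(0, len(tri), block):
        A, AB, AC = a[s : s + block], ab[s : s + block], ac[s : s + block]
        ap = points[:, None, :] - A[None]  # (P, T, 3)
        d1 = np.einsum("ptk,tk->pt", ap, AB)
        d2 = np.einsum("ptk,tk->pt", ap, AC)
        aa = np.einsum("tk,tk->t", AB, AB)
        bb = np.einsum("tk,tk->t", AC, AC)
        abdot = np.einsum("tk,tk->t", AB, AC)
        denom = np.maximum(aa * bb - abdot**2, 1e-300)
        v = (bb * d1 - abdot * d2) / denom
        w = (aa * d2 - abdot * d1) / denom
        v = np.clip(v, 0.0, 1.0)
        w = np.clip(w, 0.0, 1.0)
        scale = np.clip(v + w, 1.0, None)
        v /= scale
        w /= scale
        closest = A[None] + v[..., None] * AB[None] + w[..., None] * AC[None]
        d = np.linalg.norm(points[:, None, :] - closest, axis=2)
        # clamped barycentric projection is not exact on edge regions;
        # refine by also clamping each edge parameterisation
        for E0, E1 in ((A, A + AB), (A, A + AC), (A + AB, A + AC)):
            e = E1 - E0
            ee = np.maximum(np.einsum("tk,tk->t", e, e), 1e-300)
            tpar = np.clip(np.einsum("ptk,tk->pt", points[:, None, :] - E0[None], e) / ee, 0, 1)
            ce = E0[None] + tpar[..., None] * e[None]
            d = np.minimum(d, np.linalg.norm(points[:, None, :] - ce, axis=2))
        best = np.minimum(best, d.min(axis=1))
    return best


def _winding_number(points: np.ndarray, vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Generalized winding number of each point w.r.t. a closed surface."""
    omega = np.zeros(len(points))
    block = max(1, int(2e6 // max(len(points), 1)))
    for s in range(0, len(faces), block):
        f = faces[s : s + block]
        av = vertices[f[:, 0]][None] - points[:, None, :]
        bv = vertices[f[:, 1]][None] - points[:, None, :]
        cv = vertices[f[:, 2]][None] - points[:, None, :]
        la = np.linalg.norm(av, axis=2)
        lb = np.linalg.norm(bv, axis=2)
        lc = np.linalg.norm(cv, axis=2)
        det = np.einsum("ptk,ptk->pt", av, np.cross(bv, cv))
        denom = (
            la * lb * lc
            + np.einsum("ptk,ptk->pt", av, bv) * lc
            + np.einsum("ptk,ptk->pt", bv, cv) * la
            + np.einsum("ptk,ptk->pt", cv, av) * lb
        )
        omega += np.arctan2(det, denom).sum(axis=1)
    return omega / (2.0 * np.pi)


def compute_sdf(
    surface: TriSurface, bounds: tuple, spacing: float
) -> SignedDistanceGrid:
    """Signed distance field of a watertight triangle surface on a voxel grid.

    Positive values lie inside the surface (lumen), negative outside.
    Distances are exact point-triangle distances; the sign comes from the
    generalized winding number, which requires a watertight input.

    Raises
    ------
    ValueError
        If the surface is not watertight (inside/outside is ambiguous).
    """
    if not surface.is_watertight:
        raise ValueError("sign-ambiguity: surface is not watertight")
    lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    dims = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 2)
    axes = [lo[k] + spacing * np.arange(dims[k]) for k in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    tri = surface.vertices[surface.triangles]
    values = np.empty(len(pts))
    chunk = 20000
    for s in range(0, len(pts), chunk):
        p = pts[s : s + chunk]
        d = _point_triangle_distance(p, tri)
        wn = _winding_number(p, surface.vertices, surface.triangles)
        inside = np.abs(wn) > 0.5
        values[s : s + chunk] = np.where(inside, d, -d)
    return SignedDistanceGrid(
        origin=lo, spacing=float(spacing), values=values.reshape(dims)
    )


# ---------------------------------------------------------------------------
# Trilinear queries
# ---------------------------------------------------------------------------


def _trilinear(grid: SignedDistanceGrid, points: np.ndarray) -> np.ndarray:
    rel = (points - grid.origin) / grid.spacing
    dims = np.array(grid.dims)
    i0 = np.floor(rel).astype(np.int64)
    i0 = np.clip(i0, 0, dims - 2)
    f = rel - i0
    v = grid.values
    x0, y0, z0 = i0[:, 0], i0[:, 1], i0[:, 2]
    fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]
    c000 = v[x0, y0, z0]
    c100 = v[x0 + 1, y0, z0]
    c010 = v[x0, y0 + 1, z0]
    c110 = v[x0 + 1, y0 + 1, z0]
    c001 = v[x0, y0, z0 + 1]
    c101 = v[x0 + 1, y0, z0 + 1]
    c011 = v[x0, y0 + 1, z0 + 1]
    c111 = v[x0 + 1, y0 + 1, z0 + 1]
    c00 = c000 * (1 - fx) + c100 * fx
    c10 = c010 * (1 - fx) + c110 * fx
    c01 = c001 * (1 - fx) + c101 * fx
    c11 = c011 * (1 - fx) + c111 * fx
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    return c0 * (1 - fz) + c1 * fz


def query_sdf(grid: SignedDistanceGrid, points: np.ndarray):
    """Trilinearly interpolated signed distance and unit normal at points.

    The normal is the normalised central-difference gradient of the
    interpolated field (half-spacing stencil); under the positive-inside
    convention it points toward the lumen interior.

    Raises
    ------
    ValueError
        If any point lies outside the grid bounds minus a one-voxel margin.
    """
    points = np.asarray(points, dtype=float)
    scalar = points.ndim == 1
    points = np.atleast_2d(points)
    lo = grid.origin + grid.spacing
    hi = grid.upper - grid.spacing
    if np.any(points < lo - 1e-12) or np.any(points > hi + 1e-12):
        raise ValueError("query point outside grid bounds (one-voxel margin)")
    d = _trilinear(grid, points)
    h = grid.spacing / 2.0
    grad = np.empty_like(points)
    for k in range(3):
        e = np.zeros(3)
        e[k] = h
        grad[:, k] = (_trilinear(grid, points + e) - _trilinear(grid, points - e)) / (2 * h)
    norm = np.linalg.norm(grad, axis=1, keepdims=True)
    normal = grad / np.maximum(norm, 1e-30)
    if scalar:
        return float(d[0]), normal[0]
    return d, normal
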