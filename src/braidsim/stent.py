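"""Braided-stent wire mesh generation.

A flow diverter is modelled as a tubular net of thin metallic wires with
circular cross-section.  Half of the wires wind clockwise around the tube
axis and half counter-clockwise, so that the two families interlace.  Nodal
positions follow the analytic braid parametrisation: wire ``n`` of a family
with orientation ``orient`` (+1 clockwise, -1 counter-clockwise) places its
``i``-th node at

    x = (R_s + R_w) * cos(orient * i * dtheta + Theta_n)
    y = (R_s + R_w) * sin(orient * i * dtheta + Theta_n)
    z = i * L_s / N_cells

with ``dtheta = 2 pi / (N_w / 2)`` and ``Theta_n = n * dtheta``, for
``n = 0 .. N_w/2 - 1`` and ``i = 0 .. N_cells``.  The z-advance per cell is
``L_s / N_cells`` so that nodes with equal ``i`` share a z-plane (a *ring*)
and the device has total length ``L_s``.

The resulting mesh has ``N_w * (N_cells + 1)`` nodes and ``N_w * N_cells``
two-node wire segments (beams).  At every ring each clockwise node is
geometrically coincident with exactly one counter-clockwise node; these
coincident pairs are the braid crossings, which the mechanical model ties
together with penalty springs instead of resolving wire-to-wire contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Material",
    "StentParameters",
    "StentMesh",
    "build_stent_mesh",
    "find_crossing_pairs",
    "assign_rings",
]


@dataclass(frozen=True)
class Material:
    """Linear-elastic wire material (defaults: Phynox cobalt-chromium)."""

    E: float = 225.0  #: Young modulus, GPa
    nu: float = 0.33  #: Poisson ratio
    rho: float = 9.13e3  #: density, kg/m^3


@dataclass(frozen=True)
class StentParameters:
    """Geometric and material parameters of the braided stent.

    Defaults describe a generic 48-wire flow diverter: radius 2.6 mm, wire
    radius 0.014 mm, length 15 mm, 70 repetitive cells.
    """

    N_w: int = 48  #: number of wires (even, >= 4)
    R_s: float = 2.6  #: stent radius, mm
    R_w: float = 0.014  #: wire radius, mm
    L_s: float = 15.0  #: stent length, mm
    N_cells: int = 70  #: repetitive units along the length
    material: Material = field(default_factory=Material)

    def __post_init__(self) -> None:
        if self.N_w < 4 or self.N_w % 2 != 0:
            raise ValueError(f"N_w must be an even integer >= 4, got {self.N_w}")
        if self.R_s <= 0 or self.R_w <= 0 or self.L_s <= 0:
            raise ValueError("all stent dimensions must be positive")
        if self.N_cells < 1:
            raise ValueError(f"N_cells must be >= 1, got {self.N_cells}")

    @property
    def dtheta(self) -> float:
        """Angular advance per cell along a wire, rad."""
        return 2.0 * np.pi / (self.N_w / 2)

    @property
    def dz(self) -> float:
        """Axial advance per cell, mm."""
        return self.L_s / self.N_cells

    @property
    def free_radius(self) -> float:
        """Radial distance of wire centrelines from the axis, mm."""
        return self.R_s + self.R_w


@dataclass
class StentMesh:
    """Wire mesh of the braided stent in its free (stress-free) configuration.

    Attributes
    ----------
    nodes : (N_n, 3) float array, mm
    beams : (N_b, 2) int array of node-index pairs (consecutive nodes of a wire)
    wire_id : (N_n,) int array
    orientation : (N_n,) int array, +1 clockwise / -1 counter-clockwise
    ring_id : (N_n,) int array, index of the z-plane ring the node lies on
    crossing_pairs : (N_n/2, 2) int array of coincident (cw, ccw) node pairs
    free_radius : float, mm
    """

    nodes: np.ndarray
    beams: np.ndarray
    wire_id: np.ndarray
    orientation: np.ndarray
    ring_id: np.ndarray
    crossing_pairs: np.ndarray
    free_radius: float
    params: StentParameters

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_rings(self) -> int:
        return int(self.ring_id.max()) + 1


def build_stent_mesh(params: StentParameters) -> StentMesh:
    """Generate the braided-stent wire mesh from its analytic parametrisation.

    Returns a mesh with ``N_w * (N_cells + 1)`` nodes, ``N_w * N_cells``
    beams and ``N_cells + 1`` rings of ``N_w`` nodes; every node sits at
    radial distance ``R_s + R_w`` from the z-axis.
    """
    half = params.N_w // 2
    n_per_wire = params.N_cells + 1
    dtheta = params.dtheta
    r = params.free_radius

    nodes = []
    wire_id = []
    orientation = []
    ring_id = []
    beams = []
    i_idx = np.arange(n_per_wire)
    w = 0
    for orient in (1, -1):
        for n in range(half):
            ang = orient * i_idx * dtheta + n * dtheta
            pts = np.column_stack(
                [r * np.cos(ang), r * np.sin(ang), i_idx * params.dz]
            )
            base = w * n_per_wire
            nodes.append(pts)
            wire_id.append(np.full(n_per_wire, w))
            orientation.append(np.full(n_per_wire, orient))
            ring_id.append(i_idx.copy())
            beams.append(
                np.column_stack([base + i_idx[:-1], base + i_idx[1:]])
            )
            w += 1

    mesh = StentMesh(
        nodes=np.vstack(nodes),
        beams=np.vstack(beams).astype(np.int64),
        wire_id=np.concatenate(wire_id).astype(np.int64),
        orientation=np.concatenate(orientation).astype(np.int64),
        ring_id=np.concatenate(ring_id).astype(np.int64),
        crossing_pairs=np.empty((0, 2), dtype=np.int64),
        free_radius=r,
        params=params,
    )
    mesh.crossing_pairs = find_crossing_pairs(mesh)
    return mesh


def find_crossing_pairs(mesh: StentMesh, tol: float = 1e-9) -> np.ndarray:
    """Identify coincident (clockwise, counter-clockwise) node pairs.

    At every braid crossing one node from each wire family occupies the same
    free-configuration position; the mechanical model forces such pairs to
    move together.  Pairs are matched by exact geometric coincidence within
    ``tol`` (mm).  Each node appears in at most one pair; a mesh with a
    single wire family yields an empty list.
    """
    cw = np.flatnonzero(mesh.orientation == 1)
    ccw = np.flatnonzero(mesh.orientation == -1)
    if len(cw) == 0 or len(ccw) == 0:
        return np.empty((0, 2), dtype=np.int64)

    # hash rounded coordinates; tol guards float noise on an exact coincidence
    decimals = int(round(-np.log10(tol)))
    key = np.round(mesh.nodes, decimals=decimals)
    lookup: dict[tuple[float, float, float], int] = {}
    for j in ccw:
        lookup.setdefault(tuple(key[j]), j)
    pairs = []
    used: set[int] = set()
    for i in cw:
        j = lookup.get(tuple(key[i]))
        if j is not None and j not in used:
            if np.linalg.norm(mesh.nodes[i] - mesh.nodes[j]) < tol:
                pairs.append((i, j))
                used.add(j)
    if not pairs:
        return np.empty((0, 2), dtype=np.int64)
    return np.asarray(sorted(pairs), dtype=np.int64)


def assign_rings(
    nodes: np.ndarray, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Group nodes into z-plane rings and compute ring centres.

    Nodes sharing a z-coordinate (within ``tol`` mm) form one ring; rings are
    numbered in increasing z.  The ring centre is the centroid of its nodes:
    on the free (or crimped) straight configuration the centres lie on the
    z-axis and define the initially straight stent centerline.

    Parameters
    ----------
    nodes : (N, 3) array
    tol : float
        z-clustering tolerance, mm.

    Returns
    -------
    ring_id : (N,) int array
    centres : (N_r, 3) array of ring centroids, mm.

    Raises
    ------
    ValueError
        If the z-coordinates do not cluster into well-separated planes.
    """
    nodes = np.asarray(nodes, dtype=float)
    z = nodes[:, 2]
    order = np.argsort(z)
    zs = z[order]
    breaks = np.diff(zs) > tol
    labels_sorted = np.concatenate([[0], np.cumsum(breaks)])
    ring_id = np.empty(len(z), dtype=np.int64)
    ring_id[order] = labels_sorted
    n_rings = labels_sorted[-1] + 1
    # each cluster must be tight: max spread within tol of cluster mean
    for rid in range(n_rings):
        zr = z[ring_id == rid]
        if zr.max() - zr.min() > 2 * tol:
            raise ValueError(
                "nodes are not groupable into z-planes within tolerance"
            )
    centres = np.stack(
        [nodes[ring_id == rid].mean(axis=0) for rid in range(n_rings)]
    )
    return ring_id, centres
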