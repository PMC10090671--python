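"""Crimp and positioning kinematics for stent deployment.

Deployment is driven kinematically in three stages.  First the stent is
crimped: every node receives a prescribed radially-inward displacement of
magnitude ``R_s - R_crimped`` with its circumferential coordinate blocked
and its axial coordinate free (the braid elongates axially).  The ring
centroids of the crimped stent define an initially straight centerline
``C_0`` along the z-axis.  The target centerline ``C_T`` is the projection
of ``C_0`` onto the vessel centerline: points placed along the vessel at
arc-length spacings equal to the ``C_0`` segment lengths, starting at the
deployment-site fraction ``eta``, so the total stent-centerline length is
conserved.

Each segment of ``C_T`` carries a rotation (axis = normalised cross product
with the previous segment, angle = their included angle) that realigns it
to its predecessor; the first segment is referenced to the z-axis.
Cumulatively composing these rotations straightens ``C_T`` back into
``C_0``, and scaling every rotation angle by ``t/n_steps`` produces the
intermediate centerlines ``C_t`` that sweep the stent from straight to
fully positioned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from braidsim.stent import StentMesh

__all__ = [
    "CrimpSpec",
    "CrimpField",
    "CenterlinePath",
    "crimp_displacements",
    "map_centerline",
    "segment_rotation",
    "rotation_matrix",
    "cumulative_alignment",
    "ring_rotations",
    "interpolate_configurations",
]

_EZ = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class CrimpSpec:
    """Target crimped radius of the stent wire centrelines, mm."""

    R_crimped: float = 0.9


@dataclass
class CrimpField:
    """Prescribed crimp displacement field.

    ``displacements`` are radially inward vectors of magnitude
    ``R_s - R_crimped`` per node; during crimping the radial and
    circumferential coordinates are prescribed/blocked and only the axial
    (z) coordinate is free.
    """

    displacements: np.ndarray
    target_radius: np.ndarray  # per-node wire-centre radius after crimping
    angles: np.ndarray  # per-node fixed circumferential coordinate, rad
    magnitude: float


@dataclass
class CenterlinePath:
    """Ordered centerline points with per-segment alignment rotations.

    ``axes[i]``/``angles[i]`` rotate segment i+1 parallel to its
    predecessor (segment 0 is referenced to the z-axis); ``M_tot[i]`` is the
    cumulative rotation that maps segment i+1 of the path onto +z.
    ``straightened`` is the recovered straight path C_0.
    """

    points: np.ndarray
    axes: np.ndarray
    angles: np.ndarray
    M_tot: np.ndarray
    straightened: np.ndarray

    @property
    def segments(self) -> np.ndarray:
        return np.diff(self.points, axis=0)

    @property
    def total_length(self) -> float:
        return float(np.linalg.norm(self.segments, axis=1).sum())


def crimp_displacements(mesh: StentMesh, spec: CrimpSpec) -> CrimpField:
    """Prescribed radial displacement field that crimps the stent.

    Every node moves radially inward by ``R_s - R_crimped``; the wire-centre
    radius after crimping is ``R_crimped + R_w``.

    Raises
    ------
    ValueError
        If ``R_crimped`` is not strictly between 0 and ``R_s``.
    """
    R_s = mesh.params.R_s
    if not (0.0 < spec.R_crimped < R_s):
        raise ValueError(
            f"R_crimped must lie strictly in (0, R_s={R_s}), got {spec.R_crimped}"
        )
    magnitude = R_s - spec.R_crimped
    radii = np.hypot(mesh.nodes[:, 0], mesh.nodes[:, 1])
    angles = np.arctan2(mesh.nodes[:, 1], mesh.nodes[:, 0])
    outward = np.column_stack([np.cos(angles), np.sin(angles), np.zeros(len(angles))])
    disp = -magnitude * outward
    return CrimpField(
        displacements=disp,
        target_radius=radii - magnitude,
        angles=angles,
        magnitude=magnitude,
    )


def map_centerline(
    vessel_polyline: np.ndarray,
    eta: float,
    segment_lengths: np.ndarray,
) -> np.ndarray:
    """Project the straight stent centerline onto the vessel centerline.

    Places ``len(segment_lengths) + 1`` points on the vessel centerline at
    arc-length spacings equal to the straight-centerline segment lengths,
    with the first point at arc-length fraction ``eta``; the total stent
    centerline length is conserved exactly (up to float rounding).

    Raises
    ------
    ValueError
        If ``eta`` is outside [0, 1] or the stent does not fit in the
        remaining vessel arc length.
    """
    if not (0.0 <= eta <= 1.0):
        raise ValueError(f"eta must lie in [0, 1], got {eta}")
    segment_lengths = np.asarray(segment_lengths, dtype=float)
    seg = np.linalg.norm(np.diff(vessel_polyline, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    s0 = eta * s[-1]
    targets = s0 + np.concatenate([[0.0], np.cumsum(segment_lengths)])
    if targets[-1] > s[-1] * (1 + 1e-12):
        raise ValueError(
            "placement error: stent centerline exceeds remaining vessel arc"
        )
    return np.stack(
        [np.interp(targets, s, vessel_polyline[:, k]) for k in range(3)], axis=-1
    )


def segment_rotation(seg_i: np.ndarray, seg_prev: np.ndarray):
    """Axis and angle rotating ``seg_i`` parallel to ``seg_prev``.

    ``axis = (seg_i x seg_prev) / (|seg_i||seg_prev|)`` normalised and
    ``angle = arccos(seg_i . seg_prev / (|seg_i||seg_prev|))``.  Parallel
    segments return the identity (zero angle); anti-parallel segments take
    the first coordinate basis vector orthogonal to the segment as axis.

    Raises
    ------
    ValueError
        On zero-length input segments.
    """
    seg_i = np.asarray(seg_i, dtype=float)
    seg_prev = np.asarray(seg_prev, dtype=float)
    ni = np.linalg.norm(seg_i)
    npv = np.linalg.norm(seg_prev)
    if ni == 0.0 or npv == 0.0:
        raise ValueError("zero-length segment")
    cross = np.cross(seg_i, seg_prev)
    sin_a = np.linalg.norm(cross) / (ni * npv)
    cos_a = float(np.dot(seg_i, seg_prev) / (ni * npv))
    angle = float(np.arctan2(sin_a, cos_a))
    if sin_a < 1e-15:
        if cos_a > 0.0:  # parallel
            return _EZ.copy(), 0.0
        # anti-parallel: deterministic axis orthogonal to the segment
        for k in range(3):
            e = np.zeros(3)
            e[k] = 1.0
            c = np.cross(seg_i, e)
            if np.linalg.norm(c) > 1e-12 * ni:
                return c / np.linalg.norm(c), float(np.pi)
    return cross / np.linalg.norm(cross), angle


def rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0.0:
        return np.eye(3)
    x, y, z = axis / n
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def cumulative_alignment(points: np.ndarray) -> CenterlinePath:
    """Cumulative rotations straightening a centerline onto the z-axis.

    Processes segments in order; for each, the rotation realigning it (in
    the progressively straightened frame) to its predecessor is composed
    into ``M_tot``, the first segment being referenced to +z.  Applying
    ``M_tot[i]`` to segment i+1 yields a +z-aligned vector, so the path
    unrolls into the straight centerline C_0 with identical segment
    lengths, starting at the original first point.

    Raises
    ------
    ValueError
        On repeated (zero-separation) consecutive points.
    """
    points = np.asarray(points, dtype=float)
    segs = np.diff(points, axis=0)
    lens = np.linalg.norm(segs, axis=1)
    if np.any(lens == 0.0):
        raise ValueError("degenerate path: repeated consecutive points")
    n_seg = len(segs)
    axes = np.zeros((n_seg, 3))
    angles = np.zeros(n_seg)
    M_tot = np.zeros((n_seg, 3, 3))
    Q = np.eye(3)
    straight = np.zeros_like(points)
    straight[0] = points[0]
    for i in range(n_seg):
        v = Q @ segs[i]
        ax, ang = segment_rotation(v, _EZ)
        axes[i] = ax
        angles[i] = ang
        Q = rotation_matrix(ax, ang) @ Q
        M_tot[i] = Q
        straight[i + 1] = straight[i] + lens[i] * _EZ
    return CenterlinePath(
        points=points, axes=axes, angles=angles, M_tot=M_tot, straightened=straight
    )


def ring_rotations(path: CenterlinePath) -> np.ndarray:
    """Per-ring rotation matrices mapping the straight frame to the path.

    Ring 0 keeps the identity (the first point is treated as z-aligned);
    ring i >= 1 carries ``M_tot[i-1].T``, the inverse of the cumulative
    straightening rotation of the segment ending at that ring.
    """
    n_rings = len(path.points)
    R = np.empty((n_rings, 3, 3))
    R[0] = np.eye(3)
    for i in range(1, n_rings):
        R[i] = path.M_tot[i - 1].T
    return R


def interpolate_configurations(points: np.ndarray, n_steps: int) -> list[np.ndarray]:
    """Intermediate centerlines sweeping from straight C_0 to the target C_T.

    Every per-segment rotation angle is scaled by ``t / n_steps`` and the
    partially rotated segments are re-chained from the fixed first point;
    all intermediate paths preserve every segment length.  Returns the
    ``n_steps + 1`` paths ``[C_0, ..., C_T]``.
    """
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    path = cumulative_alignment(points)
    lens = np.linalg.norm(path.segments, axis=1)
    configs = []
    for t in range(n_steps + 1):
        f = t / n_steps
        Q = np.eye(3)
        pts = np.zeros_like(path.points)
        pts[0] = path.points[0]
        for i in range(len(lens)):
            Q = rotation_matrix(path.axes[i], f * path.angles[i]) @ Q
            pts[i + 1] = pts[i] + Q.T @ (lens[i] * _EZ)
        configs.append(pts)
    return configs
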