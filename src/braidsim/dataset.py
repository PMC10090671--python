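"""Design of experiments, outcome labelling and dataset assembly.

The deployment study samples the six simulation parameters

    mu_B = (y_P1, z_P1, D_v, D_a, y_Ca, eta)

with a Latin hypercube: the vessel shape (middle Bezier point), vessel and
aneurysm diameters, aneurysm offset and the deployment site.  Since
misplacement is the object of study, the deployment site is sampled so
that the stent's first ring lands near the aneurysm neck: the LHS draws a
dimensionless neck offset ``u`` in [-1, 1] and the first ring is placed at
arc length ``s_mid + u * D_a`` (one dome diameter to either side of the
neck centre), from which ``eta`` follows.  The aneurysm-centre offset is
sampled as ``y_Ca = D_v/2 + offset`` with ``offset`` in [0, 2] mm, giving
wide-neck saccular aneurysms of the kind flow diverters treat.

A deployment *fails* when any node of the stent's extremity rings ends up
inside the aneurysm sac: node ``x_p`` is inside when

    R_a - ||C_a - x_p|| - r_w >= 0,

i.e. its wire surface lies fully within the sphere.  Successful, converged
solutions provide the displacement snapshots assembled column-wise into
the snapshot matrix used by the reduced-order model.

The alternative geometric predictors

    mu_cl = (y_Q1, z_Q1, ..., y_QNcl, z_QNcl, D_v, D_a, y_Ca)

replace (P1, eta) with ``N_cl`` points sampled equidistantly (by arc
length) along the positioned stent centerline C_T; they are computed
purely geometrically - the crimped stent length follows from wire
inextensibility - and need no mechanical simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

from braidsim.kinematics import CrimpSpec, map_centerline
from braidsim.solver import DeploymentResult, SolverSettings, run_deployment
from braidsim.stent import StentParameters, build_stent_mesh
from braidsim.vessel import (
    VesselParameters,
    aneurysm_centre,
    centerline_polyline,
)

__all__ = [
    "ParameterRanges",
    "SimulationParameterVector",
    "SnapshotMatrix",
    "lhs_sample",
    "label_outcome",
    "crimped_segment_length",
    "centerline_predictors",
    "build_snapshot_matrix",
    "run_study",
    "StudyResult",
    "train_test_split",
    "Standardiser",
]

MU_B_NAMES = ("y_P1", "z_P1", "D_v", "D_a", "y_Ca", "eta")


@dataclass(frozen=True)
class ParameterRanges:
    """Sampling ranges of the deployment study (mm where dimensional)."""

    y_P1: tuple = (0.0, 15.0)
    z_P1: tuple = (25.0, 35.0)
    D_v: tuple = (2.0, 4.0)
    D_a: tuple = (5.0, 10.0)
    y_Ca_offset: tuple = (0.0, 2.0)  #: y_Ca - D_v/2
    neck_offset: tuple = (-1.0, 1.0)  #: first-ring offset from neck, units of D_a

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.y_P1, self.z_P1, self.D_v, self.D_a,
             self.y_Ca_offset, self.neck_offset]
        )


@dataclass(frozen=True)
class SimulationParameterVector:
    """One draw of the simulation parameters mu_B."""

    y_P1: float
    z_P1: float
    D_v: float
    D_a: float
    y_Ca: float
    eta: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.y_P1, self.z_P1, self.D_v, self.D_a, self.y_Ca, self.eta]
        )

    def vessel(self) -> VesselParameters:
        return VesselParameters(
            y_P1=self.y_P1, z_P1=self.z_P1, D_v=self.D_v,
            D_a=self.D_a, y_Ca=self.y_Ca,
        )


def lhs_sample(
    ranges: ParameterRanges, N_s: int, seed: int
) -> tuple[list[SimulationParameterVector], np.ndarray]:
    """Latin hypercube sample of the simulation parameters.

    Returns the resolved parameter vectors and the raw stratified design
    in physical units (columns ordered as ``ParameterRanges``).  Each
    dimension places exactly one sample in each of ``N_s`` equal-width
    strata; the design is reproducible from the seed.  The deployment-site
    fraction ``eta`` is resolved per sample from the stratified neck
    offset and the vessel arc length.
    """
    if N_s < 1:
        raise ValueError("N_s must be >= 1")
    arr = ranges.as_array()
    if np.any(arr[:, 1] <= arr[:, 0]):
        raise ValueError("inverted or empty sampling range")
    unit = qmc.LatinHypercube(d=6, seed=seed).random(N_s)
    design = arr[:, 0] + unit * (arr[:, 1] - arr[:, 0])
    samples = []
    for row in design:
        y_p1, z_p1, d_v, d_a, off, u = row
        y_ca = d_v / 2.0 + off
        vp = VesselParameters(y_P1=y_p1, z_P1=z_p1, D_v=d_v, D_a=d_a, y_Ca=y_ca)
        poly = centerline_polyline(vp)
        seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
        arc = seg.sum()
        s_mid = arc / 2.0
        eta = float(np.clip((s_mid + u * d_a) / arc, 0.0, 1.0))
        samples.append(
            SimulationParameterVector(
                y_P1=float(y_p1), z_P1=float(z_p1), D_v=float(d_v),
                D_a=float(d_a), y_Ca=float(y_ca), eta=eta,
            )
        )
    return samples, design


def label_outcome(
    result: DeploymentResult,
    vessel: VesselParameters,
    stent: StentParameters,
    ring_id: np.ndarray | None = None,
) -> bool:
    """Label a converged deployment: True = success, False = failure.

    Failure means one or more extremity nodes (first or last ring) landed
    inside the aneurysm sac: ``R_a - ||C_a - x_p|| - r_w >= 0`` (boundary
    counted inside).

    Raises
    ------
    ValueError
        For non-converged results (labelling refused).
    """
    if not result.converged:
        raise ValueError("labelling refused: simulation did not converge")
    if ring_id is None:
        ring_id = build_stent_mesh(stent).ring_id
    n_rings = int(ring_id.max()) + 1
    ends = (ring_id == 0) | (ring_id == n_rings - 1)
    x_p = result.positions[ends]
    c_a = aneurysm_centre(vessel)
    depth = vessel.R_a - np.linalg.norm(c_a - x_p, axis=1) - stent.R_w
    return not bool(np.any(depth >= 0.0))


def crimped_segment_length(stent: StentParameters, crimp: CrimpSpec) -> float:
    """Axial length of one crimped cell from wire inextensibility.

    A wire segment spans one cell with chord components ``dz`` axially and
    ``2 r sin(dtheta/2)`` circumferentially; crimping reduces the braid
    radius while conserving segment length, so the axial span grows to
    ``sqrt(dz^2 + c_free^2 - c_crimped^2)``.
    """
    r_free = stent.R_s + stent.R_w
    r_crimp = crimp.R_crimped + stent.R_w
    half = np.sin(stent.dtheta / 2.0)
    c_free = 2.0 * r_free * half
    c_crimp = 2.0 * r_crimp * half
    arg = stent.dz**2 + c_free**2 - c_crimp**2
    return float(np.sqrt(arg))


def centerline_predictors(
    mu: SimulationParameterVector,
    stent: StentParameters,
    N_cl: int,
    crimp: CrimpSpec | None = None,
) -> np.ndarray:
    """Geometric predictor vector mu_cl of dimension ``2*N_cl + 3``.

    ``N_cl`` points are sampled on the positioned stent centerline C_T,
    equally spaced by arc length with Q_1 and Q_Ncl at its endpoints; the
    y and z coordinates of each (the geometry is planar in x) are followed
    by (D_v, D_a, y_Ca).  No mechanical simulation is involved.
    """
    if N_cl < 2:
        raise ValueError("N_cl must be >= 2")
    if crimp is None:
        crimp = CrimpSpec()
    vp = mu.vessel()
    poly = centerline_polyline(vp)
    seg_len = crimped_segment_length(stent, crimp)
    total = seg_len * stent.N_cells
    # N_cl - 1 equal arc spacings spanning the full crimped centerline
    spacings = np.full(N_cl - 1, total / (N_cl - 1))
    q = map_centerline(poly, mu.eta, spacings)
    return np.concatenate([q[:, 1:].ravel(), [mu.D_v, mu.D_a, mu.y_Ca]])


@dataclass
class SnapshotMatrix:
    """Snapshot matrix S: columns are displacement vectors u_h(mu_i)."""

    S: np.ndarray  # (N_h, N_s)
    parameters: list  # index-aligned SimulationParameterVector list

    @property
    def N_h(self) -> int:
        return self.S.shape[0]

    @property
    def n_snapshots(self) -> int:
        return self.S.shape[1]


def build_snapshot_matrix(
    results: list[DeploymentResult],
    parameters: list[SimulationParameterVector] | None = None,
) -> SnapshotMatrix:
    """Assemble converged successful displacement vectors column-wise.

    Raises
    ------
    ValueError
        On empty input, mixed mesh sizes or non-converged members.
    """
    if not results:
        raise ValueError("empty snapshot set")
    n_h = len(results[0].u_h)
    cols = []
    for r in results:
        if not r.converged:
            raise ValueError("non-converged result in snapshot set")
        if len(r.u_h) != n_h:
            raise ValueError("mixed mesh sizes in snapshot set")
        cols.append(r.u_h)
    if parameters is None:
        parameters = [None] * len(results)
    return SnapshotMatrix(S=np.column_stack(cols), parameters=list(parameters))


# ---------------------------------------------------------------------------
# Batch simulation
# ---------------------------------------------------------------------------


@dataclass
class StudyRecord:
    mu: SimulationParameterVector
    converged: bool
    success: bool | None
    u_h: np.ndarray | None
    kinetic_energy: float = float("nan")


@dataclass
class StudyResult:
    """Outcome of a batch of LHS-sampled deployment simulations."""

    records: list
    stent: StentParameters
    ranges: ParameterRanges
    seed: int

    @property
    def converged_records(self) -> list:
        return [r for r in self.records if r.converged]

    @property
    def successful_records(self) -> list:
        return [r for r in self.records if r.converged and r.success]

    def classification_arrays(self):
        """(X, y) over converged records: mu_B rows, success labels."""
        recs = self.converged_records
        X = np.stack([r.mu.as_array() for r in recs])
        y = np.array([bool(r.success) for r in recs])
        return X, y

    def snapshot_matrix(self) -> SnapshotMatrix:
        recs = self.successful_records
        if not recs:
            raise ValueError("no successful converged simulations")
        return SnapshotMatrix(
            S=np.column_stack([r.u_h for r in recs]),
            parameters=[r.mu for r in recs],
        )


def run_study(
    stent: StentParameters,
    ranges: ParameterRanges,
    N_s: int,
    seed: int,
    settings: SolverSettings | None = None,
    crimp: CrimpSpec | None = None,
    sdf_spacing: float = 0.2,
    n_position_steps: int = 20,
    min_successes: int | None = None,
    max_batches: int = 6,
    progress: bool = False,
) -> StudyResult:
    """Run an LHS batch of deployment simulations and label the outcomes.

    With ``min_successes`` set, further batches of ``N_s`` samples (fresh
    LHS designs seeded from ``seed``) are appended until that many
    successful converged simulations are available or ``max_batches`` is
    exhausted.  Non-converged runs are kept in the records but excluded
    from classification arrays and snapshots.
    """
    if settings is None:
        settings = SolverSettings()
    if crimp is None:
        crimp = CrimpSpec()
    mesh = build_stent_mesh(stent)
    from braidsim.solver import assemble_model

    model = assemble_model(mesh, settings=settings)
    records: list[StudyRecord] = []
    n_success = 0
    for batch in range(max_batches):
        samples, _ = lhs_sample(ranges, N_s, seed + 7919 * batch)
        for mu in samples:
            vp = mu.vessel()
            try:
                res = run_deployment(
                    stent, vp, mu.eta, settings=settings, crimp=crimp,
                    sdf_spacing=sdf_spacing, n_position_steps=n_position_steps,
                    mesh=mesh, model=model,
                )
            except ValueError:
                # degenerate geometry or placement failure: unusable draw
                records.append(
                    StudyRecord(mu=mu, converged=False, success=None, u_h=None)
                )
                continue
            if res.converged:
                success = label_outcome(res, vp, stent, ring_id=mesh.ring_id)
                records.append(
                    StudyRecord(mu=mu, converged=True, success=success,
                                u_h=res.u_h.copy(),
                                kinetic_energy=res.final_kinetic_energy)
                )
                n_success += int(success)
            else:
                records.append(
                    StudyRecord(mu=mu, converged=False, success=None, u_h=None)
                )
            if progress:
                print(
                    f"  sim {len(records)}: converged={res.converged} "
                    f"successes={n_success}", flush=True,
                )
            if min_successes is not None and n_success >= min_successes:
                break
        if min_successes is None or n_success >= min_successes:
            break
    return StudyResult(records=records, stent=stent, ranges=ranges, seed=seed)


# ---------------------------------------------------------------------------
# Splitting and standardisation
# ---------------------------------------------------------------------------


def train_test_split(n: int, n_test: int, seed: int):
    """Deterministic shuffled index split (train, test)."""
    if n_test >= n:
        raise ValueError("n_test must be smaller than the dataset")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    return idx[n_test:], idx[:n_test]


@dataclass
class Standardiser:
    """Per-feature standardisation fitted on the training split only."""

    mean: np.ndarray = field(default_factory=lambda: np.zeros(0))
    std: np.ndarray = field(default_factory=lambda: np.ones(0))

    def fit(self, X: np.ndarray) -> "Standardiser":
        self.mean = X.mean(axis=0)
        self.std = X.std(axis=0)
        self.std = np.where(self.std < 1e-12, 1.0, self.std)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.std

    def inverse(self, X: np.ndarray) -> np.ndarray:
        return X * self.std + self.mean
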