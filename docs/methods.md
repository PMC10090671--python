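# Methods

`braidsim` simulates the endovascular deployment of a braided
flow-diverter stent into an idealised aneurysmal artery and builds two
machine-learning layers on top of the simulations: binary classifiers that
predict whether a deployment succeeds, and a non-intrusive reduced-order
model (POD + Gaussian-process regression) that predicts the deployed stent
shape in milliseconds. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic studies do and do
not demonstrate.

## Stent geometry

The device is a tubular braid of `N_w` wires (half wound clockwise, half
counter-clockwise) of radius `R_w`, braided on a cylinder of radius `R_s`
over `N_cells` repetitive units and total length `L_s`. Node positions are
analytic: wire `n` of orientation `o = +-1` places node `i` at azimuth
`o*i*dtheta + n*dtheta` (with `dtheta = 4*pi/N_w`) and height
`z = i*L_s/N_cells`, at cylindrical radius `R_s + R_w`. This yields
`N_w*(N_cells+1)` nodes, `N_w*N_cells` wire segments, `N_cells+1` rings of
`N_w` nodes, and one geometrically coincident clockwise/counter-clockwise
node pair per ring slot — the braid crossings. The default device (48
wires, `R_s = 2.6` mm, `R_w = 0.014` mm, `L_s = 15` mm, 70 cells, Phynox:
E = 225 GPa, nu = 0.33, rho = 9130 kg/m^3) has 3,408 nodes and 3,360
segments.

## Vessel geometry and signed distance field

The artery is a constant-diameter tube (`D_v` in [2, 4] mm) swept along a
planar quadratic Bezier centerline with fixed endpoints
`P0 = (0, 0, 0)` and `P2 = (0, 0, 60)` mm and a free middle control point
`(0, y_P1, z_P1)`. A spherical aneurysm sac (`D_a` in [5, 10] mm) is
centred at the arc-length midpoint of the centerline offset by
`(0, y_Ca, 0)`. The 60 mm length was chosen because the crimped stent
elongates to roughly 20 mm (see below) and the sampled deployment sites
must leave room for the device distal of the aneurysm neck; a shorter
vessel cannot host the full deployment-site window.

The tube/sphere Boolean union is implicit: the vessel signed distance
field is the voxelised pointwise maximum of the tube field
(`D_v/2 - dist(p, centerline)`) and the sphere field
(`R_a - |p - C_a|`), positive inside the lumen. Near the union seam this
is a valid implicit function though not an exact Euclidean distance; the
contact solver only queries it near the wall where it is exact. Surfaces
(for STL export) are extracted from the zero level set by marching cubes.
A mesh-based SDF for arbitrary watertight surfaces is also provided
(exact point-triangle distances, generalized-winding-number sign). The
default grid spacing is 0.1 mm (0.2 mm at study scale), below the 0.15 mm
imaging-resolution threshold used to judge ROM errors.

## Mechanical model

Wires are modelled as a network of springs assembled once in the free
(stress-free) configuration:

* axial springs per wire segment, stiffness `EA/L0`;
* turning-angle springs at interior wire nodes, energy
  `1/2 * (EI/l_v) * (theta - theta0)^2` with `l_v` the mean of the two
  adjacent segment lengths (half an edge at a clamped end, which
  reproduces the Euler-Bernoulli cantilever to < 1%);
* scissor springs at the braid crossings: distance springs of stiffness
  `EI/l^3` between the wire successors, and between the wire
  predecessors, of each coincident pair. These penalise changes of the
  local angle at which the two wire families cross — the collective
  degree of freedom that sets the braid radius. Without them the wire
  twist distribution is unconstrained: a braid crimped to a smaller
  radius would be (almost) as stress-free as the nominal helix, the model
  would have no radial re-expansion drive, and the released device would
  not recover its free shape. A positional discrete-torsion (dihedral)
  term was evaluated and rejected: its gradients scale as 1/sin(theta)
  and the fine braid's nearly straight crimped wires sit in that singular
  regime. Rod torsion (`GJ`) is otherwise omitted — a deliberate fidelity
  reduction;
* penalty springs (default 10x the relaxation axial stiffness) forcing
  the coincident crossing-pair nodes to share a position;
* unilateral viscoelastic penalty contact against the rigid vessel wall:
  with wall distance `d` (trilinear SDF interpolation) a node penetrates
  when `d < R_w` (the wire surface touches first); the normal force is
  `k_n*delta + c_n*max(d(delta)/dt, 0)`, clamped non-negative (no
  adhesion), along the inward SDF gradient. Tangentially the relaxation
  kernel uses slip-stick Coulomb friction with an anchored elastic-slip
  spring capped at `mu_f * F_n` (velocity-regularised laws cannot carry
  static tangential load and the stent then creeps indefinitely); the
  stateless single-node contact law exposed in the API uses the smooth
  `mu_f * F_n * tanh(|v_t|/v_reg)` form.

Defaults: `k_n = 10` N/mm, `c_n = 1e-3` N s/mm, `mu_f = 0.2`,
`v_reg = 1` mm/s. The contact penetration at equilibrium is
`F_n/k_n`, typically well below a micron per node.

## Equilibrium solver

Static equilibria are found by dynamic relaxation: explicit pseudo-time
stepping with fictitious nodal masses proportional to the summed incident
stiffness (`m_i = dt^2 * k_i`), light viscous damping (2 %/step), kinetic
damping (global velocity reset at kinetic-energy peaks, with a 500-step
refractory period so that local contact chatter cannot stall the coherent
expansion), and a per-step displacement cap of 0.02 mm that keeps the
release quasi-static. Because masses scale with `dt^2` the trajectory is
independent of the nominal time step. A state is converged when the
kinetic energy is below 1e-12 mJ *and* the largest out-of-balance force
on a free node is below `force_tol` (default 5e-6 N, about 0.1 % of a
typical contact force; the residual position error of the softest end
modes at this tolerance is ~0.1 mm, well below the 0.4 mm CTA threshold —
tests that verify the stress-free state itself use 1e-8 N). Runs that
exhaust `max_steps` are flagged not converged and excluded from datasets.

For conditioning, the axial stiffness used during relaxation is capped at
2 N/mm: the braid is bending-dominated and the cap bounds axial strains
to O(1e-3) under deployment-scale forces while accelerating the soft
collective modes by orders of magnitude. Models assembled without solver
settings keep the physical `EA/L0` (used by the element-level tests).

## Deployment procedure

1. **Crimp.** Every node is displaced radially inward by
   `R_s - R_crimped` (default target radius 0.9 mm, so the crimped device
   fits the narrowest 2 mm vessel) with circumferential coordinates
   blocked and the axial coordinate free; relaxation elongates the braid
   according to wire inextensibility (15 mm -> ~19.7 mm at study scale).
2. **Position.** Ring centroids of the crimped stent define the straight
   centerline C_0. The target centerline C_T places the same arc-length
   spacings along the vessel centerline starting at arc fraction `eta`.
   Per-segment rotation axes/angles (cross products and included angles
   of consecutive segments, the first referenced to the z-axis) are
   accumulated to straighten C_T onto C_0; scaling every angle by
   `t/n_steps` generates the intermediate centerlines C_t. The stent is
   swept through the C_t by rigid per-ring transforms (20 steps by
   default). This stage is purely kinematic: the ring coupling is
   enforced exactly rather than through constraint forces.
3. **Deploy.** Constraints are released and wall contact activates. The
   release is staged through a *virtual sheath*, a coaxial tube around
   the vessel centerline whose radius grows from just above the crimp
   radius to the vessel radius over a couple of intermediate relaxations before
   the final unconstrained equilibrium. The spring network has no
   wire-to-wire excluded volume, and dumping the full crimping energy at
   once can fold the fine braid through itself into tangled local minima;
   gradual unsheathing (as in clinical practice) keeps the expansion
   ordered. The final displacement vector `u_h` (length `3*N_n`) is
   measured from the free reference configuration.

## Study design and labelling

The simulation parameters are
`mu_B = (y_P1, z_P1, D_v, D_a, y_Ca, eta)`. A Latin hypercube samples
`y_P1` in [0, 15] mm, `z_P1` in [25, 35] mm, `D_v` in [2, 4] mm, `D_a` in
[5, 10] mm, the aneurysm offset `y_Ca - D_v/2` in [0, 2] mm (wide-neck
sacs, the flow-diverter indication), and a dimensionless neck offset `u`
in [-1, 1] that places the first stent ring at arc length
`s_mid + u*D_a` — one dome diameter to either side of the neck centre, so
the design sweeps from clearly proximal, across the neck, to clearly
distal placements. `eta` is derived from `u` per sample and stored in
`mu_B`.

A converged deployment is labelled a *failure* if any node of the first
or last ring ends inside the sac: `R_a - |C_a - x_p| - r_w >= 0`, the
wire surface fully inside the sphere, boundary inclusive. (The printed
inequality convention is used with the sign that makes interior nodes
positive, consistent with the positive-inside SDF convention.) Under the
default ranges roughly half the draws succeed. Successful displacement
vectors form the snapshot matrix `S` column-wise.

The alternative predictors `mu_cl` replace `(P1, eta)` with the y, z
coordinates of `N_cl` points equally spaced by arc length along C_T
(computed geometrically — the crimped length follows from wire
inextensibility, no simulation involved) followed by
`(D_v, D_a, y_Ca)`.

## Classification

Six families (logistic regression, k-NN, Gaussian naive Bayes, decision
tree, a 10-10-10 tanh feed-forward network, and a degree-2 polynomial
SVM with `coef0 = 1`) are trained on standardised `mu_B` (statistics from
the training split only) with the positive class = success. Metrics:
accuracy, sensitivity, specificity, precision, F1 (zero-denominator
ratios reported as undefined), plus the ROC step curve whose trapezoid
AUC equals the Mann-Whitney concordance. Model selection prefers high
specificity: a false positive — predicting success for a deployment that
would fail — is the clinically costly error. Unstated hyperparameters are
scikit-learn defaults recorded in the run manifest.

## Reduced-order model

Thin SVD of `S` gives `S = U Sigma Z^T`; the basis `V` keeps the first
`L` left singular vectors, with `L` fixed (default 15) or chosen as the
smallest integer whose cumulative *first-power* singular-value fraction
reaches `1 - eps_POD` (the squared-energy fraction is also reported).
Each reduced coefficient is regressed on the parameters by an independent
single-output Gaussian process with a Matern 5/2 kernel (unit initial
length-scales/variance, jitter 1e-10, per-feature and per-output
standardisation; conflicting duplicate predictors trigger a larger-jitter
fallback with a warning). Prediction maps the posterior means through
`V`; per-coefficient posterior variances can be sampled independently (no
cross-output correlation is modelled) to visualise nodal uncertainty.
Errors are nodewise Euclidean distances: order-reduction `E_rb`,
prediction `E_p`, and `E_gpr = E_p - E_rb`; per-case averages/maxima (AE,
ME) are aggregated over the test set with exceedance counts against the
0.15 mm (3DRA) and 0.4 mm (CTA) imaging resolutions.

## Scaled-down study sizes

All shipped studies run on one CPU: the POD/ROM study uses the 48-wire
device at 20 cells (1,008 nodes, ~3 s per deployment) with LHS batches of
24 until at least 47 successful snapshots exist (~100 simulations); the
classification study uses a coarser 16-wire, 6-cell braid over a
300-sample design with a 200/100 train/test split. These sizes are the
package's study conditions; the full-scale device (70 cells, ~10,000
DOFs) is used for geometry and mesh-level results.

## What the synthetic studies show — and what they do not

The geometry generator *is* the study population: idealised planar
vessels, spherical wide-neck sacs, rigid walls, a single device size.
Passing tests demonstrate that the pipeline's mathematics behave as
specified (mesh counts, kinematic exactness, contact laws, POD/GPR
identities, classifier behaviour on a learnable boundary) and that the
qualitative trends hold (fast singular-value decay, prediction error
non-increasing with training size, centerline predictors at least as good
as raw parameters, high classification accuracy). They do not validate
the wire-network mechanics against a corotational-beam finite-element
code, patient-specific anatomy, deformable walls, or the printed error
magnitudes of cluster-scale studies.

## Known limitations

* The spring network approximates beam mechanics; there is no
  wire-to-wire contact except the tied crossings, no plasticity and no
  rod torsion term (scissor springs stand in for the torsional stiffening
  of the interlaced families).
* The quasi-static path (kinematic positioning, staged sheath release,
  slip-stick friction) selects one equilibrium among the many a frictional
  contact problem admits; path-dependent effects such as push-pull
  delivery are out of scope.
* At the default residual tolerance the softest end-flare modes retain
  ~0.1 mm of slack, comparable to the strictest (3DRA) imaging threshold.
* The aneurysm success criterion tests only the sphere; sac-interior
  nodes that remain inside the vessel tube at the neck still count as
  failures, which slightly inflates the failure rate for deeply
  overlapping sacs.
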