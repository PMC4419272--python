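# Methods

This note records the models, the numerical choices, and the open design
decisions behind `morphomap`, in enough detail to reimplement it.

## Coordinate conventions

All positions are in micrometres in the frontal plane of the organ:
+x along the proximal→distal (P-D) axis, +y along the anterior→posterior
(A-P) axis, right-handed. All tensors are expressed in the reference
(before-deformation) frame, so anisotropy axes are comparable across
stages and datasets. Anisotropy is an axis, not a vector; the canonical
representative has a non-negative x component (non-negative y when x is
exactly 0). When the two stretch eigenvalues coincide to within 1e-12
relative, the axis is undefined and is reported as `None` with magnitude 1
rather than as an arbitrary eigenvector of a degenerate eigenproblem.

The polar decomposition F = R·U is computed from the SVD F = WΣVᵀ
(R = WVᵀ, U = VΣVᵀ) rather than via a matrix square root; this is accurate
for near-singular F, and tensors with condition number above 1e12 are
rejected as degenerate. Orientation-reversing tensors (det F ≤ 0) are
rejected everywhere: they cannot arise from continuous tissue deformation.

## Map estimation

### Model

Unknowns are the deformed positions y_j of the nodes of a regular lattice
(spacing default 200 µm, within the 150–250 µm range appropriate for
limb-bud-scale data; 1 margin cell). Each landmark contributes

    x_i = Σ_j w_j(X_i) · y_j + ε_i,     ε_i ~ N(0, σ² I₂),

with w_j the bilinear hat weights of its cell's four nodes. The prior on
node displacements d = y − ref is Gaussian with precision ∝ α LᵀL, where L
stacks the discrete second differences D_xx, √2·D_xy, D_yy (the discrete
thin-plate bending energy). Two properties motivated this choice of L over
a 5-point Laplacian:

* its null space is **exactly** the affine maps, so noiseless affine data
  is reproduced exactly at every node for *any* α, and α → ∞ recovers the
  best-fit affine map — uniform stretch is biology, not roughness;
* a Laplacian penalty leaves all discrete harmonics unpenalized, which
  neither pins down the α → ∞ limit nor excludes spurious saddle-shaped
  deformation in data gaps.

The posterior mean solves (WᵀW + ασ²·LᵀL + ρI) d = Wᵀ(x − W·ref) per
coordinate, ρ = 1e-10 a numerical ridge for nodes without data support.

### Numerics

The solve is detrended by the exact least-squares affine fit (which lives
in the penalty null space): the regularized system then only carries the
small non-affine residual, and one step of iterative refinement brings
affine exactness to ~1e-12 µm, far below the 1e-6 µm contract. Duplicate
reference positions (measurement replicates) are averaged with a warning;
collinear landmark configurations are rejected as unidentifiable, as are
datasets with fewer than 6 pairs.

### Hyperparameters

With the prior covariance scaled by σ² (standard in ridge-type evidence
computations), σ² profiles in closed form and the marginal likelihood is
maximized over a 25-point log grid of the effective smoothing weight
λ = ασ² ∈ [1e-4, 1e5]. The evidence uses the determinant identity
det(I + W P⁻¹Wᵀ) = det(P + WᵀW)/det(P) with sparse LU factorizations
(P = λLᵀL + 1e-8·I makes the prior proper); the dense marginal covariance
is never formed — with a diffuse prior on the affine directions it is
numerically indefinite. On the default synthetic scenario the profiled σ̂
lands near the generating 20 µm noise (σ̂ ≈ 19 µm).

### Pooling embryos

Multi-embryo datasets are pooled into one estimation after each embryo is
brought to a common frame by a rigid (no scaling — size differences are
biology) transform. The synthetic generator applies and *records* each
embryo's camera jitter, mimicking registration via the organ outline,
where the transform is known rather than estimated from the markers;
`unjitter` undoes it. For data without recorded frames,
`register_embryos` offers a moment-based fallback (centroid plus
principal-axis angle, smallest-rotation convention), adequate for the
small mounting jitters it is meant to absorb.

## Validation

Cross-validation refits the map on each training fold (lattice rebuilt
from the training pairs) and predicts held-out positions; errors are
reported as means — and medians — of |Δpd|, |Δap| and Euclidean distance.
The default scheme holds out one embryo at a time, matching the pooled
design; a seeded k-fold over markers serves single-embryo data. Held-out
points outside a training lattice are skipped and counted rather than
extrapolated.

## Field analysis

F is evaluated at cell centers from the bilinear shape-function gradient —
one tensor per cell, since bilinear gradients are discontinuous across
edges. Only cells whose centers lie in the convex hull of the landmark
reference positions are reported; outside the hull the estimate is
extrapolation. Cells with det F ≤ 0 are flagged and excluded, not fatal.
Thickness fields interpolate bilinearly and return NaN outside support;
cells with undefined D-V growth are excluded from volume growth and
correlations (no imputation). Bead-region statistics average per-cell
values over cells with centers within 200 µm of the bead, in the reference
frame; the alternative — resampling the field densely inside the disc —
would weight partial cells differently but was not adopted (cells are the
estimation's native resolution).

## Morphogenetic simulation

The tissue is a polygonal cell complex with **fixed** neighbor topology
(no T1 rearrangements), consistent with the observed invariance of
neighbor relations in dense mesenchyme over these intervals. Cells are
coarse-grained patches (default target 20,000 µm², ~90 patches for a
2×1 mm bud), not literal cells: the driving fields vary on the 200 µm
lattice scale, so finer tiling adds cost without information.

The energy is purely geometrical — no elastic moduli, line tensions or
viscosity:

    E = Σ_c [ K_A (A_c/A_c* − 1)² + K_S ‖S_c/tr S_c − T_c/tr T_c‖²_F ]

with A_c the polygon area, S_c the gyration (second-moment) tensor of the
cell's vertices about their centroid, and (A_c*, T_c) per-cell targets.
The vertex-set gyration tensor was chosen over the area-integral second
moment for its simple analytic gradient; for the near-regular polygons the
tiling produces the two differ by a shape-independent factor. K_A = K_S = 1
by default; the two terms are dimensionless and of comparable scale, and
with these defaults uniform isotropic growth reproduces the prescribed
area factor and preserves outline shape to well within 2% per step.

Each step (i) samples the growth and anisotropy fields at the cell's
**material** centroid — the fields are Lagrangian, defined per reference
position, and fixed-topology cells retain material identity — and updates
A_c* ← g·A_c*, T_c ← D·T_c·D with D the SPD stretch with eigenvalues
√(g·a), √(g/a) along/across the local anisotropy axis (anisotropy thus
compounds multiplicatively over successive steps); (ii) relaxes the
vertices by overdamped descent: L-BFGS with analytic gradients, warm
started by the locally averaged target stretch about the tissue centroid
(the exact minimizer for uniform fields). Both energy terms are smooth
polynomials of the vertices even for inverted polygons, so a transient
flip is simply pushed back by the area penalty; a flip that persists at
the minimum raises an error. Initial targets equal the initial geometry,
so the untouched tissue is an exact fixed point.

The `vMT_II` scenario replaces growth with the mean "over the whole
wild-type organ": at each step the uniform rate is the area-weighted mean
of the growth field over the *wild-type* cell weights (compounded
per-cell growth tracked alongside the run). This telescopes so the total
prescribed growth equals the wild type's exactly; averaging with the
mutant's own uniform weights instead would leave a gap equal to the
growth field's squared coefficient of variation per step pair.

Tiling is a regular hexagonal lattice clipped to the outline — the
hexagonal lattice is the centroidal-Voronoi optimum in 2-D — with
coincident vertices merged so neighbors share edges exactly.

## Cell kinetics

The dual-label estimator assumes steady-state asynchronous cycling: cells
leave S phase at constant flux, so the second-label-positive fraction
n_s/n_total occupies T_s of the cycle and the leaving count over the
interval Δt calibrates the flux: T_s = Δt·n_s/n_leaving,
T_c = T_s·n_total/n_s. Counts are pooled across embryos for the point
estimate; per-embryo percentile bootstrap (seeded) gives intervals. No
growth-fraction correction is applied (all counted cells are assumed
cycling); with a non-cycling fraction q, T_c is overestimated by 1/(1−q).

## Synthetic data

The generator reproduces the study conditions: a paddle-shaped domain
(2000 × 1000 µm — a rectangle with a semicircular distal cap, echoing an
early-stage limb bud), 8 embryos × 30 markers per 12-h interval (within
the realistic 20–50 range), measurement noise σ = 20 µm (below the
organ-scale 40–50 µm prediction errors such data typically supports),
mean area growth 1.4 per interval with 1.5-fold spatial contrast, and
1.3-fold anisotropy aligned with +x. Embryo camera jitter is rigid,
sd 30 µm translation and 2° rotation, and recorded.

Ground-truth maps are separable, φ(x, y) = (φ_x(x), φ_y(y)), built from
cosine-tapered plateau profiles (C¹, matching the estimator's smoothness
prior) so F = diag(s_x(x), s_y(y)) is analytic: the growth-mode bias lives
in one axis profile (distal/proximal modes: rising/falling in x; posterior
mode: rising in y), the global P-D stretch in the ratio s_x/s_y ≥ 1.
Profiles are normalized so the area-weighted mean of det F over the domain
equals the prescribed base growth; parameter combinations that would drive
the anisotropy below 1 (axis flip) or det F ≤ 0 are rejected at
construction. The inverse map (needed to build the deformed-frame
thickness grid) uses dense monotone per-axis interpolation, accurate to
sub-µm.

Thickness pairs satisfy h(φ(X)) = ρ(X)·H(X) exactly up to grid
interpolation, with ρ either constant or built from the standardized
growth pattern plus an orthogonalized smooth pattern to hit a requested
growth–D-V correlation (e.g. the ~0.2 regime where frontal-plane and D-V
deformation decouple).

**What the generator does not emulate** — and what passing recovery tests
therefore do not show: non-separable deformation (shear, spatially
rotating anisotropy axes), D-V-depth dependence of the 2-D map and the
3D→2D projection step, stage-dependent changes within one interval,
marker-size growth, non-Gaussian localization error, and inter-embryo
biological variability beyond rigid mounting differences. Recovery scores
on these data are an upper bound on what identical settings achieve on
real dye-marking data.

## Problem sizes and determinism

Default experiment sizes — 240 landmark pairs on a ~13 × 8 cell lattice,
25-point hyperparameter grid, 8-fold leave-one-embryo-out, ~90–120
simulated cells for 2–10 steps — were chosen to match the scale of the
emulated study; every estimator is exact or deterministic given its
inputs, and all stochastic generators take explicit seeds, so all
reported numbers are bit-reproducible.

## Known limitations

* The estimation lattice is axis-aligned; strongly rotated organs should
  be registered to the P-D/A-P frame first.
* No extrapolation outside the lattice or the landmark hull; per-interval
  maps are not composed into multi-interval trajectories.
* The simulator is a geometric, not mechanical, model: it realizes
  prescribed deformation fields and cannot predict responses to forces.
* The anisotropy axis is reported in the reference frame; a deformed-frame
  map of the same axes (R·v₁) is a one-line transform away but is not what
  the plotting/export code emits.
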