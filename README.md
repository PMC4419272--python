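# morphomap

Quantitative analysis of tissue deformation dynamics for 2-D organ
development, built around the kind of data produced by snapshot lineage
tracing: a few tens of dye marks injected into an embryonic organ (e.g. a
chick limb bud), imaged before and after a 12-hour interval, pooled over
7–8 embryos.

From such sparse paired landmarks the package estimates a smooth
whole-organ deformation map, derives local growth-rate and
deformation-anisotropy fields, validates the map by cross-validation, and
runs geometric "virtual mutant" simulations that separate the morphogenetic
roles of spatially biased growth and globally aligned anisotropic
stretching. A synthetic-data module generates complete study datasets with
known ground truth, so every estimator can be scored against the truth that
generated its input.

## The model

**Deformation map and tensors.** Organ deformation over an interval is a
map **x** = φ(**X**) between each tissue element's position before (**X**)
and after (**x**) deformation, in the frontal plane (+x: proximal→distal,
+y: anterior→posterior, µm). Local deformation is the deformation gradient
tensor F (F_ij = ∂φ_i/∂X_j), polar-decomposed as F = R·U into a rotation R
and a right stretch U. Two independent scalar/vector summaries:

* **tissue growth rate** det F — the local area expansion factor;
* **deformation anisotropy** — magnitude λ₁/λ₂ (eigenvalues of U, λ₁ ≥ λ₂)
  with the λ₁ eigenvector as axis; isotropic deformation has magnitude
  exactly 1.

**Map estimation.** A regular lattice (default 200 µm spacing) envelops the
landmarks before deformation; the deformed node positions are the unknowns.
Each observed landmark ties its cell's four nodes together through bilinear
interpolation plus Gaussian measurement noise σ², and a thin-plate
smoothness prior α‖L d‖² penalizes the discrete second differences of node
displacements. The penalty's null space is exactly the affine maps, so
uniform stretch, rotation and translation are never shrunk. The posterior
mean solves

    (WᵀW + ασ²·LᵀL) d = Wᵀ(x − W·ref)

per coordinate; (α, σ²) are chosen by empirical Bayes (marginal-likelihood
maximization over a log grid, σ² profiled in closed form). Map quality is
reported as leave-one-embryo-out prediction error along each axis.

**Derived fields.** Per-cell F from the bilinear shape-function gradient
gives growth-rate and anisotropy maps; D-V growth h(φ(X))/H(X) comes from
gridded thickness fields before/after; volume growth is their product;
bead-perturbation experiments are summarized as treated-minus-control means
within 200 µm of the bead.

**Morphogenetic simulation.** A vertex tissue (hexagonal tiling of the
organ outline, fixed neighbor topology) descends an energy containing only
geometrical constraints — a per-cell target area and a trace-normalized
target shape tensor — driven by prescribed growth/anisotropy fields.
Scenario `vMT_I` keeps the wild-type growth pattern but flattens anisotropy
to 1; `vMT_II` keeps the anisotropy pattern but makes growth spatially
uniform at the wild-type mean.

**Cell kinetics.** Dual-label pulse-chase counts give S-phase and total
cycle time via the leaving-fraction estimator T_s = Δt·n_s/n_leaving,
T_c = T_s·n_total/n_s.

## Worked example

```python
from morphomap.workflows import run_recovery
from morphomap.vertexsim import run_scenario

res = run_recovery(seed=1)   # 8 embryos x 30 markers, sigma = 20 µm
print(f"residual           {res.residual_um:.1f} µm")
print(f"LOEO prediction    {res.cv.err_euclid:.1f} µm "
      f"(P-D {res.cv.err_pd:.1f}, A-P {res.cv.err_ap:.1f})")
print(f"det F within 10%   {100 * res.frac_det_within_10pct:.0f}% of cells")
print(f"growth-field r     {res.det_pearson_r:.2f}")

wt  = run_scenario(res.gt, "WT",     steps=2)
v1  = run_scenario(res.gt, "vMT_I",  steps=2)
v2  = run_scenario(res.gt, "vMT_II", steps=2)
print(f"final aspect ratio WT {wt.aspect_ratio[-1]:.2f}  "
      f"vMT_I {v1.aspect_ratio[-1]:.2f}  vMT_II {v2.aspect_ratio[-1]:.2f}")
```

prints

```
residual           23.2 µm
LOEO prediction    26.2 µm (P-D 17.2, A-P 16.0)
det F within 10%   96% of cells
growth-field r     0.97
final aspect ratio WT 4.02  vMT_I 1.58  vMT_II 3.09
```

The held-out prediction error (26 µm) sits well below the 200 µm lattice
mesh, and the recovered growth field matches the generating truth at 96% of
data-supported cells — the map is trustworthy at the scale it is drawn.
The simulation contrast makes the mechanistic point: uniform growth with
P-D-aligned anisotropy (vMT_II) elongates the bud almost as much as the
full wild-type fields, whereas wild-type growth without anisotropy (vMT_I)
produces a rounded outline; directional stretching, not biased growth,
drives elongation.

The same steps are available from the shell:

```bash
morphomap synth --mode distal_biased --embryos 8 --markers 30 --seed 7 --out data/
morphomap estimate --landmarks data/landmarks.tsv --out map.json
morphomap validate --landmarks data/landmarks.tsv --scheme loeo --out report.json
morphomap analyze --map map.json --thickness-before data/thickness_before.tsv \
                  --thickness-after data/thickness_after.tsv --out field.tsv
morphomap simulate --scenario vMT_II --steps 2 --out sim/
```

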