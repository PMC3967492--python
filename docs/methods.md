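# Methods

This note records the model, the parameter choices, the numerical decisions
and the known limitations of the `meshsharp` pipeline, in the order the
stages run.

## Normal tensor voting

The per-vertex voting tensor is `A_v = Σ_j w_j n_j n_jᵀ` over the one-ring
faces, with weight

```
w_j = (area(f_j) / area_max) · exp(−‖c_j − v‖ / (σ/3)),
```

`area_max` the largest incident-face area and `c_j` the face barycenter.
The eigenvalues of `A_v` are the classification signal: `(s, 0, 0)` on a
plane, `(s, s, 0)` across an ideal dihedral edge, `(s, s, s)` at an ideal
trihedral corner.  Only these *patterns* are meaningful; absolute
magnitudes scale with valence and sampling density.

**The ring scale σ.**  Default: the longest edge of the axis-aligned
bounding box of the one-ring vertices (`bbox_mode="longest"`), with the box
diagonal as an option.  Both are frame-dependent: rotating the mesh changes
the box, the weights, and (slightly) the eigenvalues.  A rotation-invariant
mode (`"diameter"`: max pairwise ring-vertex distance scaled by 1/√2 to a
box edge) is provided and makes the tensor exactly equivariant; it is not
the default because the downstream k-means boundary is sensitive to even
percent-level weight changes and the axis-aligned convention behaves better
on the reference fixtures.  Users processing meshes in arbitrary poses
should prefer `"diameter"`.

Eigenvalues are clamped at zero from below (negatives up to 1e−12 are
numerical); eigenvectors are sign-normalised (first nonzero component
positive) so outputs are deterministic under eigenvalue ties.  Boundary
vertices use their partial one-rings as-is.

## Feature space and Mahalanobis distance

Each vertex maps to its sorted eigenvalue triple `(σ₁, σ₂, σ₃)` — the
rotation-invariant discriminator of the local structure class.  k-means
(k = 3, k-means++ with 10 restarts, fixed seed, default 0) partitions these
points; the **smooth set** is the cluster whose centroid is most dominated
by its first coordinate, i.e. maximal `σ₁/(σ₁+σ₂+σ₃)`.  Two guards matter
in practice:

- selection is by the *fraction*, not the raw first coordinate, because the
  raw σ₁ scales with sampling density and a densely sampled fillet band can
  out-vote the flats;
- clusters holding < 5 % of the vertices are ineligible — a couple of
  anomalous-valence vertices (fan apices of revolution meshes) otherwise
  form a far-out σ₁ cluster that hijacks the selection and degenerates the
  covariance.

The feature distance is the canonical Mahalanobis distance

```
D(x) = sqrt( (x − μ)ᵀ Σ⁻¹ (x − μ) ),
```

with μ, Σ from the smooth cluster and Σ regularised by a relative ridge
`1e−6·tr(Σ)/3`, floored at `1e−12·mean‖x‖²/3` so a cluster of numerically
identical points (perfectly flat regions of analytic solids) still inverts:
members then get D ≈ 0 and everything else a very large finite D.  The
square root is essential: with the un-rooted quadratic form the field
scale grows quadratically in the cluster separation, `exp(−αD)` saturates,
and the sharpness control α loses all effect in its working range
[0.2, 0.8] — with the rooted distance, blurred-band distances land at
O(1–10) and α grades the filter exactly there.  D is evaluated at every
vertex, smooth members included.

## Graph-cut feature detection

Faces are nodes of the dual graph (one edge per interior mesh edge); two
virtual terminals represent the smooth (source) and feature (sink) regions.
The regional table assigns `R(feature) = D`, `R(smooth) = 1/max(D, 1e−8)`
(per-face D = max of its three vertex distances), and these values act as
**terminal-link capacities**: a face pays the penalty named for a terminal
when the cut separates it *from* that terminal, so a face labeled smooth
costs `λ·D` and a face labeled feature costs `λ/max(D, 1e−8)`.  Deep
feature faces therefore land on the feature side, and the unary crossover
sits at D = 1.  The boundary term `exp(−|Dᵢ−Dⱼ|/D_max)` is charged only on
label boundaries, enforcing spatial coherence.  λ defaults to 1.  The cut
is exact (max-flow via networkx), so the labeling is a certified global
minimiser; the test suite verifies it against exhaustive enumeration on
small graphs, which also pins down the capacity wiring unambiguously.

Because in-cluster Mahalanobis distances follow roughly a χ distribution,
the D = 1 crossover is aggressive on noise-dominated data: when vertex
noise (rather than geometric variation) sets the smooth-cluster spread,
half the smooth faces sit above the crossover and the feature region grows
far beyond the blurred bands.  This costs computation and anchors, not
correctness — flat regions are fixed points of the downstream filter — but
it is the main behavioural difference from heavy-tailed real-scan feature
spaces, where the bulk of the smooth region sits well below D = 1 and the
detected regions are narrow bands.

## Controllable normal filtering

Within the feature region, each face normal is replaced by the normalised
weighted average over its vertex-sharing one-ring *including itself*:

```
nᵢ′ = normalize( Σ_{k ∈ N(fᵢ) ∪ {fᵢ}} w_k n_k ),    w_k = exp(−α · max vertex D of f_k).
```

Faces are processed greedily in ascending per-face feature distance
(nearest-to-smooth first, ties by index) with in-place updates, so smooth
geometry flows across the band within a single sweep.  α trades retention
against propagation: relative stencil weights are `exp(−α·ΔD)`, so α = 0 is
uniform averaging, moderate α blends the original blurred normal with the
inflowing plane normals, and large α approaches winner-take-all
propagation.  Two deliberate details:

- **Keep-original fallback.**  If the weighted sum has norm < 1e−12 the
  face keeps its current normal.  Besides exact cancellation this catches
  the saturated case where every stencil weight underflows (αD ≳ 700):
  deep-feature faces then retain their original normals, which is exactly
  the retention behaviour the weights are designed for, and what makes a
  perfectly sharp input an exact fixed point of the whole pipeline.
- **Few sweeps (default `max_passes = 3`).**  The filter iterated to its
  fixed point forgets the initial normals entirely (the fixed point depends
  only on the relative weights), which erases the retention that α
  controls; with a small sweep cap the α dial works as published.  Sweeps
  also stop when the largest per-face rotation falls below
  `normal_tol_deg` (default 0.1°).

The oversharpening reference (`hard_propagation=True`) is the binarised
limit: a single priority sweep whose source front (initially the smooth
faces, then every face already visited) grows as the sweep advances; each
face becomes the unweighted average of its source-side stencil.  This
reproduces the classic propagate-until-sharp behaviour that the α-weighted
filter is designed to moderate.

## Vertex update

The filtered normals are turned into geometry by minimising

```
E₁(X) = Σ_{k∈F} Σ_{(i,j)∈∂F_k} ( n_k′ · (xᵢ − xⱼ) )²,
```

∂F_k the three undirected edges of face k (an interior mesh edge therefore
contributes through both its faces).  Free variables are the vertices
incident to at least one feature face; all others are anchored, which both
confines the edit to the feature region and removes the translational null
space.  E₁ is quadratic, so the default solver is conjugate-gradient
descent with an exact closed-form line search (monotone in E₁ by
construction, `vu_max_iters = 200`, relative-decrease stop at 1e−6).  Plain
steepest descent is available (`method="gd"`) but converges linearly with
the quadratic's condition number (measured κ ≈ 570 on the box fixture —
thousands of iterations to get within 1e−3 of the optimum), and a direct
sparse least-squares solve (`method="lstsq"`, scipy LSQR) serves as the
oracle in tests.  With few anchors the quadratic has near-null tangential
directions; the iterative solvers stay near the input along them, while the
direct solve can drift, which is another reason the iterative path is the
default.

## Synthetic fixtures

The generators emulate what a structured-light scanner does to sharp
edges.  `make_filleted_box` samples the sharp box on an exactly welded
lattice and applies a Minkowski clamp-and-offset map, so flat-region
vertices equal their sharp counterparts exactly, edge-band vertices lie on
circular arcs of exactly the requested radius, and corners on exact
spheres — residual-radius measurements therefore have analytic ground
truth.  `make_rounded_disk` does the same for a revolved profile (toroidal
rims).  `make_canonical_one_ring` builds the flat / dihedral / corner test
patterns, and `add_vertex_noise` adds seeded isotropic Gaussian
displacement.

**Study conditions.**  Pipeline-level tests run on the unit filleted box
(radius 0.1, ~4.8k faces) with noise σ = 0.001 length units: the ~60 µm
accuracy of structured-light scanners referred to a 60 mm part — the scale
of the mechanical models such scanners typically digitise.  The noise is
not cosmetic: on a perfectly analytic solid the smooth-cluster covariance
collapses, every feature distance saturates, and the sharpness control has
no measurable effect, so the noiseless limit lies outside the method's
domain.  What the synthetic fixtures do *not* emulate: curved anatomy
(their smooth regions are exact planes/cylinders, making the feature space
noise-dominated rather than curvature-dominated, see the detection note
above), scanner-specific anisotropic noise, holes, and outliers.  Passing
tests therefore certify the machinery and the direction of the published
effects, not performance on clinical scans.

## Measurement

Mesh deviation is the vertex-sampled symmetric Hausdorff distance with
exact point-to-triangle distances (all pairs, chunked; deterministic).
Residual fillet radius is measured on cross-sections perpendicular to the
ground-truth edge lines: section points near the corner are split into
flank points (within 5° of a known flank line) and transition points, and
the transition points receive the least-squares member of the
one-parameter family of arcs tangent to both flanks.  The tangency
constraint is what makes the estimate usable: an unconstrained circle
through the scatter of a sharpened (jagged) crease is ill-posed and can
report radii that grow with sharpening.  On the analytic fixture the
estimator recovers the exact fillet radius; on sharp creases it reads ≈ 0.

## Known limitations

- α controls the *flanks* of a blurred band strongly but an exactly
  symmetric crest only weakly at small α: the crest face's stencil is
  symmetric, its weighted blend is the bisector — its own normal — so at
  α = 0.2 the crest's curvature radius is retained rather than reduced.
  Radius reduction below the input at low α should not be expected; the
  monotone ordering across α is robust.
- Feature detection over-includes on noise-dominated data (see above).
- The default ring scale is frame-dependent; use `bbox_mode="diameter"`
  for pose-independent results.
- k-means cluster boundaries (and hence the D scale) can shift under
  percent-level perturbations of the voting weights; seeds fix the
  clustering for reproducibility but the sensitivity is intrinsic to the
  feature-space construction.
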