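# Methods

This note records the models, parameter defaults and numerical choices
behind `facemaps`, and what the synthetic test bed does and does not show
about real data.

## Surface representation and alignment

Surfaces are triangle meshes (`TriangleMesh`): vertices in length units
(mm for facial scans), faces with consistent counterclockwise winding, and
edge-manifold-with-boundary topology enforced on construction.  Vertex
normals are area-weighted averages of incident face normals; the global
winding is flipped when the mean normal opposes the configured viewing
axis (default +z), so that convex features carry positive curvature
downstream.  Continuous surface locations (`SurfacePoint`) are a face
index plus barycentric weights, the representation every landmark uses.

Ensemble alignment is two-stage, mirroring the usual scan-processing
order: a least-squares rigid transform (Kabsch, reflection-corrected) over
three labelled fiducials (outer eye corners and nasion in the facial
setting) imposes a rough common orientation, then point-to-point ICP
(nearest-vertex matching, rigid update per iteration, only improving
iterations accepted) refines it.  The ICP reference subject is a required
argument; there is no canonical choice.  Tolerance: stop when the RMSD
improves by less than `1e-6` of the reference bounding-box diagonal.

## Discrete geodesics

All on-surface distances come from a Steiner-augmented graph: every mesh
edge receives `steiner_per_edge` extra nodes (default 5), and all boundary
nodes of each face are pairwise connected by in-face straight segments.
Dijkstra on this graph recovers a path whose face sequence ("sleeve") is
then unfolded isometrically into the plane, and the exact shortest path
through the sleeve is extracted with the funnel (string-pulling)
algorithm.  When the taut path bends around a mesh vertex, the sleeve is
locally rerouted through the complementary face fan and the shorter
variant kept, iterating to a locally shortest path.  Consequences:

- on a planar mesh the result is exact to rounding for generic query
  points (degenerate vertex-to-vertex queries aligned with the grid can
  retain a fraction-of-a-percent overestimate from sleeve ties);
- on a subdivision-4 icosphere the pole-to-pole distance is within 0.06%
  of the great-circle value, and the error decreases monotonically with
  subdivision level (the residual is the piecewise-planar approximation of
  the sphere, not the search);
- the distance function is made exactly symmetric by evaluating each
  unordered pair in a canonical order.

The logarithmic map takes its direction from the first straight segment of
the refined path (which lies in the source face plane by construction) and
its norm from the path length.  The exponential map traces straightest
geodesics — straight within each face, continued straight in the planar
unfolding across each crossed edge; at a vertex the continuation enters
the incident face whose in-plane projection of the incoming direction
deviates least (ties to the lowest face index).  On open surfaces a trace
reaching the boundary is clipped there and flagged; facial meshes are open
and no boundary rule is canonical, so clipping is the least surprising
choice for a user-facing query.

## Ensemble landmark optimization

The correspondence objective is `Q = H(Z) − Σ_j H(P_j)`.

- `H(P_j)` is the sampled entropy of the landmark distribution on surface
  j under a geodesic Gaussian kernel with bandwidth σ.  Default
  `σ = sqrt(mean surface area / (π M))` — one kernel covers roughly one
  landmark's share of area — recomputed at each doubling level.  Kernel
  sums are truncated at 4σ (relative error < e⁻⁸); within the optimizer
  each landmark keeps at most its 24 nearest neighbors, raw graph
  distances stand in for refined ones (their few-percent error is far
  below σ), and in-plane chord directions stand in for initial geodesic
  directions (for neighbors at kernel range the angular error is a few
  degrees).  The user-facing `surface_density` / `uniformity_gradient`
  functions use the fully refined solver.
- `H(Z)` is the Gaussian entropy of the N shape vectors (3M-dimensional
  concatenated landmark coordinates), `0.5·Σ log(λ_k + α)` over the sample
  covariance spectrum computed through the N×N dual Gram matrix.  The
  regularizer defaults to `α = 1e-4 · trace(cov)/3M`.

The uniformity update is `−γ` times the kernel-weighted mean log-map
(`γ = 0.1 σ²`, so a landmark moves about 10% of its distance to a crowding
neighbor per iteration).  The correspondence update deserves a note: the
raw entropy gradient is `Y (YᵀY/(N−1) + αI)⁻¹/(N−1)`, which scales
near-null covariance modes by `γ/α` and diverges under any practical step
size.  The implemented step therefore shrinks each dual eigenmode's
deviation by `min(γ/(λ+α), 0.3)` — the same descent direction, with a
trust-region-style cap that guarantees per-mode stability and converges
exponentially (the raw formula is retained in `correspondence_gradient`
and verified against a finite-difference oracle).  Each step is projected
onto the landmark's face plane and applied through the exponential map;
backtracking halves the step when Q rises, and a step that cannot decrease
Q is rejected outright.  Updates whose trace would cross the open boundary
are progressively halved and finally rejected, because a clipped update
would otherwise deposit landmarks on the rim, where repulsion from the
interior pins them permanently.

Splitting doubles the landmark count: each landmark spawns a child offset
by `ε·σ` along a direction drawn once per landmark index and shared by all
surfaces (correspondence-preserving).  Default `ε = 0.5`: children land
near the post-split target spacing immediately.  A small offset (0.1) was
tried first and requires ~25 gradient iterations per level to re-uniformize
— repulsion grows separations only ~10% per iteration — which starves
surface coverage under any realistic iteration budget.  `iters_per_level`
may be a single budget or a per-level schedule; correspondence is mostly
established at the cheap coarse levels and preserved by splitting, so
front-loaded schedules are effective.  Stopping within a level: five
consecutive relative cost changes below `tol` (default 1e-6).  All
randomness (initial seed point, split directions) flows from one seed;
runs are bit-reproducible.

The target count must be a power of two — the doubling schedule defines
the algorithm (4,096 landmarks = 12 rounds), and any other target would
need an arbitrary partial-split rule.

## Curvature phenotypes

At a landmark, the 2×2 symmetric shape operator is fitted by least squares
from finite differences of vertex unit normals against tangent-plane
displacements over the vertices within a metric radius (default two mean
landmark spacings, `2·sqrt(area/(πM))`; near boundaries or on coarse
fixtures an empty ball falls back to the six nearest vertices).  Its
eigenvalues are K_max ≥ K_min, signed positive for convex-outward
curvature.  The four indices follow the standard definitions (MC, GC, CU,
SI); at umbilic points, where the shape index is undefined, SI is taken as
the sign of the mean curvature (+1 dome, −1 cup, 0 flat).  Validation:
sphere of radius 10 → MC 0.1, GC 0.01, CU 0.1, SI 1 within 5%; cylinder of
radius 5 → SI 0.5; scaling a mesh by s divides MC and CU by s, GC by s²,
and leaves SI unchanged.

## Traits

Seventeen named fiducials (glabella, nasion, pronasale, subnasale,
gnathion, and left/right alare, exocanthion, endocanthion, zygion,
cheilion, gonion) are located once on the average face — each labelled 3D
pick maps to the nearest average-face landmark, ties to the lowest index —
and propagate to every subject through the index correspondence.  The ten
standard distance traits (lower/middle face heights, nose height and
protrusion, nose/intercanthal/biocular/zygomatic/mandible/mouth widths)
are measured either as chords (EDT) or on-surface (GDT); EDT ≤ GDT always.

Age is removed either as a covariate inside the twin model (univariate
route) or by OLS pre-residualization (multivariate route); both give the
same fit, but sparse PCA needs the residualized matrix.  Regional traits
are sequential rank-one sparse components: maximize explained variance
subject to ‖w‖₂ = 1 and ‖w‖₁ ≤ c (power iteration with an L1-ball
soft-threshold projection, bisected to the bound), then deflate by
subtracting the rank-one fit.  `c` interpolates from 1 (single landmark)
to √M (dense PCA); component orthogonality is not enforced (no sparse PCA
guarantees it).  Explained variance of component k is
`var(X·w_k) / total variance of the original matrix`.

## Twin variance-components model

For a trait on MZ/DZ pairs, the bivariate-normal likelihood uses
`var = a²+c²+e²`, `cov_MZ = a²+c²`, `cov_DZ = a²/2+c²`, mean `μ (+ β·age)`
shared by co-twins.  Assumptions inherited from the classical twin design:
equal environments across zygosities, additivity (no dominance), no
assortative mating.  Fitting maximizes the likelihood over nonnegative
variance components with L-BFGS-B (bounded parameterization reaches the
a = 0 boundary exactly, which the zero-heritability test requires),
moment-based starting values plus random multi-starts.  The saturated
reference model frees per-zygosity means, variances and covariance
(10 parameters, +1 shared age slope), closed-form without age.  Standard
errors come from the inverse numerical Hessian on the path-coefficient
scale (NaN at a boundary), h² SE by the delta method.

Model choice: fit ACE, AE, E; keep the minimum AIC (ties favor fewer
parameters); E is never dropped.  Goodness of fit is the LRT against the
saturated model (χ² with the parameter-count difference as df).  The
zero-heritability test compares AE against E; since a² sits on the
boundary under the null, the statistic follows the 50:50 mixture of χ²₀
and χ²₁ and both the corrected and naive p-values are reported.  Measured
calibration at 200+200 pairs: type-I error 0.041 at nominal 0.05,
goodness-of-fit pass rate 0.944 at nominal 0.95, mean ĥ² within 0.005 of
truth at 500+500 pairs for h² ∈ {0.2, 0.5, 0.8}.

No multiple-testing correction is applied across landmarks — maps report
raw per-landmark estimates, with the goodness-of-fit p-value available as
a display mask only.

## Synthetic twin faces

The generator builds subdivided icospheres scaled to an ellipsoid (default
semi-axes 1.0 × 1.2 × 0.9), radially displaced by Gaussian bumps (nose and
brow analogues), cropped to the +z hemisphere to create the open boundary
of a cropped facial scan, optionally jittered with seeded vertex noise.
Default fixtures use subdivision 2–4 (73–2,562 vertices); the test suite
deliberately runs at the small end so that full twin cohorts (120 meshes)
can be landmarked in minutes on one core.

Twin structure enters through bump amplitudes:
`A = a·G + c·C + e·U` with variance shares summing to 1; G is shared by MZ
co-twins and constructed as `(G_shared + G_own)/√2` for DZ co-twins
(genetic correlation exactly 1/2), C always shared, U never.  Amplitude =
`base·(1 + amp_sd·A)` with `amp_sd = 0.5` by default — a 50% coefficient
of variation, deliberately strong so that fixture-scale cohorts carry
measurable signal.  Empirical check: MZ amplitude correlation ≈ a²+c², DZ
≈ a²/2+c², both within Monte-Carlo error.

What the synthetic bed does **not** emulate: scanner texture, expression
and pose variation, soft-tissue deformation, asymmetry, non-rigid growth
with age, and realistic facial topography beyond a few bumps.  Passing the
end-to-end tests therefore demonstrates that the pipeline machinery —
correspondence, curvature, variance decomposition — recovers planted
genetic signal at fixture scale, not that any particular real facial
region is heritable.

## Scales used by the validation suite

- Power analyses: 1,000 Monte-Carlo cohorts per design.
- Landmark doubling: 3 surfaces, subdivision-2 meshes, one optimization
  pass per level, 12 splitting rounds to 4,096 landmarks.
- End-to-end discrimination: 10 cohorts of 30 MZ + 30 DZ pairs, two bumps
  (h² = 0.8 vs h² = 0), 32 landmarks, front-loaded iteration schedule
  [12, 12, 12, 10, 10, 10]; a bump's heritability is summarized as the
  mean ĥ² of the landmarks within 0.5 rad of its center, falling back to
  its three nearest landmarks when the sampler left the window empty (a
  region-mean is undefined on an empty set).
- Estimator calibration: 1,000 replicates (type-I error, goodness of fit),
  200 replicates per heritability level (recovery).

## Known limitations

- Geodesic accuracy degrades gracefully, not uniformly: queries between
  grid-aligned mesh vertices can retain ~0.5% error where the sleeve
  search ties; generic points are exact on flat regions.
- The optimizer's uniformity is local (truncated kernels): coverage of a
  large surface from a single seed relies on the splitting cascade, and
  strongly non-uniform initializations can leave transient density ripples.
- The correspondence term penalizes shape variance, so regions that truly
  vary across subjects are sampled slightly more sparsely than uniform.
- Standard errors at variance-component boundaries are reported as NaN
  rather than by profile likelihood.
- ADE (dominance) models, multivariate genetic correlations and extended
  pedigrees are out of scope.
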