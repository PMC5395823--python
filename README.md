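# facemaps

Dense 3D surface landmarking, curvature phenotyping and twin heritability
maps.

## What this package does

Classical facial-heritability studies reduce a face to a handful of
manually placed landmarks and a few inter-landmark distances, which caps
both the spatial detail and the reproducibility of the estimates.
`facemaps` implements the automated alternative for ensembles of 3D facial
surface scans (triangle meshes):

1. **Rigid alignment** — three-fiducial orientation followed by
   point-to-point ICP brings all scans into a common pose.
2. **Dense corresponding landmarks** — an ensemble entropy optimizer places
   M landmarks on every surface by minimizing

   `Q = H(Z) − Σ_j H(P_j)`

   where `H(Z)` is the Gaussian entropy of the landmark configurations in
   3M-dimensional shape space (minimizing it tightens the point-to-point
   correspondence across subjects) and `H(P_j)` is the entropy of the
   landmark distribution on surface j under a geodesic-distance Gaussian
   kernel (maximizing it spreads landmarks uniformly).  All updates move on
   the surface via discrete exponential maps; the landmark count doubles by
   iterative splitting until the target `2^L` is reached (4,096 landmarks =
   12 rounds from a single seed point).
3. **Curvature phenotypes** — at every landmark the principal curvatures
   (K_max, K_min) are estimated from finite differences of vertex normals,
   and condensed into Mean Curvature `MC = (K_max+K_min)/2`, Gaussian
   Curvature `GC = K_max·K_min`, Curvedness `CU = sqrt((K_max²+K_min²)/2)`
   and Shape Index `SI = (2/π)·atan((K_max+K_min)/(K_max−K_min))`.
4. **Distance and regional traits** — classical fiducial distances
   (nose width, zygomatic width, ...) in both Euclidean and geodesic
   versions, plus sparse-PCA regional traits whose loadings painted on the
   average face ("Eigenface maps") delineate coherent facial regions.
5. **Twin heritability** — for each trait the classical ACE variance
   decomposition is fitted by maximum likelihood on MZ/DZ pair data
   (`var = a²+c²+e²`, `cov_MZ = a²+c²`, `cov_DZ = a²/2+c²`), the ladder
   ACE → AE → E is ranked by AIC, fit quality is checked against a
   saturated model by likelihood-ratio test, and the per-landmark
   `h² = a²/(a²+c²+e²)` estimates are painted onto the average face as a
   heritability map.

Because real twin-cohort scans cannot be redistributed, the package ships a
synthetic-twin generator (`facemaps.synthetic`): face-like half-ellipsoid
meshes with Gaussian bumps whose amplitudes follow an exact ACE covariance
structure between co-twins.  Every pipeline stage is tested against it.

## Worked example

Estimate the power of a twin design, then run the full synthetic pipeline:

```python
>>> from facemaps.heritability import power_simulation
>>> power_simulation(n_mz=38, n_dz=37, h2_true=0.8, n_replicates=200, seed=1)
{'rate': 1.0, 'se': 0.0, 'n_replicates': 200, 'n_rejections': 200}
```

With 38 MZ and 37 DZ pairs, every one of 200 simulated cohorts with true
heritability 0.8 rejects the zero-heritability null — the classical "about
75 pairs suffice for strongly heritable traits" design rule.

Fitting a single trait returns a statsmodels-style results object:

```python
>>> from facemaps.heritability import TwinSEM
>>> from facemaps.synthetic import simulate_twin_traits
>>> table = simulate_twin_traits(200, 200, a2=0.6, c2=0.0, e2=0.4, seed=7)
>>> print(TwinSEM(table, "AE").fit().summary())
Twin variance-components model (AE)
==============================================
pairs: 400    age covariate: False
log-likelihood: -1044.4753    AIC: 2094.9505
free parameters: 3
----------------------------------------------
param         estimate     std err
a              0.71833     0.03910
e              0.61954     0.02898
mu            -0.07106     0.03991
----------------------------------------------
h2 = 0.5734  (SE 0.0430)
```

The true simulated h² is 0.6; the fitted AE model estimates 0.573 with a
standard error of 0.043 — within one standard error of the truth.

The full mesh pipeline runs from the command line:

```bash
facemaps simulate --out run --n-mz 10 --n-dz 10 --seed 1
facemaps gessa --meshes run/meshes --out run/landmarks --m 64 --seed 1
facemaps curvature --meshes run/meshes --landmarks run/landmarks --out run/curv
facemaps heritability --traits run/curv/curvature_MC.csv \
    --pairs run/pairs.csv --out run/h2.csv
facemaps maps --results run/h2.csv --mesh run/meshes/subject_0000.ply \
    --landmarks run/landmarks/subject_0000.landmarks.csv --out run/h2map.ply
```

or as one YAML-configured pipeline (`facemaps pipeline --config cfg.yaml`).

## Layout

| module | contents |
| --- | --- |
| `facemaps.mesh` | `TriangleMesh`, `SurfacePoint`, OBJ/PLY I/O, fiducial + ICP alignment |
| `facemaps.geodesic` | `GeodesicSolver`: distances, log/exp maps on meshes |
| `facemaps.gessa` | ensemble entropy optimizer, landmark splitting, validation |
| `facemaps.curvature` | principal curvatures, MC/GC/CU/SI, curvature maps |
| `facemaps.traits` | fiducial distance traits, age residualization, sparse PCA |
| `facemaps.heritability` | `TwinSEM`/`TwinSEMResults`, model selection, power, maps |
| `facemaps.synthetic` | face-like meshes and ACE-structured twin ensembles |
| `facemaps.cli` | command-line pipeline |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
numerical design choices.
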