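# Methods

## The nuclear drop model

The package's solver treats the interphase nucleus as a pressurized drop
bounded by an inextensible lamina: shape changes conserve nuclear volume
V_nuc and lamina surface area A_nuc. A rounded nucleus therefore stores
"excess area" — area beyond that of the equal-volume sphere — as wrinkles,
and unfolds it as the cell spreads; once the lamina is taut, the shape is
geometrically, not mechanically, determined. The cell cortex is modeled as a
minimal-area surface (a cap pinned at the adhesion perimeter on the
substrate plane z = 0) enclosing a fixed cell volume V_cell, and the nucleus
is confined between cortex and substrate.

Equilibrium shapes minimize

    E_tot = E_cell + E_nuc
          + γ (A_nuc/A_nuc,0 − 1)²
          + β_nuc (V_nuc/V_nuc,0 − 1)²
          + β_cell (V_cell/V_cell,0 − 1)²

over the vertex positions of two triangle meshes. E_cell is the cortex area
(normalized by A_nuc,0) plus a small centroidal-Voronoi-tessellation (CVT)
mesh-quality regularizer; E_nuc is the CVT regularizer alone — the lamina
area is constrained, not minimized. The CVT energy is the per-vertex second
moment ∫_{v_i} ‖x − x_i‖² dA over barycentric dual cells (the region of each
triangle where that vertex's barycentric coordinate is largest), computed
exactly by midpoint quadrature with an analytic gradient.

Constraints are enforced softly: the stiffnesses (γ, β_nuc, β_cell) are
raised through a schedule of 10²…10⁸ (×10 per stage), and a state counts as
converged when all three relative residuals |A_nuc/A_nuc,0 − 1|,
|V_nuc/V_nuc,0 − 1|, |V_cell/V_cell,0 − 1| fall below 10⁻³.

### Numerics

- **Descent.** Each stage runs quasi-Newton (L-BFGS-B) sweeps over the free
  vertices; the substrate constraint z ≥ 0 enters as a box bound, pinned
  (adhesion-perimeter) vertices are excluded from the variables. The line
  search guarantees monotone energy within a sweep — a tested invariant.
  Plain damped gradient descent was tried first and does not converge in
  usable time once stiffnesses reach 10⁸; the quasi-Newton sweep keeps the
  same monotone-acceptance contract.
- **Contact.** Between sweeps, interpenetration is resolved by closest-point
  projection: nuclear vertices outside the cortex are moved just inside it,
  cortex vertices inside the nucleus just outside, vertices inside a
  micropost are reflected to its wall or top, whichever is nearer. Signed
  sidedness uses the nearest face's normal. A stage ends when projections
  are quiescent (max displacement < 2×10⁻⁴ µm) and descent has stalled.
- **Mesh maintenance.** Edges are flipped to the local Delaunay criterion
  (two opposite angles summing beyond π + 10⁻⁸; ties never flip; flips that
  would duplicate an edge or create a degenerate triangle are skipped) after
  every sweep; vertices of near-degenerate triangles produced by projections
  are nudged toward their neighbor centroid (10% umbrella step).
- **Volumes.** Enclosed volume uses the divergence theorem; for the open
  cortex cap the flux form ∫ z n_z dA gives the volume between cap and
  substrate exactly.
- **Initial meshes.** DISTMESH-style: seeded point sets (Fibonacci layouts on
  spheres/ellipsoids, staggered grids in footprint polygons) equilibrated by
  repulsive edge springs with projection to the target surface, triangulated
  by convex hull or Delaunay. Typical quality: minimum angles ≳ 35°.

### Worked configurations

- **Isoperimetric control.** A free nucleus (no cell, no substrate) with
  A_nuc,0 equal to the sphere area of V_nuc,0 = 800 µm³, started from a
  1.25:1:0.8 ellipsoid at ~1900 faces. The unique equilibrium is the sphere;
  the solve ends with residuals ~10⁻⁴ and < 0.5% radial deviation. The mesh
  must be fine enough that the discrete isoperimetric offset (a polyhedral
  sphere needs slightly more area per volume than the smooth one) stays well
  below the residual tolerance.
- **Monolayer-cell shape.** Cell volume 2800 µm³ and nuclear volume 800 µm³
  with the lamina area at 37% excess over the equal-volume sphere
  (570.8 µm²). The published parameter set quotes two mutually inconsistent
  area figures — "1543 µm²" and "37% excess" (the former is 270% excess for
  an 800 µm³ nucleus, and 37% excess at 1543 µm² would require a nuclear
  volume larger than the cell's) — and both parameterizations are exposed
  rather than silently reconciled. Only the 37% reading reproduces the
  published smooth shape: at 270% excess the slack lamina generically
  wrinkles, including µm-scale basal folds whose placement depends on the
  mesh seed (that configuration ships as an exploratory study in
  analysis/02). The adhesion footprint is a circle sized so the unobstructed
  cortex height V_cell/(πR_f²) is half the taut-pancake height of the
  nucleus — firm apical contact, the regime the published calculation
  targets by fitting the cell volume to measured x–z cortex profiles. The
  converged nucleus is a taut drop: flat apical contact (apical/rim
  mean-curvature ratio ≈ 0.02–0.03), curved free rim, flat basal face
  (bottom envelope variation ≈ 0.00 µm), at ~1850 nuclear and ~1200 cortex
  triangles (the published indented-case mesh resolution; the same solve
  seeds the indentation study below).
- **Micropost indentation.** Starts from the converged monolayer
  equilibrium above. A 1-µm-diameter, 5-µm-tall post is stepped along the rim
  normal in steps of half a mean edge length, each step followed by
  continuation sweeps at full stiffness; after withdrawal the state is
  re-equilibrated through the second half of the stiffness schedule (the
  quasi-static premise is full equilibration; softening lets mesh-scale
  contact scars relax, while re-annealing from the softest stages is itself
  non-reproducible and is avoided).

### Recovery metric and its floor

Round-trip recovery is reported as the symmetric Hausdorff distance between
pre- and post-indentation nuclear surfaces (vertex-to-triangle, both
directions), normalized by the reference mesh's bounding-box diagonal — the
convention of standard mesh-comparison tools. Perturbation controls
(vertices jittered by 0.05 µm, then re-equilibrated, no post) put the
solver's intrinsic equilibrium-reproducibility floor at 0.1–0.3 µm at this
resolution; the deviations concentrate in bistable micro-buckles of the
basal contact sheet and rim tucks, not at the indentation site. Round-trip
distances (~0.1–0.2 µm, 0.4–0.8% of the diagonal) are statistically
indistinguishable from that floor, i.e., recovery is complete to within
solver reproducibility; a deliberately de-equilibrated state shows ~1.1 µm
(≈4%), so the 2% bar still discriminates failed recovery.

## Morphometrics

- **Bulk nuclear masks**: Otsu threshold on the lamin max-projection, hole
  filling, connected components; labels touching the frame or within a
  one-pixel dilation of another label are excluded (nuclei that merged into
  one component enter as a single object — beyond this rule's reach).
- **Sub-pixel lamina tracing**: the intensity along the outward normal of
  each bulk-contour point is sampled (cubic interpolation, ±1.5 µm default
  probe) and the ridge localized by a three-point parabolic fit; flat
  profiles or probes leaving the image keep the bulk position.
- **Elliptical Fourier analysis**: 15 harmonics of the closed contour;
  per-harmonic semiaxes are the singular values of the 2×2 coefficient
  matrices. The contour is parameterized uniformly per point: traced
  contours have near-equal spacing, where this matches the classical
  chord-length convention, and a parametric ellipse then decomposes exactly
  into its first harmonic (the chord-length convention leaks ~6% of a 2:1
  ellipse into harmonic 3, which would defeat the smoothness readout).
  The EFC ratio — (major₁+minor₁) / Σ₂..₁₅(majorₙ+minorₙ), higher = smoother
  — is capped at 10³, where the denominator vanishes for perfect ellipses.
  Per nucleus, the ratio is averaged over the planes at 25/50/75% of nuclear
  height, each re-traced at sub-pixel resolution.
- **Nuclear height**: per-plane mean in-mask lamin intensity is compared
  with the per-plane mean over a cell-free background region; onset/offset
  are the first/last planes whose background-subtracted plane mean exceeds
  3 SD of the background plane means, floored at 5% of the peak excess
  (a pixel-level SD criterion misses the dim tangent-cap planes). Height is
  (offset − onset)·dz. Because the lamina shell has finite thickness and the
  PSF spreads it, the measured extent of a flat-topped nucleus is biased
  high by roughly the shell + PSF width (~0.3–0.5 µm); tolerances on
  synthetic recoveries account for the acquisition geometry used.
- **Nuclear surface area and volume**: Otsu threshold, 3D hole-fill, largest
  component; volume = voxel count × voxel volume, area from a marching-cubes
  isosurface of the lightly smoothed (σ = 1 voxel) binary region with
  anisotropic spacing.
- **Monolayer height maps**: channels summed, global Otsu binarization,
  per-column apical-minus-basal z-extent, margin crop, iterative
  neighbor-mean fill of uncovered columns, block-mean downsampling (grid
  truncated to a multiple of the factor — partial blocks would be
  zero-padded), roughness = SD of the final grid.
- **YAP N/C**: (nuclear mean − background) / (cytoplasmic mean − background)
  on max-projections; non-positive cytoplasmic excess ⇒ missing value.
- **Focal adhesions**: Otsu, connected components, area gate 0.5–15 µm²,
  circularity 4πA/P² in [0.1, 1] with the perimeter from the pixel-boundary
  convention and circularity clipped at 1 (small blobs can exceed 1 under
  this estimator), ROI-edge objects excluded; density = count / ROI area.
- **Detachment traces**: per-label areas over the mask time series; an
  object is detached when it disappears after a non-increasing decline over
  a 3-frame window; identity gaps split the trace (retained, warned).

## Synthetic data

Generators are deterministic given their seed and always return ground
truth. Wrinkled nuclei are radial spherical-harmonic perturbations of a
sphere (degrees 4–8 by default, coefficients drawn once per seed), with the
amplitude bisected so the mesh-measured excess area hits the target within
1% and the mesh rescaled to the target volume; the surfaces are star-shaped
by construction. Renders use a splatted-surface Euclidean distance transform
for the lamin shell (0.25 µm band) and exact column-parity rasterization of
the mesh interior for solid (chromatin-like) signal, followed by Gaussian
PSF blur (σ = 0.2 µm default), a constant background, and Poisson-Gaussian
noise (signal level 100 photons ⇒ shot-noise SNR ≈ 10; read noise σ = 2).
The default z-step is 0.13 µm (Nyquist-sampled confocal acquisition);
monolayer fields use 0.26 µm and 0.4 µm pixels to keep stacks small.
Monolayers are seeded Voronoi tessellations (one cell per ~π(10 µm)²) at
base height 3 µm; a chosen fraction of cells carries a parabolic dome to
8 µm. YAP scenes set nuclear intensity to background + ratio × (cytoplasm −
background) so the requested N/C is exact in the noiseless limit.

What the generators do **not** emulate: optical sectioning anisotropy of the
PSF (it is isotropic here; real confocal axial PSFs are 2–3× wider),
chromatic shifts, bleaching, cell-to-cell intensity variation, textured
chromatin, partial confluency, or segmentation failures of real cell
boundaries. Passing recoveries therefore demonstrate correctness of the
measurement code on geometry like the paper's, not robustness to every
acquisition artifact.

## Statistics

The roughness contrast uses a two-sample permutation test on the difference
of per-image means (two-sided, add-one rule p = (1 + #{|T*| ≥ |T|})/(B+1),
B = 10,000 by default, seeded and vectorized). Type-I error is calibrated in
the test suite (1000 null simulations, α = 0.05 ± 0.02) along with power at
a 3-SD gap with n = 8 per group. Mann-Whitney U p-values are pass-throughs
from SciPy and reported alongside.

## Problem sizes

The shipped studies run on one CPU core: ~1900-face isoperimetric control,
one shared ~1850/1200-face monolayer-prediction solve that also seeds the
indentation round trip (21 post positions including withdrawal), 16
monolayer renders of 150×150×35 voxels, and 1000 + 400 permutation-test
simulations at B = 999.
These sizes were chosen to resolve the rim geometry at the published
triangle counts while keeping a full acceptance run in the tens of minutes.

## Known limitations

- Penalty (soft) constraints: residuals are ~10⁻⁴–10⁻⁷, never exactly zero,
  and the lamina tension is implicit in the area-penalty multiplier.
- Contact by per-vertex projection admits facet-scale interpenetration
  between projections and bistable micro-buckles at flat contacts; the
  equilibrium is reproducible only to ~0.1–0.3 µm at the shipped
  resolutions.
- The cortex is a cap over a convex footprint with pinned boundary; no
  junctional mechanics, no neighboring cells.
- Merged nuclei defeat the overlap-exclusion rule; EFC ratios of extremely
  spiky contours depend on the tracing probe length.
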