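# Methods

## The measurement problem

Cortical bone is threaded by vascular canals a few tens of micrometres
wide.  Micro-CT at ~2 µm voxels resolves them in 3D, after which the
standard workflow is: denoise, threshold the low-attenuation canal
phase, skeletonize it, and read off morphometrics — canal volume
fraction (porosity φ), per-canal diameter, areal frequency in transverse
section, and the branching/terminal split of the skeleton nodes.  The
segmented volume also feeds image-based finite-element homogenization:
one hexahedral element per voxel, canal voxels assigned one of three
fillings (bone, liquid, gas), prescribed-strain load cases, effective
engineering constants out.

This package implements that whole chain.  Because the reference scan
is not redistributable, a generator produces ground-truthed synthetic
volumes under the same reported conditions, which both stands in for
the data and provides closed-loop validation: every statistic the
pipeline reports can be checked against the generator's truth.

## Synthetic microstructure model

A canal network is grown as explicit centerline polylines:

- **Trunks** seed a planar point process over the transverse section
  (count fixed at `round(density × area)`; positions random, thinned to
  25 % in the outer rim beyond 0.9 of the half-width).  Each trunk grows
  along +z in 10 µm steps; step directions blend the previous direction
  (weight 0.75) with a fresh von Mises–Fisher draw about +z
  (concentration `orientation_kappa` = 60), giving smooth, persistent,
  predominantly longitudinal tubes.
- **Branches** appear at `branch_prob` = 0.62 per 100 µm of growth.  A
  daughter either reconnects to the nearest point of another canal
  within 150 µm (`anastomosis_frac` = 0.55) — an anastomosis, creating a
  second branching node on the host — or wanders off radially/laminarly
  and ends at a terminal node (length ~ 20 µm + Exp(70 µm)).
  Anastomoses are essential: a pure branching tree can never exceed 50 %
  branching nodes (a tree with B bifurcations has B+1 leaves), while the
  tissue being emulated shows 63 %.  They are also what produces the
  "cellular" look of the middle zone.
- **Radii** are per-point Normal(`radius_mean`, `radius_sd`) = (5.65,
  1.0) µm, AR(1)-correlated along the canal (marginal unchanged) and
  truncated below at 2 voxels so no generated canal can fall under the
  sub-resolution removal rule.
- **Large pores** — spheres with radii uniform in 18–40 µm — populate
  the inner zone (inside 0.35 of the transverse half-width).  Fine
  canals at the reported diameter and frequency contribute only ~1.5 %
  of volume, so the pores carry the remaining ~14 pp of the 16 %
  porosity target; geometrically this makes the core pore-dominated,
  the synthetic counterpart of the pore-filled inner region seen in the
  imaging.  Smaller pore radii cannot reach the target at all: a
  Boolean model confined to the inner zone saturates well below it.

Voxelization sweeps spheres along each polyline (half-voxel arc steps)
onto a 2 µm grid.  A closed calibration loop then adds inner-zone pores
until φ is within ±0.5 pp of `porosity_target` = 0.16, sampling
candidate pores preferentially where the zone is still bone (12-point
occupancy probe, ≥25 % uncovered required) so coverage does not stall,
with pore radii allowed to inflate by at most +10 % late in the loop;
failure to converge in 20 iterations is an error reporting the achieved
porosity.  Added pores are appended to the truth network.

### Measured-statistic calibration

The reported tissue statistics are *measurements* — they include the
bias of skeleton-based estimation and of imaging.  The generator is
therefore calibrated so the default pipeline's **measured** outputs land
on the targets, not the seeded inputs:

- `trunk_density` = 133 mm⁻² seeds canals such that the measured
  transverse frequency is ~110 mm⁻² (branches and pores add profiles;
  canal merging in the pore-rich core removes them).  The trunk count is
  deterministic because Poisson count noise would dominate the
  run-to-run variance of a calibrated statistic.
- `radius_mean` = 5.65 µm, not 10.6/2: blur plus Otsu-based hysteresis
  erodes ~5-µm-radius dark cylinders by ~0.3 µm per side (the threshold
  sits slightly above the edge intensity of thin, partial-volume
  features), and the estimator itself reads the bumpy rasterized tubes
  slightly thin.  The seeded value is the one for which the *measured*
  mean diameter is 10.6 µm.
- `branch_prob` / `anastomosis_frac` are tuned so both the ground-truth
  network (~0.645) and the skeleton-measured value (~0.61) sit inside
  63 ± 5 pp; graph extraction systematically loses ~3–5 pp to junction
  merging.

### CT degradation

Phase attenuations (matrix 0.6, bone 1.0, canal 0.2 — canals dark;
polarity is a flag) → Gaussian PSF blur → multiplicative radial cupping
gain `1 + c·(ρ/ρ_max)²` (c = 0.08), the simplest artefact that makes
edges read brighter the way beam hardening does → additive Gaussian
noise.  Defaults: `psf_sigma` = 1.7 µm, chosen as a realistic
good-detector figure at 2 µm pixels (a Gaussian PSF reaches 10 % MTF at
bar width ≈ σ/0.68 ≈ 2.5 µm); `noise_sd` = 0.10 of the bone level,
i.e. canal–bone contrast-to-noise ≈ 8, a clean but honest micro-CT
setting.  Not modelled: polychromatic spectra, scatter, rings, detector
blur anisotropy, sediment-matrix geometry.  Consequently a passing
pipeline here demonstrates correctness of the chain under
realistic-but-idealized degradation; it does not certify performance on
scans with structured artefacts or matrix/bone contrast inversion.

## Segmentation

Non-local means (scikit-image, fast mode, patch 3, search radius 2,
h = 0.8·σ̂) → automatic thresholds: the *weak* threshold is the Otsu
split of the (denoised) histogram, the *strong* one sits α = 0.5 of the
inter-mode gap below it; hysteresis keeps weak voxels 26-connected to a
strong seed.  Unimodal histograms are rejected by counting separated
peaks (smoothed 256-bin histogram, 5 % prominence) — a mode-gap test
cannot flag a pure Gaussian, whose Otsu split always shows a ~1.6 σ gap.
Cleanup: canal components under `min_voxels` = 27 return to bone
(despeckle), then components whose largest inscribed-sphere diameter
(2 × max EDT) is below the certified resolution are removed.  Both
cleanup stages are idempotent and only ever exchange bone and canal
codes.  Manual correction is replaced by these rules plus an optional
user-supplied mask, for reproducibility.

## Resolution (IQI / MTF limit)

The simulated star-style IQI stacks eight square-wave gratings (bar
widths 32 → 4 µm).  Per grating, the profile is averaged along the
bars, detrended by a one-period boxcar (which nulls the bar fundamental
and all harmonics, leaving only the falloff that blur drags in from the
grating edge), trimmed of its outermost period, and read as modulation
(Imax − Imin)/(Imax + Imin) via the residual amplitude over the baseline
level.  Gratings under 2 px per bar are aliasing, not signal, and are
flagged unresolvable.  The resolution is the finest bar spacing whose
modulation clears a configurable threshold (default 0.10), linearly
interpolated between the bracketing gratings; +∞ signals nothing
resolved.  The pipeline feeds this estimate to sub-resolution removal
and to the FE element-size floor.

## Canal-network morphometry

Skeletonization is scikit-image 3D thinning (topology preserving; note
that a perfectly even-symmetric through-cylinder has no on-grid medial
voxel and thins to nothing — oracle phantoms use odd grids; generated
canals never sit on exact grid symmetry).  Graph extraction classifies
skeleton voxels by 26-neighbour count: ≥3 junction, 1 endpoint.
Junction voxels within 2 voxels merge into one branching node (thinning
leaves junction clumps); chains of degree-2 voxels become edges;
isolated cycles are kept as closed edges with no nodes.  Nodes are
*branch points and endpoints only* — degree-2 path voxels are never
nodes.

Per-point radii are EDT values of the canal phase at skeleton voxels;
an edge's mean diameter excludes points inside the inscribed sphere of
a branching end node, where the junction inflates the thickness
reading.  The diameter statistic is the unweighted mean/sd of per-edge
mean diameters, excluding edges above 30 µm (the large-pore cutoff;
configurable, length-weighting optional).  Frequency counts 8-connected
2D canal components per transverse slice over the tissue area in mm².
Orientation classes (longitudinal/radial/laminar) come from the largest
cylindrical-frame component of the edge's end-to-end displacement
(principal axis for cycles), length-weighted.  The radial profile bins
canal area fraction by normalized distance from the transverse
centroid.

On ideal cylinders of radius ≥ 2 voxels the diameter estimator is
accurate to well under one voxel; on clean rasterized truth the
recovered statistics are tighter than on degraded volumes, as the test
suite checks.

## Micro-FE homogenization

One trilinear 8-node hexahedral element per voxel (optionally coarsened
by integer majority vote; element edges must not fall below the
certified imaging resolution), small-strain isotropic elasticity, 2×2×2
Gauss quadrature.  Default materials (order-of-magnitude engineering
choices, all overridable): bone E = 20 GPa, ν = 0.3, ρ = 2.0 g/cm³;
liquid E = 0.132 GPa, ν = 0.49 (a near-incompressible soft solid with
water's ~2.2 GPa bulk modulus — fluids are represented elastostatically,
not as fluid elements); gas E = 2·10⁻⁵ GPa (10⁻⁶ of bone; exactly zero
is singular), ν = 0, ρ = 0.0012.  The liquid density 1.375 g/cm³ makes
the liquid scenario carry 5 % less mean density than solid at 16 %
porosity.

Load cases at 2 % applied strain:

- **Uniaxial** (per axis): rollers on both faces normal to the axis
  (bottom 0, top = strain × length), lateral faces traction-free,
  in-plane rigid modes pinned at corner nodes.  For a homogeneous bar
  this reproduces exact uniaxial stress, so isotropic recovery is exact.
  E_i = prescribed-face reaction / (face area × strain); ν_ij from the
  mean relative displacement of the lateral face pairs (all six ratios
  are reported; reciprocity ν_ij/E_i = ν_ji/E_j holds to solver
  tolerance).
- **Shear** (per plane): the affine simple-shear field is prescribed on
  the *entire* boundary.  With free lateral faces a finite block cannot
  sustain uniform shear stress (the required lateral tractions are
  absent) and under-reads G by several percent through edge effects,
  which would break exact homogeneous recovery; the kinematic-uniform
  condition restores it.  G_ij = tangential reaction on the driven face
  / (area × strain).
- An optional `kubc` mode applies the affine field on the whole
  boundary for uniaxial cases too (documented as not the default
  configuration).

Solver: matrix-free element-by-element conjugate gradients (numba
kernels; one reference stiffness per material), node-block-Jacobi (3×3)
preconditioning, and a cascadic initial guess — the factor-2-coarsened
problem (majority-vote materials) is solved recursively and prolonged
trilinearly; scenario sweeps additionally warm-start each scenario from
the previous one's displacement fields.  Default relative-residual
tolerance 1e-8 for verification-scale problems; the 64×64×128
qualitative runs use 1e-4, where the measured constants differ from
tighter solves by ~0.3 %, two orders below the ≥16 % ordering margins
they are used to test.  Non-convergence raises with the residual
history.  Stresses are evaluated at element centroids; von Mises from
the principal values σ_vM = √(((σ₁−σ₂)² + (σ₂−σ₃)² + (σ₃−σ₁)²)/2).

Background voxels are legal only as boundary padding (components
touching the volume boundary are excluded from the mesh); interior
background is a modelling error and is rejected.

### Bounds and their fine print

For two phases with *equal* Poisson ratio, the Reuss harmonic and Voigt
arithmetic means bound the axial modulus, and the series-laminate /
prismatic-column closed forms are exact (series exactly so only at
ν = 0: a bonded laminate with ν ≠ 0 is genuinely stiffer than Reuss
through interface constraint — ~4 % at ν = 0.3).  With unequal ν
(bone 0.3 vs liquid 0.49) the axial modulus of aligned composites
exceeds the scalar Voigt mean by the classical positive ν-mismatch
term; bound-containment checks therefore allow 0.5 % on the Voigt side
and keep Reuss strict.

### What the phase comparison does and does not claim

On synthetic longitudinal-canal geometry the package reproduces the
qualitative mechanical findings: every E and G drops when canals soften,
E_z drops least of the Young's moduli, and gas removes ~φ·100 % of the
density while liquid removes ~5 %.  The *numeric* percent reductions
reported for the real specimen (mean E −4.1 % liquid / −3.1 % gas, mean
G −4.3 % / −4.2 %, G_rθ > 6 %, ν +2.1 %) depend on that scan's geometry
and on unpublished supplementary material values; synthetic geometry at
desk scale cannot and does not reproduce them, and no test asserts
them.  Note also that with the physically conventional defaults used
here the liquid scenario is slightly *stiffer* than gas, so the
liquid-softer-than-gas ordering of those unpublished values is not
asserted either.

## Pipeline, seeds, determinism

One root seed fans out per stage via SHA-256 (`stage_seed`), so any
stage can be rerun in isolation; all outputs are pure functions of
(config, seed), single-threaded, and each artifact records the config
hash.  The default FE coupon is a 128×128×256-voxel block (downsampled
×2 → 64×64×128 elements at 4 µm) anchored toward the canal-bearing
wall; with a ~115-µm-radius pore core in a 400-µm section no sizable
transverse window avoids the core entirely, so the coupon's porosity
(~0.29) exceeds the tissue value — the qualitative phase tests use the
parallel-canal phantom instead.  Problem sizes throughout (default
200×200×400-voxel volumes, three seeds; 64×64×128-element FE blocks)
are chosen as the smallest at which the reported statistics stabilise
against their run-to-run scatter.

## Known limitations

- The generator emulates the *statistics* of the canal network, not its
  biology: no osteon geometry, cement lines, lamellae, LAGs, or
  collagen; sediment matrix is a uniform background code.
- Segmentation assumes bimodal contrast and dark canals; heavily
  matrix-infiltrated scans violating either need manual thresholds or a
  correction mask.
- The FE model is linear-elastic with isotropic phases; no fracture,
  no fluid–structure interaction, no geometric nonlinearity.  Canal
  fluids as soft solids slightly overestimate shear coupling in the
  liquid scenario.
- Apparent (boundary-condition-dependent) constants are reported, not
  periodic-homogenization constants; on a coupon a few canal diameters
  wide the two differ at the percent level.
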