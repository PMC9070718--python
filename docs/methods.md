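# Methods

This note records the models, conventions and numerical choices behind
`porequal`, and what its synthetic validation does and does not establish
about real data.

## Geometry and units

Volumes are indexed (z, y, x), 0-based, voxel centers on the integer
lattice. The isotropic voxel edge length is carried in nanometres;
distances derived from it are reported in nm, volumes and areas in µm³/µm²
(1 µm = 1000 nm). The metric pipeline always operates on the native
floating-point gray values; 8-bit conversion exists only as an explicit,
separate operation.

## Isolated-pore selection

Pore-phase connected components (26-connectivity by default, configurable
to 6/18) are classified as *main pore space* if they touch any face of the
analyzed cube, and otherwise as isolated. When a mineralized-tissue mask is
supplied, components whose 1-voxel dilation intersects it are also removed:
such pores are open to tissue and violate the two-known-materials
assumption. Survivors pass the shape filter — strictly more than 1000
voxels and sphericity S = A/(36πV²)^(1/3) strictly below 1.3 — which
removes segmentation debris. Pores whose bounding box touches the analyzed
cube are excluded from metric computation (their distance shells are
truncated); every exclusion is counted and reported, and the counts
partition the labeled set.

Note this sphericity convention equals 1 for a sphere and *increases* with
irregularity — the reciprocal of the common ≤ 1 convention — because that
is the form that is scale-free and penalizes irregular objects from above,
matching the filter's direction.

## Surface-area estimation

All areas come from a marching-cubes triangulation at level 0.5. The binary
support is first smoothed with a Gaussian of σ = 0.7 voxel: raw 0/1 fields
mesh to stair-stepped surfaces that overestimate a digitized r = 20 sphere
by ~9%, while the smoothed field is within ~1%; the symmetric smoothing
leaves the 0.5-level on the original interface. The width was chosen by
measuring the estimator against closed-form ball, cube and prolate-spheroid
areas: at σ = 0.7 all three agree within 3% at half-widths ≥ 10 voxels.
The residual known bias: sharp edges and corners are rounded, so
polyhedral objects at half-width ~10 voxels lose ~4–6% of area; smooth
blob-like objects (the use case) are essentially unbiased. Structures too
thin to survive the smoothing fall back to the unsmoothed mesh.

For pore shapes the support is padded so the mesh closes around the object;
for morphometric specific surfaces it is not, which silently drops faces on
the analyzed-cube boundary (local-tomography truncation artifacts).

## Signed distance and shells

The signed distance to the segmented pore surface is
`EDT(inside) − 0.5` within the pore and `0.5 − EDT(outside)` elsewhere:
the surface lies midway between adjacent voxel centers, adjacent voxels
take ±0.5, and the field equals the naive all-pairs computation exactly
(squared voxel distances are integers, so no tie-breaking is needed).
Shell k collects voxels with signed distance in [k−0.5, k+0.5); the curve
therefore advances in steps of exactly one voxel. Outside shells are
intersected with the scaffold mask so neighboring pores, tissue or the
main pore space never contaminate the scaffold plateau; inside shells are
restricted to the pore itself. Inner range defaults to
min(10, inscribed-ball radius) so the opposite interface of small pores
cannot bend the inner plateau; outer range defaults to 10 voxels. Each
shell contributes its unweighted mean as one fit sample with equal weight
(voxel-count weighting is available); an empty shell truncates the range
with a warning.

## Erf fit and FWHM

The step model f(d) = A1 + (A2−A1)/2·[1 + erf((d−x0)/(√2σ))] is fitted by
bounded Levenberg–Marquardt (trust-region reflective), initialized from the
outer plateau means and the mid-level crossing, with σ bounded to (1e−6,
2·span). Failures are flagged per pore, never fatal: contrast below a
configurable floor → "no contrast"; non-convergence → excluded from
resolution statistics.

The resolution is the distance between the crossings of the *measured*
curve with L1 = A1 + c·ΔA and L2 = A1 + (1−c)·ΔA, c = [1 − erf(√ln 2)]/2 ≈
0.11952 — the unique levels for which that distance equals the FWHM of the
blurring Gaussian on an ideal erf step. c is configurable for sensitivity
analysis. Crossings are located on a monotone cubic (PCHIP) interpolant
through the shell means; piecewise-linear interpolation at 1-voxel spacing
biases the width outward by ~3% even on exact erf samples, while the
shape-preserving cubic keeps the bias below 1% without overshooting on
noisy profiles. Among multiple crossings (noise), the pair bracketing the
fitted center x0 is used. The model-implied width 2√(2 ln 2)·σ_fit is
reported alongside as a consistency diagnostic.

On spherical interfaces the measured width carries a small curvature bias;
it is bounded (≲5% on σ) for pore radius ≥ 4σ, which motivates the radius
floor used in the validation phantoms.

## SNR

Pore and scaffold are eroded with the inclusive digital ball of radius 5
(voxel centers with ‖v‖₂ ≤ 5). Erosion is computed as `EDT > radius` on the
zero-padded mask — exactly equivalent to the all-offsets definition with
out-of-bounds treated as background, and fast for large structuring
elements. SNR = (μ_pore − μ_scaffold)/max(σ_pore, σ_scaffold) with sample
standard deviations; validity requires strictly more than 100 pore voxels
after erosion. A noiseless degenerate input yields an infinite-SNR sentinel
marked invalid.

The scaffold region is, by default, restricted to eroded scaffold voxels
within 15 voxels of the pore's surface (configurable; a global mode
exists). Rationale: the slow background drift of up to ~20% across the
volume would inflate a globally computed scaffold SD and read as noise; a
local shell sees at most the drift gradient across ~30–70 voxels. Whether
the original protocol computed the scaffold statistics globally or locally
is not determinable from its description; both modes are provided and the
local one is the default.

Aggregation reports mean ± sample STD (n−1) and the count, for SNR and
resolution separately, skipping invalid entries rather than zero-filling;
a single-sample aggregate is flagged.

## Phantom generator

The generator emulates the features of a reconstructed nanoCT volume that
the metrics respond to: a scaffold matrix (gray 100 by default), brighter
spherical closed pores (gray 200), a box-shaped main pore channel touching
the volume boundary, optional mineralized-tissue block, isotropic Gaussian
edge blur, additive i.i.d. Gaussian noise, and a slow multiplicative
background drift.

Blur is synthesized analytically — each pore adds the closed-form radial
profile of a ball convolved with an isotropic Gaussian, boxes add separable
products of 1D Gaussian CDFs — so noiseless gray values match the continuum
model to floating-point precision rather than carrying rasterization error.
Ground truth records centers, radii, the label volume, the true FWHM
2√(2 ln 2)·σ·voxel and the true SNR contrast/noise_σ.

Pores are placed by seeded rejection sampling with bounded retries;
surface-to-surface separations of at least 2×(3σ) between pores and from
the channel/boundary guarantee the superposition is exact and shells stay
clean. The drift field is a fixed smooth form (diagonal ramp plus one
low-frequency sine), normalized so its peak-to-peak span on a
scaffold-level background equals exactly `drift_amplitude × gray_scaffold`;
it takes no random draws, so matched seeds with and without drift share
identical geometry and noise — the basis of the drift-robustness check.
Noise is added after blurring (reconstruction-domain noise); its
distribution and the drift's functional form are configurable because
neither is pinned down by the physical protocol being emulated.

Defaults used in the validation experiments: 200³ voxels at 50 nm, 32
pores with radii in [max(9, 4σ), max(9, 4σ)+3] voxels (the 9-voxel floor
keeps > 100 voxels after radius-5 erosion; the 4σ floor bounds the
curvature bias of the erf fit), blur σ ∈ {1.5, 2, 3} voxels, noise set for
true SNR ∈ {4, 8, 10}, drift 0 or 0.2. These sizes give ≥ 30 valid pores
per condition and keep a full recovery experiment under ~10 s.

What the phantom does *not* emulate: ring artifacts, phase-retrieval
residuals, spatially correlated noise, non-spherical pore shapes,
gray-level variation within the mineralized tissue, and partial-volume
effects beyond Gaussian blur. Passing recovery tests therefore shows the
estimators are unbiased under the stated model, not that real
reconstructions satisfy that model.

## Pipeline and segmentation stand-in

Real analyses of this kind derive D1/D2 from semi-automatic watershed
segmentation with manual editing; that workflow is out of scope. The
pipeline accepts externally produced D1/D2 directly, or derives them by
thresholding (fixed level or Otsu) with an optional Gaussian pre-smoothing
(default σ = 1 voxel) applied *only* to the field being thresholded — the
metrics always read raw gray values. Mid-level thresholding places the
segmented surface slightly inside the true pore radius (by ≈ 2σ²/r for a
blurred sphere); this shifts the edge-center x0 but not the FWHM, which is
a crossing *difference*, and biases per-pore voxel counts low, which only
matters near the 1000-voxel filter boundary.

Everything downstream of the configuration is deterministic; the only
randomness (phantom synthesis) flows from a single seed, and repeated runs
produce byte-identical tables.

## Known limitations

- The resolution estimate is conservative on small or highly curved pores
  (curvature bias), and undefined where the profile never reaches a level
  crossing; such pores are flagged and excluded, which can bias a scan
  summary toward its better-resolved pores.
- The sphericity filter depends on the surface estimator; the smoothing
  width trades sphere accuracy against corner rounding and is fixed at 0.7
  voxel.
- Morphometric coverage is counted on voxel faces (6-adjacency), an
  intentional asymmetry with the mesh-based areas: contact is a topological
  question and face counting is robust to mesh artifacts, but the two
  measures are not interchangeable.
- The local-shell SNR convention differs from a global-scaffold convention
  in the presence of drift by construction; comparisons across tools should
  fix the convention first.
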