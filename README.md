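# porequal

Per-pore image-quality metrics for 3D tomographic volumes of porous
mineralized biomaterials — spatial resolution from edge-spread curves,
signal-to-noise ratio from erosion-cleaned regions — plus three-phase
morphometry and a synthetic phantom generator with known ground truth.

## The problem

Synchrotron nanoCT of bone-substitute scaffolds (e.g. β-tricalcium
phosphate with ingrown mineralized tissue) produces reconstructions whose
quality must be compared quantitatively across acquisition setups. Two
effects make naive global metrics unreliable: the gray level of mineralized
tissue varies with its degree of mineralization, and local-tomography /
beam-intensity artifacts impose a slow background drift of up to ~20% of
the gray level across the analyzed volume.

`porequal` sidesteps both by evaluating resolution and SNR only on
*isolated closed pores* inside the scaffold — pore-phase components not
connected to the boundary-reaching main pore space and not in contact with
mineralized tissue. Each such pore is a bright, roughly spherical object of
one material embedded in another, giving hundreds of independent,
user-input-free measurements per scan.

## The metrics

Given a labeled pore volume (D1), a binary pore/scaffold segmentation (D2)
and the raw floating-point reconstruction (D3):

**Pore selection.** Each pore's sphericity is

    S = A / (36 π V²)^(1/3)

with A a triangulated-isosurface area and V the voxel-count volume; S = 1
for a perfect sphere, growing with irregularity. Only pores with more than
1000 voxels and S < 1.3 are analyzed.

**Resolution.** The mean D3 gray value is binned by signed Euclidean
distance from the segmented pore surface in steps of one voxel (positive
into the pore), yielding a sigmoid step-up curve f. Modeling the interface
as a density step blurred by a Gaussian, f is fitted with

    f(d) = A1 + (A2 − A1)/2 · [1 + erf((d − x0)/(√2 σ))],

A1/A2 being the scaffold/pore gray levels. The resolution figure of merit is
the FWHM of the blurring Gaussian, read off the measured curve as x2 − x1
where f(x1) = L1, f(x2) = L2 and

    L1 = A1 + c (A2 − A1),  L2 = A1 + (1 − c)(A2 − A1),
    c = [1 − erf(√ln 2)]/2 ≈ 0.1196,

the levels at which the ideal erf step brackets the half-maximum points of
its derivative. For an exact erf profile this equals 2√(2 ln 2) σ.

**SNR.** Pore and surrounding scaffold are eroded with a radius-5 spherical
structuring element to exclude the blurred interface, then

    SNR = (μ_pore − μ_scaffold) / max(σ_pore, σ_scaffold)

over the remaining raw gray values; pores with ≤ 100 voxels left after
erosion are excluded. By default the scaffold region is a local shell
around each pore so the background drift does not masquerade as noise.

Per-scan results aggregate as mean ± sample STD with the pore count, one
row per pore in a CSV table. `morphometry` adds three-phase analysis:
specific surface area (per bulk volume) of the scaffold with and without
closed porosities, surface-to-volume ratios, and the fraction of the
available scaffold surface covered by mineralized tissue.

## Worked example

Generate a 160³ phantom (voxel 50 nm) with 20 closed pores, Gaussian edge
blur σ = 2 voxels and noise giving a true SNR of 8, then run the full
evaluation:

```python
from porequal import PhantomSpec, PoreQualityModel

spec = PhantomSpec(grid_shape=(160, 160, 160), n_closed_pores=20,
                   pore_radius_range=(9, 12), blur_sigma=2.0,
                   noise_sigma=12.5, voxel_size=50.0, seed=11)
results = PoreQualityModel.from_phantom(spec).fit()
print(results.summary())
```

prints

```
Per-pore image quality evaluation
=================================================
SNR (mean +/- STD)              7.88 +/- 0.16  (n=20)
Resolution nm (mean +/- STD)    224 +/- 6.9  (n=20)
Number of porosities            20
-------------------------------------------------
labeled 20 | boundary 0 | size 0 | sphericity 0 | erosion 0 | fit 0
```

The measured SNR (7.88) recovers the generating value 8 to ~1.5%, and the
mean resolution (224 nm) the true Gaussian FWHM 2√(2 ln 2)·2·50 ≈ 235.5 nm
to ~5%; the last line accounts for every labeled pore (none excluded here).
`results.table` holds the per-pore DataFrame; `results.save(dir)` writes
`pores.csv` and `summary.json`.

The same pipeline runs from the shell on real or synthetic data:

```sh
porequal phantom spec.yaml -o phantom/
porequal evaluate --volume D3.tif --mask D2.tif --labels D1.tif -o out/
porequal run config.yaml          # one YAML drives everything
porequal morpho --volume vol.tif --t-low 60 --t-high 160 -o report.json
```

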