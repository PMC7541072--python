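# swmrelax

A generative multiscale model of iron-driven R2\* contrast in
superficial white matter (SWM), the thin band of white matter directly
beneath the cortical gray–white boundary. The package connects tissue
composition — iron concentration, myelin volume fraction, and fiber
orientation — to the effective transverse relaxation rate R2\* observed
in gradient-echo MRI at 7 T, across four spatial scales:

- **Nanoscale**: ferritin-bound iron relaxes water protons with a
  field-strength-dependent relaxivity (0.0225 s⁻¹ per µg/g at 7 T).
  This is a linear, orientation-independent contribution.
- **Microscale**: iron-rich cell somata (oligodendrocytes and
  perivascular cells) act as magnetized perturbers. The package
  simulates the induced Larmor frequency field over a digitized iron
  concentration map with an FFT dipole convolution, histograms the
  frequencies, and fits Gaussian/Lorentzian line shapes whose width
  (FWHM) is the static-dephasing R2\*′ contribution.
- **Mesoscale**: the SWM band itself carries more iron than the deeper
  white matter. A uniformly magnetized slab of iron excess ∆c_Fe shifts
  its internal frequency by δΩ = γB₀·∆χ·(sin²θ − 2/3), where θ is the
  angle between the slab normal and B₀; partial-volume mixing of slab
  and non-slab signal in a voxel produces an orientation-dependent
  R2\*′ ≈ p(1−p)/2 · δΩ² · TE.
- **Myelin/orientation**: myelinated fibers contribute a quadratic
  R2\*(θ\*) = c + a₁sin²θ\* + a₂sin⁴θ\* dependence on the fiber-to-field
  angle θ\*. For SWM fibers lying in the plane tangent to the cortical
  surface, averaging over in-plane directions gives closed-form starred
  coefficients in terms of the surface-normal angle θ.

On top of the forward model the package provides the analysis tools
used to study SWM contrast: cortical depth-profile extraction with
named depth bands, the empirical linear contrast model
R2\* = 0.35·c_Fe + 47·ν_m + 13.7 (iron in µg/g, myelin volume fraction
ν_m), a per-vertex orientation GLM R2\* = β₀ + β₁sin²θ + β₂sin⁴θ with
orientation correction and variance accounting, and seeded synthetic
generators (cellular iron scenes, cortical ribbon phantoms, surface
sample tables) with machine-readable ground truth.

## Worked example

Simulate the microscale line width on a synthetic cellular iron scene
(200 × 200 µm, 1 µm pixels, 10 µm section, somata holding ~12 % of the
iron mass):

```python
import swmrelax as sw
from swmrelax.synthetic import CellularSceneConfig

iron, truth = sw.gen_cellular_iron_map(CellularSceneConfig(seed=7))
line = sw.simulate_line_width(iron)
print(iron.values.mean())        # 35.09  (µg/g, mean section concentration)
print(line.model, line.fwhm)     # gaussian 20.15  (rad/s)
print(truth["soma_fraction"])    # 0.1184
```

Evaluate the forward model for an SWM-like voxel (c_Fe = 55 µg/g, iron
excess 22 µg/g, slab normal parallel to B₀, slab partial volume 0.5,
TE = 20 ms, microscale relaxivity 0.215 s⁻¹/(µg/g)):

```python
voxel = sw.VoxelComposition(
    c_fe=55.0,
    slab=sw.SlabGeometry(theta=0.0, delta_c_fe=22.0, p=0.5, te=0.02),
    myelin=sw.MyelinOrientationModel(),
    micro_relaxivity=0.215,
)
print(sw.forward_r2star(voxel))
# {'nano': 1.2375, 'micro': 11.825, 'meso': 3.539..., 'myelin': 0.0,
#  'other': 0.0, 'total': 16.601...}
```

The microscale term dominates, the mesoscale slab term is intermediate,
and the nanoscale term is smallest — the mechanism ordering the model
is built around.

Fit the linear contrast model on a noisy cortical ribbon phantom
(true coefficients 0.35, 47, 13.7; noise SD 3 s⁻¹):

```python
from swmrelax.synthetic import RibbonPhantomConfig

ph = sw.gen_ribbon_phantom(RibbonPhantomConfig(seed=0))
prof = {k: sw.extract_profiles(ph[k], ph["boundary"], ph["cortical_depth"])
        for k in ("r2s", "iron", "myelin")}
fit = sw.fit_linear_contrast_model(prof["r2s"].mean, prof["iron"].mean,
                                   prof["myelin"].mean)
print(fit.coefficients)          # (0.3565, 46.75, 13.54)
print(fit.variance_explained)    # 0.9975   (full model)
print(fit.variance_explained_reduced)  # 0.8766 (myelin-only model)

swm, _ = sw.band_average(prof["r2s"], "swm")
dwm, _ = sw.band_average(prof["r2s"], "dwm")
print(swm, dwm)                  # 49.41 46.34  — elevated SWM R2*
```

Fit the orientation GLM on a 10⁴-vertex surface table whose generator
allocates 8 % of the R2\* variance to orientation:

```python
from swmrelax.synthetic import SurfaceTableConfig

table, truth = sw.gen_surface_table(SurfaceTableConfig(seed=17))
glm = sw.fit_orientation_glm(table)
print(glm.betas)                                   # [20.15  2.49 -0.64]
print(sw.orientation_variance_fraction(table, glm))  # 0.0711
corrected = sw.correct_orientation(table, glm)
```

## Command-line interface

The `swmrelax` command exposes the same functionality:

```bash
swmrelax gen-synthetic cellular --seed 7 --out scene
swmrelax simulate-field --iron-map scene/cellular_iron.csv --b0-dir z \
    --threshold 70 --out line_shape
swmrelax forward-model --config voxel.yaml --sweep theta --out sweep.csv
swmrelax gen-synthetic ribbon --seed 0 --out phantom
swmrelax fit-profiles --map phantom/ribbon_r2s.csv \
    --iron phantom/ribbon_iron.csv --myelin phantom/ribbon_myelin.csv \
    --boundary phantom/ribbon_boundary.csv --cortical-depth 60 \
    --out contrast_fit.json
swmrelax run --config pipeline.yaml    # multi-stage seeded pipeline
```

Quantitative maps are CSV/TIFF/NIfTI files with a JSON sidecar carrying
pixel size, units and section thickness; all outputs come with
provenance records (inputs, parameters, package version).

## Testing and reproduction

```bash
pytest -q                     # full suite, including acceptance tests
```

`tests/test_acceptance.py` checks the headline scientific properties:
the FFT dipole solver against the analytic dipole field (< 5 %), the
mesoscale approximation against the exact two-compartment signal,
Monte-Carlo validation of the in-plane averaging formulas (10⁻³),
static-dephasing linearity (1 %), coefficient recovery for the contrast
model and orientation GLM at 2-standard-error tolerances, and the
micro > meso > nano mechanism ordering.

To recompute all headline quantities from scratch and write them to a
JSON report:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The script regenerates every synthetic input from the given seed, reruns
the simulations and fits, and stores each quantity as
`{"name": {"value": ..., "n": ...}}` where `n` is the sample or grid
size behind the value. It takes well under a minute and needs nothing
outside the repository.

See `docs/methods.md` for the model equations, parameter conventions,
numerical choices and limitations.
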