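# Methods

This note documents the model implemented by `swmrelax`, its
assumptions, parameter conventions, the design of the synthetic
generators, the numerical choices, and the known limitations.

## 1. Model overview

The package decomposes the effective transverse relaxation rate R2\*
of a white-matter voxel at 7 T into additive contributions from
mechanisms at four spatial scales:

R2\* = R2,nano + R2\*′,micro + R2\*′,meso + R2\*(θ\*),myelin + R2,other

Additivity is an assumption: it holds when the mechanisms act on
distinct spatial scales and each stays in its own validity regime
(linear relaxivity for nano, static dephasing for micro, small phase
accrual for meso). The `other` term is a free offset for residual
sources (deoxyhemoglobin, exchange, macromolecules) that the model does
not resolve.

### 1.1 Nanoscale

Ferritin-bound iron relaxes water with a linear relaxivity:

R2,nano = r2,nano · c_Fe,  with r2,nano = 0.0225 s⁻¹/(µg/g wet tissue) at 7 T.

At c_Fe = 55 µg/g this gives 1.2375 s⁻¹.

### 1.2 Microscale (static dephasing around cellular iron)

A digitized iron concentration map c(r) (µg/g of fresh-tissue
equivalent) is converted to volume susceptibility

χ(r) = χ_mass · c_wtw(r),  χ_mass = 1.37·10⁻⁹ per µg/g,

where the wet-weight concentration accounts for section shrinkage and
tissue density: c_wtw = c_section · shrinkage / density with shrinkage
0.7 and density 1.05 g/ml by default. The induced Larmor frequency
offset is the Fourier-domain dipole convolution

δω(r) = γB₀ · F⁻¹[ D(k) · F[χ] ],  D(k) = 1/3 − (k·b̂)²/|k|²,  D(0) = 0,

with γ = 2.675·10⁸ rad s⁻¹ T⁻¹ and B₀ = 7 T. Setting D(0) = 0 removes
the mean field; the simulation is periodic, so the map is treated as
one tile of an infinite medium. 2-D section maps are extruded to 3-D by
stacking `round(thickness/dz)` planes per section and repeating the
stack (default 3 repeats) to reduce finite-thickness boundary effects.

In the static dephasing regime (no diffusion) the voxel signal is the
characteristic function of the intravoxel frequency distribution, so
the line width of that distribution is the R2\*′ contribution. The
package histograms δω (201 symmetric bins), least-squares fits both a
Gaussian (FWHM = 2√(2 ln 2)·σ) and a Lorentzian (FWHM = 2·half-width)
to the density, and reports the lower-residual model. The FWHM is
quoted in rad/s; in static dephasing it scales exactly linearly with
the source amplitude, which the tests verify to within 1 % for scale
factors 0.5–4.

A soma-restricted simulation masks the source map at a concentration
threshold (default 70 µg/g) before the convolution, quantifying how
much of the line width the discrete somata alone produce. The
microscale relaxivity is defined as FWHM divided by the mean source
concentration; for a width of 8 s⁻¹ over 37 µg/g this is
8/37 ≈ 0.216 s⁻¹/(µg/g), used as the rounded default 0.215 in the
forward model.

### 1.3 Mesoscale (iron-rich SWM slab)

The SWM band is modeled as a uniformly magnetized infinite slab with
iron excess ∆c_Fe over its surroundings. The internal frequency offset
is

δΩ = γB₀ · χ_mass · ∆c_wtw · (sin²θ − 2/3),

with θ the angle between the slab normal and B₀. A voxel containing
slab fraction p has two-compartment signal
|S(t)| = |(1−p) + p·e^{iδΩt}|, defining the exact rate
−ln|S(TE)|/TE. To second order in δΩ·TE this equals

R2\*′,meso ≈ p(1−p)/2 · δΩ² · TE,

which is what the forward model uses; the tests bound the relative
error of the approximation by 0.25·(δΩ·TE)² over a grid of p, ∆c_Fe
and TE. The rate vanishes exactly at p ∈ {0, 1} and on the magic angle
sin²θ = 2/3. With defaults ∆c_Fe = 22 µg/g, p = 0.5, TE = 20 ms and
θ = 0 the term evaluates to ≈ 3.54 s⁻¹.

θ = 0 (slab normal parallel to B₀, the |sin²θ − 2/3| maximum) is the
package default for single-voxel evaluations; it is the configuration
in which the mesoscale term reaches the quoted magnitude and the
mechanism ordering micro > meso > nano holds.

### 1.4 Myelin and fiber orientation

Myelinated fibers contribute
R2\* = c + a₁sin²θ\* + a₂sin⁴θ\* in the fiber-to-field angle θ\*. SWM
fibers are assumed to lie in the plane tangent to the cortical surface
with uniformly distributed in-plane direction. If θ is the angle
between the surface normal and B₀, averaging over the in-plane
direction φ gives the closed forms

⟨sin²θ\*⟩ = 1 − sin²θ/2,
⟨sin⁴θ\*⟩ = 1 − sin²θ + (3/8)sin⁴θ,

derived by expanding cos θ\* = sin θ·cos φ and integrating powers of
cos φ. The averaged model is again quadratic in sin²θ with starred
coefficients

c\* = c + a₁ + a₂,  a₁\* = −(a₁/2 + a₂),  a₂\* = (3/8)a₂.

The closed forms are validated against 10⁶-sample Monte Carlo to
within 10⁻³ in the acceptance tests.

## 2. Cortical depth profiles and the contrast model

Profiles are sampled along straight normals to a user-supplied
gray–white boundary polyline, parameterized by signed depth: −1 at the
pial surface, 0 at the gray–white boundary, +1 at full cortical-depth
distance into white matter. Normals are the +90° rotation of the local
tangent, with a `wm_side` sign to select which side is white matter.
Default extraction: 20 equally spaced profiles of 40 bilinear samples
each; profiles leaving the map are excluded and counted. Named depth
bands: cortex-upper [−1, −0.75], cortex-middle [−0.70, −0.35], swm
(0, 0.20] (strictly below the boundary), dwm [0.50, 1.0].

The empirical contrast model relates depth-profile means:

R2\* = 0.35·c_Fe + 47·ν_m + 13.7,

with c_Fe in µg/g, myelin volume fraction ν_m dimensionless, R2\* in
s⁻¹. It is fit by ordinary least squares (statsmodels); the fit
reports coefficient standard errors, the variance explained by the
full model and by a myelin-only reduced model, and a collinearity
diagnostic (condition number of the design).

## 3. Orientation GLM on surface samples

Per-vertex SWM samples (R2\*, surface-normal angle θ to B₀) are fit
with

R2\* = β₀ + β₁sin²θ + β₂sin⁴θ + ε.

sin²θ and sin⁴θ are strongly collinear on sphere-like θ
distributions; the fit therefore exposes the coefficient covariance
and condition number, and an optional ridge penalty. Orientation
correction subtracts β₁sin²θ + β₂sin⁴θ, leaving intercept plus
residual; by construction the corrected values regress on sin²θ with
slope numerically zero. The orientation variance fraction is
var(fitted − β₀)/var(R2\*).

## 4. Synthetic generators

All generators are pure functions of a configuration object and an
integer seed and return machine-readable ground truth alongside the
data.

- **Cellular scene** (`gen_cellular_iron_map`): 200 × 200 µm at 1 µm
  pixels by default. Background is smoothed Gaussian noise (mean
  33 µg/g, relative SD 0.3, 5 µm correlation length, clipped at 0).
  Somata are non-overlapping Gaussian profiles (radius 2.5 µm,
  σ = radius/2) placed by rejection sampling; the common soma amplitude
  is solved in closed form so the soma-mask iron fraction hits the
  configured target (default 0.12) exactly on the generated scene.
  Densities whose non-overlap placement cannot succeed raise an
  "infeasible soma density" error. Realism limits: somata share one
  amplitude, the background is stationary, and the scene is a 2-D
  section extruded to 3-D, so the simulated perturbers are effectively
  columnar rather than spherical — adequate for linearity, masking and
  relative-width experiments, not for absolute line-shape claims.
- **Ribbon phantom** (`gen_ribbon_phantom`): a 160 × 200 px flat
  cortical ribbon with a horizontal gray–white boundary, 60 px cortical
  depth, piecewise-constant iron and myelin depth bands (SWM iron
  elevated over deep white matter), R2\* computed exactly from the
  contrast model plus i.i.d. Gaussian noise (SD 3 s⁻¹). Band edges are
  placed so default profile samples never straddle an edge, which makes
  noiseless coefficient recovery exact. Realism limits: flat geometry,
  piecewise-constant composition, homoscedastic noise.
- **Surface table** (`gen_surface_table`): 10⁴ vertices, θ = arccos of
  uniform(−1, 1) (isotropic normals), R2\* = β₀ + β₁sin²θ + β₂sin⁴θ
  plus region effects and noise. The non-orientation variance is scaled
  so the realized orientation variance share matches the configured
  target (default 0.08); the realized share is recorded in the truth
  dictionary. Realism limits: no spatial autocorrelation between
  vertices; region labels are random, not contiguous patches.

## 5. Numerical choices

- **Dipole-solver oracle.** The discrete FFT kernel truncated at
  Nyquist produces ringing concentrated along the coordinate axes of a
  single-voxel source (sign flips near the axis), while off-axis
  directions match the analytic dipole to ~1 %. The acceptance oracle
  therefore uses a compact spherically symmetric source (Gaussian ball,
  σ = 1.25 voxels, unit total moment) on a 128³ grid: outside a
  spherically symmetric source the exact field is that of a point
  dipole, so the analytic reference is unambiguous. Measured agreement:
  maximum relative error < 0.7 % over radii 5–16 voxels (excluding the
  near-null cone |3cos²β − 1| ≤ 0.1), and magic-angle cone residual
  < 0.2 % of the shell peak. A median-error off-axis check for the
  single-voxel source is kept in the unit tests.
- **Demeaning and units.** D(0) = 0 enforces a zero-mean field; all
  frequencies and line widths are angular (rad/s). Rates derived from
  them (e.g., the microscale relaxivity) inherit rad/s ≡ s⁻¹.
- **Line-shape fitting.** Both candidate models are fit with
  `scipy.optimize.curve_fit` on the 201-bin density, centered at the
  histogram mean; the lower-SSE model wins, ties preferring Gaussian;
  near-degenerate fits are flagged.
- **Interpolation.** Profile sampling uses bilinear
  `scipy.ndimage.map_coordinates`; optional along-profile smoothing is
  a 3-sample moving average.
- **Fits.** All regressions use statsmodels OLS; standard errors are
  conventional OLS standard errors.
- **Problem sizes.** Default grids (200 × 200 × 30 after extrusion for
  the cellular scene, 128³ for the oracle, 100 ribbon replicates,
  10⁴ vertices) are chosen so the full test suite runs in seconds to a
  few minutes on a single CPU; they are package choices, not physical
  constraints.
- **Seeding.** Multi-part computations derive independent child seeds
  (< 2³¹) from a single CLI seed via `numpy.random.SeedSequence`, so
  every pipeline and the acceptance script are bit-reproducible per
  seed.

## 6. Limitations

- Static dephasing ignores water diffusion; for perturbers at the
  few-µm scale at 7 T this is the appropriate regime, but the package
  does not model the motional-narrowing crossover.
- The mesoscale slab is infinite and uniform; curvature, finite extent
  and intra-slab heterogeneity are not modeled beyond the quadratic
  validity bound that the tests enforce.
- Additivity of the mechanism terms is assumed, not derived; cross
  terms (e.g., myelin–iron microstructure correlations) are absorbed
  into `other`.
- The contrast-model coefficients (0.35, 47, 13.7) are empirical
  defaults of the generator and forward conveniences, not quantities
  the package estimates from first principles; the package's own
  claim is only that its fitting machinery recovers whatever
  coefficients generated the data (exactly without noise, within 2
  standard errors with noise).
- The in-plane fiber average assumes a uniform in-plane direction
  distribution; fanning out of the tangent plane or anisotropic
  in-plane dispersion would change the starred coefficients.
- Orientation angles take B₀ along +z by default; folded angles
  (θ ↦ π − θ for θ > π/2) are equivalent for the sin-power model and
  available via `fold=True`.
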