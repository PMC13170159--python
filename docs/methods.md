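# Methods

`holostain` simulates and inverts lensless in-line digital holographic
microscopy of Gram-stained blood-culture smears, then interprets the
reconstructed colour images into the standard blood-culture Gram morphology
vocabulary. Everything runs on synthetic specimens with known ground truth,
so every stage of the pipeline is testable end to end. This note records
the models, the parameters that matter, and the design decisions taken
where more than one reasonable choice existed.

## Optical forward model

The instrument class being emulated records, for each of several coherent
illumination wavelengths, the intensity of the light diffracted by the
specimen directly onto a sensor a fixed distance downstream — no lenses, no
mechanical focusing. We model this as scalar diffraction of a unit plane
wave in a unit-magnification geometry:

- **Specimen**: a thin transmittance object. Every cell contributes a
  projected chord-thickness profile `t(x, y)` (µm). Absorption follows a
  two-chromophore Beer–Lambert model (below); the phase delay is
  `2π·Δn·t/λ` with a refractive-index contrast `Δn = 0.04` for bacteria.
  Δn is deliberately modest: it keeps the worst-case optical path below
  half the shortest wavelength so the phase never wraps, which the
  multi-wavelength phase-retrieval coupling (below) relies on. Arrangement
  groups carry a per-group axial offset (default span 4 µm, quantized to
  the 1 µm reconstruction step); recording propagates through the
  per-depth transmittance planes in order, so depth differences are
  physically encoded in the fringes.
- **Propagation**: the angular spectrum method. The transfer function
  `exp(i 2π z sqrt(1/λ² − fx² − fy²))` is applied in the FFT domain with
  evanescent components zeroed. On the periodic FFT grid this operator is
  unitary, so forward and backward propagation round-trip to machine
  precision — the property the reconstruction stages depend on. An
  optional Matsushima-style anti-aliasing band limit is available
  (`propagate(..., anti_alias=True)`) for simulating isolated fields; it
  is off by default because at desk-scale grids (64–256 µm extent at
  z ≈ 600 µm) it would discard nearly all fringe content, whereas the
  periodic wrap-around is benign for a self-contained simulation.
- **Sensor**: intensities are block-averaged from the simulation pitch
  (default 0.25 µm) to the sensor pitch (default 1.0 µm, i.e. 4×4 pixel
  binning), degraded by scaled-Poisson shot noise (default 5000
  photons per unit intensity) plus Gaussian read noise (default σ = 0.005
  intensity units) and clipped to a well depth of 4.0 (the plane-wave
  background sits at 1.0). The true sample-to-sensor distance is
  `z_nominal` (600 µm) plus a seeded uniform jitter (±30 µm by default),
  emulating slide-loading tolerance.

Wavelengths default to 0.45, 0.52 and 0.63 µm — three channels spanning
the visible band, one per RGB primary.

## Stain colour model

Gram-positive cells carry a crystal-violet-like chromophore, Gram-negative
cells a safranin-like counterstain. Each is an extinction curve per µm of
stained material, anchored at the three default wavelengths
(crystal violet: 0.14/1.10/0.55; safranin: 0.55/1.00/0.15) and linearly
interpolated. The `stain_quality` scalar in [−1, 1] models decolorization
errors by mixing the two chromophores: over-decolorization (negative)
strips crystal violet from Gram-positives, under-decolorization (positive)
leaves it in Gram-negatives. The mixing slopes are chosen so that the
spectral-separation property (Gram-positives absorb more at the longest
wavelength than the shortest, and vice versa) holds for all
|stain_quality| < 0.5.

After reconstruction and RGB composition (longest wavelength → red,
gamma 1.8), Gram-positive objects land near hue 280° (purple/violet) and
Gram-negative objects near 335° (pink). These two hue-band centres, with a
common 40° half-width, are the image-side constants used by the
interpretation rules; they are a linked pair with the extinction curves
and were calibrated once by measuring reconstructed phantoms. Per-object
hue is computed as the hue of the mean RGB over the object mask —
averaging in RGB space first is far more robust to the wavelength-dependent
ringing at object edges than averaging per-pixel hues.

## Specimen generator

Three slide classes are generated, with bacterial cell density in
cells/mm² of field:

- **GNB**: independent rods 2.5–4.5 × 0.8–1.1 µm (aspect ratio ≥ 2).
- **GPC_clusters**: grape-like clumps of 4–12 cocci (diameter ~N(1.05,
  0.12²) µm clipped to 0.5–1.5), placed with a minimum spacing of one
  mean diameter so members touch without superimposing.
- **GPC_pairs_chains**: collinear runs of 2–12 cocci at touching spacing
  (1.00–1.15× the mean diameter), with small perpendicular jitter.

Arrangement groups are placed by rejection sampling with non-overlapping
group envelopes; if a bounded number of attempts cannot place the
requested density the generator raises a "specimen too dense" error, the
synthetic counterpart of a smear too thick to image. Red cells (default
150/mm²) are pale 6.5 ± 0.6 µm disks with low stain uptake; debris objects
are larger lumpy blobs used by the triage tile suite. Everything is
driven by one `numpy` generator seed, and regeneration is bit-exact.

Group sizes are capped near the remaining cell budget so the realized
count tracks the requested density; without the cap a single 12-cell chain
could triple a sparse tile's content, blurring the sparse/dense
distinction the quality-triage suite depends on.

These organism dimensions and densities are textbook values for positive
blood cultures, not fitted to any particular instrument's slides.

## Computational autofocus

The sample-to-sensor distance is recovered by back-propagating the square
root of one channel's intensity to ≥30 uniformly spaced depths spanning
≥200 µm (at reduced resolution; default 2× binning), scoring each
amplitude image, and taking the argmax (ties toward smaller z; a boundary
argmax raises a warning).

Two contrast metrics are provided. `focus_score` is the classical
Tenengrad (mean squared Sobel gradient): constant-invariant, zero for flat
images, and accurate for extended absorbing content. For sparse
holographic scenes, however, the defocused twin-image fringes dominate the
global gradient energy and Tenengrad mislocates focus by tens of µm; the
default scan metric is therefore the Tamura coefficient of the gradient
magnitude (`sqrt(std/mean)`), a normalized sparsity measure that
concentrates at true focus. Measured over seeded scans, the Tamura metric
recovers the true distance with a median error under one slice spacing,
with or without default sensor noise. A fine refinement scan
(`refine_focus`, ±1 coarse spacing, 9 steps) runs between the coarse scan
and phase retrieval; the iterative loop's object-domain constraints assume
the sample plane is where the constraints hold, so a few µm of residual
defocus measurably hurts convergence.

Inside a tight object mask the twin-image bias does not apply, so
per-object focal selection uses masked Tenengrad.

## Multi-wavelength phase retrieval

`gs_reconstruct` is an angular-spectrum Gerchberg–Saxton loop over the
wavelength channels, cycling in ascending wavelength order:

1. propagate the current sample-plane estimate of channel c to the sensor;
2. record the relative RMS mismatch between simulated and measured
   amplitude (the residual);
3. replace the simulated amplitude with the measurement — exactly at
   native sampling, or as an upsampled block-ratio correction when the
   sensor is coarser than the grid;
4. back-propagate; the returned amplitude updates channel c's sample
   amplitude, and the returned phase updates a single optical-path-length
   (OPL) map shared by all channels (`phase_c = 2π·OPL/λ_c`, the
   thin-specimen, weak-dispersion coupling).

Two object-domain constraints are enforced on the sample plane: amplitude
≤ 1 (a passive specimen) and OPL ≥ 0 (the specimen only retards the
wave). They are what suppress the twin image: without them the in-focus
amplitude correlation with ground truth plateaus around 0.85–0.9; with
them it exceeds 0.95 per channel on noiseless sparse phantoms.
Initialization is the measured amplitude of the shortest-wavelength
channel with zero phase. The loop keeps the best-residual state, stops on
a relative residual change below `tol` (default 1e-4) or after three
non-improving cycles, and reports the residual trace of the returned
state (non-increasing on noiseless input). Non-convergence within
`max_iters` (default 100) sets a flag rather than raising.

The converged sensor-consistent field is then back-propagated to a
30-slice z-stack at 1 µm steps centred on the focal estimate. Colour
composition picks, per pixel, each channel's amplitude at the slice given
by a focus map (global best slice, or the per-object map), normalizes to
the bright background (80th percentile), applies gamma 1.8, and maps
wavelengths to RGB primaries by order. An optional bicubic upsampling
provides a finer display grid without claiming extra optical resolution.

## Hologram quality triage

Each acquisition tile maps to one of six categories — no sample, valid
sparse, valid dense, invalid/too thick, hardware failure, undefined
debris — via a fixed-order decision list over interpretable features:

| check (in order) | feature | default cut |
|---|---|---|
| hardware failure | saturated or dead pixel fraction | > 0.05 |
| too thick | mean transmission < 0.35, or occupancy > 0.85 |
| no sample | occupancy < 0.0015 |
| undefined debris | fringe-band energy fraction < 0.11 |
| dense vs sparse | bacteria-band spectral variance ≥ 0.0019 |

Occupancy is the fraction of pixels deviating from the background median
by more than 4 noise sigmas (robust Laplacian estimate) with a 6%
contrast floor. The fringe band is 0.08–0.45 cycles/pixel, where
bacteria-scale diffraction rings live; large smooth debris diffracts only
into lower frequencies, which is what the debris rule keys on. The
sparse/dense split uses the *absolute* spectral variance in that band
rather than occupancy: defocused fringes from even a few cells can cover
most of a frame, while band variance grows with the amount of
bacteria-scale material and ignores red cells. Thresholds were calibrated
once on the seeded construction-labelled tile suite (`make_tile_suite`)
and frozen; categorical agreement with construction labels is ~97–98% on
200 tiles. Only the two valid categories proceed to reconstruction; a
slide with no valid tile is flagged rejected and excluded from accuracy
denominators, reported separately.

## Interpretation rules

Segmentation thresholds a smoothed darkness map (1 − min(RGB) > 0.16),
removes sub-0.25 µm² speckle, and splits touching cocci by a watershed
seeded at h-maxima of the distance transform (h = 0.14 µm): each convex
lobe contributes one marker while a rod's flat ridge keeps a single
marker. Two stages handle what the watershed cannot:

- An elongated crystal-violet blob no wider than a coccus is subdivided
  along its major axis into `round(aspect)` pieces. At 0.25 µm pitch a
  chain's touching members blur into one sausage; since Gram-positive
  rods are outside the call vocabulary, purple + elongated + narrow can
  only be a merged chain. Pink rods are untouched.
- Components in the arrangement graph (edges when centroid distance ≤
  2 × mean diameter) are called `pair_chain` only if the member centroids
  are collinear (RMS perpendicular residual ≤ 0.45 diameters) *and* the
  pooled member pixels are no wider than a coccus (perpendicular pixel
  RMS ≤ 0.72 µm); compact clumps that happen to have near-collinear
  centroids fail the width test. Non-collinear components of ≥4 are
  clusters; everything else is singleton.

Per-object Gram reaction is hue-band membership (nearer band centre wins
ties), shape is the aspect-ratio rule (≥1.8 → bacillus), and red cells
are excluded by the darkness threshold and a 20 µm² area cut. The
slide call aggregates per-object votes — GNB = negative ∧ bacillus;
GPC_clusters = positive ∧ coccus ∧ cluster; GPC_pairs_chains = positive ∧
coccus ∧ pair_chain; all other combinations abstain — and a category wins
with > 60% of classifiable votes and ≥10 detections, else the call is
Undefined. The attention map covers the winning category's object masks
(all objects when Undefined), weighted by hue-band confidence and
normalized to [0, 1].

## Benchmark conditions and problem sizes

The end-to-end benchmark uses a 384×384 grid at 0.25 µm (a 96×96 µm
field) with sensor pitch equal to the grid pitch, density 2500 cells/mm²
(≈20 cells per field — positive blood cultures are organism-rich),
stain quality ~ U(−0.3, 0.3), default sensor noise, one tile per slide,
and 30 GS iterations; 30 slides, 10 per class over seeds 1–30. Unit and
acceptance tests use 256×256 grids. These sizes keep a full run on one
CPU to a few minutes while leaving every object several pixels across;
they are the package's desk-scale operating point, not a claim about any
instrument's field of view. Measured on these conditions: slide-call
accuracy 96.7% (29/30 with all slides accepted by triage; the
characteristic failure is a cluster slide abstaining as Undefined, not a
wrong class).

## What the synthetic data does and does not show

The generator emulates the features the pipeline's logic depends on —
multi-wavelength absorption/phase contrast, stain-quality variation,
arrangement geometry, depth spread, red-cell background, shot/read noise,
distance jitter — and none of the messiness of real smears: partially
coherent illumination, multiple scattering in thick clumps, drying
artifacts, stain precipitate, sensor MTF, mixed morphologies. Passing
tests therefore demonstrate that the algorithms are correctly implemented
and self-consistent (the forward model is honestly inverted, the rules
recover the constructed truth), not that the pipeline would reach the
same figures on clinical material. The bundled validation matrices are
the bridge to real data: their metrics are reproduced exactly from the
printed counts, while the synthetic benchmark is the property-based
analogue run under this package's own conditions.

## Known limitations

- The thin-object, product-of-planes scattering model ignores multiple
  scattering; very thick clumps are rendered darker than physics would
  make them, which the triage "too thick" rule partly absorbs.
- The shared-OPL coupling assumes no dispersion in the refractive-index
  contrast and unwrapped phase; both hold by construction here but not
  for arbitrary specimens.
- Chain subdivision relies on the purple/pink dichotomy; a genuinely
  Gram-positive rod (outside the vocabulary, e.g. *Bacillus* spp.) would
  be mis-split into pseudo-cocci.
- The triage thresholds are calibrated to the synthetic tile suite's
  geometry (z ≈ 600 µm, 0.25 µm pitch); different geometries need
  recalibration.
- Polymicrobial scenes, yeast and Gram-positive bacilli are out of scope
  throughout.
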