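# Methods

This note records the models, conventions and numerical choices behind each
stage of the pipeline, what the synthetic phantoms do and do not emulate,
and the known limitations.

## Coordinate conventions

One convention is used everywhere: `y` is the rotation axis, `z` the beam
propagation axis, `x` the lateral scan axis. Volumes are arrays `[z, y, x]`
with per-axis voxel spacing in micrometres; sinograms are `[angle, y, x]`.
All coordinates are 0-based and voxel-centre; continuous coordinates
interpolate between centres. Rotation angles are sampled at bin centres
starting at 0° on the half-open interval [0°, 360°).

## Acquisition planning (`optics`)

Closed forms for a weakly focused scanned beam:

* depth of field `DoF = 2 n λ / NA²` — the Gaussian-beam confocal-parameter
  scaling; the quadratic exponent is what makes NA ≈ 0.013 at 532 nm in an
  n = 1.556 medium give a ~10 mm usable depth (a linear NA dependence would
  give 0.13 mm, far below any whole-lobe sample);
* lateral resolution `Δx = λ / (2 NA)`;
* the projection-count rule for a full revolution: as in computed
  tomography, the number of projections must equal the number of lateral
  sampling points, so 1500 lateral samples demand 1500 projections at
  0.24° increments;
* axial step scaling: when the objective's design immersion and the sample
  medium differ, the focus moves `scale_factor` times the nominal stage
  step (default 1.36, i.e. 2 µm commanded → 2.72 µm measured).

Mosaic bookkeeping floors the tile pixel count (a tile cannot exceed its
physical field: 350 µm at 0.3295 µm/px → 1062 px) and rounds mosaic extents
half-up (6515 µm → 19772 px). Grid counts are the minimal number of tiles
at pitch `tile·(1 − overlap)` covering the extent. Note that a 5% overlap
yields a 20 × 45 grid for a 6515 × 14965 µm extent; acquisitions that
report 20 × 46 tiles for the same extent imply ~7% effective overlap — the
planner follows its single consistent rule rather than reproducing both
numbers.

## Lobe phantom (`phantom`)

The phantom emulates a cleared, resin-embedded lung lobe at mesoscopic
sampling, as a *texture* model, not an anatomical one:

* an ellipsoidal lobe (default radii 760 × 860 × 700 µm in a ~2 mm field at
  20 µm voxels) with a pleural shell of configurable thickness (45 µm);
* alveoli as spherical voids of 60 µm diameter — three 20 µm beam widths,
  the alveolar scale of a rat lung — placed by greedy Poisson-disc-style
  dart throwing so voids are vesicular but non-clustered;
* airways as 2–3 levels of tapering cylinders branching from a single stem
  (enough tubular structure to exercise oblique reslicing; no airway-tree
  realism claimed);
* fibrotic patches as a sum of anisotropic Gaussian blobs thresholded
  starting at half maximum; the threshold is bisected (≤ 20 iterations)
  until the covered fraction of lobe voxels is within 0.01 of the target
  (the contract tolerance is 0.03; the tighter internal setting leaves
  margin). Patches consolidate parenchyma and the voids inside it, but
  respect pleura and airways.

Absorption (1/µm) and fluorescence (arbitrary units) are assigned per
class — parenchyma 0.002/µm and 1.0, pleura 0.0035/µm and 1.6, lumina near
zero — with fibrosis at `contrast_ratio` (default 2.0) times parenchyma on
*both* channels. The contrast ratio is a free parameter because dense
remodelled tissue is reported qualitatively ("higher density") rather than
as a measured ratio. Multiplicative Gaussian texture (σ = 5%) is applied,
clipped at zero. All randomness flows from a single
`numpy.random.Generator`; identical parameters and seed give bit-identical
phantoms.

What the phantom does **not** model: vasculature, anatomically realistic
airway trees, detector noise and PSF blur, refractive-index inhomogeneity,
scattering. Tests passing on the phantom therefore validate geometric and
algorithmic correctness of the pipeline, not robustness to real detector
physics.

## Projection (`projector`)

Per angle φ the volume is resampled into the beam frame (linear
interpolation, rotation about the volume centre, integration step = voxel
size) and summed along z. Transmission is `I = I₀ exp(−Σ μ Δl)`;
fluorescence is the plain line integral `Σ f Δl` with no self-absorption
(the cleared-sample assumption: both channels are treated as independent
projection sets). A point at radius r traces the sinusoid
`x(φ) = x_c + r cos(φ − φ₀)`.

The fan model captures an f-theta scan lens to first order: the beam
launched at detector column x propagates at in-plane angle
`β(x) = shear_rate · (x − center_x)`, implemented by integrating along the
tilted line through the focal plane with path element `Δl / cos β`; tilts
beyond 45° are rejected as outside the model's validity. Equivalently,
column x of the fan sinogram is the parallel projection at effective angle
φ + β(x) (sub-pixel lateral compression by cos β is neglected; at the 2°
worst-case edge tilt it is 0.03 px). Since the fan angle of the real lens
is not published, `shear_rate` defaults are chosen to exercise the
correction (≈ 2° at the field edge).

## Sinogram preparation (`sinogram_prep`)

Beer–Lambert inversion `−log(I/I₀)` rejects non-positive intensities with a
count of offending pixels. De-shearing resamples each sinogram column x
along the angle axis at `φ − β(x)` — circularly, because scans cover full
revolutions — with linear interpolation between angle samples; applied to
fan data this restores the sinusoid traces of parallel geometry so a
parallel-beam reconstruction applies. The shear is linear in x (first-order
f-theta model) and its parameters come from configuration/calibration, not
from estimation. De-shearing by the opposite rate inverts the operation to
interpolation accuracy.

## Filtered back projection (`recon`)

Standard two-step FBP per y-slice: frequency-domain filtering of each
projection (zero-padded to ≥ 2× the detector width) with `2|f|` (ramp),
sinc-apodized (Shepp–Logan) or Hann-windowed ramp, then backprojection with
linear interpolation, scaled by `π / (2 N_angles)` and divided by the
integration step so a unit-line-integral disk reconstructs to unit density.
Voxels outside the inscribed circle are zeroed by default (detector
coverage). Angular undersampling (fewer projections than lateral samples)
warns rather than fails.

The default filter is the Hann-windowed ramp (standard noise suppression).
The synthetic phantoms, however, contain structure at the voxel scale
(3-voxel alveolar voids), where the Hann apodization costs measurable
fidelity: on the 96³ lobe phantom the in-lobe Pearson correlation with
ground truth is 0.94 with the pure ramp vs 0.84 with Hann. Quantitative
round-trip checks therefore use `filter="ramp"`.

## Correlative alignment (`reslice`)

The plane through three landmarks is
`n = normalize((p2 − p1) × (p3 − p1))`, canonically oriented to n₃ ≥ 0
(ties toward +y, then +x) since a section plane's normal sign is arbitrary.
The rotation pair aligning n with the stack axis solves
`R_x(α_x) R_y(α_y) n = e_z` with right-handed rotations; writing
`n = R_y(−α_y) R_x(−α_x) e_z = (−sin α_y cos α_x, sin α_x, cos α_y cos α_x)`
gives the closed forms `α_x = asin(n₂)` and `α_y = asin(−n₁ / cos α_x)` on
the principal branch. This x-then-y decomposition is the unique one
consistent with the relation `sin α_y = n₁ / cos α_x` (up to the sign
convention). A normal along ±y makes cos α_x = 0 and the decomposition
degenerate (gimbal); it is rejected explicitly.

Volume rotation resamples trilinearly about the centre (nearest-neighbour
selectable for label volumes, which must never be averaged) and grows the
output bounding box *symmetrically by whole voxels* so the rotation centre
stays on the voxel lattice — without this, repeated rotations acquire a
half-voxel offset and round trips do not invert. Flat reslices interpolate
between slabs at fractional indices; curved reslices sample the volume
along an arc-length-parameterized polyline (unit-voxel steps, output width
= ⌈total arc length⌉) crossed with the stack axis.

## Stitching (`stitch`)

Tile grids are modelled by two translation vectors: u between
column-adjacent and v between row-adjacent tiles, non-integer and
non-axis-aligned because the stage axes are tilted against the optical scan
axes. Estimation is iterative: the current basis predicts each adjacent
pair's overlap strip; normalized cross-correlation over integer shifts with
3-point quadratic peak interpolation measures the actual offset; the
median across pairs (robust to low-texture tiles) becomes the new
estimate, until the update falls below `tol_px` (default 0.05 px).

Blending uses a separable pre-weighting mask: per axis the weight ramps
linearly as `(i + 0.5)/margin` at the edges, which makes two tiles abutting
at offset `extent − margin` sum to exactly 1 everywhere in the overlap
(partition of unity). Tiles are placed at `r·v + c·u` by bilinear
splatting of both the weighted image and the weights, and the canvas is
normalized where coverage exists. At zero noise this assembly exactly
inverts the tile-fixture generator on covered pixels.

`stack_mosaics` records z-spacing as `nominal_step × scale_factor` (the
index-mismatch focus scaling) and uses the slice-thickness convention
`depth = n_slices × step` — 146 slices at 2.72 µm → 397 µm. Vignetting is
*not* corrected beyond blending.

## ROI screening (`segment`)

The screening chain is gradient anisotropic diffusion → gradient magnitude
→ watershed → per-region density classification, run batch with
configuration-supplied markers or flood level (the interactive brush of the
original workflow is out of scope; the filter chain is kept).

* Diffusion is Perona–Malik with exponential conductance
  `g(d) = exp(−(d/κ)²)` on 6-neighbour differences, in conservative flux
  form with Neumann boundaries (global mean preserved exactly). The
  explicit step is capped at 0.25 and defaults to 0.15, slightly under the
  von Neumann bound 1/6 for the 3D 6-neighbour Laplacian.
* Gradient magnitude is the spacing-scaled central difference norm.
* Watershed floods the gradient landscape from markers
  (`skimage.segmentation.watershed`, 6-connectivity); with a flood level,
  markers are the connected components of the sub-level set.
* Regions at or above the density threshold (mean intensity) are classed
  fibrotic, others parenchyma; speckle regions under `min_region_voxels`
  are folded into parenchyma.

Shipped defaults (`ScreenParams`) are tuned for the phantom's absorption
channel and declared, not claimed to match any instrument: conductance
5×10⁻⁴ (a quarter of the parenchyma→fibrosis step), 12 iterations, flood
level at 10% of the maximum gradient, density threshold 0.00375/µm — above
the pleural mean (0.0035) and below the fibrotic mean (0.004), because the
pleura is the one normal structure nearly as dense as lesions. Median Dice
against planted fibrosis over ten seeded 64³ phantoms is ≈ 0.88.

## I/O

Volumes and sinograms travel as multipage grayscale TIFF with a YAML
sidecar carrying spacing, channel, angles and fan parameters; the sidecar
is authoritative because TIFF resolution tags cannot hold µm-precision
spacing or per-angle lists. Volumes can also be written as MRC/CCP4 mode-2
float maps (via gemmi) with cell = shape × spacing and header axis order
equal to the array order. Landmarks, polylines and tile indices are
header-bearing CSV in 0-based voxel units.

## Problem sizes and determinism

The test suite and the acceptance script run the tomographic round trip at
96³ voxels with 128 projections and screening at 64³ over ten seeds —
sizes chosen so every stage exercises its full code path while the complete
verification stays at desk scale (≈ 1 minute end to end). All stochastic
paths take explicit seeds; two runs with the same seed are bit-identical.

## Known limitations

* No scattering, refraction, PSF or detector-noise modelling; the forward
  model is purely geometric.
* The fan model is first-order (linear shear); a lens-calibrated nonlinear
  φ-offset would need a calibration table.
* Shear parameters are configuration inputs; automatic shear estimation is
  out of scope.
* Stitching estimates one global basis, not per-tile positions (no bundle
  adjustment), and does not flat-field vignetting.
* The screening defaults are phantom-tuned; real reconstructions will need
  their own conductance/threshold settings.
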