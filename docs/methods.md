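# Methods

## Scope and model

`efovct` simulates and reconstructs 2D fan-beam CT of objects that are
wider than the scanner's scan field-of-view (sFoV).  The scanner model is
a desk-scale stack of independent 2D fan-beam slices (the only cross-slice
coupling is the optional 3D Gaussian smoothing inside the HDFoV
binarization step).  Helical/cone-beam geometry, detector physics (noise,
scatter, beam hardening) and clinical reconstruction kernels are out of
scope.

Default geometry (all configurable):

| parameter | value | meaning |
|---|---|---|
| RF | 595 mm | focus-to-isocenter distance |
| RFD | 1086 mm | focus-to-detector distance (flat detector) |
| sFoV radius | 250 mm | fully measured circle |
| bore radius | 400 mm | outer limit of any object |
| channels | 512 x 2 mm | physical detector (covers the sFoV) |
| angles | 720 over 360 deg | full-scan sampling |
| mu_water | 0.02 / mm | water attenuation (~70 keV effective) |

The detector half-width is not an independent input: it is derived from
the requirement `asin(sfov/RF) <= atan(half_width/RFD)`; with 2 mm
channel pitch, 512 channels are the smallest even count that covers the
500 mm sFoV.  The "bore-wide" channel grid used by every detruncation
step widens the same detector symmetrically until it covers the 800 mm
bore (988 channels at the defaults).

## Projector and FBP

The forward projector integrates the linear attenuation coefficient
(`mu = mu_water * (1 + HU/1000)`, clipped at 0) along each fan ray by
fixed-step midpoint sampling with bilinear interpolation; the default
step is half the image pixel pitch.  Rays are clipped to the image's
bounding circle.

Reconstruction is the standard flat-detector fan-beam FBP on the virtual
detector at the isocenter: cosine pre-weighting `RF/sqrt(RF^2+t^2)`,
convolution with the band-limited (Ram-Lak) ramp — halved for the
double-covered full rotation — and distance-weighted backprojection
`RF^2/U^2`.  An optional Hann apodization is available; the default is
the plain ramp.  Accuracy at the defaults: a centered water disc
reconstructs to 0 +/- ~4 HU inside the object and the object mask agrees
with the analytic disc to Jaccard > 0.99.

**Convolution-only extensions.**  `fbp_reconstruct` accepts an extended
(bore-wide) sinogram that replaces the input during weighting and
filtering while backprojection reads only the measured channel block.
This is the mechanism behind the network-input reconstructions: the
extrapolated tails condition the ramp filter but are never backprojected.

## Projection mass and detruncation

"Projection mass" is the parallel-equivalent row integral.  A fan ray
(view `beta`, channel fan-angle `gamma`) belongs to the parallel view
`theta = beta - gamma`; `projection_mass` gathers, per channel, the fan
view `theta + gamma(t)` (periodic linear interpolation over the full
rotation) and integrates with the ray measure `cos^3(gamma) * dt_iso`
(the fan weight `RFD/sqrt(RFD^2+u^2)` times the Jacobian of the
impact-parameter map `s = RF sin(gamma)`).  With this definition the
mass of complete data is constant over views and equals the area
integral of `mu` to <0.5% for arbitrary phantoms in the bore (measured:
~0.02% for compact phantoms, ~0.2% for the 560 mm thorax).  A naive
per-fan-view weighted sum does *not* have this property — magnification
makes it swing by several percent across views even for centered wide
objects — which is why the rebinned definition is used throughout.

`cosine_detruncate` enforces mass consistency: the reference is the
maximum of the measured-block mass over views (truncation only removes
mass); each view's deficit is split between the two truncated edges in
proportion to the edge values and absorbed by a `p_edge *
cos^2((pi/2)(x/W))` tail whose width `W` is solved by bisection so the
added weighted mass matches the deficit exactly.  If even the bore-wide
tail cannot absorb the deficit, the amplitude is boosted by a logged
correction factor.  Views whose edge channels carry no signal are left
untouched, which makes the operation the identity on untruncated data.
Extensions are solved in the rebinned-parallel domain and scattered back
to fan rows; measured channels are never modified (bit-exact).
Post-detruncation flatness of the normalized mass profile is <= 1e-3 by
construction plus a rebinning interpolation error of order 1e-4.

`linear_cos2_detruncate` implements the slope-matched extrapolation used
for the network inputs: `max(0, p_edge + s*x) * cos^2((pi/2) x/W_bore)`
per fan row, with `s` the one-sided finite difference at the edge
channel and `W_bore` the distance from the edge to the bore-wide grid
boundary.  It is intended exclusively as a convolution-only extension.

## HDFoV

Two passes: (1) cosine detruncation, bore-wide FBP at a 256 matrix
(first pass needs only the object outline); (2) Gaussian low-pass
(default sigma 5 mm in-plane, 1 slice across slices), threshold at
-400 HU, largest connected component, per-slice hole filling (internal
air such as lungs belongs to the body outline); the water-filled mask is
forward-projected on the bore-wide grid, measured channels replace the
simulated ones bit-exactly with a 3-channel feather of the junction
discrepancy on the simulated side, and the final FBP runs at the 512
matrix / 800 mm FoV.  An empty first-pass mask falls back to the
detruncated reconstruction with a logged warning.

## HDeepFoV

The estimator input is the linear x cos^2 convolution-only
reconstruction at 800 mm FoV, area-averaged from 512 to the 256 network
grid — identically during training and inference.  The estimator (any
callable satisfying the 256-grid contract; oracle / identity / trained
U-Net are provided) returns a full-FoV HU estimate which is
forward-projected directly from its 256 grid on the bore-wide detector
(no upsampling anywhere), fused with the measured data in the projection
domain, and reconstructed by plain FBP at 512.  The 512 output is
therefore a genuine full-resolution reconstruction; the estimate only
enters through the projector.

## Synthetic data

*Thorax phantom*: a 560 x 270 mm body ellipse (+100 HU, a printed-
plastic-like bulk), two lung ellipses (-700 HU), and nine 12 mm circular
tissue inserts in a row below the lungs (inhale lung -800 to cortical
bone +1200; nominal values, configurable).  A quadratic per-slice
scaling profile (default 3 slices, 2% droop) emulates the smooth
superior-inferior contour; the droop is sized so adjacent 3 mm slices
differ by a few mm of lateral extent, as a smooth body contour does.  The ground-truth mask is always the analytic
union of the component supports, never a thresholded image.  Couch
height shifts translate the phantom (equivalent to moving the couch);
no patient table is modeled, so the mask "exclude table" option is a
no-op predicate hook.

*Training corpus*: each pair draws a random body-like slice — an ellipse
that provably exceeds the sFoV and fits the bore (rejection sampling),
with random rotation/shift, two lungs, a bright vertebra-like disc and a
few soft-tissue structures — rasterized at 512 over 800 mm, forward-
projected at 360 angles, truncated, and passed through the exact
network-input procedure; the target is the down-sampled ground truth.
Pairs are bit-reproducible from `(seed, index)` via spawned seed
sequences, and the generator is unlimited.  What the corpus does *not*
emulate: detector noise, scatter, beam-hardening, real anatomy texture,
couch/table structures — so passing tests demonstrate geometric
completion ability on piecewise-constant anatomy, not clinical
performance.

*Stitched reference*: the phantom is scanned twice shifted laterally by
+/-60 mm so that each half lies inside the sFoV, each truncated scan is
mass-consistency detruncated and reconstructed, shifted back, and the
two measured halves are joined with a hard midline seam.  Interior
agreement with a single untruncated reconstruction is ~20 HU; the seam
jump on the body interior stays below 30 HU.

## Estimator and training

The estimator network is a compact numpy U-Net (3 pooling levels, base 8
channels doubling per level, 3x3 convolutions, Leaky-ReLU slope 0.01,
2x2 average pooling, nearest-neighbour upsampling, skip concatenation)
with a residual 1x1 head; by default the body runs at half resolution
(one stem average-pool, correction upsampled before the residual sum),
trading top-level detail — which the final reconstruction does not take
from the estimate anyway — for a ~4x cheaper CPU pass.  Images enter
normalized from [-1000, 3000] HU to [0, 1].

The loss is DSSIM = (1 - SSIM)/2 with the standard constants (k1 0.01,
k2 0.03, Gaussian window sigma 1.5 truncated at 3.5 sigma, population
statistics, half-window border excluded); it matches the scikit-image
SSIM to machine precision, and its analytic gradient (adjoint Gaussian
filterings of the pointwise partials) is verified against finite
differences.  Optimization is Adam (lr 1e-3, batch 4), with the best-
validation-DSSIM checkpoint retained.  Training is deterministic given
(seed, config, backend): corpus, initialization and batch order all
derive from the seed.

Desk scale: the configuration defaults are 500 pairs / 30 epochs; the
automated acceptance run uses 48 pairs / 8 epochs (~4 min on one CPU),
which already reduces validation DSSIM from ~0.34 (untrained) to ~0.11
and makes the trained estimator beat the identity estimator's
eFoV Jaccard through the full pipeline on 8/8 held-out slices.  All
claims about the trained network are ordinal (better than untrained /
identity), never absolute.

## Evaluation protocol

The eFoV region is `distance-from-isocenter > sfov_radius` in the scan
frame.  Object masks come from threshold (-400 HU) + largest component +
hole filling.  The Jaccard Conformity Index is computed after
intersecting both masks with the eFoV; an empty union is defined as 1
with a flag (nothing to disagree about).  Per-slice eFoV volumes are
voxel counts outside the sFoV circle times the voxel volume; the volume
RMSD is taken over all slices and couch positions against the analytic
ground truth.  Insert HU statistics average a 10 mm radius cylinder over
up to five consecutive slices.  Histograms default to 10 HU bins.
Registration is unnecessary: all transforms are known by construction.

## Numerical choices and edge cases

- Bisection for the cosine tail width: 60 iterations on a monotone
  objective evaluated with the same discrete quadrature as the mass
  profile, so the enforced consistency is quadrature-exact.
- Merging feathers the junction *discrepancy* rather than cross-fading
  absolute values, so simulated data that already agree with the
  measurement pass through unchanged.
- All-zero sinograms are rejected by `projection_mass` (undefined
  reference); all-air images raise a distinct empty-mask error.
- HU floors at -1000 after every reconstruction (air); estimator output
  clips to [-1000, 3000].
- The first-pass HDFoV reconstruction uses the same ramp kernel as the
  final pass (the clinical kernel choice is out of scope).

## Desk-scale problem sizes

Default experiment: 3 slices, 720 angles, 512 reconstruction matrix,
three couch heights (0 / +90 / +120 mm, the cumulative shifts of the
evaluation protocol).  Unit tests run mostly at 360 angles and 256-512
matrices.  These sizes are the package's chosen desk scale; every
pipeline accepts larger values through the configuration.

## Known limitations

- 2D stacked fan-beam; no cone-beam effects.
- No noise/scatter/beam-hardening physics; HU accuracy statements refer
  to the ideal projector.
- The per-fan-view mass functional is only exactly invariant after
  parallel rebinning; the implementation therefore rebins, which assumes
  a full rotation of evenly spaced views.
- The trained estimator is a desk-scale demonstration (hundreds of
  pairs); its absolute accuracy is far below a production network
  trained on tens of thousands of clinical images.
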