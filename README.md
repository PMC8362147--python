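# efovct — extended field-of-view fan-beam CT reconstruction

CT scanners measure complete projections only inside a central circle,
the *scan field-of-view* (sFoV, here 500 mm across).  Large patients —
or patients on positioning devices — extend beyond it, into the annulus
between the sFoV and the scanner bore (800 mm): the *extended
field-of-view* (eFoV).  Projections of such objects are truncated, and a
naive filtered backprojection produces a bright rim at the sFoV edge and
loses the anatomy outside it.  Radiotherapy planning needs that anatomy:
body contours and Hounsfield units in the eFoV feed directly into dose
calculation.

`efovct` implements, at desk scale on a simulated fan-beam scanner, the
two reconstruction strategies for this problem, together with the
synthetic phantoms and the quantitative protocol to compare them:

- **HDFoV (mass-consistency detruncation).**  For complete data the
  parallel-equivalent projection mass M(θ) = ∫ p(θ, s) ds is the same at
  every view; truncation makes it drop.  Each truncated row edge is
  extended with a cos²-shaped tail whose width is solved so that the
  per-view mass deficit is absorbed exactly.  A first-pass
  reconstruction of the detruncated data is smoothed, binarized into an
  object mask, the water-filled mask is forward-projected, and the final
  image is reconstructed from measured data inside the sFoV merged with
  the mask projections beyond it.
- **HDeepFoV (projection-domain network fusion).**  An image-domain
  estimator (a U-Net at desk scale; oracle and identity baselines are
  built in) sees a standardized 256² reconstruction made with a
  slope-matched linear×cos² extrapolation that is used *only during the
  convolution step* of the FBP.  The estimate is forward-projected on
  the bore-wide detector and fused with the measured data in the
  projection domain — measured channels stay bit-exact — and the final
  512² image is reconstructed by ordinary FBP.  The network output never
  enters the image directly, so sFoV resolution and noise texture are
  those of a plain reconstruction.

Evaluation follows the geometric protocol: binary object masks, the
Jaccard Conformity Index restricted to the eFoV (|A∩B|/|A∪B| after
removing the sFoV region; 1 = perfect, 0 = disjoint), per-slice eFoV
volumes and their RMSD, insert HU statistics, and eFoV HU histograms.

## Worked example

Reconstruct the 560 mm-wide synthetic thorax (wider than the 500 mm
sFoV) at three couch heights and compare all three algorithms against
the analytic ground truth:

```bash
efovct reproduce-experiment --out scratch/exp --estimator oracle
```

prints (desk scale: 3 slices, 720 angles, 512² matrix; ~4 min):

```
               naive: eFoV Jaccard 0.081 +/- 0.026
               hdfov: eFoV Jaccard 0.831 +/- 0.174
            hdeepfov: eFoV Jaccard 1.000 +/- 0.000
  stitched_reference: eFoV Jaccard 1.000 +/- 0.000
               naive: volume RMSD 37.29 cm^3
               hdfov: volume RMSD 15.09 cm^3
            hdeepfov: volume RMSD 0.00 cm^3
  stitched_reference: volume RMSD 0.00 cm^3
```

Reading the numbers: the naive zero-padded FBP recovers almost none of
the body outside the sFoV (Jaccard ≈ 0.08).  Mass-consistency
detruncation recovers most of it (≈ 0.83) but its accuracy swings with
couch height (the ±0.17 spread; per-height means range from ≈ 0.60 to
≈ 0.95 in the JSON report).  With a perfect estimator, the
projection-domain fusion pipeline reconstructs the eFoV contour
essentially exactly at every height — the upper bound of the method.
The per-slice numbers, volumes, insert HU statistics and the stitched
two-scan reference are written to `scratch/exp/report.json`.

Other entry points: `efovct simulate` (phantom → truncated sinogram,
HDF5), `efovct reconstruct --algorithm {naive,hdfov,hdeepfov}`,
`efovct train` (estimator training on the synthetic corpus), `efovct
evaluate` (Jaccard/volume report between two images).  All commands take
`--config <yaml>` and `--seed`; every library function is importable
from `efovct` directly.  See `docs/methods.md` for the model, parameter
and design documentation.

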