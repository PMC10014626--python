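# femfall

Voxel finite-element femoral strength and agreement analysis for paired
QCT-like and reconstruction-like proximal-femur images.

## The problem

3D shape-and-density reconstructions estimated from planar DXA scans promise
QCT-like assessment of hip fracture risk without a CT acquisition.  Before
such reconstructions can drive FE-based strength estimates, one needs to
quantify how their known defects — smoother density fields, a systematic
negative volumetric BMD bias, slightly smaller bone volumes, millimetre-scale
surface error — propagate through an FE pipeline to the predicted femoral
strength, and how far simple mineral-content (BMC) corrections can repair
the damage.  `femfall` implements that entire evaluation chain for
researchers in computational bone biomechanics, using synthetic femur
phantoms with known ground truth in place of a cadaver dataset, so every
stage is verifiable.

## What it computes

* **Synthetic phantoms** — constructive femur geometries (head sphere, neck
  frustum, shaft, trochanter bosses) voxelised with partial-volume
  supersampling, six-insert calibration phantoms, per-slice HU drift, and a
  degradation operator producing the paired "reconstruction-like" image
  (default: −64 mg/cm³ mean BMD offset, 7% volume deficit, 4 mm FWHM
  smoothing, 1 mm surface noise).
* **Calibration** — slice-wise HU→BMD lines from the insert discs
  (five-slice moving average; slice-mean-HU extrapolation where the phantom
  is invisible).
* **Registration** — two-stage rigid alignment (masks, then densities) by
  mutual information over a four-level pyramid; B-spline free-form
  deformation for mapping fields onto a template femur.
* **Morphometry** — the implicit coordinate system of the proximal femur
  (neck and shaft axes iterated until they intersect, head sphere,
  lesser-trochanter peak), unsigned surface distances, ROI volumes.
* **FE strength** — side-fall pose (shaft 10° above horizontal, vertical
  neck-shaft plane), distal cut one head radius below the LT, 3 mm voxel
  hexahedra with spherical BMD mapping and embedding caps; an
  elastic–perfectly-plastic material with BV/TV-scaled properties
  (E = 24 GPa, σ_t/σ_c = 199/264 MPa at BV/TV = 1; 15.9 GPa at 0.907), a
  tension/compression-asymmetric quadric yield surface, and isotropic
  damage driven by cumulative plastic strain.  Strength is the reaction at
  the head driving node at a displacement of 4% of the head–trochanter
  distance.
* **Agreement** — per-ROI BMD/BMC, voxel-wise density correlation, mean
  |ΔBMD| maps on a template, collective and individual BMC corrections with
  FE re-runs, and regression/SEE/MAE/Lin's-CCC statistics with bootstrap
  confidence intervals.

See `docs/methods.md` for the model details and assumptions.

## Worked example

`examples/strength_single_case.py` runs the full chain on one reduced-size
phantom:

```
model: 2404 elements, 3282 nodes, head-GT distance 68.3 mm
criterion displacement: 2.73 mm (4% of head-GT distance)
force-displacement curve:
  u =  0.00 mm   F =      0.0 N
  u =  0.23 mm   F =   1898.2 N
  u =  0.46 mm   F =   3537.4 N
  ...
  u =  1.37 mm   F =   4640.0 N
  ...
  u =  2.73 mm   F =   4449.6 N
femoral strength: 4450 N
peak damage: 0.49
```

The curve rises elastically, yields, and flattens as plasticity spreads
through the trochanteric region; the strength is read at the criterion
displacement, not at a force peak.  `examples/cohort_agreement.py` extends
this to a paired cohort: uncorrected reconstruction-based strengths come out
biased low (regression slope > 1 against the reference), and rescaling each
model's densities to matched BMC pulls the regression toward identity and
raises the concordance correlation.  The other examples demonstrate phantom
generation, calibration, registration and morphometry individually.

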