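# Methods

## Model and procedure

The water-equivalent diameter of an axial CT slice is

    D_W = 2 · sqrt[ (mean_HU/1000 + 1) · A_ROI / π ]        (cm)

with `A_ROI` the body-region area in cm² and `mean_HU` the mean Hounsfield
value over that region.  The quantity `(mean_HU/1000 + 1)` is the mean
attenuation relative to water, so `(mean_HU/1000 + 1)·A_ROI` is the area of
the water cylinder with equal total attenuation, and D_W its diameter.  A
uniform water region (0 HU) therefore reproduces the equal-area circle
diameter exactly; pure air (−1000 HU) gives D_W = 0.

The pipeline assumes axial, non-tilted slices with uniform in-plane spacing,
fixed tube current, and a body fully inside the reconstructed field of view.
Truncated anatomy is processed without correction (D_W is then an
underestimate); a per-slice flag marks masks that touch the image border.

### Calibration

Stored pixel values map to HU linearly, `HU = stored·S + I`, using the
rescale slope/intercept carried by the series.  When a series carries no
rescale metadata the conventional `S=1, I=−1024` is applied with a logged
warning; data already in HU uses the identity calibration (`S=1, I=0`).
Signed/unsigned stored-pixel representation follows the file metadata as
interpreted by pydicom.  D_W is invariant to the (S, I) representation of
the same underlying HU field.

### Contouring

Per slice: threshold at −200 HU (skin ≈ 0 HU vs. air ≈ −1000 HU), label
connected components with 8-connectivity, keep the largest by pixel area,
fill enclosed holes.  Component labeling subsumes an explicit edge-detection
pass: only component identity and area are consumed, so any operator
producing closed boundaries is equivalent.  Filling never removes pixels,
so the mask always contains the thresholded component.  Equal-area ties
break toward the component whose centroid is closest to the image center
(patients are normally centered), with a logged warning.  Components
touching the border are retained and flagged.  High-HU structures (bone,
metal) need no handling — they lie above the threshold inside the body.
Slices with no above-threshold pixel are flagged "no body" and excluded
from every average; a volume with no body on any slice is rejected.

A documented failure mode: a table tangent to the skin at pixel resolution
can merge with the body into one component. The generator treats a negative
body–table gap as an error, and real cases show up in the QA overlays.

### Scan-level estimators

`D_W,all` is the unweighted mean of per-slice D_W over included slices;
slice thickness is not used as a weight (exact for uniform-thickness
series).  `D_W,n` averages n slices spread evenly over the included range,
endpoints included, symmetric about the center; n = 1 takes the central
slice.  Fractional ideal positions round half away from the center, which
preserves symmetry and keeps the n indices distinct whenever n ≤ n_total.
The signed percentage difference is `PD = 100·(D_W,n − D_W,all)/D_W,all`.

A mean HU below −1000 (possible under noise or calibration drift) is
clamped to −1000 before the square root; the occurrence is logged.
Likewise per-voxel values below the −1024 scale floor are clamped at volume
construction with a warning — Gaussian noise around an air background
routinely dips below the floor and rejecting such volumes would be wrong.

### SSDE

`nSSDE = nCTDIvol · k(D_W)`.  k tables load from YAML config, either as
exponential coefficients `k = a·exp(−b·D_W)` or as a node list interpolated
log-linearly (exact for exponentially decaying k; the two routes agree to
<1% when nodes sample the exponential at 1-cm steps).  Out-of-range
diameters clamp to the table boundary with a warning.  The bundled files
carry the public AAPM Report 204 fit coefficients (body 32 cm:
a = 3.704369, b = 0.03671937; head 16 cm: a = 1.874799, b = 0.03871313)
with provenance strings; they are defaults, not baked-in constants, and the
reference phantom is always an explicit user choice because a head/body
misselection biases dose by roughly 2×.  The tool multiplies whatever dose
index it is given (CTDIvol or nCTDIvol) and labels the output with the
supplied units; computing CTDIvol from scan parameters is out of scope.

## Synthetic phantoms

The generator emulates the study objects in the HU domain (no projection or
reconstruction physics): a uniform disk of 120 HU for the PMMA CTDI
phantoms (16/32 cm), an elliptical thorax (default 30×20 cm, 40 HU soft
tissue) with two −850 HU lung ellipses, and a head ellipse (16×19 cm,
60 HU), on a −1000 HU air background, default 512×512 raster.  Options add
a high-HU table slab below the body (area-checked to stay below the body
area), Gaussian HU noise (seeded, bit-reproducible), and a per-slice
geometric scale profile along z.

Rasterization uses pixel-center inclusion (a pixel belongs to a shape iff
its center is inside, boundary inclusive), which makes the pixel oracle
exact and reproducible.  Ground truth is dual: analytic (exact continuous
areas with the area-weighted mean HU — internal structures scale with the
slice, so D_W scales linearly with the profile factor) and a pixel oracle
from the noiseless raster.  The raster D_W converges to the analytic value
as spacing shrinks; because lattice-point counts fluctuate for a single
geometry, the convergence check averages the error over slices of varied
radius.

Longitudinal profiles: the head-like profile is a flat dome with concave
taper at both ends, `f(u) = 1 − c·|2u−1|^p` with `c = 0.08`, `p = 0.25`.
With `p < 0.5` the taper mass concentrates at the scan ends, so the central
slice exceeds the longitudinal mean and endpoint-included even sampling
approaches `D_W,all` from above as n grows — the qualitative signature of
head examinations (central-slice overestimate of several percent shrinking
to under 1% by n = 9).  The thorax-like profile superposes two random
low-order harmonics (≈5% amplitude, seeded), giving near-zero mean PD with
a large spread at n = 1 that collapses by n = 9.  What passing these checks
shows is that the estimator machinery and the profile geometry reproduce
the known head/thorax contrast; it does not certify cohort-level means or
spreads on real patients, nor robustness to truncation, contrast agents,
implants outside the body, or tube-current modulation, none of which the
generator emulates.

## Parameters that matter

| parameter | default | units | notes |
| --- | --- | --- | --- |
| contour threshold | −200 | HU | skin/air separation; scanner kernels may warrant tuning |
| n for D_W,n | 1,3,5,7,9 | slices | evenly spread, endpoints included |
| noise σ (generator) | 0 (tests use 20) | HU | 20 HU emulates a noisy body protocol |
| pixel spacing (generator) | 1.0 | mm | validation fixtures; 0.5 mm for the 32-cm disk study |
| background | −1000 | HU | air |
| k tables | AAPM 204 fits | — | YAML-overridable, phantom explicit |

## Numerical and design choices

- Geometry is handled in mm internally; areas convert to cm² only at the
  D_W formula boundary.  Slice indices are 0-based in the API, 1-based in
  all reports.
- Slice ordering uses longitudinal position metadata when present, instance
  order otherwise (logged).  Ordering does not affect D_W,all but does
  affect which slices D_W,n selects.
- The 32-cm disk validation series is rasterized at 0.5 mm on a 704×704
  grid (35.2 cm field of view, matching a body reconstruction circle); a
  32-cm body does not fit the default 512×512 grid at that spacing, and the
  generator refuses bodies larger than the field of view unless truncation
  is requested.
- The noise-agreement suite uses 3-slice volumes on a 512×512, 1.0 mm
  raster — the per-slice computation is identical for any slice count, and
  this keeps the 120-volume suite fast.
- Reports are byte-deterministic for identical input and configuration
  (sorted JSON keys, fixed float formats, no timestamps).

## Known limitations

- No truncation compensation; flagged, not corrected.
- Single-body assumption: only the largest component is kept.
- Unweighted slice averaging is approximate for mixed slice thicknesses.
- The bundled k coefficients are fits; site-specific tables should be
  supplied where exactness matters.
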