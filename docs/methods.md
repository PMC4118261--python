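# Methods

## The measurement problem

A thorax CT acquired slowly (minutes) during quiet tidal breathing images
the lung in its time-averaged mid-tidal state, roughly FRC plus half a
tidal volume. Because CT intensity in soft tissue is proportional to
physical density, such a scan is a quantitative map of how much of each
voxel is air. `lungfavc` turns a calibrated low-resolution scan of this
kind into:

* per-lung **space volume** (everything inside the lung envelope),
  **air volume** and their ratio, the mean **fractional air volume
  concentration** (FAVC);
* a **10-shell radial decomposition** of air volume about the hilum with
  the central-to-peripheral (c/p) ratio;
* lungs **registered to a template shape** by a radial elastic transform,
  from which cohort mean FAVC images and 1D orthogonal profiles are formed;
* cohort summary and test-retest repeatability statistics.

## Density and FAVC model

With calibration intensities `I_air` (pure air) and `I_tissue` (pure soft
tissue), voxel density relative to water is the linear rescaling

    rho_v = (I_vox - I_air) / (I_tissue - I_air)

and the air fraction of the voxel's space volume is

    FAVC = 1 - rho_v / rho_t,      rho_t = 1.05

where `rho_t` is the mean density of lung tissue and blood. Air volume in
a voxel is `FAVC * v` (voxel volume `v`); both maps are kept **unclamped**
because image noise is zero-mean and clipping to [0, 1] before summation
would bias volumes upward. A clamped copy exists for display only.

Both rescalings are affine in intensity, which has two useful
consequences exploited throughout: the measurement is invariant to a
common intensity offset of image and calibration, and spatial blurring
commutes with the intensity-to-FAVC conversion.

## Segmentation

Lung delineation is semi-automatic. The user supplies three landmarks (a
trachea seed and the two hila, taken at the first bifurcation of each
main bronchus); voxels with density below a threshold are candidate air;
the trachea/main bronchi are grown from the trachea seed within slices at
or superior to the more superior hilum; each lung is grown from its hilum
through the remaining candidates and then morphologically closed (3x3x3
cube, twice) so hilar vessels up to ~2 voxels thick are included in the
envelope — they occupy lung space even though they contain no air.

The base threshold is density 0.5, midway between pure air and pure
tissue — the conventional choice (about -470 HU). On blurred mid-tidal
images, however, the boundary between parenchyma (density
`rho_t * (1 - FAVC)`, about 0.34 at FAVC 0.68) and the chest wall (about
1.05) has its 50% level near density 0.7, so a fixed 0.5 threshold places
the contour systematically inside the lung and strips most of the outer
voxel layer (about 14% of the space volume on the phantom). By default a
second pass therefore re-thresholds at the midpoint between the measured
core parenchyma density (mean over the twice-eroded first-pass envelope)
and `rho_t`; under symmetric blur the midpoint threshold localises the
true interface. The refinement is an upward-only adjustment and can be
disabled (`refine_threshold=False`); with it, phantom envelope Dice
exceeds 0.99 and the space volume error is below 0.1%.

Failure modes are explicit errors, not silent degradation: a seed voxel
at or above threshold (mis-placed landmark or mis-set threshold), and
right/left growths merging into one component after trachea removal
(threshold leakage, reported with an approximate merge location).

## Volumes and the partial volume correction

Space volume is the voxel count of the (undilated) envelope times the
voxel volume. Finite resolution redistributes apparent air content
across the envelope boundary: boundary voxels read too dense, voxels just
outside gain apparent air. Because the intensity model is affine, the
*sum* is conserved, so the air volume is summed over the envelope
**dilated by one voxel**; mean FAVC is air volume over (undilated) space
volume. On the phantom with the study blur, the plain summation loses
about 6% of the true air volume and the dilated summation recovers
99.8%. The correction assumes no air-bearing structure within one voxel
(plus blur tail) of the envelope — near the main bronchi this is only
approximately true and contributes a small (<0.5%) positive bias.

## Radial geometry

Two transform centres are used deliberately:

* **Shell analysis** centres on the **hilum**, since airways and vessels
  branch approximately radially from it; equal fractional-radius shells
  then approximate airway generation ordering. The lung is divided into
  10 shells of fractional radius `f = |OV| / |OE|`, where E is the
  outermost point at which the ray from the centre through the voxel
  leaves the envelope ("outermost" makes the definition robust to
  interior vessel holes). c/p is the air volume of shells 1-5 over
  shells 6-10.
* **Registration** centres on a point **in the middle of the lung**: the
  hilum displaced halfway to the lateral envelope edge along x at the
  hilum's (y, z). The hilum itself sits on the medial edge, so nearly
  half of the rays from it would have near-zero length in the lung. The
  displaced-midpoint form `o_x = h_x + (p_x - h_x)/2` is used; the
  historical verbatim form `o_x = h_x + p_x/2` (equivalent only when the
  hilum is near x = 0) is available behind a `literal` flag.

Rays are marched at 0.25-voxel steps; voxels whose discretised `f`
marginally exceeds 1 are assigned to the outermost shell. Registration
maps each template-envelope voxel to the subject voxel with the nearest
fractional radius along the same-direction ray from the subject centre,
ties resolved toward the smaller radius (deterministic output). FAVC
values are copied, never rescaled, so registration preserves the value
multiset exactly and is the exact identity when subject and template
coincide. Template rays that find no subject voxel (possible when the
subject centre sits close to its envelope edge) are filled from the
nearest-direction successful ray and flagged in the output.

## Mean image, edge correction, profiles

Registered right and left lungs live on disjoint regions of the template
grid, so the combined per-subject image is their union; cohort images
are averaged voxel by voxel without weighting. The outer voxel layers of
the mean image remain depressed by the partial volume effect, so three
one-voxel layers are peeled off the envelope by successive erosion and
each of the two outer layers is multiplied by `mean(layer 3)/mean(layer
k)`. The correction equalises the three layer means exactly and is
idempotent. Envelopes too thin to support three erosions skip the
correction with a warning — thin basal sections therefore stay
under-corrected, which should be remembered when reading profile tails.

1D profiles are slice means of FAVC over envelope voxels only, along
lateral-medial, anterior-posterior and superior-inferior directions,
with the abscissa normalised to the envelope bounding extent per lung
(this makes differently sized lungs comparable); the lateral-medial
orientation resolves per side (-1 right, +1 left under the
x-toward-subject-left convention).

## Statistics

Sample (n-1) standard deviations throughout; COV = 100 sd/mean.
Test-retest repeatability is the standard error of the estimate of the
OLS regression of visit 2 on visit 1 (direction fixed by convention),
as a percentage of the grand mean of all values — a pure random-error
measure, since a constant inter-visit offset is absorbed by the
intercept. Paired comparisons use the paired t-test, associations the
Pearson correlation, variability comparisons the two-sided
variance-ratio F-test, and agreement the Bland-Altman bias and 1.96-sd
limits. A reference table of 11 healthy adult male never-smokers
(height, weight, FEV1, helium-dilution FRC) ships with the package; its
FRC column summarises to mean 3332 ml, COV 19.9%.

## The synthetic thorax phantom

No real study scans are distributable, so validation rests on a phantom
with exact ground truth. It emulates the acquisition geometry: a
64 x 64 x 90 grid of 4.42 mm cubic voxels holding a soft-tissue body
with a lateral exterior-air shell, two lung ellipsoids (right about
1.5 l space volume, left about 1.2 l after a medial cardiac notch), a
trachea/main-bronchus Y-tube in the mediastinum, and tissue-density
vessel capsules radiating from each hilum into shells 2-3 (reproducing
the characteristic vessel dip of the shell FAVC profile). Lung
intensities invert the measurement model, `I = I_air + (I_tissue -
I_air) rho_t (1 - FAVC)`, with a constant, linear-gradient or
radial-gradient FAVC field; the image is then blurred (Gaussian, default
8 mm FWHM, emulating tidal-cycle averaging plus scanner resolution) and
optionally degraded with additive Gaussian noise (seeded,
bit-reproducible). Truth masks, FAVC field and volumes are computed on
the clean field.

Deliberate modelling choices:

* **Body tissue density is 1.05** (= `rho_t`, perfused muscle and
  mediastinum) rather than 1.0, so background FAVC is exactly zero. With
  a density-1.0 background every voxel of the 1-voxel dilation shell
  would carry FAVC 0.048 of spurious air (~1-2% of lung volume) — an
  effect that in real scans is part of the method's bias budget but
  would confound phantom ground-truth comparisons.
* **Main bronchi stop about two voxels short of the lung surface**
  (standing in for airway walls), keeping tube air disconnected from
  lung air so the trachea region cannot flood the lung during region
  growing and blurred airway air does not contaminate the dilated
  summation.
* Airway calibre is anatomical (trachea 8 mm radius, main bronchi 6 mm):
  at 4.42 mm voxels under 8 mm blur, thinner tubes blur above the
  segmentation threshold and disappear.

What the phantom does **not** model: airway trees beyond one
bifurcation, bone, gravity-dependent density gradients (available only
as an explicit FAVC gradient field), cardiac/respiratory motion beyond
isotropic blur, and beam-hardening or scatter artefacts. Passing phantom
tests therefore demonstrates correctness of the measurement chain under
the stated image formation model, not clinical performance on real
scans.

## Problem sizes and numerical tolerances

Tests and the acceptance script run the full 64 x 64 x 90 study grid for
single-subject validation (a few seconds per run) and a 40 x 40 x 48
variant of the same thorax for multi-subject cohort flows, with lung
semi-axes scaled per subject by a clipped normal factor (sd 4%) to
emulate inter-subject size variation. Analytic radial-geometry checks
use digital balls of radius 20 voxels, where discretisation keeps the
c/p ratio within 0.01 of the continuum value 1/7. Ray marching uses
0.25-voxel steps; fractional-radius oracles are asserted to +/-0.05;
shell partition and air conservation hold to 1e-9 relative; edge
correction equalisation and idempotence to 1e-12.
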