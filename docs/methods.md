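# Methods

This note documents the models, numerical choices and limitations behind
`corneadic`: what each stage assumes, which knobs matter, and what the
synthetic study conditions do and do not establish about real exams.

## Coordinate and sign conventions

x is the column index (rightward), y the row index (downward), origin at the
top-left pixel of frame 0; all grid coordinates are 0-based.  V is positive
toward the image bottom, the direction of the incoming puff.  Strains are
dimensionless and scale-free (computed in pixel units); velocities are px/ms
and strain rates 1/ms, using the sequence's frame interval (default
30/139 ms ≈ 0.216 ms, i.e. 140 frames spanning ~30 ms — the device's true
frame pitch and pixel size are not public, so both are documented assumptions,
overridable per sequence).

## Incremental DIC

**Model.** Subset matching between *consecutive* frames with a
translation-only shape function per increment, accumulated into total
displacements.  The core assumption is that per-frame motion is small (well
under a pixel here) even when the total deformation is many pixels — that is
what makes a translation-only increment adequate and is the reason for the
incremental design.  The reference subset is re-sampled every frame at the
point's current (subpixel) position, so the texture being matched is always
the current local appearance.

**Matching criterion.** ZNSSD, which is exactly invariant to affine intensity
changes a·I + b.  The pipeline is: exhaustive integer search within
`search_radius` of the initial guess (the point's previous increment; the
spatial median of already-solved neighbours when it has no history), then
inverse-compositional Gauss–Newton on a bicubic B-spline interpolant of the
deformed frame, with a separable paraboloid fit of the 3×3 correlation surface
as fallback when the refinement diverges.  Reported quality is the ZNCC at
the optimum.

**Validity rules.** A point is invalidated from a frame onward when its ZNCC
drops below `quality_threshold`, its integer optimum hits the search radius,
its subset loses texture (zero variance), or its subset can no longer keep one
pixel of slack inside the frame (the material point is leaving the field of
view; without this rule an edge-hugging subset can lock onto a neighbouring
speckle with plausible quality).  Invalid points are in-filled with the median
of valid neighbours within 1.5 grid steps and flagged, never silently.
Tracking aborts with the frame index if more than half the points are invalid.

**Defaults** (all overridable): subset 25 px, grid step 8 px, search radius
6 px, ZNCC threshold 0.8.  On noise-free synthetic shifts the matcher is exact
at integers and accurate to ~0.013 px at subpixel shifts; on a full 140-frame
synthetic puff with sensor noise (sd 2 gray levels) the accumulated V error is
~0.02 px RMS.

**ROI.** Otsu threshold on frame 0, largest connected component,
morphological closing (disk radius 3) and hole filling — dark speckles inside
the band belong to the band.  A user-supplied mask can replace this.  Grid
centres must lie on the mask with the whole subset inside the mask dilated by
3 px; the dilation lets subsets overhang the band edge slightly, which is
necessary for the band to carry 2–3 grid rows per column — fewer rows make the
strain plane fit rank-deficient.

## Strain and rates

The pointwise least-squares strain fits planes to U and V over each point's
valid neighbours within `window_radius` (default 2 grid steps, a ~5×5
stencil); the fitted slopes are the strains.  γ_xy is the engineering shear
(∂u/∂y + ∂v/∂x), the common DIC convention; `engineering_shear=False` gives
the tensor half-shear.  The fit needs ≥ 6 valid neighbours spanning a
full-rank design; collinear neighbourhoods are flagged invalid rather than
extrapolated.  Because a plane fit interpolates affine fields, strains are
exact to machine precision there; on the smooth synthetic puff the window
averaging biases the peak shear down by ~1–3% at the default window.

Temporal rates use central differences at interior frames and first-order
one-sided differences at the two ends (exact for series linear in time,
endpoint-complete, and a linear operator — all tested).  Rigid whole-eye
motion can be compensated by subtracting the per-frame mean displacement of a
peripheral band (outermost 10% of points by |x − apex|), where the puff
response is negligible; this is OFF by default and flagged on the output.

## Evolution curves and features

Per frame, the mean and maximum over valid grid points of |V|, |γ_xy|, |VR|,
|γ_xy_R| give eight curves per exam.  Magnitudes are used because the sign of
V is an imaging convention and signed maxima flip with noise polarity; a
signed variant is available.  Invalid points are excluded, not in-filled.
The default feature vector concatenates the four *average* curves over the
first k frames (k = 140 → 560 features); the maxima are noticeably noisier,
which is why averages are the default feature set.

## Classifiers

Gaussian Naive Bayes and logistic regression (L2, C = 1) run on z-scored
features whose standardiser is fit on the training rows only; the Random
Forest (100 trees, seeded) runs on raw features.  The voting ensemble's
class-1 score is exactly the arithmetic mean of the NB and RF class-1
probabilities — soft voting, because a continuous score is what gives the
ensemble its own ROC curve.  Hard labels use a 0.5 threshold throughout.
Constant training columns are dropped with a warning (frame-0 displacement
curves are identically zero in noise-free data); NB additionally floors
per-feature variances at 1e-9 times the largest column variance.

Caveat on invariances: NB is exactly invariant to duplicating every training
row (it fits sufficient statistics); the penalised logistic model and the
bootstrap forest are not, so the determinism contract is stated as "same data
and seed ⇒ identical fit".

## Synthetic study conditions

The simulator renders a bright corneal band (quadratic arc, super-Gaussian
cross-profile, 48 px thick in a 576×200 frame) carrying dark speckles (hard
disks, 0.5 px Gaussian blur so bicubic interpolation sees smooth gradients),
8-bit gray levels, per-frame i.i.d. Gaussian sensor noise (sd 2) clipped to
[0, 255].  Deformation is the separable phenomenological field

    V(x, t) = −P(t) · S(x) + drift_y·t,
    U(x, t) =  drift_x·t + c · ∂V/∂x,

with P a rise–fall pulse ((t/t_peak)^2 up to the peak, exp(−(t−t_peak)/lag)
after — the lag is the viscoelastic recovery time constant) and S a Gaussian
bump at the apex (σ = 60 px) plus an optional narrower bump modelling focal
weakening.  Frames are rendered by fixed-point inversion of the forward map
and bicubic sampling, so a tracker following a frame-0 grid point should
recover the analytic displacement at that point exactly; ground-truth strains
and rates come from closed-form derivatives.  This is deliberately *not* a
physical fluid–structure simulation: it provides exact oracles and a
plausible class contrast, nothing more.

**Frozen cohort priors** (a documented fixture, not physiology): normal exams
draw amplitude ~ N(7.0, 1.5) px and recovery lag ~ N(11, 3.5) frames;
disease-like exams draw amplitude ~ N(8.0, 1.5), lag ~ N(22, 7), and always
carry a focal weakening bump of N(1.2, 0.5) px extra amplitude.  In fast
(curves) mode each curve receives Gaussian noise at 15% of its own maximum,
emulating the measurement noise of the tracking stage.  The within-class
spreads are intentionally wide enough that cohorts contain borderline exams:
with cleanly separated classes every model saturates at AUC 1.00 and the
ensemble cannot demonstrate any advantage over its members.  An optional
exam-level log-normal gain (`scale_jitter_sd`, default 0) can add a common
scale nuisance across all of an exam's features.

Under these conditions (ten replicate 50+50 cohorts, stratified 80/20 splits)
the voting ensemble's mean validation AUC is ≈ 0.91–0.95, it strictly exceeds
the worse of its members in most replicates, and the time-point sweep rises
from AUC ≈ 0.6 at one time point to ≈ 0.91 at 140.  What passing these checks
shows: the pipeline recovers a class signal placed in deformation amplitude
and recovery dynamics at realistic noise, and the ensemble behaves as an
ensemble should.  What it does not show: anything about real corneas — the
generative model, priors and noise are fixtures.

## Problem sizes

Unit tests use a scaled-down geometry (288×120 px, 8–16 frames); the
acceptance checks track one full 140-frame, 576×200 px exam at default grid
density (~180 points, about a minute on one CPU) and run the ten-replicate
cohort study in fast mode (a few seconds per cohort).  These sizes are the
package's chosen desk-scale study conditions.

## Known limitations

* The deformation model is separable in x and t and constant through the band
  thickness (ε_yy ≡ 0 in truth), so depth-resolved strain gradients are not
  exercised by the oracle.
* The incremental engine assumes per-frame motion within the search radius
  (6 px ≫ the ~0.7 px/frame maximum here); violent motion would need a larger
  radius or pyramid initialisation.
* The pulse has a derivative kink at the peak frame; closed-form rates use the
  right derivative there, while the pipeline's central differences smooth it —
  curve comparisons near the peak carry that (documented) discrepancy.
* Published-table reconstruction works at 2-decimal rounding and n ≤ 10⁴; one
  published row (logistic-regression validation) is internally inconsistent
  and is reported as such (empty reconstruction set).
* `reconstruct_confusion` enumerates all compositions (O(n³)); it is meant for
  table-scale totals, not large cohorts.
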