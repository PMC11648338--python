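# Methods

This note records the models, parameter choices and numerical decisions
behind `ofrtrack`, and what the synthetic qualification results do and do
not establish.

## Measurement model

The quantity of interest is the rotation of one eye in the head over the
open-loop window of the ocular following reflex. With frames at 0, 80 and
160 ms after stimulus-motion onset, the movement-epoch eye-in-head
displacement is

    (pupil(t2) − pupil(t1)) − head(t1→t2)    [image pixels],

converted to degrees by the small-angle arc relation
`deg/px = footprint / (eye_radius) · 180/π`. The small-angle form (arc =
r·θ rather than r·sin θ) errs by < 0.005% below 1°, far below every other
error source. The object-plane footprint (µm covered on the face per image
pixel) depends on camera placement and is always a configuration input —
the package makes no attempt to derive it from lens equations, because in
practice it is obtained by calibration. Default eye diameter is 22 mm
(pediatric average); the clinical configuration `deg/px = 0.168`
corresponds to a 32.3 µm footprint. Positive y is downward in image
coordinates; "up"/"down" stimulus labels are mapped by the caller.

Head motion over one 80 ms epoch is treated as pure translation: the head
is on a chin rest, residual drift is tens of µm, and rotation over such
intervals moves the marker by far less than the tracker's resolution.

## Region detection and the confidence gate

Region finding is a deterministic intensity/shape detector. Dark connected
components are thresholded at a fractional level (default 0.3) of the
frame's robust intensity range (0.1th–99th percentile — the low anchor must
sit below the darkest *feature*, which occupies well under 1% of the
frame). Context disambiguates the two dark, similar-looking features: the
pupil is the dark blob adjacent to near-saturated corneal-reflection blobs
(the eye box is grown 2.6× around it); the marker is a dark blob of
circularity ≥ 0.6 *outside* the eye box. Each box carries
`confidence = contrast score × shape score ∈ [0, 1]`; the shape score is an
aspect-ratio ramp that collapses when an eyelid flattens the pupil blob, so
blink frames fall under the 0.5 discard threshold. The threshold is
configurable; 0.5 cleanly separates the nominal scenes (confidence ≈ 0.7+)
from half-occluded ones (≈ 0.1) in the rendered sweeps.

An annotation-ingestion path (`load_annotations`) accepts external or
manual ROI boxes in the same box+confidence interface, for users with their
own detector.

## Marker displacement

Two stages. *Whole pixels*: each marker ROI is shrunk to the tight
rectangle around its thresholded blob (threshold = midpoint of the ROI's
5th/95th intensity percentiles, recorded in the result). Two
robustness details matter at nominal noise: the mask is median-filtered
(3×3) before labeling, and rectangle bounds ignore rows/columns with fewer
than 3 blob pixels — a round blob's true extreme column contains a chord of
many pixels, so this trims only noise protrusions and preserves exact
translation equivariance. Rectangles whose sizes differ by more than 2 px
per axis abort the trial (the two anti-aliased edges each quantize by
±1 px, so a tolerance of 1 would discard legitimate pure translations).
The corner difference gives the integer displacement.

*Subpixel fraction*: Pearson correlation (mean-subtracted, variance
normalized — required for the Fisher r-to-z transform to be meaningful) of
the rectangle's interior in frame A against the nine one-pixel shifts in
frame B, z = atanh(r) with r clipped to ±(1−10⁻¹²). If the 3×3 grid
maximum is not the center the window is re-anchored on it (the integer
estimate absorbs the shift), so interpolation always happens around an
interior peak.

Peak localization is the one place where a naive reading fails: a
piecewise-bilinear interpolant of the 3×3 *grid* attains its maximum at a
node, and any polynomial interpolant of the sharp z spike suffers
peak-locking at the 0.1 px level. The bilinear interpolation is therefore
applied to the *image*: a bilinearly shifted patch is a fixed linear
combination of the four surrounding integer-shift patches, so the Pearson
correlation at any fractional shift has a closed form in the 9-patch Gram
matrix, and the z surface is searched densely (coarse step 0.01 px, fine
step 0.001 px, ties toward the smaller shift). Bilinear interpolation
attenuates sensor noise at fractional shifts, which would bias the peak
toward half-pixel offsets; the denominator adds back the suppressed noise
variance using a wavelet-based noise estimate. Finally the whole estimate
is computed in both directions and antisymmetrized, which makes
`disp(A,B) = −disp(B,A)` exact and cancels residual one-sided bias. A
closed-form separable paraboloid peak (`method="quadratic"`) is kept for
comparison; it agrees with the dense search to ~0.05 px.

Measured on rendered ground truth: noiseless recovery within 0.016 px;
at nominal noise, SD ≈ 0.017 px per axis with 100% of 100 random shifts
within 0.05 px.

## Pupil center

The pupil's diameter fluctuates continuously (SD ≈ 0.21 px per 80 ms), so
frame-to-frame correlation would confound size change with displacement;
the center is instead extracted independently per frame.

1. *Tight rectangle*: as for the marker, but pixels above the 99th
   percentile of the eye patch (corneal reflections) are masked first.
2. *Template bank*: normalized cross-correlation against elliptical
   templates (semi-major radii 8–60 px step 2, aspect ratios 1.0–0.85,
   acceptance score 0.5). The tight rectangle supplies a size hint, so only
   the few neighboring radii are tried. No match above threshold → trial
   discarded.
3. *Annulus refinement*: Nelder-Mead over (cx, cy, a, b, θ) from the
   template fit (parameter tolerance 10⁻⁴ px, at most 400 evaluations;
   center bounds ±2 px, semi-axes constrained to ±1 px of the template
   stage, hitting the box flags the fit low-confidence). The objective is
   the sum of squared residuals against a dark-ellipse-on-light model
   within a ±3 px annular band around the initial edge, bright pixels
   excluded (mask dilated 2 px to cover the optical-blur skirt). Inner and
   outer intensity levels are medians well inside / outside the initial
   ellipse and stay fixed during optimization.

The model edge matters. An exact anti-aliased (area-coverage) edge is
available in `_raster.ellipse_coverage` (16×16 sub-sampling per edge pixel)
and is used to rasterize templates and synthetic scenes. Fitting that
*sharp* model to optically blurred data, however, provably compresses size
changes (≈20% for a PSF of 0.8 px — the band-limited SSE minimum sits short
of the true radius), while leaving the center untouched. The fit model
therefore carries an edge-softness parameter (default 0.8 px, the optical
PSF scale); the PSF and the pixel aperture (variance 1/12) compose into a
single Gaussian edge profile whose pixel integral is one normal CDF per
band pixel — equal accuracy for the locally straight pupil boundary and
~100× faster than sub-sampling. With `edge_sigma_px = 0` the profile
reduces to the pixel-aperture ramp, i.e. the pure anti-aliased edge.

Measured: noiseless center error < 0.001 px; nominal-noise center SD
≈ 0.02–0.03 px per axis; a programmed +1.0 px diameter step is recovered as
1.00 ± 0.04 px; ~50 ms per fit.

## Trial pipeline and statistics

Fixation gate: trials whose fixation-epoch eye-in-head magnitude exceeds
0.2° are discarded (`fixation_break`). The bound is configurable; 0.2° sits
an order of magnitude above the tracker's fixation-epoch noise and well
below task-relevant saccades. Every tracking failure signals a typed
discard reason, and per-subject summaries account for every input trial
exactly once.

Up-vs-down comparisons use Welch's unequal-variance two-tailed t test at
α = .05, applied to the vertical component per axis (the fixation-epoch
test is expected non-significant). Welch's form is the safe default when
per-condition variances are not assumed equal. Statistic-level simulations
confirm calibration: type-I rate 5% ± 3% over 1000 null sessions, and
≥ 95% power for ±0.2° responses at 0.07° noise with 15 trials per
condition.

The four-frame consistency analysis ({0, 80, 100, 180} ms) compares
d01+d13 with d02+d23 — both measure the 0→180 ms head displacement, so the
componentwise absolute difference is pure measurement error. Calibration
sweeps are summarized by OLS regression of estimated (px) on true (µm)
displacement; the residual SD (ddof = 2) is the bench resolution figure.

## Synthetic scenes

The renderer emulates the recorded near-IR view: smooth skin background
(base 150/255 with a gentle gradient), iris disk (intensity 95), darker
elliptical pupil (25), near-saturated reflection blobs (245–250), dark
marker disk (20, radius 30 px ≈ a 2.4 mm sticker at 40 µm/px), optional
eyelid occlusion. Features are placed with subpixel accuracy by
supersampled rasterization (8× by default) with area-weighted edge pixels;
a self-consistency test confirms a 100×-weighted centroid oracle recovers
programmed centers to 0.01 px.

Two physical layers sit on top of the geometry:

* **Optics** — a Gaussian PSF, default σ = 0.8 px (the diffraction scale of
  an f/2.8 lens at 800 nm on 3.45 µm pixels). Without it, rendered edges
  are unphysically sharp and any 3×3 correlation-peak interpolation pins to
  grid nodes; real systems never present such edges.
* **Sensor noise** — additive Gaussian with SD = 2% of the dynamic range
  plus Poisson shot noise (4 effective photoelectrons per count), a
  deliberately conservative regime chosen to land marker-tracking
  residuals between an ideal bench setting and in-vivo conditions.

Trial simulation composes cumulative paths: head drift as a smooth
quadratic arc with endpoint magnitude uniform up to 40 µm (chin-rest
regime); eye rotation zero until the 80 ms reflex latency, then a linear
ramp sized so the 80–160 ms displacement equals the programmed amplitude
(0.05–0.5°); pupil diameter as a random walk with SD 0.21 px per 80 ms.
Corneal reflections are modeled as offsets from the pupil center; since
they are masked out of every fit, their first-order head-fixed kinematics
are immaterial here.

What the synthetic results do **not** show: real pupils are not perfect
ellipses, the pupil center wobbles relative to the visual axis (a hard
floor for any pupil-based tracker that no synthetic ellipse reproduces),
eyelashes and skin texture are absent, and the PSF/noise model is an
idealization of one camera. Passing these benchmarks demonstrates
algorithmic correctness and internal precision, not in-vivo accuracy.

## Benchmark problem sizes

The qualification studies (`ofrtrack.bench`, reused by
`scripts/acceptance.py` and the test suite) use: a 5-seed replication of
the full calibration sweep (440 displacement estimates on 260×220 px
bench frames), 100 four-frame reliability trials, and 200 three-frame
clinical trials on 640×480 px scenes — sizes at which every reported
statistic has a small standard error while the whole script completes in
about two minutes on one CPU. Frame dimensions scale the scene, not the
algorithms; all operations accept arbitrary raster sizes including the
native 2448×2048.

## Known limitations

* The detector keys on corneal reflections to find the eye; scenes without
  any reflection need an explicit eye ROI (the annotation path).
* Marker and pupil must not overlap in the image; the detector separates
  them by context, not appearance.
* No torsion, no iris-texture tracking, no latency estimation: the package
  measures displacement between scheduled frames only.
* `GeometryConfig` assumes an isotropic footprint; anisotropic optics
  would need per-axis factors.
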