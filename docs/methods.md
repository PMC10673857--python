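# Methods

This note documents the models, estimators, numerical choices and known
limitations of the package, module by module.

## Stimulus geometry and calibration

**Looming discs.**  An object of radius *r* approaching at constant speed
*v* subtends the half-angle θ(t) = arctan((r/v)/t_c), where t_c is the
time remaining to collision; r/v alone parameterizes the expansion.  The
renderer places collision at the end of the expansion period, so frame
*k* of *n* (frame rate *f*) shows θ evaluated at t_c = duration − (k+1)/f
and the final expansion frame (t_c = 0) covers the whole display.  With
the default r/v = 120 ms and a 1 s expansion, the first frame starts at
≈ 6.8°.  A half-angle of 90° or more is rendered as full coverage: at
collision the disc has passed the viewing plane, and parts of the display
lie more than 90° from a lateral disc center.  Disc membership uses
great-circle angular distance on the azimuth/elevation sphere because the
stimulus is specified by angular size, not screen projection.  Frames
live on a regular 1°-bin angular grid (display span −20°…100° azimuth,
±50° elevation for discs); rendering errors out if the grid is too coarse
to resolve the starting disc (diameter below one bin).

**Competing edges.**  The azimuth span is divided into `n_windows`
windows of `window_width` degrees (defaults 8 × 30°), defined directly in
angular coordinates (i.e. already perspective-corrected).  Per cycle
(0.25 s) a green edge grows from the left window border and a UV edge
from the right, each filling the window at the cycle's end (30°/0.25 s =
120 °/s, 4 Hz).  Frame *k* of a cycle shows the fill fraction (k+1)/n, so
the last frame is fully filled.  Window edges are hard (aliased); the
physical display's antialiasing behavior is unknown, and hard edges keep
the time-reversal identity exact.  OFF stimuli are constructed as the ON
cycle's frames in reverse order, and counterclockwise stimuli as the
clockwise frames mirrored in azimuth, which makes the corresponding
identities bit-exact by construction (they are asserted as invariants,
not approximations).

**Calibration.**  UV intensities are 4-bit integers (0–15); green is
never an independent variable.  `build_green_mask` solves, under a linear
display model, for the per-site green mask value that makes green
irradiance equal `scale` × UV irradiance (default scale 2.3, the value
that centers behavioral isoluminance in the UV range), and returns the
achieved-ratio grid for QC.  The green-doubling manipulation is exposed
as a scalar mask multiplier.  Stimulus time is indexed from stimulus
onset; any closed-loop preamble is metadata only.

## Behavioral analysis

Mirror-image stimulus pairs (clockwise/counterclockwise rotation,
right/left disc positions) are folded by sign-inverting the mirrored
member, doubling the per-condition trial count; unmatched pairs are a
hard error listing the orphans.  Response metrics are window means on the
500 Hz ΔWBA trace: the half-open 100 ms window starting at the
expansion-end sample for discs (50 samples), the full 2 s stimulus for
edges.

The behavioral isoluminance estimator scans UV levels upward from the
lowest tested level for the first adjacent pair with mean(u₁) ≤ 0 <
mean(u₂) and interpolates linearly; ties at exactly zero on the lower
side count as crossings, and the first crossing wins.  A curve already
positive at its first level returns that level, and a curve with no
crossing returns its last level, both flagged `capped` — the estimate is
pinned by the tested range rather than measured.  Compact-range (UV 3–9)
recordings clamp estimates to [3, 9] for the same reason.  On noiseless
piecewise-linear curves the estimator is exact to machine precision; for
curved response functions the linear interpolation between tested levels
carries a small bias (≈ 0.008 levels for the default tanh response with a
crossing at 9.2 bracketed by levels 9 and 10).

## Calcium-imaging pipeline

**Alignment.**  The template is the Otsu-binarized mean image over one
reference stimulus: the UV = 0 trials for OFF-polarity cells (their
strongest disc response) and UV = 15 for ON cells.  Each frame is
binarized the same way and the integer circular shift (search window
±32 px) maximizing the spatial cross-correlation with the template is
removed.  Otsu thresholding is the package's choice; only "binarized" is
prescribed.  Integer-pixel shifts suffice for the column-scale ROIs
analyzed here, and a recording in which any shift component exceeds
25 px is flagged rejected (the caller discards it).  Alignment is
idempotent: re-aligning an aligned movie yields zero shifts.

**ROI detection.**  The reference-stimulus mean image is smoothed with a
Gaussian of 11 px FWHM (σ = FWHM/2√(2 ln 2)).  Local maxima separated by
at least one column spacing and above a floor (mean + 1 SD of the
smoothed image; no floor is prescribed, and this one admits planted-blob
peaks while rejecting background texture) seed a watershed of the
inverted smoothed image.  Each seed's territory is then cut at an
intensity stop: pixels must exceed the image background (smoothed
minimum) by at least 20 % of the seed's own rise above background.  The
stop is defined relative to background rather than as an absolute
fraction of the peak because baseline fluorescence offsets every pixel;
an absolute 20 %-of-peak floor falls below baseline whenever background
fluorescence is appreciable, which would inflate masks to entire
watershed territories and dilute ΔF/F₀.  Masks are disjoint (watershed
territories) and connected (component containing the seed).  Column
spacing defaults to 60 px, the lobula value for T4/T5 fields of view
(≈ 4 µm at 17 µm/256 px); medulla fields of view (34 µm/256 px, ≈ 5 µm
columns) correspond to ≈ 38 px, exposed as `min_separation`.

**ΔF/F₀ and metrics.**  F₀ is the mean mask fluorescence over the 1.5 s
before stimulus onset, per trial; non-positive F₀ invalidates the ROI.
The disc-response metric is the mean ΔF/F₀ over the two frames
immediately after full expansion; the Dm9 cell class, which keeps
responding through the hold period, instead uses the two frames after the
screen returns to green.  For ON-edge control stimuli the response to the
pre-edge blank screen can be subtracted via `blank_response`.

**Thresholding and estimates.**  An ROI is kept iff its mean metric over
the polarity's reference levels (UV 12–15 for ON cells, 0–3 for OFF, 0–1
for Dm9) reaches the threshold; `threshold_sweep` reports cohort
isoluminance ± SEM and fly count across thresholds, the stability
diagnostic for choosing the cutoff.  The ROI isoluminance scans downward
from UV = 15 for ON cells and upward from UV = 0 for OFF cells for the
first transition to a negative mean response and interpolates linearly.
With no sign change the level of the curve's minimum is returned
(`crossing_found=False`); a curve already negative at the scan start
returns that end level flagged `capped` (a case the estimator definition
leaves open).  Estimates average ROIs → fly and flies → grand mean, each
fly weighted equally; the population isoluminance applies the ROI rule to
the across-fly mean tuning curve.

**Recorded window.**  Trials are nominally 8 s but only 7.6 s are
recorded; the generator produces exactly the recorded frames and the gap
exists only as timing metadata, so no missing-sample interpolation path
exists downstream.

## Synthetic data

The generators' defaults are the study conditions under which the
analyses are validated.

**Behavior.**  Per-trial mean response = amplitude · tanh(slope·(UV − I))
for competing edges (I = i_on for ON protocols, i_off for OFF; defaults
i_on = 4.5, i_off = 9.2, amplitude 1, slope 0.5/level, noise SD 0.05,
5 presentations per rotation).  Only the zero crossing is constrained by
the measurements; tanh is an arbitrary odd, monotone choice, and the
slope sets how sharply the response crosses zero.  Disc responses occupy
the post-expansion window and scale with the distance to the nearer
visibility-band boundary, zero when `predict_visibility` says the disc is
invisible (a green disc on a UV background strictly inside
(i_on, i_off) drives neither pathway; a UV disc on green always drives at
least one, since the bands overlap whenever i_on ≤ i_off).  Mirrored
trials carry sign-inverted responses; all draws come from one seeded
generator.

**Movies.**  Planted ROIs are isotropic Gaussian blobs (FWHM = one
column spacing, 60 px) at centers at least one spacing apart, over a
baseline of 100 with blob amplitude 150 (arbitrary fluorescence units).
A blob's response factor is ±gain·(UV − iso)/15 (positive slope for ON
polarity, gain 0.6), multiplied by the disc drive (linear ramp during the
1 s expansion, sustained for the 1 s hold) convolved with a causal
exponential kernel (τ = 0.3 s) standing in for indicator kinetics.  The
noiseless ΔF/F₀ metric is therefore exactly linear in UV with a zero at
the planted isoluminance; background dilution inside the mask scales the
curve but cannot move the zero.  Jitter is an integer-rounded Gaussian
circular shift per frame, recorded for alignment-recovery tests (integer
circular shifts are exactly recoverable, so recovery error measures only
the noise sensitivity of the correlator); noise is additive Gaussian
(SD 4 by default in validation cohorts), clipped at zero — a deliberate
simplification of photon shot noise.  Eleven UV levels
{0,2,4,5,6,7,8,9,10,12,15} × 3 trials × 51 recorded frames per fly keep
a 16-fly validation run to a few minutes; the reference experiment used
5 trials per level.

**Test images.**  A hard-edged colored disc on a colored background, with
optional per-pixel noise and an optional smooth achromatic texture
(Gaussian-filtered noise shared by all channels) that mimics the
luminance structure of natural scenes.  The texture matters for the
channel-symmetric motion control: on an exactly luminance-balanced flat
image the symmetric-weight contrasts are pure floating-point residue, and
a rank test over their consistent signs is meaningless; with genuine,
radially unbiased luminance structure the approach/recede comparison is a
proper null.

**What the generators do not emulate.**  Photoreceptor spectral sampling,
flight dynamics, non-rigid tissue motion, shot noise, bleaching, neuropil
contamination, and response adaptation.  Passing recovery tests therefore
demonstrates correctness of the analysis chain under its stated
assumptions, not robustness to every artifact of real recordings.

## Hexagonal-lattice motion model

**Lattice.**  Flat-topped hexagons, width 120 px point-to-point and
height 104 px flat-to-flat (only this orientation makes those dimensions
a near-regular hexagon), tile with horizontal pitch 90 px and vertical
pitch 104 px, alternate columns offset by 52 px.  Pixels are assigned to
the nearest center after rescaling y so the tiling is regular, using the
integer-valued quantity h²Δx² + 3(w/2)²Δy² with lexicographic
(distance, Δy, Δx) tie-breaking.  Because the tie-break depends only on
the pixel's offset from the candidate center, every interior cell is an
exact integer translate of every other and owns exactly
(3/4)·120·104 = 9360 pixels.  Sites are indexed by axial coordinates
(q = column, r), and border-clipped sites keep their partial pixel sets.

**Contrast and motion.**  The home group is a site plus its six
neighbors; the background group for a direction is the three facets
adjacent to the home group's leading edge (offsets read from the model's
neighborhood diagram and exposed as a configurable template).  The
directional Weber contrast is (I_h − I_b)/I_b on channel-weighted
intensities.  ON evidence in direction *d* is max(C_d, 0) under the ON
channel weights, OFF evidence max(−C_d, 0) under the OFF weights; each
feeds a 2-D vector sum over the four cardinal unit vectors (pixel frame,
up = −y), projected onto the site's radial unit vector — away from the
focus for approach, toward it for recede — and summed into the combined
estimate.  Spectrally asymmetric pathways are weight vectors, e.g.
ON = (1,0,0) with OFF = (0,0,1) for red-driven ON and blue-driven OFF.

**Border rule.**  Contrast groups admit only full (unclipped) hexagons.
Clipped cells average far fewer pixels, and their noisier means inflate
|contrast| toward the image border — radially outward from a central
focus — which would bias approach above recede even for channel-symmetric
weights.  The number of included sites is reported rather than matched to
any particular figure; the lattice origin and border handling make the
absolute site count convention-dependent.

**Statistics.**  Approach and recede are compared across jointly valid
sites with a two-sided Wilcoxon rank-sum test.  Neighboring sites share
group members, so the per-site values are spatially correlated and the
nominal p-value is anticonservative; it is used as a summary statistic of
effect direction and strength, as in the analysis it reproduces.  Sites
are instantaneous estimates: temporal correlation, depth and parallax are
out of scope.

## Statistics module

Benjamini–Hochberg is used for "FDR correction" (the procedure is not
named in the source analyses; BH is the standard default).  Rank tests
use exact small-sample nulls when scipy's policy allows (no ties, n ≤ 25)
and tie-corrected normal approximations otherwise.  Degenerate inputs are
handled explicitly: all-tied paired differences and all-tied rank-sum
pools return p = 1 with a warning; a zero-variance one-sample t reports
the limiting p with a warning rather than NaN.  Normality screening
(Anderson–Darling) is advisory and never gates an analysis.

## Validation cohorts and problem sizes

`cohorts.behavior_cohort` (10 flies, 5 presentations per rotation, noise
SD 0.1) recovers median ON/OFF isoluminances within ±0.25 levels of the
planted (4.5, 9.2) and yields a decisive paired signed-rank split.
`cohorts.imaging_validation_cohort` (8 flies × 3 ROIs, jitter SD 2 px,
noise SD 4, 11 levels × 3 trials) mirrors the UV-background validation
design in which the planted zero crossing is unambiguous (UV = 5 for the
ON configuration, UV = 8 for OFF) and recovers the grand mean within
±0.3 levels; `scripts/acceptance.py` reruns exactly these two cohorts.
Per-fly seeds derive from one root seed, so every cohort is
bit-reproducible.

## Known limitations

- Integer-pixel, rigid, circular-shift alignment only; real movies with
  sub-pixel or non-rigid motion need external correction first.
- The ΔWBA–contrast transfer function is an artifact choice (tanh); only
  zero-crossing behavior should be compared against real data.
- The hexagonal rank-sum p-values ignore spatial correlation between
  sites (see above).
- The flood-fill stop criterion and binarization rule are package
  choices among the many consistent with "flood filling around peaks"
  and "binarized"; both are exposed as parameters.
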