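# Methods

## The measurement model

`skystereo` implements a stereovision rig for monitoring airspace above a
runway: two identical cameras on a **vertical baseline** of length *B*, with
both optical axes parallel and tilted by a common **rotation angle** α away
from the perpendicular to the baseline. α = 0 is classical stereovision;
tilting the axes lets a single installation cover an elevated observation
cone without tilting the whole rig geometry out of its closed form.

Pixel coordinates along the baseline-aligned (vertical) image axis are
signed, origin at the image center; the positive direction is chosen so that
an object lying between the two optical axes has y₁ > 0 in camera C1 and
y₂ < 0 in C2, hence positive disparity y₁ − y₂. (Hardware that indexes rows
0…y₀ from one sensor edge maps to this convention by
y_centered = y_edge − y₀/2.)

With y₀ the vertical resolution and φ₀ the vertical field of view, a pixel
maps to a ray tangent tan φ = y·tan(φ₀/2)/(y₀/2), and the distance from C1
to the *object plane* (plane through the object perpendicular to the axes)
is

    D = B·cos α · y₀ / (2 tan(φ₀/2) (y₁ − y₂)) + B·sin α · y₂ / (y₁ − y₂).

The equivalent angle-space form
D = B(cos α − sin α·tan φ₂)/(tan φ₁ + tan φ₂) is computed alongside and the
two are asserted to agree to machine tolerance on every call — a cheap,
permanent consistency check of the sign conventions.

Two altitude estimators are provided, because the printed closed form of the
source model, H = D·cot(φ₀/2 + φ₂), does not reference α or the mount height
and its angle convention cannot be reconciled unambiguously with the rig
figure. `altitude_eq10` is that literal formula; `altitude_from_ray` is the
geometry-consistent value H = mount_height + D sin α − lateral·cos α with
lateral = D·tan φ₁, which round-trips exactly with the forward projection.
The processing pipeline uses the geometry-consistent one; the literal form
is kept for comparison and makes no claim about which the original field
prototype used.

`forward_project` is the exact inverse (metric position → real-valued pixel
coordinates); substituting its output into the distance formula recovers D
to machine precision, which the property suite exercises on random rigs.

## Quantization uncertainty

Integer pixel coordinates make D a discrete function; the exact differential
of the pixel-space formula gives one quantization step

    ΔD = [y₀ cos α/(2 tan(φ₀/2)) + y₂ sin α] · B/(y₁ − y₂)²  =  D/(y₁ − y₂),

an identity asserted at machine tolerance wherever ΔD is evaluated. For
α > 0, ΔD grows with y₂ as well as with D: uncertainty increases with
object elevation, which is why surfaces and the baseline trade study are
evaluated over the full y₂ range.

ΔD is a *one-step* measure, not a supremum of the recovery error. For true
positions that project exactly onto integer pixels, quantized triangulation
is exact and trivially within ΔD. For generic sub-pixel positions the two
pixel errors can add up to almost one full pixel of disparity error, and the
sharp bound (proven from the closed form, verified by brute force in the
test suite) is

    |D̂ − D| ≤ (D̂ + B sin α / 2)/(y₁ − y₂ − 1),

which exceeds ΔD by a factor of at most (y₁−y₂)/(y₁−y₂−1) — a few percent at
the disparities of interest. Disparities below 1 px are reported as
non-triangulable rather than mapped to enormous distances, since ΔD
diverges there.

The published field analysis quotes worst-case values (±81 m at B = 1 m,
±61 m at B = 1.5 m at a 300 m range, and "could be of 70 m") that are not
reproducible under any single consistent reading of the uncertainty formula
(candidate readings give ≈90–128 m); those numbers are therefore documented
but never used as reference values. The baseline sweep instead reports, per
candidate baseline and per y₂ extreme (±y₀/2), the uncertainty at the last
integer disparity that still reaches the range limit — evaluated as a
formula bound, i.e. without requiring y₁ = y₂ + disparity to sit on the
sensor, since at the top extreme no on-sensor y₁ exists. At fixed true
distance ΔD scales as 1/B, reproducing the ordering of the published
baseline study and its selection rule (smallest B meeting the uncertainty
target; B = 1 m with the default camera).

## Size model and classification

A detection's pixel box (p_W, p_H) at distance D gives metric wingspan and
height via PW = D·p_W·SIA/(f·y₀) (SIA the sensor dimension along the
disparity axis, f the focal length). The silhouette is modeled as an
isosceles triangle, and its area O = PW·PH/2 is the one-number size measure.
Boundaries come from reference raptors: common buzzard (1.1 × 0.4 m →
0.22 m²) and red kite (1.45 × 0.66 m → 0.4785 m²). The second boundary is
stored at full precision, with a flag for the conventionally printed 0.48;
boundary membership follows "smaller than Ob1 is small, at least Ob2 is
large", so an object exactly on a boundary belongs to the larger class.

The wingspan formula has no printed uncertainty companion; consistent with
the exact-differential treatment of ΔD, we define
ΔPW = (SIA/(f·y₀))(p_W·ΔD + D·Δp), with a one-pixel box quantum Δp = 1.
Evaluated along distance with the continuous on-axis disparity, the
resulting class envelopes for 1 m and 1.67 m wingspans stay separated over
the small class's working range, reproducing the class-separation picture
of the size-uncertainty analysis.

## Motion detection and pairing

Blob extraction is deliberately the simplest defined operator: absolute
difference of two frames of one camera, binary threshold (default 20 of 255),
8-connected components, minimum area (default 16 px²), tight bounding boxes,
intensity-weighted centroids. Identification (bird vs. artifact) and
statistical track filtering are out of scope and replaced by a pass-through.

Stereo pairing matches blobs across cameras greedily by horizontal proximity
(|x₁ − x₂| ≤ 30 px default), subject to disparity ≥ 1 px after converting
rows to signed coordinates. For the vertical coordinate the *bounding-box
center* row is used rather than the weighted centroid: the centroid of a
triangle silhouette sits p_H/6 below the box center, so the box center is
the unbiased estimator of the projected object center under the silhouette
model (both quantities are kept on the `Blob`).

Two-frame differencing of consecutive frames necessarily shows both the
current silhouette and a "ghost" at the previous position. The end-to-end
runner therefore differences each frame against a rendered target-free
background frame of the same camera (a static-scene reference) — the same
operator, with the reference frame chosen so that exactly one blob per
camera appears and its box is the exact rendered silhouette. Consecutive-
frame operation remains available (it is what the CLI `detect` command does
on frame sequences) but is noisier: slow apparent motion yields partial or
absent difference blobs.

## Synthetic scenes

The simulator emulates the validation campaign: a target of known wingspan
and height passes the station at near-constant distance and altitude.
Trajectories hold D and H at their scenario means plus temporally smoothed
Gaussian jitter whose realized mean and standard deviation are pinned
exactly to the requested values (centering and rescaling after smoothing),
so scenario conditions are controlled rather than merely approximate; the
horizontal coordinate is a straight constant-speed pass through the image
center. A GPS-like reference adds i.i.d. Gaussian noise to (D, H); its
default (1.0 m, 0.5 m) is a conventional consumer-GPS figure, configurable
because the campaign's σ columns mix flight-path variation with recorder
error and pin down no separate value.

The nine scenario presets use the campaign's per-scenario mean
distance/altitude, spreads and sample counts (durations are (N−1)/fps so
sample counts match the test plan at the default 15 FPS; the frame rate
itself is configurable — the field system states only a >15 FPS computation
rate), with drone dimensions 0.24 × 0.10 m, 1.20 × 0.53 m, 1.99 × 1.04 m
and speeds 4.0, 20.0, 15.0 m/s.

Rendering draws the target as a filled isosceles triangle — matching the
size model, which makes the classification round trip exact — of width
round(wingspan·f·y₀/(depth·SIA)) px at each camera's own axial depth,
centered at the forward-projected, integer-quantized vertical pixel. Ties
round half away from zero everywhere, fixed for bit-reproducible fixtures;
anti-aliasing is off. A silhouette with even pixel height has no centered
placement, so its measured box center sits exactly 0.5 px off the projected
row; the offset is common to both cameras except when their rendered
heights differ in parity, which bounds any disparity error at 0.5 px (the
pipeline tests assert exactly this envelope). Targets whose extent rounds
below one pixel, and out-of-FoV samples, render empty frames.

Frames are y₀ rows by a configurable width (default 320 columns): the
vertical axis is the physical disparity axis at full resolution, while the
horizontal axis maps the full horizontal FoV (derived from SIA and f) onto
the chosen width. The horizontal coordinate is plumbing — it never enters
triangulation — so the compressed mapping trades file size for nothing that
is being measured.

What the simulator does *not* model: photorealistic appearance, wing-beat
pose variation, weather/illumination, lens distortion, calibration or
synchronization error, and multiple simultaneous targets. Passing tests
therefore demonstrate correctness of the geometry, uncertainty propagation
and statistics pipeline under the silhouette model — not field detection
performance of real cameras on real birds.

## Evaluation statistics

Detection efficiency: time is counted in whole frames at the track's frame
rate; a range bin (a, b] (half-open, as the field tables print) accumulates
flight time from reference frames whose distance lies in the bin and
detection time from the subset with a detection; the ratio is reported as an
integer percentage, ties rounded up. Localization accuracy per scenario:
means and *population* (N-denominator) standard deviations per source — the
convention is pinned by the regression tests, the source tables do not state
it — with absolute accuracy |mean_sys − mean_ref| and relative accuracy as
its percentage of the reference mean, printed at one decimal. Classification
confusion: 3×3 counts with per-true-class reliability (diagonal percentage).
`report` serializes all three deterministically (sorted keys, embedded
config hash and seed), so identical runs produce byte-identical files.

Several cells of the published field tables are internally inconsistent
(printed value ≠ arithmetic of the same row's printed entries under either
rounding convention the tables mix); the regression tests reproduce every
self-consistent cell and list the handful of typo cells explicitly.

## Problem sizes and defaults

| Parameter | Default | Why |
|---|---|---|
| y₀ | 1440 px | reference camera resolution of the field system |
| φ₀ | 48.8° | reference camera vertical FoV (3 mm lens) |
| f, SIA | 3 mm, 3.76 mm | reference sensor/lens pair |
| B | 1 m | baseline selected by the trade study |
| α | 24.4° (= φ₀/2) | field configuration of the rotated axes |
| mount height | 0 m | altitude is reported relative to the rig base |
| fps | 15 | simulator default matching the stated real-time rate |
| frame width | 320 px | desk-scale horizontal crop; vertical axis stays full |
| threshold / min area | 20 / 16 px² | generic detection defaults; the synthetic runner uses min area 2 px² because the small target covers <16 px² near its range limit |

End-to-end scenario runs (nine presets, 875 frame pairs total at the
table-matched durations) complete in well under a minute on one CPU; the
exhaustive integer-pixel brute-force check covers ~10⁶ pairs vectorized.
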