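# Methods

`polarflip` quantifies how channel-confined, neutrophil-like cells respond to
optogenetic stimulation delivered at their rear: whether the rear-localized
Cdc42 activity rises, whether the front disengages, when the cell stalls and
reverses, and how the 1D activity pattern evolves. This note documents the
models, parameter choices and numerical decisions behind each stage, what the
synthetic generator does and does not emulate, and the known limitations.

## Coordinate and timing conventions

The microfluidic channel runs along the image row (vertical) axis; one cell
occupies one channel. Frames are acquired every `frame_interval_s` (default
3 s) at `pixel_size_um` (default 0.21 µm/px). Time is measured from the first
stimulation pulse: frame `stim_frame` (default 21, i.e. 63 s of unperturbed
migration) is t = 0, pre-stimulus times are negative. The transient assay
delivers 12 pulses (t = 0…33 s), the center assay 5 pulses (t = 0…12 s), and
persistent stimulation continues to the end of the recording.

## Synthetic microscopy generator

Because every downstream stage must be verifiable against ground truth, the
generator is a first-class, tested component rather than a test fixture.

**Cell geometry.** A cell is an axially elongated super-ellipse
(`|Δr/a|^4 + |Δc/b|^4 ≤ 1`, default half-axes 55 × 11 px ≈ 23 × 4.6 µm,
≈ 2200 px area), moving along the channel axis at a baseline speed of
0.14 µm/s (2 px/frame). Length and width are constant; the real cells'
stimulus-induced elongation is not modelled.

**Activity model.** The 1D activity profile interpolates between a rear trace
r(t) and a front trace f(t) through a plateau–smoothstep–plateau shape: the
rear and front thirds of the cell are flat at r(t) and f(t) with a smooth
ramp between. Baselines are r₀ = 0.95 and f₀ = 1.15 ratio units, a 0.2-unit
front–rear contrast that is large against the 0.03 front-engagement
threshold. Traces are piecewise linear, and the class-specific slopes are
*solved from the configured event schedule* so that the detection definitions
(1% threshold crossings relative to the t = 0 value, velocity zero crossing,
trace intersection) are met at exactly the configured times. For the reversed
class the defaults follow the observed cohort medians: rear response 5 s,
front response 20 s, stall 27 s, cross-point 51 s; the rear and front caps
swap the two baseline levels so polarity fully reverses. The strong class
engages both edges (final activity gap ≈ 0.011 < 0.03) but recovers its
original direction and polarity after the stimulus ends; the medium class
caps its rear rise at 4% (> 2% threshold) with the front untouched; the
no-response class changes nothing. Signed velocity ramps linearly through
zero at the stall time with a 9 s half-width.

**Myosin.** The myosin reporter mirrors the activity polarity with a
configurable rear fraction (default 0.45 of total signal in the rear third)
and follows polarity changes with a 6 s lag, emulating the slower myosin
redistribution relative to the activity response.

**Rendering.** Channels are `dark_offset + illumination × signal`, with the
ratio-bias map additionally multiplied into the acceptor channel; donor
signal is uniform (600 counts) inside the mask so the noise-free flat-field
acceptor/donor ratio reproduces the ground-truth activity exactly (the
machine-precision invertibility the round-trip tests rely on). Optional
Poisson shot noise acts on the illumination-scaled signal and Gaussian read
noise on the final counts; both are off by default. Rendering is
bit-reproducible for fixed (parameters, seed); per-cell seeds in cohorts are
hash-derived from (master seed, cell index) so cohorts are reproducible under
reordering or subsetting.

**What the generator does not emulate.** Optics beyond the pixel grid (no
PSF), photobleaching, cell-shape dynamics (constant length/width, no
elongation peak), background structure (flat zero background plus noise),
channel walls, and multi-cell fields. Passing tests therefore demonstrate the
correctness of the *analysis chain* under the stated forward model — mask
recovery, trace extraction, timing, classification logic — not robustness to
every artifact of real recordings.

**Fixture noise levels.** Trace-level cohort studies (event ordering,
classification) use additive Gaussian noise of 0.004 ratio units per sample
on the activity traces and 20% of the baseline speed on the velocity trace —
chosen so that the 1% detection thresholds sit ≈ 2.4 standard deviations
above the per-sample noise, the regime in which threshold detection is
meaningful at all. Image-level noise tests use a read-noise SD of 174 counts,
which puts the summed two-channel cell signal at SNR ≈ 5.

## Image corrections

Camera correction is `(raw − dark) / sensitivity`; negative results are kept
(noise can undershoot the dark level) so that downstream sums are unbiased.

The ratio-correction image removes the smooth field-dependent bias in
apparent FRET ratio. From a stack of cells tiling the sensor: per-pixel
median ratio over all cell pixels → median over 24 × 24 px blocks (partial
edge blocks use their available pixels) → Gaussian smoothing with σ = 5 in
block units → cubic-spline resize to the full field. Two numerical choices:
(1) smoothing acts on the *residual about a least-squares plane*, because any
finite-boundary Gaussian filter flattens a genuine large-scale linear trend
near the edges — the plane passes through untouched and only local
variability is smoothed; (2) the plane is evaluated analytically at full
resolution and only the smoothed residual is spline-upsampled, avoiding
constant extrapolation of the spline beyond the outermost block centers.
Building the correction on an already-corrected stack returns ≈ 1 everywhere
(idempotence, verified to 1%). The stage is optional in the pipeline
configuration; myosin imaging does not need it.

## Segmentation

Segmentation runs on the donor + acceptor sum. Background seeds are the
pixels below the 25% intensity quantile (cells occupy ≲ 15% of these fields,
so this quartile is conservatively background); the background image is the
local median of seed pixels in 64 px tiles, smoothly upsampled. After
subtraction, edges are enhanced by unsharp masking — the background-subtracted
image plus its difference from a σ = 5 Gaussian-smoothed copy — rather than
the difference image alone, which would zero the interior of a flat-topped
object and leave Otsu thresholding only an edge ring. The negative ring the
unsharp step leaves just outside the object is clipped to zero so Otsu splits
background vs cell. After thresholding: hole filling, a 200 px minimum size,
and selection of the largest object. A solidity gate (≥ 0.6) rejects the
ragged percolation clusters that thresholded pure noise produces (solidity
≈ 0.3–0.45) while confined cells score > 0.95; a frame failing these checks
is reported as "no cell" and skipped rather than failing the track.
Segmentation is invariant to common intensity rescaling of both channels.

Inter-camera registration is assumed done upstream; `align_channels` offers a
single rigid cross-correlation translation as a fallback for unaligned
inputs.

## Ratio and region quantification

The FRET ratio is acceptor/donor, undefined (NaN) outside the mask and where
the background-subtracted donor is ≤ 0. Undefined pixels are excluded from
all sums. (The two plausible orientations of the ratio only flip the sign
convention of "activity"; acceptor/donor is used consistently so that
stimulated-rear activity *rises*.)

Front and rear regions are the `region_size_px` (default 800, ≈ 35 µm²) mask
pixels nearest the front/rear edge. The edge is the set of mask pixels
extreme along the movement direction — the tip pixel of a rounded cell, the
whole end row of a flat-ended one — and distance ties are broken in (row,
col) order, making the region definition exactly reproducible (verified
against a brute-force distance-sort oracle). Event ordering is insensitive to
halving or quartering the region size. The middle region is the rectangle
over the central third of the axial extent intersected with the mask. Region
activity is the ratio of summed channels (not the mean of per-pixel ratios),
which weights pixels by brightness and is invariant to common rescaling;
myosin-mode region signal is normalized by the whole-cell sum, giving
fractions in [0, 1] comparable across expression levels. Regions are anchored
to the *pre-stimulus* front and rear throughout, so a reversal appears as the
rear trace overtaking the front trace.

## Kinematics

Raw speed is the centroid displacement between consecutive frames divided by
the frame interval. Smoothing is loess — tricube-weighted local regression
with a second-degree polynomial over a 10% span — implemented in-package
because available library smoothers are degree-1 only; a local quadratic
reproduces constants and linear trends exactly (to 1e−9), which the tests
pin. Relative length (mask major axis) and area are normalized to the
stimulation-onset frame. For stall detection the *signed* channel-axis
velocity is used (positive along the original direction), computed with
central differences so the velocity sample at frame k reflects motion at t_k;
a forward difference would bias the interpolated stall time late by half a
frame (+1.5 s at 3 s sampling, a visible error against a 27 s median).

## Event detection and classification

Event times are linear interpolations between the two samples bracketing a
crossing, exact on piecewise-linear traces: rear response at a 1% rise and
front response at a 1% fall relative to the t = 0 value, stall at the first
signed-velocity zero crossing, cross-point at the first front/rear trace
intersection. Two baseline conventions coexist deliberately: event detection
is anchored at the t = 0 sample, while classification compares against the
6-frame (15 s) pre-stimulus average — they answer different questions (onset
timing vs whether a response happened at all) and are kept separate.

Classification cascade: rear rise < 2% of the pre-stimulus baseline →
no response; rise ≥ 2% with min(front) − max(rear) > 0.03 → medium;
otherwise both edges are engaged and the final 15 s of the trace decide:
original direction → strong, flipped direction *and* flipped front/rear
ordering → reversed. The 15 s terminal window mirrors the baseline
convention. Persistent runs use the same conjunction (direction and activity
ordering both flipped) for the reverser call; a net post-stimulus
displacement below one cell length makes the terminal direction ambiguous and
conservatively yields non-reverser with a warning. For myosin-line data
without an activity reporter the same rules run on myosin polarity; under
ROCK inhibition a config flag (`speed_only_classification`) marks conditions
where only migratory speed is informative.

## Center-stimulation assay and responder fractions

Whole-cell activity is averaged in three fixed pre-stimulus windows
([−60,−42], [−39,−21], [−18,0] s) and a peak window centered on the activity
maximum within [3,33] s with a ±9 s half-width (matching the control window
width). Control response = mean(C2)/mean(C1); peak response =
mean(Peak)/mean(C3). Cohort-level estimates: since the control-response
distribution is symmetric about its median m, half of the truly
non-responding cells fall below m in peak response, so
`f_median = 1 − 2·P(peak < m)`; the stringent bound counts peak responses
above the control 95th percentile. Both thresholds are cohort-derived
quantities and are reported with the estimates. Note a known positive bias of
`f_median` on null data: the peak window is argmax-selected, which shifts the
null peak-response distribution slightly above the control distribution; the
stringent estimate does not share this bias (it is exactly the 5% tail by
construction), which is one reason it is the lower bound.

## Statistics

Rank-sum comparisons use the exact null distribution for combined n ≤ 25
without ties and the tie-corrected normal approximation otherwise (method
recorded on the result). Fisher's exact test: 2×2 hypergeometric; R×C by full
enumeration of the margin-fixed support (total count ≤ 200) summing
probabilities ≤ the observed table's, else seeded Monte-Carlo over
Patefield-sampled tables with the standard error reported. Binomial
proportions carry exact Clopper–Pearson intervals (beta quantiles). All exact
paths are tested against independent brute-force enumeration oracles. No
multiple-testing correction is applied; p-values are per-comparison.

## Profiles and kymographs

Per-frame 1D profiles along the channel axis are row-wise ratios of sums
(FRET) or row means (single channel), centered on the centroid and oriented
rear → front. Cell length varies, so profiles are resampled to a fixed length
(the cohort mean of per-cell mean major-axis length, rounded) with a cubic
smoothing spline using the p-convention in which p = 0 is the least-squares
line and p = 1 the interpolating spline (default p = 0.5); internally the
penalized spline with λ = (1−p)/p realizes the same objective, with p = 0 and
p = 1 special-cased. Kymographs average the resampled profiles over cells per
timepoint (NaN frames excluded, contributing counts recorded), rear at row 0.

## Degenerate inputs and tie-breaks

Frames with no acceptable object are skipped and logged; single-frame gaps
are bridged by the tracker, longer gaps split the track with a warning.
Regions smaller than the requested size saturate to the whole mask with a
warning. Zero movement direction falls back to the previous frame's
direction. Rear-target selection breaks angular ties by distance then (row,
col); region-distance ties are broken in (row, col) order using integer
squared distances, so results are exactly reproducible across platforms.

## Problem sizes

The packaged studies run at deliberately modest sizes chosen to exercise
every code path with tight statistical margins: 51-frame recordings
(63 s pre / 87 s post stimulus), 256 × 64 px channels, 75-cell field tiling
for the flat-field study, 100-cell trace-level cohorts for event ordering and
classification, 500-cell center-stimulation cohorts, and an 8-cell rendered
cohort for the image-level round trip. All are configurable upward.

## Known limitations

- The generator's kinetics are phenomenological piecewise-linear schedules,
  not a biochemical model; amplitudes and slopes are simulation choices, and
  only the event-time structure is anchored to observed cohort medians.
- Classification of myosin-line data approximates the original
  manually-curated medium/no-response split with the automated rules.
- The tracker assumes one cell per channel; crossing or dividing cells are
  out of scope (a split track is reported, not resolved).
- `f_median` inherits the argmax selection bias described above; treat it as
  the optimistic end of the responder-fraction bracket.
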