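# Methods

`wormcal` quantifies the intestinal Ca²⁺ oscillations that pace the
*C. elegans* defecation motor program (DMP) from paired
brightfield/fluorescence time-lapse recordings of freely moving animals,
and ships a synthetic recording generator with a full ground-truth channel
so every stage of the measurement chain can be validated without recorded
data. This note documents the models, the defaults and why they are what
they are, and the choices made where several designs were defensible.

## The measurement chain

**Segmentation.** The worm appears dark on a bright background in
transmitted-light brightfield. Each frame is thresholded with Otsu's
method computed over 256 equal-width histogram bins spanning the frame's
intensity range; the threshold is a bin *edge*, class means are computed
from exact per-bin intensity sums, and ties resolve to the lowest
candidate, which makes the operator reproducible bin-for-bin against an
exhaustive search. The foreground (below threshold for a dark object) is
reduced to its largest 8-connected component, then refined by a
morphological closing (dilation then erosion with 2 px disks), another
largest-component pass, and interior hole filling. The erosion treats
out-of-frame pixels as foreground, so the closing remains extensive and
idempotent even when the object touches the frame edge. A single
connected, hole-free mask is a precondition for skeletonization, which is
why the largest-component and fill steps exist at all.

**Bulk trace.** The bulk Ca²⁺ signal of a frame is the mean GCaMP
intensity inside the mask minus the mean outside it. Using the entire
mask complement as background makes the statistic invariant to global
additive offsets and equivariant under multiplicative gain — both are
asserted as tests. Frames whose segmentation fails (empty or full-frame
foreground) keep their slot in the trace via linear interpolation between
neighboring valid frames and are flagged invalid, so peak detection sees
an uninterrupted, honest-length series.

**Peak detection.** The trace is smoothed with a 1 s moving average and
local maxima are kept when their topographic prominence reaches 4× the
median absolute deviation of the first-differenced raw trace — a robust
noise scale that ignores however many waves the trace contains — and when
peaks are at least 10 s apart (the taller wins). The 10 s floor is half a
plausible shortest DMP cycle; the 4-MAD floor detects a 50 s rhythm of
physiological amplitude while producing zero false positives on
wave-free traces at the generator's default noise. All three parameters
are exposed in the pipeline configuration.

**Interval statistics.** Inter-wave intervals are successive peak-time
differences; the per-animal summary reports their mean, sample (n−1) SD,
and CV (SD/mean, defined only from three waves up). A recording is called
*oscillation-absent* only when no wave was detected **and** the recording
lasted at least 240 s — shorter observations cannot distinguish absence
from one long interval; with a regular ~50 s rhythm, 240 s of silence is
≥4 missed cycles.

**Midline and kymograph.** Each mask is thinned to a one-pixel skeleton.
The skeleton is treated as an 8-adjacency pixel graph and the midline is
the longest geodesic between degree-1 endpoints, found exactly by BFS
from every endpoint; side spurs fall away automatically. Because
topological thinning retracts the skeleton from the body tips by roughly
the local halfwidth, both ends are extended along the end tangent, in
1 px steps, until they leave the mask; this restores full axial coverage
(a 100 px rectangle yields a ~99 px centerline). The midline is
arc-length parameterized into 100 equal segments; fluorescence is sampled
by bilinear interpolation along the normal at each segment midpoint
(default span 1.5× the mask-derived halfwidth, so the perpendicular line
always crosses the full body), the per-segment maximum is taken, and the
100 maxima are linearly resampled to 200 axial positions. Rows over time
form the kymograph.

**Coiled frames.** A coiled posture has no single open midline. A frame
is flagged coiled when (a) the mask contains an interior hole (the body
encloses background), (b) the skeleton graph contains a cycle of ≥10
pixels — shorter 3–4 pixel cycles are artifacts of 8-adjacency at branch
points, not loops — or (c) the midline arc length falls below 0.6× the
recording-level median arc length (the "median" is computed over the
whole recording in a second pass, which is simpler and more stable than a
causal running median). Coiled rows are stored as missing values, never
interpolated.

**Orientation.** The pharynx expresses no GCaMP, so the anterior end of
the axial profile is the dimmer one. Per frame, the first and last 15% of
axial positions are compared after time-averaging over ±15 frames; the
profile is flipped so the anterior sits at column 0. Frames whose
relative end asymmetry is below 5% are marked orientation-unknown. A
majority vote then fixes a single head identity per contiguous run of
valid frames (midline point order is first made consistent from frame to
frame by endpoint matching), overriding and flagging isolated dissenting
frames. Per-run voting was chosen over per-frame correction because a
worm cannot reverse its own head mid-run; purely per-frame behavior is
recovered by shrinking the averaging window.

**Wave geometry.** For each bulk peak, a window from 10 s before to 5 s
after the peak is cut from the kymograph. Each axial column is smoothed
over 1 s in time: the per-segment maxima are extreme-value statistics of
the pixel noise, so their raw window maxima sit several units above
baseline even in silent columns, and without smoothing a weak (ectopic)
peak's response threshold would admit noise columns. A column *responds*
when its window maximum exceeds its baseline (10th percentile) plus half
the peak's prominence. Onset per responding column is the crossing of
baseline + 50% of the column's excursion *that leads into the column
maximum* (a backward search from the maximum) — taking the first
crossing anywhere in the window lets segmentation flicker at the pharynx
boundary pre-date the actual wave. The initiation site is the median
axial position of the earliest-onset columns within the contiguous
responding run around the strongest column (gap tolerance 2 columns);
propagation extent is the fraction of all 200 columns responding; an
event is *propagated* at extent ≥ 0.7 and *ectopic* when it initiates in
the medial third of the body without propagating.

**Group statistics.** Cohort tables join per-animal interval summaries
with wave-geometry counts. Group comparisons use Welch's two-sample
t-test (unequal variances) and the step-down Holm–Šídák adjustment,
adj p = 1 − (1 − p)^(m−k+1) for rank k of m with enforced monotonicity,
applied across the explicitly requested pairs — which pairs form the
correction family is the caller's decision. Animals with an undefined
metric are excluded per test and counted, never silently dropped.

## The synthetic generator

The generator emulates exactly the statistical structure the analysis
assumes, with a truth channel (per-frame midlines, wave schedule,
noiseless axial intensity, coiled-frame set) for parameter-recovery
testing.

*Posture* is a traveling sinusoid riding on a drifting, slowly rotating
chord, cut to a fixed arc length of 140 px and resampled uniformly;
drift reflects off a margin so the worm never leaves the frame. A coiled
frame (Bernoulli per frame) replaces the open curve with a circular arc
wrapping 1.25 turns, so the rendered body encloses a hole. *Calcium*
dynamics place waves at intervals drawn from a truncated (>5 s) normal
with configurable mean and SD; each wave starts at the posterior (axis
fraction 1) and sweeps the axis at 1 body length/s, with a 2 s linear
rise and 4 s exponential decay at each position and a spatial amplitude
decay of exp(−distance/2 body lengths). Ectopic events are a Poisson
process, uniformly positioned in [0.35, 0.65] and confined to ±0.05 of
the axis. The anterior 12% of the axis (pharynx) carries zero signal.
*Rendering* rasterizes the body as a tube of halfwidth 5 px (tapered over
the end 10%), paints brightfield a fixed 80 units below the 200-unit
background, paints fluorescence with the axial intensity at each pixel's
nearest midline position, adds zero-mean Gaussian noise (SD 5), clips at
zero, and quantizes to uint16.

Defaults follow the biology where it is known — 15 frames/s, 5-minute
recordings, ~50 s wave period, posterior-to-anterior propagation, medial
ectopic initiation, a GCaMP-free pharynx — and are invented round
numbers where it is not (frame 192×256 px, worm 140 px, drift 3 px/s,
undulation 10 px amplitude / 70 px wavelength / 0.4 Hz): no published
calibration ties this class of imaging setup to pixel units, and these values merely
need to exercise the geometry realistically. Everything is a pure
function of (config, seed); per-frame noise streams are derived from the
seed, so recordings are bit-reproducible.

What the generator does **not** model — photobleaching, illumination
drift, pharyngeal pumping, body-width individuality, lawn texture,
partial occlusions, multi-worm scenes, realistic coil kinematics (coils
appear as independent frames, not bouts) — bounds what green tests mean:
they certify the measurement chain on data that satisfies the analysis
assumptions, not robustness to every artifact of real microscopy.

## Numerical choices and degenerate inputs

- Otsu on a constant image is an error; a frame that fails segmentation
  is flagged invalid, and a recording where every frame fails is fatal.
- Sub-pixel sampling is bilinear everywhere (`map_coordinates`, order 1);
  samples outside the frame are NaN and excluded from maxima.
- The 100→200 axial resampling is linear with endpoints preserved
  exactly; a segment with no valid perpendicular sample is interpolated
  from its neighbors.
- Peak-time ties under the minimum-distance rule resolve to the higher
  peak (scipy `find_peaks` semantics, matching the stated rule).
- CV is NaN below three waves; SD is NaN below two intervals; absence is
  never asserted for recordings shorter than 240 s.
- Seeds below 2³¹ everywhere; per-animal cohort seeds derive from
  `SeedSequence([master, index])`.

## Problem sizes

Validation recordings are 300 s at 15 fps (4500 frame pairs, 192×256 px),
matching the acquisition protocol the analysis targets; cohort-level
checks use 10 regular animals (interval regularity) and 24 animals with
4 wave-free members (absence classification). Ectopic-geometry recovery
uses four 240 s recordings at 2.5 ectopic events/min with normal waves
disabled, giving ≥20 matchable events. Operator-level oracle tests run on
arrays of at most 32×32 pixels.

## Known limitations

- The anterior/posterior call depends on the pharynx dimness contrast; a
  recording with symmetric end brightness stays orientation-unknown and
  unflipped rather than guessed.
- Wave-geometry extent is inflated by a few percent by segmentation
  flicker columns; classification thresholds (0.7 extent, medial third)
  absorb this, but the extent value itself is an upper estimate.
- Interval SD from a 5-minute recording rests on ~5 intervals; its own
  sampling error is substantial, which is why cohort-level statistics
  compare distributions rather than single animals.
- Coiled frames are excluded, not recovered; a recording dominated by
  coiling yields a warning at >80% invalid rows and an error at 100%.
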