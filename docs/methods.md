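# Methods

This note documents the models, estimators, defaults and known limitations
behind beatkit's pipelines: what each stage assumes, which parameters
matter, and what the synthetic-data generator does and does not emulate.

## The synthetic beating heart

The generator renders a two-chambered contracting tube in ventral view —
atrium on the right (inflow), ventricle on the left, joined by a narrow AV
canal — with an S-curved centerline in the image plane. The geometry is
analytic:

* centerline: x spans a 200 µm tube; y = 15 µm · sin(2πs) for the
  normalized tube coordinate s ∈ [0, 1]; the AV canal sits at s = 0.5;
* resting radius: Gaussian chamber bumps over a canal baseline,
  r₀(s) = r_can + (r_atr − r_can)·exp(−((s−0.25)/0.16)²)
  + (r_ven − r_can)·exp(−((s−0.75)/0.16)²), with defaults
  r_atr = 25 µm, r_ven = 22 µm, r_can = 8 µm;
* contraction: r(s, t) = r₀(s) · [1 − a·(1 − cos(2πf·t − λs))/2], with
  beat frequency f (default 2.5 Hz), wall-motion amplitude a (default
  0.25, fraction of radius) and peristaltic lag λ (default 0.5 rad from
  inflow to outflow). Phase 0 is atrial diastole onset; the ground-truth
  diastole frame is the frame of maximal atrial radius.

**Brightfield mode** renders a bright lumen (170 intensity units) bounded
by a darker 4 µm wall band (50) on a mid-gray background (90), matching the
contrast polarity of brightfield blood imaging. Blood is dark speckle:
Gaussian spots (σ 1.5 px, depth 90) advected along the tube at the signed
arc speed the flow schedule prescribes for the current cycle phase;
particles wrap at the tube ends, so their number is conserved. The schedule
is an ordered list of phase intervals partitioning [0, 1) with a class
(anterograde / retrograde / no-flow) and a speed in µm/s; the ground-truth
class fractions are the interval widths. Gaussian noise (default σ 6) is
added last. Intensity levels and noise are free parameters of the
generator, chosen once as plausible for spinning-disc brightfield — they
are not claims about any particular instrument.

**Fluorescence mode** gives the tube an endocardial surface glow: at image
point with in-plane signed distance d from the centerline and plane depth
offset c from the local tube center, intensity is
bg + A(s)·exp(−(ρ − r(s,t))²/(2σ²)) with ρ = √(d² + c²) and σ = 2.5 µm,
i.e. a Gaussian shell around the tube surface. A(s) is elevated
`av_enrichment`-fold at the canal (Gaussian profile, width 0.06 in s). For
plane series the tube is tilted in depth (ventral inflow first) across an
8·r_atr ≈ 200 µm working depth so all 50 planes at 4 µm spacing intersect
it; each plane's movie starts at its own phase offset in frames (drawn
uniformly over one period in "random" mode), which is the quantity the
realignment stage must recover. Expression stacks are the same rendering at
a stopped heart (t = 0) with A(s) following an arbitrary per-segment
multiplier profile.

What the generator does **not** emulate: optics (PSF, scattering, depth
attenuation), deformable-wall mechanics beyond the radial cosine, actual
hemodynamics (particles move as plug flow at the scheduled speed), pigment
or yolk autofluorescence, photobleaching, and heart-rate variability.
Passing the recovery batteries therefore demonstrates correctness of the
estimators under known geometry and kinematics with realistic noise — not
robustness to every artifact of real larval imaging.

For gcamp-mode validation the peristaltic lag is set to 0: per-plane
realignment assumes all planes share one waveform timing, and a spatial
phase gradient would make the "true offset" of a plane ill-defined (each
plane sees a different part of the tube). This is a property of the
validation design, not of the estimator, which only requires a common
period.

## AV flow profiling

The readout is a kymograph: intensity sampled at evenly spaced arc
positions along the midline within ±20 µm of the AV point (spacing = half a
pixel width), averaged across a 3-pixel band normal to the midline, one
line per frame.

*Displacement.* For each consecutive line pair, the displacement is the
argmax over integer sample lags (±15 µm) of the Pearson correlation of the
overlapping parts, refined by parabolic interpolation of the peak and its
two neighbors; the peak correlation is the confidence. Two light low-pass
filters stabilize the sub-sample estimate: σ = 1 sample along the line and
σ = 0.75 frames along time. The temporal filter matters for slow flows:
without it, peak-locking pulls sub-sample displacements toward zero and
slow anterograde movement is misread as no-flow in noisy movies; with it,
schedule transitions smear by about one frame, a ~1% effect per cycle. A
3-frame median over the displacement series removes single-pair outliers.

*Classification.* A frame pair is no-flow when |d|·f < v₀ or when the
confidence falls below 0.3 (motion unmeasurable); otherwise the sign of d
decides the direction. The default threshold v₀ = 115 µm/s (~0.25 px/frame
at 240 fps) suits the ~300 µm/s flows of mid-larval hearts; in the
validation batteries, where speeds span 50–600 µm/s, the threshold is set
per movie to half the slowest scheduled speed (floor 25 µm/s) — a threshold
must sit below the slowest true flow to separate it from no-flow. The
no-flow fraction is non-decreasing in v₀ by construction.

*Cycles.* The atrial diameter is measured per frame on five parallel
chords centered on the mid-atrium segment (per-frame median across chords):
along each chord the dark wall band on each side is the intensity minimum
over the outer 60% of the half-chord — blood speckle cannot corrupt this
because it stays inside the lumen, and the chord is capped at 1.5× the
annotated radius so it cannot reach other parts of the curved tube. A
coarse period comes from the first prominent autocorrelation peak of the
detrended trace; it is refined by maximizing the periodogram on a fine
period grid (waveform harmonics do not bias the fundamental, so this
tolerates the plateaued traces that contraction produces). Cycle boundaries
are successive diastole peaks; percentages are computed over frame pairs
per cycle and averaged over the first three complete cycles (deterministic
choice; the per-cycle triples each sum to 100 exactly).

Orientation equivariance — reversing the annotation's inflow/outflow
orientation swaps the anterograde and retrograde percentages exactly —
holds because every geometric step (arc-length resampling, smoothing with
reflected ends, symmetric band sampling) is mirror-symmetric, so the
reversed kymograph is the mirrored original and the correlation argmax
negates; it is asserted at machine precision over a fixed cycle set, since
"the mid-atrium chord" itself switches chambers when the annotation flips.

## Midline segmentation

Within each chamber (wall sub-polylines split at the AV markers) both walls
are resampled to 256 points by normalized arc length; the midline point is
the midpoint of each pair, refined by two mid-distance projection steps
(each point moves to the midpoint of its nearest feet on the two walls).
The refinement matters where curvature makes the inner wall shorter than
the outer: pure arc-length pairing leaves up to ~5% equidistance error on
strongly curved atria, the projection brings it below ~3%. Chamber
midlines join at the AV point (midpoint of the two markers) and are
smoothed by a 5-point moving average with pinned endpoints.

The 100 segments are allocated to the chambers proportionally to their
midline arc lengths (rounding preserves the total), with equal spacing
within each chamber — uniform spatial resolution along the tube. Diameters
are wall-to-wall chords through segment centers normal to the midline
(nearest intersection per wall); a chord that misses a wall at an open
trace end yields a missing value, not an exception.

Segment intensity uses an exact arc-length partition of the wall-bounded
region: each pixel inside the two walls is assigned to the segment whose
arc interval contains its midline projection. For gentle curvature this
coincides with the band between adjacent normal chords, but the partition
remains unambiguous at the AV constriction, where chords can cross, and it
makes intensity conservation exact: segment means times pixel counts sum to
the total intensity of the region. A `rim_um` option restricts the region
to pixels within that distance of either wall (endocardium-adjacent rim)
for signals that live in the wall rather than the lumen; whether a given
stain should be profiled over band or rim is a user decision, not a fact
the package asserts.

Enrichment calls on a profile compare the maximal canal segment (arc within
12 µm of the chamber boundary) against interior baseline segments (beyond
twice that distance from the boundary and 15 µm from the heart ends): the
canal is enriched when its peak exceeds the baseline mean by three baseline
standard deviations. Baseline spread captures both noise and residual
geometry effects, so a flat profile stays flat under this test while a
1.5-fold enrichment is detected with a wide margin; profiles from several
replicates are aggregated per segment (mean, SEM with pairwise missing-value
exclusion) before testing, mirroring per-larva averaging.

## 4D calcium realignment

Per-plane traces are means over the top temporal-variance decile of pixels
rather than whole-image means: the plain mean dilutes the beating signal
with static background, and the activity-weighted trace multiplies the
modulation-to-noise ratio severalfold, which is what makes weak (deep or
tangent) planes alignable. The common period is the median over the ten
strongest planes of autocorrelation estimates refined on the periodogram;
planes deviating more than 10% (heart-rate drift) are flagged rather than
corrected — the model assumes a stable rhythm over the acquisition.

Each trace is folded to the period (100 phase bins, circular smoothing
σ = 2 bins) and registered by circular cross-correlation: first propagating
outward from the reference plane (maximal variance) against the running
average of already-aligned profiles — adjacent planes share waveform shape,
distant planes may not — then two refinement passes against the grand
aligned average. Planes whose peak correlation stays below 0.2 are flagged
unalignable and excluded from assembly. Offsets are reported in frames
modulo the period, with the convention that plane p lags the reference by
offset[p]; realignment circularly shifts each plane by −round(offset) (no
temporal interpolation: the projection is robust to sub-frame error and
interpolation would alter intensities). The maximum z-projection then
dominates every aligned plane pixelwise by construction.

Diastole and systole frames are read from the atrial diameter of the
projection (bright interior against dim background, so the diameter is the
span of above-half-intensity samples on the mid-atrium chords), folded over
the beat period so that all cycles contribute; the selected frames are the
nearest integer frames to the folded extremes within the first period.
Calcium profiles delegate to the midline profiler on the chosen projection
frame and add a whole-heart-normalized column, the scale-free form in which
AV-canal enrichment is compared across animals.

## Valve morphometry

Leaflet length is the polyline arc length of the per-plane superior-leaflet
trace times the pixel width; the per-animal statistic is the maximum over
planes. The binary elongation call uses a recorded length threshold
(default 10 µm) because published calls of this kind are visual judgments
with no printed criterion; every output carries the threshold used, and
calls are invariant under pixel/µm unit round-trips. Contingency tables for
two groups feed the Fisher test.

Cell counting deduplicates per-plane nucleus detections by greedy
nearest-neighbor chaining: walking planes in order, a detection extends the
nearest open chain within 3 µm in xy and at most one plane below, else
starts a new chain. Greedy chaining equals connected-component counting
whenever distinct cells are separated by more than twice the link radius —
the regime sparse valve nuclei are in, and the regime the planted-nucleus
generator enforces (pairwise separation ≥ 2.5× link radius), which is what
the brute-force oracle test certifies. An undeduplicated per-plane sum is
available since some published counts may not have deduplicated across
planes.

## Statistics

The two-sided Fisher exact test sums hypergeometric probability masses of
all margin-consistent tables at most as probable as the observed one — the
convention of standard statistical software, as opposed to doubling the
one-sided tail. The implementation works in exact integer arithmetic
(binomial coefficients), so tie comparisons are exact and the result
matches a rational-arithmetic enumeration oracle to 0 for every table with
total ≤ 30. Odds ratio is ad/bc (infinite when bc = 0 with ad > 0); a zero
margin returns p = 1, flagged degenerate.

Student's t is equal-variance by default ("Student's t-test" taken at its
word), with Welch as an option; p comes from the t distribution. ΔΔCt fold
changes average technical replicates per (biological replicate, gene)
first, subtract the reference gene per replicate, center on the control
mean ΔCt, and report per-replicate folds with mean and n−1 standard
deviation; adding a constant to every Ct of one sample (reference included)
leaves folds unchanged. Group summaries use n−1 standard deviations,
SEM = sd/√n, and Tukey inclusive-median quartiles (the median participates
in both halves), matching box-and-whisker plotting of small per-animal
samples. No multiple-testing correction is applied: comparisons are
reported per condition against the control, and the caller owns any
family-wise correction.

## Validation batteries and problem sizes

`beatkit.validation` packages the recovery experiments: 20 brightfield
movies spanning the schedule/speed/noise ranges at ~6.5 beats each (so at
least three complete cycles plus period-estimation margin at every beat
frequency), 10 simulated hearts for midline geometry, expression stacks at
1×/1.5×/2× enrichment with 4 replicates, and ten 50-plane calcium series
with noise up to 15%. Movies are 128×160 px at 1.92 µm/px — the full heart
plus margin at the paper-scale pixel size — keeping a complete battery run
in the low minutes on one CPU. `tests/test_acceptance.py` asserts the
recovery tolerances (fractions within 5 points in ≥18/20 movies, heart rate
within 2%, equidistance and diameters within 5%, enrichment ratios within
10%, ≥48/50 planes within one frame, exact statistics oracles);
`scripts/acceptance.py` reports the same quantities as JSON.

## Known limitations

* Wall traces are inputs; no automatic segmentation of heart walls from
  pixels is attempted, matching how such traces are produced in practice.
* The displacement estimator reads net motion along the midline at the
  canal; it is not a velocimeter (no absolute flow volumes, no regurgitant
  fractions).
* Realignment assumes one rhythm across planes; arrhythmic hearts are
  flagged, not warped.
* The diameter-trace wall detector assumes the wall band is the darkest
  persistent structure in the outer half-chord (brightfield) or a filled
  bright interior (fluorescence projections); exotic contrast settings may
  need the chord parameters adjusted.
* Greedy cell linking is only certified equal to connected components for
  well-separated nuclei; densely packed nuclei closer than the link radius
  would need global matching.
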