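# Model and methods

## The problem

A vernier target (two nearly collinear vertical lines, the lower one offset
left or right by a few arcseconds) is hard to judge when flanking elements
surround it — crowding. When the flankers form coherent objects (rectangles,
perspective cubes) and there is enough processing time, they perceptually
group away from the target and performance recovers — uncrowding. This
package implements a desk-scale recurrent-segmentation model of these
dynamics together with the psychophysical machinery (adaptive staircase,
psychometric fitting) used to measure them, and a synthetic-stimulus module
that builds the exact displays of four experiments: duration manipulations
(20 vs 160 ms), flanker previews and postviews across a 120-ms gap, preview
gaps from 20 ms to 2 s, and intermediate frames inserted between a preview
and the flanked target.

## Stimuli

All stimuli are white line drawings specified in arcmin in a
stimulus-centered frame (x rightward, y upward). The vernier is two vertical
40′ lines separated by a 4′ gap (total height 84′); the signed offset (in
arcsec) is applied to the bottom line. Flanker configurations nest: Lines
(two 84′ verticals at ±23′), Rectangles (add a 117′-wide outline),
Cubes (add three 45°, 53′ obliques per side plus back-face edges forming a
perspective cube). Experiment 4 adds Triangles (84′ inner side, 124.3′
obliques whose apex lands at the cube's far front edge, ≈±140′), a single
central 46′×84′ rectangle, and Scrambled Cubes.

The scramble repositions each cube stroke (length and orientation
preserved) uniformly inside the cube's bounding box, subject to: at least
35′ from the midline (clear of the target and the template-readout zone),
5′ clearance between strokes, and 6′ clearance from the outer (|x|≥58′)
front-face outline and from 26′ stubs of the obliques at the front corners.
The last two rules implement the defining property of this stimulus — the
strokes are disconnected from one another and from where the cube's
boundary was drawn — and are what makes the scramble interrupt, rather than
relay, the preview signal in the model. Long strokes necessarily cross the
inner portions of the outline rows; those crossings lie beyond the reach of
the selection process (see below).

Frames are rasterized onto a 401×201-px canvas (0.5 px/arcmin, x∈±200′,
y∈±100′) into four binary orientation channels (vertical, horizontal, and
the two diagonals; arbitrary angles bin to the nearest channel). Strokes are
drawn by integer-pixel marching along the major axis with round-half-even
for the minor coordinate (which commutes with mirroring), half-open at the
end farther from the stimulus centre, so a stroke of L arcmin occupies
round(L·px_per_arcmin) pixels.

## Contour dynamics

Each of two segmentation layers holds per-pixel, per-channel activity in
[0,1]. Layer 0 receives bottom-up drive (gain 1, hard-saturated); both
layers leak with τ_contour = 180 ms per 20-ms step. This time constant is
the simplification of the spiking substrate of the full model: it keeps a
contour above half strength through a 120-ms blank but below 4% after
600 ms, which carries both the preview persistence and the long-gap failure.

## Selection and segmentation

One circular top-down selection signal per flanker side sits at a fixed,
configuration-specific location: on the flanking line for Lines (radius
45′, covering the line and the vernier zone), on the outer front edge
(±140′, radius 30′) for the larger configurations. Placement is jittered
(Gaussian, σ = 8′, truncated at 1.5σ — the signal aims at a known location
and gross mislocations do not occur). Trial-to-trial variability in the
model comes solely from this jitter and from the scramble; there is no
neural noise.

Every step the signal marks living contours (activity > 0.45) inside its
disk with mask value 1. From previously marked pixels the mask grows by
8-connected breadth-first rings over living contours (activity > 0.5), with
a two-tier budget per 20-ms step:

* a fast sweep, up to 40 px, that advances only across strongly driven
  contours (pixels the current stimulus draws, or traces still at ceiling)
  and launches only from selected pixels on or adjacent to such contours;
* a slow crawl, 7 px, across any living contour.

Selection therefore races over an object while it is on screen, crawls
along its decaying trace during a blank, and stops when the trace fades.
The mask itself decays with τ_selection = 100 ms; a pixel stops recruiting
neighbours about 50 ms after it was last reached, and a selection built
during a preview is lost after gaps of a few hundred milliseconds — this
decay is what bounds the preview benefit at interstimulus intervals of
260 ms and beyond.

Selected Layer-0 activity transfers to Layer 1 at the same pixel locations
(rate 0.9·mask per step, capped so Layer 1 stays within [0,1]); the
per-pixel two-layer sum is exactly conserved at the instant of transfer.
Bottom-up input at locations whose mask exceeds 0.25 is routed into
Layer 1: a re-presented object joins its shifted representation instead of
refilling Layer 0. If a seed disk covers the target location, the vernier
is co-selected and transferred along with the flankers — segmentation then
does not help, which is why the Lines configurations stay crowded at every
duration and after previews.

## Evidence readout

Left and right templates are the vernier rasterized at ∓4′ (vertical
channel), extended 15 px toward their own side, so each also covers the
flanking line on its side. Template scores S_L, S_R sum Layer-0
vertical-channel activity under the masks; the per-step contrast is
C = (S_R − S_L)/(100 + S_R + S_L) and model evidence sums C over 20–100 ms
after vernier onset (five steps, endpoints inclusive; the denominator
constant 100 is part of the model definition and not exposed as a
parameter). Flankers remaining in Layer 0 inflate the denominator
symmetrically and shrink |C| (crowding); moving them to Layer 1 restores
|C| (uncrowding); a faded target shrinks |C| through the numerator (the
postview account). Model trials always use a right offset of 4′ (2 px);
readout is always from Layer 0.

## Experiments and the pattern suite

`run_experiment` covers the full condition inventories (Experiment 1: three
flanker types × {20, 160} ms plus an unflanked 20-ms reference; 2:
{Lines, Cubes} × {baseline, preview, postview}; 3: Cubes previews at gaps
of 20–2,000 ms plus baseline; 4: six intermediate frames plus baseline),
100 trials per condition by default. All conditions of an experiment share
one seed-derived random stream (common random numbers), so between-condition
comparisons are free of placement variance. The qualitative predictions are
encoded as z-tests on mean evidence in pooled-SE units ("greater": z ≥ 3,
"approximately equal": |z| < 2, at n = 100 with a fixed seed): uniform
crowding at 20 ms; release for Cubes/Rectangles but not Lines at 160 ms;
preview (not postview) release for Cubes only; preview benefit at gaps of
20 and 120 ms but none at 260 ms and beyond; intermediate Cubes,
Rectangles and Triangles propagate the preview while Lines and Scrambled
Cubes interrupt it, with the Central-Rectangle at or below Lines. All 24
assertions pass under the shipped defaults across several master seeds.

## Psychophysics

The staircase follows the classical sequential-testing rules: a Wald test
at 75% correct (deviation limit 1) decides level changes; the step (400″
initially) halves on reversals, repeats once in the same direction, then
doubles, with the usual post-reversal exception; offsets start at 800″ and
are clipped to (5″, 1,600″]. Offset directions are random with runs capped
at four. Blocks are 80 trials; two blocks (160 trials) per condition.
Thresholds come from a post-hoc binomial maximum-likelihood fit of
P(correct|δ) = 0.5 + (0.5 − λ/2)·Φ((ln δ − μ)/σ) with lapse λ = 0.02 fixed,
threshold at P = 0.75, censored at 1,600″ when the fit is degenerate.
Recovery simulations (160 trials, 200 replicates, σ_log ∈ [0.1, 0.4]) show
median bias below 5% and SD below 20% of the true threshold.

A simulated observer links the model to behaviour through
μ_log = α − β·E (α = ln 900, β = 3, σ_log = 0.25 by default): larger
condition evidence means a lower psychometric location, hence a lower
fitted threshold. The link is a monotone convention — the model itself
predicts only orderings, and only the orderings are asserted.

## Numerical choices and degenerate inputs

Rounding is half-to-even throughout rasterization so mirror-image stimuli
produce mirror-image rasters (with the two diagonal channels swapped).
Transfer is capped by Layer-1 headroom; routed drive is added after
transfer within a step so the cap never deadlocks draining. A seed disk
that intersects no contour selects nothing for the entire trial (Layer 1
stays identically zero). Offsets beyond the 1,600″ staircase cap, unknown
configuration names, scrambles without a seed, sub-pixel reference offsets,
and shape mismatches all raise immediately.

## What the generator does and does not emulate

The synthetic stimuli reproduce the printed display geometry and frame
timing exactly, on an idealized canvas: no luminance calibration,
anti-aliasing, display persistence, fixation dot, or eccentricity-dependent
cortical magnification (the 9° eccentricity is metadata). Simulated
observers respond by a stationary psychometric function — no learning,
lapses beyond the fixed rate, or serial dependence. Passing tests therefore
show that the mechanism reproduces the qualitative phenomenon under its own
stated conditions, not that it fits any individual's data.

## Known limitations

* The evidence differences between conditions are small relative to the
  denominator constant, so condition effects are z-robust but the absolute
  evidence scale is not meaningful.
* Under the shipped scramble rules the Scrambled-Cubes intermediate
  interrupts the preview in every trial; the occasional single-trial
  preview effect that a looser scatter would produce does not occur.
* The Central-Rectangle intermediate behaves exactly like the Lines
  intermediate because templates read the vertical channel only; its
  horizontal strokes produce no extra interference, so it sits at (not
  below) the Lines level, satisfying the ordering only weakly.
* Segmentation of a 160-ms flanked display completes near the end of the
  20–100-ms readout window, so part of the duration benefit in
  Experiment 1 reflects contour persistence rather than completed
  segmentation.
* Spreading operates on rasterized contours with no grouping connections
  between separate elements; stimuli whose grouping depends on good
  continuation across gaps would not group here.
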