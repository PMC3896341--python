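# Methods

This note documents the models, parameter choices and numerical
conventions behind `beetrack`, in the order the pipeline runs.

## Coordinate and data conventions

Pixel coordinates are `x` = column, `y` = row, 0-based, origin at the
top-left corner; centroids are real-valued. All modules share this
convention. Frames are 8-bit grayscale; color input is converted by
Rec. 601 luminance weighting. The canonical movie interchange format is a
directory of numbered PNG stills; video containers are read through
imageio when a suitable plugin is available.

## Segmentation

The background model is the per-pixel maximum over all frames. It assumes
stable lighting and animals darker than a static arena; it needs every
pixel to be animal-free in at least one frame, so an animal that never
moves for the *entire* movie is absorbed (a deliberate property shared
with the underlying method — there is no adaptive update, which is what
lets long-resting bees stay foreground). A pre-recorded empty-arena image
can be supplied and is used verbatim.

Foreground is `background − frame ≥ threshold` with the difference
clamped at zero, so pixels brighter than the background can never be
foreground (the clamped-difference dialect; an absolute-difference
variant would also mark brightenings). The default threshold is 43 gray
levels; on the reference footage accuracy is flat for thresholds roughly
38–53, and `threshold_sweep` reproduces such robustness curves on
synthetic movies. Components are 8-connected by default because thin bee
bodies frequently touch diagonally; a one-pixel binary opening is
available but off by default. Regions touching the frame border are kept
(the arena wall lies inside the frame).

## Size calibration

All region areas from the first `calib_frames` frames (default 500 =
20 s at 25 fps) are pooled. The modal area is the most frequent value
inside the fullest histogram bin (bin width 2 px²; using the in-bin mode
rather than the bin center keeps the modal area an attainable value, so
`min ≤ mode ≤ max` holds even for degenerate samples). Areas outside
[0.5, 1.5] × mode are discarded before taking the closed interval
[min, max] as the RSS: merged two-bee blobs sit near 2× the mode and
specks near zero, so both are rejected even when bees already touch
during calibration. The body length is the mean major axis (from second
moments) of the retained regions. The interval may be widened by a
relative margin (`rss_margin`, default 0); this exists because a bee's
rasterized area depends on its body orientation, and a calibration
window in which bodies hold few orientations under-samples that
variation. The two/three-agent scripted fixtures are exactly such a
case (each agent keeps one heading for the whole approach), so the test
suite tracks them with a 10 % margin; full arena movies sample all
orientations within the calibration window and use the default 0.

If the movie is shorter than the calibration window, all frames are used
and a warning is issued. A movie with no foreground at all yields an
empty track set rather than an error.

## Identity assignment

Size classes (SBS/PBS/NBS) use the closed RSS interval. Overlap classes
(NBR/OBR/TBR) count the previous frame's *resolved masks* intersecting
the region; dormant tracks do not participate. Because the per-region
rules can let two current regions both claim the same previous identity
(e.g. at the frame where a merged pair separates), claims are resolved
globally first: each previous ID goes to the current region with the
largest pixel overlap (ties to the earlier region in scan order). Regions
are processed in centroid scan order, which makes the tracker invariant
to the labeling of connected components. New IDs come from an increasing
counter and are never reused.

Position prediction is the two-point constant-velocity extrapolation
`p̂(t) = 2 p(t−1) − p(t−2)` (or the last position for one-record tracks).

**Fused single-size blobs (SBS ∧ TBR).** The blob cannot support one full
mask per bee, so each claimant keeps its identity at its predicted
position projected to the nearest blob pixel. For bookkeeping the blob's
pixels are partitioned by nearest projected point (coincident points are
nudged half a pixel along each claimant's velocity, so two bees passing
exactly through each other keep separate, momentum-consistent masks).

**Merged plural-size blobs (PBS ∧ TBR).** Regional matching places each
claimant's previous mask rigidly into the region, searching integer
translations within one body length of the predicted position and a
small set of body rotations (0°, ±10°, ±20° — a walking bee rotates its
axis at most ~20° per frame, and matching the rotated body where it
stands must be able to beat sliding the unrotated mask onto a similarly
aligned neighbour). The objective is *distance-regularized overlap*,
`pixel overlap − 2 × distance from the predicted position`: with pure
overlap, two similar adjacent bodies are nearly interchangeable and
rasterization noise decides, whereas the prediction is precisely the
information that delineates identities; the penalty of 2 overlap-pixels
per pixel of distance means a placement a body length away must be
clearly better supported, while genuine accelerations of a few pixels
cost almost nothing. Ties break toward the prediction, then
lexicographically; between rotations the smaller |angle| wins ties.
Pixels covered by one placed mask belong to that claimant; contested
pixels go to the claimant with the nearest placed center (velocity-nudged
on ties); leftover region pixels attach to the mask owning the nearest
claimed pixel. The recorded position during a merge is the center of the
best-placed translated mask, *not* the centroid of the claimed pixels:
the claimed-pixel centroid is biased by whatever the contest removed,
and feeding that bias into the velocity estimate makes predictions
collapse during long merges. The same procedure generalizes unchanged to
three or more claimants. A claimant with zero achievable overlap is
reported unmatched and goes dormant.

Dormant tracks are frozen at their last centroid and excluded from
overlap tests; a bee that reappears gets a fresh ID. `stitch_tracks`
(off by default) can afterwards join a track ending at frame *t* to one
starting within `max_gap` frames and one body length.

## Trajectories and kinematics

Speed is `|p(t) − p(t−1)| · fps`, acceleration the discrete difference of
speed times fps, heading the direction of the displacement into frame
*t*. Values requiring more history than a record has are missing (NaN;
empty CSV fields), never zero — a zero would fake resting. Dormant frames
emit no rows. The CSV schema is
`frame,id,x,y,area,speed,heading` with six-decimal floats; re-import is
lossless at that precision.

## Interaction events

An encounter episode is a maximal run of frames with pairwise centroid
distance below one body length (default the calibrated value; 15 px at
the reference scale). Pair episodes sharing a bee with overlapping frame
spans are merged into one multi-participant episode; its contact time T1
is the first contact frame. Classification parameters (not dictated by
the underlying taxonomy; defaults chosen to separate the category
prototypes cleanly and exposed in config): direction-change angle
θ = 45°, same-direction cone φ = 90°, stop speed 0.1 body lengths/s,
heading window W = 12 frames. Pre/post headings are directions of the
net displacement over W frames before/after the episode (undefined below
half a pixel of net motion). "Merged" is inferred from centroid distance
dropping below half a body length — a geometric proxy chosen so the
classifier behaves identically on tracked tables and on ground-truth
tables, which have no pixel masks. Precedence when rules co-fire, most
specific evidence first: multiple > waiting > overlapping >
touching/passing > crossing; crossing is the fallback (it also absorbs
the taxonomically unnamed case where exactly one bee deflects without
stopping). Waiting requires exactly one participant stopped for ≥ 90 %
of the frames after T1.

## Evaluation metrics

Association is declared, not inferred from any external convention: per
frame, computed points are greedily matched to the nearest true point
within a radius (default one body length; ties to the lower truth ID,
one match per point per frame), and each computed track is assigned to
the truth track it matches in the majority of its matched frames, so a
computed track counts toward exactly one truth track. TFF(g) is the
number of assigned computed tracks (undefined and excluded, with a
warning, for uncovered truth tracks); TCF(g) is covered frames over
total frames, zero if uncovered. Means are reported at two decimals and
percentages at one decimal — the conventional printed precision for
these scores. Identity swaps are counted per computed track by comparing
the majority truth ID over the first and last quarter of its matched
frames, using all per-frame matches (pre-majority), so brief
cross-matches inside a contact do not register but a genuine exchange
does. An event is "preserved" if every participant keeps a single,
identical computed track across a guard window before and after the
episode; category false rates are failures over occurrences × 100.

## The synthetic arena

The simulator emulates the reference recording geometry — 600×600-pixel
frames, 25 fps, 1500 frames (one minute), sixteen dark elliptical agents
(major × minor body axes 15 × 9 px) on a brighter circular arena disc
(bee gray 60, arena 200, surround 140, additive Gaussian pixel noise
σ = 3) — with swarm-rule motion: straight walking at 2 px/frame with 6°
per-frame heading noise, specular wall reflection with ±30° jitter
(which yields wall-following paths), a stop-and-wait of 12–75 frames
when within one body length of another agent followed by a turn away
(±60° jitter), and spontaneous rests of 25–250 frames with per-frame
probability 0.002. The agent count and kinematics of the original
artificial-agent footage are not published, so these are the package's
own choices of plausible walking-bee values at the reference pixel
scale. Waiting durations are drawn uniformly rather than
stimulus-dependently: the swarm algorithm serves here only as a
generator of plausible arena motion, not as an aggregation model.

Three physical details matter for benchmark honesty. Bodies turn at most
20° per frame, executing large course changes (wall turns, post-wait
turns) in place over several frames — instantaneous axis flips are not
something a walking bee can do. Bodies are solid: a move that would take
an agent's center within 0.6 body lengths of another's is blocked, so
partial climbing overlap can occur but near-total coincidence (two bees
occupying the same pixels for hundreds of frames) cannot; identity
through such coincidence is unrecoverable from silhouette video for any
method. A 24-frame post-wait refractory suppresses re-triggering of the
contact wait so pairs actually separate. Rendering is hard ellipse fill
with no antialiasing, so segmentation ground truth is exact; noise is
added afterwards.

What the simulator does **not** emulate: photorealistic appearance,
legs/wings/antennae and body flexion (real bees bend along the arena
wall — the known failure mode of the linear-motion assumption), shadows
and lighting gradients, camera distortion, and bee-sized debris. Passing
tests on these movies therefore demonstrates the identity logic under
controlled merge/split/rest/wait conditions at realistic geometry and
noise, not performance on laboratory footage.

Scripted scenarios construct each interaction category analytically
(piecewise-linear paths meeting at a scripted T1 on a 260×260 arena),
with contact distances chosen so that *crossing/touching/passing* touch
without body fusion (minimum separation ≈ 11–12 px), *overlapping* passes
through coincidence, *waiting* freezes one agent from first contact
until the other is a body length away, and *multiple* routes two movers
past a resting third with overlapping contact spans. The resting agent
walks in before resting so the background model sees its spot uncovered.

## Problem sizes used in validation

The test suite and the acceptance script run entirely on generated
inputs: unit fixtures use 50–250-frame movies of 2–8 agents at
140–400 px, and the end-to-end benchmark uses the full-scale
16-agent, 600×600 px, 1500-frame movie. The self-comparison check uses a
6-agent, 200-frame ground-truth set evaluated against itself.

## Known limitations

- Identity maintenance relies on linear motion and rigid-mask matching;
  strong body flexion combined with contact (wall-following pairs) is the
  expected failure mode, consistent with the method's provenance.
- The RSS is global and static: per-individual size models and online
  recalibration are out of scope, so a movie whose animals change
  apparent size (e.g. climbing onto one another at steep angles) will
  misclassify sizes.
- Encounter detection is distance-only; "facing" is not operationalized.
- Event classification thresholds (θ, φ, stop speed, W) separate the
  scripted prototypes cleanly but have not been validated against
  human-annotated laboratory footage, which is not distributed.
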