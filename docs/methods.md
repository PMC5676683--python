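# Methods

This note documents the models, parameters and numerical choices behind
`toxid`, and what the synthetic-scene tests do and do not demonstrate.

## Detection model

Frames are 8-bit grayscale; animals are assumed darker than a roughly
constant bright background (a config flag inverts the polarity). Foreground
pixels are those below a user threshold; connected components use
**8-connectivity**, which keeps thin diagonal bodies (tails, antennae) in
one piece, and are filtered to a size window `[min_size, max_size]` to drop
noise specks while still admitting the enlarged blobs formed when two
animals merge during an occlusion. Components are reported in row-major
order of their first pixel so the pipeline is order-deterministic.

Coordinates are 0-based with `x` = column and `y` = row; the centre of mass
is the unweighted mean of pixel centres.

Per blob the pipeline records the pixel count, the histogram of the
**contrast-normalised** enclosing rectangle (min → 0, max → 255; a constant
rectangle maps to all zeros), and the seven Hu moment invariants of the
normalised intensities with background pixels zeroed, so arena texture
cannot leak into the shape descriptor. Two intentional edge rules:

* a normalised value of exactly 255 is counted in the top histogram bin —
  with purely half-open bins the brightest pixel (always present after
  normalisation) would vanish, breaking mass conservation;
* a blob that fills its own bounding box with uniform intensity normalises
  to all zeros and has no intensity moments; `extract_detection` then falls
  back to silhouette (binary) moments, which still encode the shape.
  `hu_moments` itself raises on the degenerate input so callers that need
  intensity moments notice.

The histogram covers the whole rectangle (body + background margin) rather
than the body pixels only: the ratio of body to background mass encodes the
body's contrast structure and empirically discriminates better; a config
flag (`mask_histogram`) switches to body-only histograms. The default bin
count is `kn = 32` — fine enough to separate textures, coarse enough that
per-bin counts are stable for bodies of a few hundred pixels.

## Fragment tracking

The motion model is a constant-velocity Kalman filter with state
`(x, y, vx, vy)` (pixels, pixels/frame), position-only measurements, process
noise 1e-2 and measurement noise 1.0 (pixel² scale) — loose enough to follow
turning animals, tight enough to smooth segmentation jitter. The filter is
initialised at the first detection with zero velocity and a diffuse velocity
covariance, so the second detection effectively fixes the velocity; a
fragment with a single sample predicts its own position.

Per frame, predictions and detections are matched by
`scipy.optimize.linear_sum_assignment` on the Euclidean distance matrix,
padded square with a large sentinel so unequal counts are handled; the gates
are applied *after* the global assignment. Fragments are closed
(never reopened) when:

* the matched distance exceeds `cost_limit`,
* the symmetric relative size change exceeds `size_change_limit` (default 1.0),
* they go unmatched for more than `max_missed_frames` frames (default 10), or
* **occlusion**: at least two fragments predict within `proximity_limit` of
  the same detection *and* that detection is the nearest one for each of
  them. Both fragments are closed and the ambiguous detection seeds a fresh
  fragment. The nearest-detection condition matters: without it the rule
  already fires while two clearly separate detections exist a body-length
  apart, several frames before the blobs actually merge, and once per nearby
  detection instead of once per occlusion.

`cost_limit` and `proximity_limit` default to 4× and 1.5× the median blob
diameter estimate `2·sqrt(S/π)`, measured from the first frame containing
detections and then frozen — an online, deterministic calibration that
adapts the gates to the animal size without manual tuning. A gated pair is
rejected without re-running the assignment; the detection seeds a new
fragment, so every detection belongs to exactly one fragment.

Processing is strictly online (frame *k* uses only frames ≤ *k*), which the
tests verify by comparing streamed against batched input byte for byte.

## Identity linking

The appearance similarity of two fragments is the maximum Pearson
correlation between their sample histograms times a Gaussian-weighted
distribution of all pair correlations over `Ln = 10` levels on [0, 1). The
Gaussian weight is the **unnormalised** kernel `exp(−(m_L − μ)²/(2σ²))`
(μ = 1, σ = 0.05) at the level midpoint: with a probability-density
normalisation the similarity scale would change with σ, while the kernel
form keeps `Sim ≤ A ≤ 1` and still concentrates essentially all weight on
correlations above ≈ 0.9. A correlation of exactly 1 is placed in the top
level; negative correlations fall in no level but stay in the denominator,
so dissimilar pairs dilute the score. A negative amplitude clamps the whole
similarity to 0.

Sample-pair filters: pairs whose symmetric size change exceeds 0.5 are
skipped. A shape filter on `ShapeDiff = Σ |1/Hu^h − 1/Hu^h|` is implemented
(with reciprocals guarded by `hu_epsilon = 1e-8`) but **disabled by
default** (`shape_diff_limit = inf`): Hu invariants 3–7 of real blobs have
magnitudes around 1e-4…1e-12 with noise-driven sign flips, so reciprocal
differences between samples of even the *same* animal span many orders of
magnitude and any fixed finite threshold behaves like a coin flip. Skipped
pairs still count in the denominator. Fragment pairs whose cross product
exceeds `max_pairs = 10,000` are subsampled without replacement, seeded by
the run seed and the (sorted) fragment-id pair so the similarity stays
symmetric and reproducible.

The identity likelihood `Id[R, C]` is the Pearson correlation of the two
fragments' similarity profiles over all *other* fragments (the self-columns
R and C are excluded — their 1.0 entries would inflate every correlation),
clamped to [0, 1]; coexisting fragments (inclusive frame intervals overlap;
mere abutment does not count) are hard zeros and the diagonal is 1. With
fewer than two remaining profile entries the correlation is undefined and
the entry falls back to the raw similarity normalised by the matrix maximum.

Assignment proceeds exactly as the similarity design intends: fragments
with ≥ 50 samples are *long*, those with 25–49 *short*, those under 25
discarded. Complete groups — sets of exactly `n_animals` long fragments
simultaneously alive at some frame — are found by a sweep over interval
endpoints; the earliest group anchors identities 1..n in start-frame order,
and each later group is matched to the labelled set by Hungarian
maximisation of the identity likelihoods (forbidden = coexistence
violations; all-zero rows stay unassigned). Remaining fragments join
greedily, largest likelihood first, long pool before short pool, stopping
below `min_correlation = 0.5`; ties break by earlier start frame, then lower
fragment id. Each new label propagates two hard constraints into the working
matrix: the labelled fragment's entries towards fragments that coexist with
its identity are zeroed, as are its entries towards fragments of other
identities. If no complete group exists, the anchors are the longest
pairwise non-coexisting fragments (logged as a warning) — an explicit
extension for sparse videos.

## Evaluation protocol

Each identity label's *reference animal* is the majority ground-truth animal
of the first-starting fragment carrying that label; a later fragment with
the same label is correct only if its own majority animal equals that
reference, so one early swap counts every subsequent fragment of both
identities as incorrect (error propagation). Fragment truth uses the
majority sample label to tolerate occasional mismatches during partial
occlusions. Detections are matched to truth centres by nearest neighbour
within `match_radius` (default 30 px ≈ 1.5 body lengths of the synthetic
animals); an unmatched detection is an error, not a silent skip. Fragments
under 25 samples vanish from all counts; incorrect fragments spanning less
than one second are excluded from the IER numerator only. "Minutes" in the
IER is the whole video duration, not the tracked duration.

## Synthetic scenes

The generator emulates top-down laboratory video: rigid elliptical bodies
(default semi-axes 12 × 7 px) whose intensity texture — three band-limited
sinusoids in body coordinates — rotates with the heading like real markings;
dark bodies (intensity band 20–170) on a 240 background with additive
Gaussian pixel noise (σ = 2); bounce-off-walls random walk at 3 px/frame
with heading noise (σ = 0.25 rad) and soft repulsion keeping free animals
≥ 4 semi-major axes apart, so the only occlusions are the scripted ones.
`texture_distinctness` interpolates between one shared texture (0) and
disjoint per-animal intensity bands with independent patterns (1).

A scripted crossing steers the pair so their centres coincide at the
scheduled frame (velocity `(target − pos)/frames_left`, refused if this
would exceed 3× the cruise speed), after which both continue along their
approach headings and separate. Because the bodies touch before the centres
meet, the *realised* occlusion begins a few frames before the scheduled
frame; the generator therefore logs, per crossing, the first frame at which
the two rendered masks actually intersect, and that logged frame is the
reference the tests compare the tracker's occlusion cut against.

What passing these tests shows — and does not. The scenes exercise the full
causal chain (occlusion → cut → appearance-based re-linking → error-counted
metrics) under controlled, known conditions; on the canonical 5-animal,
10-crossing, distinct-texture scene the pipeline recovers every retained
sample's identity. They do not include body deformation, perspective or
lighting drift, reflections, or animals leaving the arena, and distinct
intensity bands are an idealisation of real inter-individual contrast
differences; performance on real video will degrade with texture similarity
(the identical-texture stress scene verifies only that the coexistence
invariant survives when appearance is uninformative, not that identities
are recovered — they cannot be).

## Problem sizes and runtimes

The packaged scenes are sized so the whole suite stays comfortably
interactive: the canonical identity-recovery scene uses 5 animals, 2,000
frames at 400 × 400 px (≈ 10,000 retained samples, ≈ 30 fragments; a full
pipeline run takes ≈ 25 s on one CPU), the occlusion-cut scene 2 animals and
600 frames at 320 × 320 px. Unit and property tests run on frames of at most
100 × 100 px and hand-built fragments.

## Known limitations

* One global intensity threshold: no background model, so slow lighting
  drift breaks segmentation before it breaks identity linking.
* Appearance enters only at the fragment level (by design); a tracker
  swap *inside* a fragment that survives all four gates is invisible to the
  linker and is what the strict error-propagating metrics are for.
* The similarity assumes histograms are comparable across the video; it has
  no mechanism for appearance change over time (moulting, fatigue).
* More fragments than `max_pairs`-sized cross products are subsampled, a
  deliberate constant-memory trade-off.
* Group anchoring needs all animals visible simultaneously at least once;
  otherwise the logged fallback anchors on the longest non-coexisting
  fragments and labels may not cover all animals.
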