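# Methods

`nemapose` detects the posture of a single *C. elegans* in one grayscale
frame, with no initialization and no information from neighboring frames,
and is designed to keep working when the posture is *complex* — the body
touches or overlaps itself, as in omega turns, spools and figure-8 coils.
Detection is generative and coarse-to-fine: a statistical model of
mid-level image features yields an approximate midline on a coarse grid,
and a second model of raw oriented edges refines it to pixel-resolution
boundaries by dynamic programming. A posture-analytics layer turns midline
time series into angles, eigenworms, coil events and locomotion states.
Because every frame is independent, batches are embarrassingly parallel.

## Edges and features

Eight binary edge types are extracted: four orientations (horizontal,
vertical, two diagonals) times two polarities. An edge of a given axis is
marked where the intensity difference between the adjacent pixel pair
exceeds a threshold and is a local maximum against the two flanking pairs
along the same axis (one-dimensional non-maximum suppression; on a
two-pixel plateau of equal differences exactly one edge is kept). The test
is purely ordinal above the threshold, which makes the maps robust to
brightness and contrast changes.

Mid-level features are count tests of oriented edge arrangements
("masks") on a coarse grid whose unit is a quarter of the worm width
(default 3 px for a 12 px wide worm):

* **body** masks: two inversely polarized edge bands one worm width apart,
  band length equal to the width, band halfwidth a quarter width (diagonal
  orientations use narrower bands — an eighth width — because long straight
  edge lines of other orientations otherwise cross them with enough pixels
  to fire);
* **head** masks: the body arrangement plus an inversely polarized *inner*
  pair at a quarter width around the axis, produced by the bright
  pharyngeal band in the anterior body;
* **double-body** masks: body-like with the bands two worm widths apart,
  for two body segments pressed together; a positive test registers body
  evidence at the two hypothesized segment centers.

A mask fires when the total count of matching edges in its bands reaches a
threshold (0.55 of the maximum attainable count — one digital edge line per
band — for body and double-body; 0.7 for head masks, so outer edges alone
can never produce a head detection). Three robustness measures matter in
practice and are part of the feature definition here: each band's count is
saturated at its attainable maximum (heavy blur turns one boundary into
several parallel edge lines, which must not substitute for a missing
band); each band must individually hold at least 25% of its attainable
count (10% for the weaker inner pair); and fired cells are thinned by
non-maximum suppression of the count across the mask's perpendicular
direction, so feature chains are about one cell wide — the same sharpening
idea applied at the feature level that the edge detector applies at the
pixel level. The suppression step can be disabled
(`detect_features(..., sharpen=False)`), in which case the count test is
monotone in the edge maps.

## Coarse model and search

A coarse posture is a sequence of 8-neighbor coarse-grid points whose
consecutive directions differ by at most 45°, with no revisited cell, and
with at most three consecutive same-sign 45° turns (a fourth would bend
tighter than the biomechanical curvature limit; the hard constraint family
follows from the same reasoning as the turn-angle restriction itself).
The likelihood compares, for each point, the feature of the orientation
parallel to the incoming step at the point (probability `p_high` = 0.6)
and at its two orthogonal neighbor cells (`p_med` = 0.35) against a
background rate (`p_low` = 0.002); all other feature terms cancel against
the background model. These probabilities are empirical on-rates measured
on labeled synthetic scenes across the full perturbation grid, then
frozen.

The prior combines three terms:

* an expected-length term `-A (n - lambda)^2` with `lambda` the worm length
  in coarse units and `A = 4.0`. `n` is measured as a sliding 4-step
  *chord* length rather than a step count: an 8-connected path over-counts
  a digitized curve by a heading-dependent 0–30% (staircase effect), so
  neither the point count nor the raw step sum is comparable to a physical
  length, whereas the windowed chord is, which is what lets the prior be
  this tight;
* a small penalty (0.5 nats) per 45° turn, breaking ties between a true
  path and zig-zag paths that oriented features cannot distinguish on
  straight bodies;
* the hard admissibility constraints above.

The search is the candidate-tracked breadth/depth hybrid: all candidates
within `DIFF` of the best posterior survive an iteration, at most one per
(endpoint, arrival-direction) pair, with
`DIFF = alpha * [(log p_high + 2 log p_med - 3 log p_low) -
(log(1-p_high) + 2 log(1-p_med) - 3 log(1-p_low))]` and `alpha = 3`,
and the search stops after 2 (head stage) or 3 (body stage) iterations
without improvement. Candidates are ranked, pruned and deduplicated by the
*prospective* posterior `lr + prior(max(n, lambda))` — an admissible bound,
since a path still shorter than `lambda` can yet reach zero prior penalty —
while the returned optimum uses the true posterior. Ranking by the current
prior instead would reward per-step length growth and send the beam off
axis-aligned worms in straight diagonals. The beam is capped at the best
64 candidates per iteration.

Detection is head-first: head-feature cells are clustered (8-connected
components), each cluster seeds short head sub-instantiations from its
strongest cell along the fired orientations (at most three clusters are
kept, largest first), and each cluster's best head hypothesis is extended
into a full body instantiation using body and double-body evidence. The
body search runs from either end of the head sub-instantiation; each run
is followed by a second pass from the far end of its result so that a
cluster seeded mid-body still yields full coverage, and accumulated scores
are recomputed exactly whenever a path is reversed (per-point orientations
attach to the incoming step). The pass that extends the head-tip side is
capped at three points: head features localize the anterior tip, and an
uncapped tip extension tends to run through head–body contact zones of
coiled postures, inflating the midline. The highest-posterior full
instantiation wins. If no head feature fires anywhere, or every
head-anchored result is shorter than 0.85 lambda, body-seeded searches from
the strongest body cell provide a fallback flagged `low_confidence`.

## Fine model and refinement

The winning coarse midline is smoothed (5-point moving average),
extrapolated tangentially by 4% of its arc length at both ends (the
tapered tips carry no body features, so the coarse stage systematically
stops short of them), and offset by half a worm width on both sides to
hypothesize the boundary chain: up the left side from the tail, through
the head tip, back down the right side, sampled every ~2 px. Each chain
point may move within a corridor of admissible pixels (radius 5 px by
default); corridors in the extension zones are capsules that always
include the pre-extension tip, so the chain can fold back exactly at the
true tip when the extrapolation overshoots (zero-length segments cost
nothing and collect no edge terms).

Each chain segment expects one oriented, polarized edge type — the type
parallel to the segment for a dark body on its body side — and scores the
log-likelihood ratio `p_obj` vs `p_bg` (0.75 / 0.10) over its rasterized
pixels (digital line, start point excluded so joins are counted once). The
prior charges `B = 4` nats per 45° step of deviation between the segment's
actual quantized direction and the coarse prediction; hops longer than
Chebyshev 4 are inadmissible (longer hops along an edge line would
re-collect the same evidence). The objective is a sum over consecutive
chain points, so the exact global maximizer is found by the standard
chain dynamic program.

The midline is the sequence of midpoints of opposite boundary points,
smoothed with a 3-point moving average (raw midpoints carry ±1 px
digitization jitter that otherwise biases the arc length upward by ~3%)
and resampled to 21 points equally spaced in arc length, giving the 20
intervals used by the analytics layer. Sub-pixel boundary placement is out
of scope; lengths are accurate to a few percent, not to fractions of a
pixel.

## Posture analytics

* **Angles**: 20 equal arc-length intervals; the 18 signed angles between
  next-nearest-neighbor interval pairs, tail to head, positive for
  counter-clockwise turning in image coordinates (row down, column right).
* **Coils**: the head (anterior) or tail (posterior) end lies within 5% of
  the midline arc length, as a Euclidean distance, of a midline point more
  than 15% arc length away from that end. Both fractions are configurable;
  the flags are not mutually exclusive, and the detection is invariant to
  rigid motions and uniform scaling. The turn direction maps to
  dorsal/ventral only when the recording's chirality convention is given,
  otherwise it is reported `unknown`.
* **Locomotion states**: a lagged-correlation propagation detector (an
  explicit, testable stand-in for tracker-specific schemes): within a
  centered 2 s window, the lag-1 cross-correlation asymmetry between each
  angle and its posterior neighbor gives a propagation score; coherent
  anterior-to-posterior propagation is `forward`, the reverse `backward`,
  motion below 0.01 rad/frame is `quiescent`, anything else `dwell`.
* **Eigenworms**: SVD of mean-centered angle vectors; modes are
  orthonormal with a deterministic sign convention (largest-magnitude
  loading positive); a posture's amplitudes are its projections. A spool
  is a posture with `a1 * a2 > 1` (severe above 4); `a1 * a2 < -4` marks
  figure-8 coils.
* **Clustering**: k-means over amplitudes with `k = 50` (25 for restricted
  spool sets) and a redundancy of 5 restarts with distinct seeds, keeping
  the lowest inertia; clusters are returned sorted by population.
* **Events**: maximal runs of coil-positive frames; durations below two
  frames are censored from the maximum-likelihood Weibull fit (scipy, scale
  fixed at zero location); the fitted scale is the characteristic duration;
  the fit is skipped below five events. Transition summaries align state
  probabilities on event entries and exits, report the fraction of coil
  events within 5 s of a forward/backward initiation, and compare directed
  propensities during coiling to their non-coiling baselines.

## Synthetic data

The generator defines the study conditions. Postures are curvature
profiles over arc length built from at most six cosine basis functions
(`cos((k-1) pi s)`), capped at a minimal bend radius of one worm width:
straight, sinuous (≈1.5 crawling wavelengths), omega (raised-cosine
curvature bump scaled until the head comes within 5% of the length of the
mid-body), spool (winding of 2.3–2.9 pi with curvature growing toward the
head so whorls do not coincide), figure-8 (`cos(pi s)` profile, opposite
end curvatures), and a band-limited random family (Gaussian coefficients
with decaying scales 2.5 … 0.8 rad) to which white curvature noise of a
chosen relative power can be added.

Scenes render a tapered tube (tail sharper than head) at intensity 60 on a
background of 200, with a brighter interior band (180) over the central
half-width of the anterior 15% of the body — the structure whose inner
edge pair the head masks test. Perturbations follow the imaging-conditions
protocol: contrast digitally rescaled about the background by 0.5–1.5,
Gaussian blur of sigma 2 or 3 px, additive Gaussian noise (sd 2). The
default corpus uses a 320x320 frame, worm length 144 px and width 12 px
(coarse unit 3 px), family mix 10% straight / 30% sinuous / 20% omega /
20% spool / 20% figure-8, contrast uniform in [0.5, 1.5], blur drawn from
{0, 2, 3}. All randomness flows from explicit seeds; identical seeds give
byte-identical scenes.

What the renderer does *not* emulate: texture inside the body, bacterial
lawn and debris clutter, uneven illumination, motion blur, and multi-animal
scenes. Passing the synthetic acceptance suite therefore demonstrates the
algorithmic properties of the method under controlled photometrics, not
performance on any particular microscope's footage.

The behavior simulator produces midline time series at 10 frames/s from
traveling bend waves (0.5 Hz, 1.5 body wavelengths) with regime-specific
coiling: `wildtype-like` (mostly forward, occasional reversals, brief
omega-like coils on well under 5% of frames), `static-coiler` (bouts locked
into a frozen spool posture with Weibull-distributed durations), and
`loopy-mover` (high-amplitude waves that cross the coil threshold while
directed locomotion continues).

## Numerical choices and degenerate inputs

Images must be 2-D, at least 8x8, finite and non-negative. Ties in the
edge and feature non-maximum suppressions keep exactly one of two equal
neighbors. Beam-search ties at the same (endpoint, direction) keep the
earlier-created candidate, making outputs byte-identical across runs.
Zero-length fine segments contribute no edge or prior term. A boundary
whose midline degenerates to zero length is rejected. Every returned
coarse instantiation is validated against its invariants (8-adjacency,
turn limit, self-avoidance).

Problem sizes used by the test suite and the acceptance script — a
200-frame corpus for the detection rate, 2,000 (tests) / 10,000 (script)
postures for the eigenmode target, 500 events for the Weibull recovery
check — were chosen so the full suite runs in a few minutes on one CPU
core while keeping the binomial/estimation error of each measured rate
well below the margin being asserted.

## Known limitations

* Head-tail identity relies on the inner edge pair of the anterior body;
  under strong blur the head cluster can be missed (body-seeded fallback,
  `low_confidence`) or a spurious cluster can win, flipping the identity.
  The length-based success criterion is insensitive to this; downstream
  analytics that need polarity should check the `status` flag.
* Tightly pressed spools remain the hardest family: corridors can straddle
  adjacent whorls and head–body contact zones are genuinely ambiguous in a
  single frame, which is where most residual length failures (~±10–15%)
  live.
* The model explains each image feature independently; evidence in a
  contact zone can support two different path segments at once, a blind
  spot inherited from the conditional-independence assumption.
* Physical units are not modeled; all geometry is in pixels, and the
  configured worm length/width act as the per-stage scale calibration that
  a real deployment would set per magnification and developmental stage.
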