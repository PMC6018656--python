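# Methods

This note records the models, conventions and numerical choices behind
`consensusclick`, in the order data flows through the package.

## Coordinate conventions

All clustering and filtering happens in the resized image space: width
fixed at 1000 px, height scaled by the same factor so aspect ratio is
preserved (1920×1080 → 1000×562.5; 2048×1536 → 1000×750), origin in the
top-left corner with y increasing downward. `rescale_point` multiplies
before dividing (`x · w / ox`) so that the full-frame corner lands
exactly on (1000, 562.5) in floating point; fractional heights such as
562.5 are carried exactly and never rounded, because the out-of-bounds
filter compares against them.

Timestamps are parsed strictly as `YYYY:MM:DD HH:MM:SS` with no timezone
inference — cameras record local time.

## Hygiene filters

**Duplicate sessions.** A volunteer occasionally classifies the same
image twice. Because the clustering constraint forces clicks by one
volunteer into separate clusters, duplicates inflate detection counts,
so only the earliest session per (volunteer, image) pair is kept and
later sessions are dropped in full. When the input lacks session
identifiers, sessions are synthesised from contiguous runs of rows for
the same pair in file order (classification exports list each session's
clicks together; the timestamp column is the image capture time, not the
classification time, so file order is the only ordering signal).
"Earliest" means the smallest session id under numeric-aware ordering.

The duplicate test is anchored to a *session registry* — the earliest
session per pair, computed once on the input table. With the registry
fixed, duplicate-ness is a per-click predicate, so the duplicate filter
and the bounds filter are each idempotent and commute exactly. Without
this anchoring, a pair whose entire first session lay out of bounds
would make the outcome depend on filter order.

**Out-of-bounds clicks.** Marker tools on touch devices can be dragged
beyond the image. A click is removed iff `x < 0`, `x > 1000`, `y < 0`
or `y > h` with `h` the image's *own* resized height (562.5 or 750) —
strict inequalities, so boundary-exact clicks are kept: the rule is
"beyond the limit of the image", and the boundary is part of the image.
The same test is available post-hoc on consensus centres
(`remove_out_of_bounds_consensus`) for workflows that filter after
aggregation instead.

Every removal is accounted for in a `FilterReport` whose counts must
reconcile (`input = duplicates + out_of_bounds + retained`), overall and
per image.

## Constrained Ward clustering

The dendrogram is built by Ward linkage on Euclidean distance over the
raw 2-D pixel coordinates (no standardisation — both axes are pixels at
the same scale), via `scipy.cluster.hierarchy.linkage`. A single click
yields a degenerate one-leaf tree with no merges.

The cut is a greedy top-down traversal: accept a node as a final cluster
iff no volunteer contributes more than one leaf beneath it, else recurse
into both children. Admissibility is inherited by descendants (a subset
of leaves uses a subset of each volunteer's clicks), so every admissible
tree-respecting partition refines the greedy one: the greedy cut is the
unique coarsest admissible antichain, which is what "maximise clicks per
cluster per branch" means precisely. The test suite pins this with two
independent oracles: exhaustive enumeration of all admissible
tree-respecting partitions (the greedy cut must equal the one with
fewest clusters), and — on well-separated instances — exhaustive search
over *all* set partitions, scored by (number of clusters, within-cluster
SSE) lexicographically. Raw SSE alone is not a usable objective (zero
for all-singletons); cluster-size maximisation is primary, spatial
tightness secondary.

Determinism: SciPy's nearest-neighbour-chain Ward agglomeration is
deterministic given the input row order, and cluster labels are assigned
in order of each cluster's first click, so results are reproducible
across runs and machines. Exact merge-height ties (possible only on
exactly symmetric integer configurations) resolve by SciPy's
agglomeration order; with continuous coordinates they have measure zero.

## Consensus statistics

For a cluster of size *m* on an image with *V* yes-voters:

- centre = coordinate-wise median of member clicks (median, not mean,
  for robustness to stray clicks; an even-sized cluster takes the mean
  of the two central values — the standard median);
- P(type) = fraction of member clicks labelled with that type, for
  adult, chick and egg; the "other" fraction is implicit as
  1 − (sum of the three) and is not emitted, matching the published
  consensus schema;
- P(true positive) = *m* / *V*, so `num_markings / P` recovers the
  whole number *V*; this integrality is validated on every record at
  1e-9 before writing.

*V* counts distinct volunteers who answered "yes, animals present" for
the image — including volunteers who answered yes but placed no clicks.
"Can't tell" answers never enter the denominator. Zero yes-voters with a
non-empty cluster is a contract violation and raises.

All labels are clustered jointly in one spatial pass ('other' clicks
included): type probabilities are computed *within* clusters, which
presumes mixed-label clusters, and a separate clustering per label would
split a penguin marked `adult` by some volunteers and `chick` by others
into two detections.

Every retained click contributes to exactly one consensus click; the
aggregation never drops clicks.

## Retirement rule

A subject retires after 4 views if the first four answers are all "no"
or "can't tell" (both count as blank), otherwise after 10 views. A yes
anywhere in the first four answers permanently cancels blank retirement.
Streams shorter than either limit report status `active` rather than
erroring, since a live project always has partially-classified subjects.

## The volunteer behaviour model

`generate_scene` plants point targets uniformly at random in the frame,
rejecting draws closer than `min_separation` (default 50 px at width
1000) to any placed target, with a bounded retry budget so infeasible
packings fail loudly. Targets also keep an edge margin (default half the
separation, i.e. the packing radius) clear of the frame boundary: a bird
half outside the frame is not a clean point target, and volunteers click
inside the image. The margin is also what makes exact-recovery
statements well-posed — without it a target *on* the edge sheds noisy
clicks past the boundary filter.

`VolunteerProfile` parameterises one simulated volunteer:

| parameter | default | meaning |
| --- | --- | --- |
| `detection` | adult 0.95, chick 0.6, egg 0.5, other 0.8 | chance of marking a target at all; chicks are missed most (brood-guarding parents conceal them) |
| `click_noise_px` | 5 | SD per axis of isotropic Gaussian click noise, resized px |
| `confusion` | none | per-type label distribution applied to detected targets |
| `false_positive_rate` | 0 | expected spurious clicks per image (Poisson, uniform placement) |
| `tag_limit` / `stop_at_limit_prob` | 30 / 0.5 | after 30 tags the volunteer is offered a stop; the offer is made once |
| `adult_first` | off | tag all adults before chicks/eggs/others |
| `duplicate_session_prob` | 0 | chance of classifying the image a second time |
| `off_image_prob` | 0 | chance, per click, of dragging the marker off the image |

A volunteer's answer ("yes"/"no") derives from whether they clicked
anything; `all_marked` is `incomplete` iff they took the tag-limit stop.
The Gaussian noise scale and the 0.5 stop probability are modelling
choices pinned by parameter-recovery behaviour rather than claims of
realism — no click-error model was available to fit. Two named profiles
bundle the interesting regimes: `ideal()` (detection 1, 2 px noise, no
limit) and `chick_miss()` (chick detection 0.5, adult-first, hard stop
at 30), the latter reproducing the *direction* of real-world chick
undercounting: on crowded scenes (>30 adults) chicks are never reached
before the stop, so underestimates dominate overestimates at every
counting threshold.

What the simulator deliberately does not model: photographic appearance
(nothing is rendered), spatially correlated misses (a dense huddle is as
easy as an isolated bird), volunteer heterogeneity over time, and
"can't tell" answers. Passing tests therefore demonstrate the
*pipeline's* correctness and the qualitative consequences of the
behaviour model, not quantitative agreement with any real survey.

## Validation

Counting uses strict thresholds throughout: `num_markings > k` and type
probability `> 0.5`. The combined adult+chick category thresholds the
*summed* probability, so an individual split 0.5/0.5 between the two
labels still counts — thresholding each label separately would make it
vanish.

Gold-standard comparisons restrict to images that contain animals and
were marked complete. "Average difference" is the mean of *absolute*
per-image differences |GS − CS| (the direction of disagreement is
reported separately as the over/under/match percentages, which always
partition 100%); σ is the sample standard deviation (ddof 1) of the
absolute differences, reported as NaN for a single image. The
chick-only comparison can be restricted to images where chicks are
present according to the gold standard and/or the consensus data, since
chick-free images make chick accuracy look spuriously high. Images
present in only one table are excluded, logged and listed, never
silently matched.

Two monotonicity properties hold exactly and are tested: per-image
counts are non-increasing in k, and as k rises the overestimate
percentage is non-increasing while the underestimate percentage is
non-decreasing — the over/under trade-off that motivates choosing an
intermediate threshold.

## Problem sizes

The test suite and `scripts/acceptance.py` use 100-image surveys
(10 volunteers; 15 targets per image for recovery, 40 for the crowded
chick-bias scenes) and 200 random instances of ≤8 clicks for the
exhaustive-oracle comparison; the oracle's partition enumeration grows
like the Bell numbers, and 8 clicks (4140 partitions) keeps the
exhaustive check exact while the whole suite runs in seconds. All
randomness flows from explicit seeds; reruns are bit-identical.

## Known limitations

- The bounds filter trusts each image's recorded original dimensions;
  a wrong `original_size_x` silently shifts the boundary.
- The constraint treats volunteer ids as opaque: the same person under
  two ids (logged-in and anonymous) can legitimately occupy one cluster
  twice.
- The greedy cut is optimal per branch of the Ward tree, not globally:
  a repeat-clicker whose two clicks are mutually nearest neighbours
  forces a singleton that an unrestricted partition could pair better.
  This mirrors the behaviour of dendrogram-based aggregation generally.
- `aggregate_table` processes images independently and in memory; very
  large exports should be chunked by image before aggregation.
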