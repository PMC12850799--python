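# Methods

## Grading model

A colon capsule video is a stream of frames. Frame *i* receives a clean-pixel
fraction `f_i ∈ [0, 1]` and a continuous cleanliness rating
`r_i = min(1 + 4 f_i, 5 − ε)` on `[1, 5)`. The affine map puts the four
Leighton-Rex grade cells at equal width: flooring a rating yields poor
(`f < .25`), fair (`.25 ≤ f < .5`), good (`.5 ≤ f < .75`) or excellent
(`f ≥ .75`). The clamp just below 5 guarantees the floor never leaves
{1, 2, 3, 4}. The underlying per-frame scale of the original trained grader
is not public, so this map is a declared, config-switchable policy of this
package, not a reconstruction of that model; the same applies to the
HSV-threshold pixel rule (dirty = hue ∈ [20°, 70°], saturation ≥ .35,
value ≥ .15 by default), which is a deterministic rule-based grader standing
on its own terms. "Ratio of clean to dirty pixels" is implemented as the
bounded clean fraction `clean/(clean+dirty)` — defined when dirty = 0 and
stable under percentile summaries — with the literal quotient exposed as a
derived convenience value.

A sequence (whole colon pooled, or one flexure-delimited segment) is
summarized by six statistics of its rating distribution — mean, median, Q1,
Q3, P2, P98 — each floored to a grade and dichotomized (poor =
nonacceptable). All six are always computed; which one "is" the algorithm's
grade is a run-level choice, because comparing them is the point of the
analysis. Frames are equally weighted: no temporal smoothing and no
correction for capsule dwell, deliberately, since dwell-compensation is a
human-reader behaviour the automated grader does not have.

Segments are half-open frame-index intervals `[b_{k−1}, b_k)` cut at the
reader-reported flexures (boundary frames are never double-counted); an
empty segment is an error naming the segment, since an unobserved segment
cannot be graded. Readers grade five segments; for three-segment comparisons
cecum+right and left+rectum each merge at the lower grade of the pair. The
readers' overall 4-point grade is taken as the minimum segment grade — a
declared policy chosen for consistency with the binary overall rule
(acceptable iff every segment acceptable), with which it commutes under
dichotomization (verified exhaustively over all 4⁵ grade vectors).

## Agreement statistics

For a k×k table with cell proportions `p_ij`, row margins `p_i·`, column
margins `p_·j`, and agreement weights `w_ij` (identity for unweighted;
linear `1 − |i−j|/(k−1)`; quadratic `1 − (i−j)²/(k−1)²`):

    p_o = Σ w_ij p_ij,   p_e = Σ w_ij p_i· p_·j,   κ = (p_o − p_e)/(1 − p_e)

The standard error is the Fleiss–Cohen–Everitt asymptotic form, with 95% CI
κ ± 1.96·SE; a percentile bootstrap (multinomial resampling of the n pairs,
2,000 resamples) is provided as a cross-check and brackets the asymptotic CI
on the published tables. Linear weights are the default for the 4-point
scale because the original analysis was run in SAS, whose weighted-κ default
is Cicchetti–Allison; quadratic is a flag. The interpretation ladder
(≤ .20 None, .21–.39 Minimal, .40–.59 Weak, .60–.79 Moderate, .80–.90
Strong, > .90 Almost perfect) is applied after rounding κ half-up to two
decimals, which closes the .20/.21 gap and makes the bands exhaustive;
negative κ labels "None". Printed κ values drop the leading zero (".10"),
while machine-readable output keeps full precision.

Percentiles default to linear interpolation between closest ranks (the
common array-library convention), with nearest-rank available; the original
study does not state its convention, and the choice only matters for short
streams.

## Synthetic cohort

Each video draws a latent grade `G ∈ {1..4}`; each of its five segments
inherits `G` with probability `segment_correlation` (default 1) or redraws.
Frame ratings are i.i.d. truncated-normal on `[1, 5)` centered at the
grade-cell midpoint `latent + 0.5` with SD `within_segment_noise` (default
0.4) — symmetric about the midpoint so mean and median floor identically at
zero noise, giving exact parameter recovery in the noiseless limit. Reader
reports pass segment latents through a 4×4 row-stochastic confusion matrix.
Segment boundaries are four random interior cuts with every segment at least
~5% of the stream; reports carry only the two flexure cuts (three-segment
mode), as the real reports did.

The study-like preset was calibrated analytically to the real cohort's
marginal rates before any simulation: with latent distribution
(.06, .40, .35, .19), correlation 1, and confusion rows whose
P(report poor | latent) are (.85, .10, .02, .005), the expected reader
overall-nonacceptable rate is
`Σ_g P(G=g) · (1 − (1 − c_g)^5) = .262` against the observed 26.37%, and
the algorithm mean-statistic nonacceptable rate ≈ P(G=1) = .06 (the
truncation at the scale floor biases the poor-cell mean up by ≈ .08, still
below the fair threshold) against the observed 5.94%. Synthetic frames use
flat palette colours (dirty hues 34–37°, mucosa ≈ 343–347°) without
anti-aliasing so the classifier recovers the painted mask pixel-exactly, and
the dirty region is trimmed to the exact rounded pixel budget.

What the generator does **not** emulate: endoscopic texture, illumination
gradients, capsule dwell and backward motion (over-representation of
locations), intra-reader drift, and ungradable segments. Passing tests
therefore demonstrate correctness of the scoring, grading and agreement
machinery under controlled conditions, not image-level performance on real
capsule video.

## Problem sizes and numerical choices

Tests exercise 1,000 random streams and 1,000 random tables against
independent sort-based and double-sum oracles at 1e-12; exhaustive checks
cover all 4⁵ grade vectors. Cohort-level checks use 842-video cohorts (the
real cohort size) across 20 seeds, with 150–400 frames per video — enough
frames that percentile statistics stabilize while the whole suite stays
interactive. Kappa on a table with all mass in one cell (p_e = 1) is
undefined and raised as an error; bootstrap resamples that degenerate are
skipped. Summary values below rating 1 (possible only for degenerate
classifier configs) clamp to poor with a warning rather than erroring.

## Known limitations

- The pixel classifier is a colour-threshold stand-in; its thresholds are
  tuned to the synthetic palette, and real frames would need either the
  thresholds re-tuned or a trained model behind the same interface.
- Segmental and subgroup agreement values from the original cohort cannot be
  checked numerically without the raw videos; the pipeline reproduces the
  published overall 2×2 analysis exactly and emits the same report structure
  for everything else from synthetic cohorts.
- Single-reader model: no multi-rater statistics (Fleiss κ, ICC,
  Krippendorff's α) and no intra-observer analysis.
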