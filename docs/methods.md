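# Methods

## Color-class segmentation

**Model.** Each stain class (yellow = disrupted fibers, blue = intact
fibers) is a per-channel interval model in RGB space: means μ and sample
standard deviations σ (ddof = 1) are estimated from the pooled pixels of the
training regions, and a pixel matches the class iff every channel lies in
[μ − k·σ, μ + k·σ]. The damage percentage is the yellow share of all colored
pixels in the bounding box; uncolored pixels never enter the denominator.

**Why per-channel intervals.** The class statistics are estimated per
channel, so the acceptance region is the axis-aligned box those statistics
define. A Mahalanobis ellipsoid using the full channel covariance would be a
natural alternative, but it estimates three more parameters from 1 000
training pixels and changes nothing in the noise regimes we simulate (class
means ~170 intensity units apart against noise SDs ≤ 10); the box is also
the rule whose parameters the output reports transparently.

**Both-class pixels.** When the boxes overlap, a pixel matching both classes
is assigned to the class with the smaller SD-normalized Euclidean distance
to its mean — deterministic, scale-aware, and equal to nearest-mean
assignment when the SDs coincide. Exact ties go to yellow and are counted
and logged; the both-class fraction is always reported so a user can see
when the two color models have drifted together.

**Numerical choices.**

* Coordinates are 0-based and half-open; `x` is the column, `y` the row.
* Pooled training pixels are sorted lexicographically before the mean/SD
  reductions, so results are bit-identical under any permutation of the
  training regions and any re-partition of the same pixel multiset.
* A zero-SD channel (constant training patch) matches only on exact
  equality — degenerate but well defined, and exactly what makes noise-free
  synthetic slices segment perfectly.
* Images are converted to 8-bit RGB on load: alpha dropped, 16-bit channels
  divided by 256, grayscale rejected, embedded ICC profiles ignored (a
  global color transform affects training and test pixels identically, so
  ignoring it is consistent).
* Study-style tables round percentages to the nearest integer; the
  unrounded value is retained in all JSON output.

**Tunable parameters.** `k` (dimensionless, default 1.7) sets the
acceptance-box half-width in SD units; larger k admits more pixels of each
class (monotonically) and eventually overlaps the classes. Ten regions of
10×10 pixels per class (the defaults) give 1 000 training pixels, enough to
estimate an SD to a few percent.

## Synthetic stained slices

The generator emulates a photographed cross-section as an ellipse (default
semi-axes 240×180 on a 640×480 canvas) on a light-gray background. The
damaged region is a chord cut: ellipse pixels are swept column by column and
the first `round(f·N)` of them are labelled damaged, so the realized
fraction equals the requested one exactly up to one pixel of quantization,
and the stored ground-truth fraction is the exact count ratio. Colors are
base RGB triples (yellow 220/200/60, blue 50/70/180, background
235/235/235 — saturated latex paint against a neutral backdrop) plus iid
per-channel Gaussian noise, clipped to [0, 255]. For a fixed seed the noise
field is drawn once as standard normals and scaled, so increasing the noise
SD never decreases the deviation from the base colors.

The canvas size is a free choice (the source protocol specifies only an
8-megapixel camera); 640×480 is the smallest round size at which a
5%-damaged sliver still admits ten non-overlapping pure 10×10 training
squares, which keeps every simulation in the test suite fast.

Training regions are sampled by rejection over the set of all top-left
corners whose square lies entirely inside the class's truth area (computed
with an integral image), uniformly at random, re-drawing any placement that
overlaps an already accepted region of the same class.

**What the generator does not emulate:** tissue texture, lighting
gradients, specular highlights, stain bleeding at the damage boundary,
camera optics, or irregular cross-section shapes. Passing the recovery
tests therefore shows that the classification rule and its estimation are
correct and noise-robust, not that the method is robust to real
photographic artifacts — on real photographs the human step of placing
training regions and the bounding box remains decisive.

Study tables are simulated as truncated normals centered on the requested
group medians (SD = `spread`), rounded to integer percent to match the
reporting convention. The truncation to [0, 100] shifts the realized median
of groups centered near the boundaries inward; tests account for that.

## Reliability (ICC)

The variant is ICC(2,1): two-way random effects, absolute agreement, single
measure — raters are interchangeable assessors and the absolute value of
the damage percentage matters, not just its ranking. It is assembled from
the two-way ANOVA mean squares

    ICC(2,1) = (MS_S − MS_E) / (MS_S + (k−1)·MS_E + (k/n)·(MS_R − MS_E))

for n subjects and k raters. Negative estimates are reported as computed.
Degeneracy is detected on the raw cell values rather than the computed sums
of squares (a constant matrix yields SS ≈ 1e−28 from float rounding, not
0): an all-equal matrix returns 1 with a warning (the raters agree
exactly), and a matrix with no between-subject variance is flagged
degenerate because the coefficient is then not interpretable.

The simulated reliability study treats region selection as the only
subjective step: each simulated rater re-samples its own training regions
on every slice (per-cell seeds derived from the rater seed) and re-runs the
full segmentation. With 1 000 training pixels per class the fitted models
are so stable that two raters differ by a few tenths of a percentage point,
giving ICC well above 0.9 across slices spanning 5–95% damage — the
simulation reproduces the mechanism of the reliability claim, not the
original observers.

## Group statistics

Groups are described by median and range (midpoint rule for even sizes) and
compared with the joint k-group Kruskal–Wallis test — mid-ranks for ties,
tie-corrected H, χ² approximation with k − 1 df. The joint test is used
because the study reports a single p per muscle; pairwise two-group tests
against a chosen reference are available as an option. The χ² approximation
is retained even at 5 observations per group (an exact permutation p would
be feasible but the reported values are consistent with the
approximation). With 5 groups of 5 the packaged per-hip table gives
H = 7.44, p = 0.115, which rounds to the printed 0.1. All-identical data
short-circuit to H = 0, p = 1. Bonferroni thresholds are α/m; dichotomous
structure outcomes are tabulated as frequencies without testing.

## Power

Power of the two-sided two-sample pooled-variance t-test is computed from
the noncentral t distribution with 2n − 2 df and noncentrality
δ/(σ·√(2/n)), both rejection tails included. Sidedness and α are not fixed
by the design description; two-sided α = 0.05 is the default (consistent
with the significance criterion used for the primary comparison) and is an
explicit argument everywhere. For the study design (n = 5, δ = 18,
σ = 8.5) the exact power is 0.834, slightly above the nominal 80%; the
smallest n reaching 80% is 5, found by increment search (power is monotone
in n).

## Problem sizes used in the checks

The automated checks run entirely on synthetic data: default 640×480
slices; 20 fixtures spanning fractions 0.1–0.9 at noise SD 10 for recovery
(mean absolute error ≤ 3 percentage points, observed ≈ 0.3); 10 fixtures ×
2 raters at noise SD 8 for the reliability simulation; 10⁵ Monte-Carlo
replicates for the power cross-check; brute-force per-pixel classification
oracles on 80×60 slices.

## Known limitations

* The per-channel box and the both-class tie-break are documented choices;
  the original software's exact rule (single color axis vs per-channel
  intervals, handling of doubly matched pixels) is not recoverable.
* The ICC simulation is a stand-in for human inter-observer variability;
  real observers also move the bounding box and disagree on ambiguous
  stain, which the simulation does not model.
* No confidence intervals for the ICC or the medians; no exact
  permutation p-values by default; equal group sizes only in the power
  module.
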