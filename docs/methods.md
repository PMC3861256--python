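# Methods

`skyline` re-creates, on synthetic imagery, a computational experiment in
visual scene perception: how well can simple, single-cue algorithms locate
the astronomical horizon in photographs of outdoor scenes, and how does
their behavior compare with human observers? This note records the models,
the free parameters and their defaults, the numerical choices, and what the
synthetic data can and cannot show.

## Coordinates and ground truth

Horizon positions are normalized vertical coordinates of the full upright
image: 0 at the top edge, 1 at the bottom, with pixel row `r` of an `H`-row
image centered at `(r + 0.5)/H`. The *astronomical* horizon (the projection
of the gravity-perpendicular plane at eye height) is a single row, but its
visually estimable position is genuinely uncertain — surface slant and
occluders leave room for disagreement. Ground truth is therefore a
*distribution*: the set of per-image rater estimates is turned into a 1-D
Gaussian kernel density

    p(y) = (1 / (n h sqrt(2 pi))) * sum_i exp(-(y - y_i)^2 / (2 h^2)),

with bandwidth `h = n^(-1/(d+4)) * sd` (Scott's rule, `d = 1`, sample sd).
Any estimate is scored by the *confidence* `p(y_est)` — a density value, so
values above 1 are routine for concentrated estimate sets. Two numerical
guards: the bandwidth is floored at 0.005 normalized units so zero-spread
synthetic estimate sets still define a density (real raters always
disagree; simulated ones need not), and evaluation is an exact kernel sum,
never grid interpolation.

Before fitting, a single-pass filter drops estimates more than three
sample standard deviations from the per-image mean; zero-spread sets are
kept whole. A subtlety worth recording: for `n = 12` the largest attainable
z-score against the set's own mean and sd is `(n-1)/sqrt(n) ≈ 3.175`, so
pure-normal estimate sets essentially never lose a point. Removals require
a genuine contaminant — which is exactly what the filter exists for.

## Synthetic scenes and simulated raters

No image corpus or rater data are distributed for this task, so the
generator fabricates both, reproducing the cue structure the estimators
rely on rather than photorealism:

* every scene starts from a sky/ground luminance split exactly at the true
  horizon row (bright, slightly blue sky gradient above; dark,
  green-brown ground below), separation scaled by `sky_ground_contrast`;
* *coast* keeps the split clean; *open country* adds a low-amplitude
  boundary undulation; *forest* and *enclosed nature* overlay dark
  vertical occluder strips crossing the horizon; *non-urban street* and
  *city* add a bundle of perspective lines through a vanishing point
  placed exactly on the horizon row (city: more and stronger lines);
  *other* picks a recipe at random;
* true horizons are uniform on the middle third of the image height,
  mirroring the original stimulus-selection rule, which also guarantees
  every subwindow condition retains the horizon;
* class proportions default to the published stimulus counts
  32/29/18/46/16/47/12 (coast, open country, forest, enclosed nature,
  non-urban street, city, other).

Simulated raters draw from a Normal centered on the true horizon,
truncated to [0, 1] by rejection, with a class-dependent spread (defaults,
normalized units: coast 0.01, non-urban street 0.02, city 0.025, other
0.03, open country/forest/enclosed nature 0.04). The magnitudes are free
parameters; their *ordering* encodes the reported pattern that agreement
is far higher on open coastal scenes than on closed natural ones. Each
draw is replaced by a Uniform[0, 1] contaminant with probability 0.0075,
calibrated once so the 3-sigma filter removes ≈0.3% of points — the
removal rate reported for real unlimited-time raters.

What passing tests on this generator do **not** show: robustness to real
photographic nuisances (clouds, reflections, night scenes, texture-rich
ground brighter than sky, camera roll), nor the absolute confidence levels
real rater densities would produce. They do show that each algorithm
extracts its intended cue, that the scoring, tuning and comparison
machinery is correct, and that informed estimators separate cleanly from
chance under the stated noise model.

## Stimulus conditions

Six manipulations, each with an affine coordinate map back to full-image
coordinates so estimates are comparable across conditions: `norm`
(identity), `inverted` (vertical mirror; map `y -> 1 - y`), `blurred`
(Gaussian low-pass, sigma = 1% of image height by default, scaling with
resolution; reflective boundaries preserve mean intensity), and the
`lower`/`middle`/`upper` subwindows keeping two thirds of the rows
(`floor(H/3)` rows cut from the top, `floor(H/6)` from top and bottom, or
`floor(H/3)` from the bottom, remainders staying with the kept block),
followed by removing columns alternately from the right and left (seeded
starting side) until the original aspect ratio is matched within one
column. Estimates mapping outside [0, 1] after correction are clamped and
flagged.

## The per-row estimators

All profile algorithms consume exactly one CIE L\*a\*b\* channel (D65) and
return one non-negative confidence per row; the readout is
winner-takes-all, `(argmax + 0.5)/H`, ties broken toward the image center
and then toward the smaller row index.

* **div / -div** — global term: difference of mean channel values above
  vs. below each row boundary (sign exchanged for `-div`); local term:
  column-mean absolute vertical derivative after Gaussian smoothing
  (default sigma 1 px). Both terms are min–max normalized over rows
  before the linear mix (`local_weight`, default 0.5), making the
  weighting scale-free. Row 0 has no division and scores 0.
* **lin** — sum over columns of the absolute forward difference between
  adjacent rows after smoothing; the last row pads with 0.
* **gab** — row-summed magnitude of the response to a horizontally
  oriented complex Gabor (wavelength 8 px, bandwidth 1 octave, aspect
  0.5 by default). The cosine component's DC response is removed by an
  envelope-weighted correction so constant images give exactly zero. The
  horizontal kernel is exactly separable, and the implementation exploits
  this; equality with the dense 2-D convolution is verified in tests.
* **van** — Canny edges vote in a Hough accumulator, weighted by gradient
  magnitude so line strength reflects both edge response and edge length.
  Lines are extracted *iteratively with support removal*: accept the
  global maximum, delete edge pixels within 2 px of that line, re-vote.
  This choice matters: naive peak picking returns the broad "butterfly"
  ridge of each finite segment, whose near-duplicate lines cross at the
  segment midpoint and systematically out-vote the true vanishing point.
  Accepted lines (near-vertical ones excluded, default within 5° of
  vertical, since they intersect rows almost uniformly) are redrawn
  across the full width into a voting image (binary, one pixel per
  column, intensity proportional to normalized strength), which is
  smoothed with a 1.5 px Gaussian — crossings within quantization
  tolerance must register — then exponentiated (default exponent 2) and
  summed per row. Defaults: 1° theta resolution, 0.5 px rho resolution,
  up to 20 lines. A caveat measured during development: intersections of
  near-parallel lines are ill-conditioned under this quantization, so
  bundles whose directions differ by only a few degrees localize poorly;
  this is a property of vanishing-point voting itself.
* **dum1 / dum2** — image-blind baselines drawing from a uniform interval
  intersected with [0, 1], or a clamped Normal. Their signatures take no
  image, which enforces the contract structurally.

## The holistic pathway

The spatial-envelope descriptor applies a Gabor bank (4 scales,
wavelengths 4–32 px; 8 orientations; bandwidth 1 octave, aspect 0.65) to
each of the three L\*a\*b\* channels, pools response magnitudes over a 4×4
grid, and concatenates (length `3*4*8*16 + 1` with the intercept).
Convolution is FFT-based with reflective padding — zero padding would give
spurious boundary responses on constant images.

The regressor is a cluster-weighted mixture: each of K components carries
a mixing prior, a diagonal-Gaussian gate in a PCA-reduced descriptor space
(default 64 dimensions, basis fitted on training folds only), and a linear
regressor with Gaussian noise. EM maximizes the joint likelihood;
responsibilities combine prior, gate and target likelihood; the M-step is
ridge-stabilized weighted least squares (ridge 1e-6, which survives the
strongly collinear descriptor dimensions). Predictions weight components
by prior-times-gate only (the target is unknown), and are clamped to
[0, 1] with a flag. Variance floors (1e-6 for gates, 1e-4 sd for noise)
prevent component collapse; restarts are selected by final log-likelihood.
With K = 1 the fit reduces exactly to ridge regression, which the tests
exploit as a closed-form oracle. The original mixture's gating scheme is
not documented in the source material; the cluster-weighted choice is this
package's assumption.

## Tuning and cross-validation

The corpus is split into k = 10 folds by hill-climbing pairwise swaps from
a seeded random equal split, minimizing the summed per-fold L1 deviation
of class proportions from the global proportions plus — with equal weight
after standardizing — the absolute per-fold mean of standardized density
peaks (each image's "difficulty" is summarized by its density's peak
value; the alternative summaries, mean density or estimate spread, are
equally defensible and the choice is recorded here). Swap acceptance is
strictly monotone, so the objective never increases.

For each fold, parameters are tuned on the other nine folds: seeded
uniform/log-uniform random search followed by Nelder–Mead refinement from
the best starts, integers relaxed during refinement and rounded at
evaluation, and a best-so-far contract so refinement never returns less
than its starting objective. The training objective is the mean confidence
of the winner-takes-all estimate under each training image's density. Two
exceptions: the dummies' objectives are averaged over 10 seeded runs, and
every `gst` parameter evaluation wraps an internal 3-fold fit-and-score
(training is part of scoring). Default search budget is 500 random samples
per fold with 3 refinement starts; the bundled experiment scripts use
smaller budgets (15–20 random samples, one refinement start) — the
objectives involved are low-dimensional and smooth, and these sizes
already saturate them on synthetic corpora. Testing scores each image
exactly once, with the parameter set tuned without its fold; provenance is
recorded so leakage is assertable.

## Behavior comparison

An algorithm's "behavior" is its pattern of mean confidences: 6 condition
marginal means followed by 7 scene-type marginal means (13 cells; the 6×7
crossed variant is available behind a flag). Patterns are compared by
Pearson correlation. The human reference is a *simulated* quick-viewing
rater population — per-class spreads inflated by per-condition factors
(norm 1.2, middle 1.1, lower 1.25, upper 1.5, blurred 1.8, inverted 2.0)
chosen to mirror the reported ordering that inversion and blur hurt most
and the middle subwindow least. These raters are synthetic stand-ins;
correlations against them validate the machinery, not human vision.

Inter-rater reliability uses the Shrout–Fleiss two-way random-effects
intraclass correlations: ICC(2,1) for single ratings and ICC(2,k) for the
k-rater mean, computed from the items×raters ANOVA mean squares after
dropping items with any missing rating.

## Problem sizes

The bundled acceptance script runs a 100-image corpus at 96×72 px with
10 folds, which keeps a full multi-algorithm tuning-plus-evaluation cycle
in the minutes range on one core while leaving every fold with 90 training
images; the test suite uses 20–300 images depending on the property under
test. Per-image Lab conversions and descriptors are memoized per condition,
since tuning evaluates the same conditioned image at many parameter
settings.

## Known limitations

* The generator's recipes make one cue dominant per class; real scenes mix
  cues and break the sky-brighter-than-ground assumption (night, snow).
* `van` degrades on bundles of near-parallel lines (ill-conditioned
  intersections) and on images whose strongest Hough line is not
  horizon-related.
* The behavior comparison inherits every assumption of the simulated
  rater model; its correlation values have no empirical counterpart here.
* Blur condition sigma and the reference resolution of the original
  stimuli are not recoverable from the source material; the 1%-of-height
  default is this package's choice and is configurable.
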