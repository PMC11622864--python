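# Methods

## Problem setting

Positive-unlabeled (PU) data consist of a feature matrix and an assigned
label `s`: `s = 1` rows are known, correctly-labeled positives (|P| of
them); `s = 0` rows are unlabeled (|U| of them), an unknown mixture of
hidden positives and negatives. The central estimand is α, the fraction of
the unlabeled set that is truly positive. α is not the class prior: with
label frequency `p(s=1|y=1)` constant,

    p(s=1) = |P| / (|P|+|U|),
    p(y=1) = (|P| + α|U|) / (|P|+|U|),
    p(s=1|y=1) = |P| / (|P| + α|U|).

Two labeling mechanisms are supported. Under **SCAR** (selected completely
at random) the labeled positives are an i.i.d. sample of all positives.
Under **SNAR** (selected not at random) the positive class has subclasses
whose proportions differ between the labeled and unlabeled sets — e.g.,
severe disease presentations are diagnosed (labeled) more often — so no
single rescaling of the labeled-positive distribution matches the hidden
positives.

Both estimators assume (1) labeled examples are true positives, and (2)
every hidden-positive subclass has support among the labeled positives.
Violations of (2) produce underestimates.

## SCAR estimation

A gradient-boosted tree classifier is trained with stratified five-fold
cross-validation treating labeled positives as class 1 and unlabeled as
class 0; every row receives a strictly out-of-fold class-1 probability.
The positive class is weighted by |U|/|P| during training to counter
imbalance; weights never touch the reported probabilities.

Densities of the positive scores (D_p) and unlabeled scores (D_u) are
estimated with a beta-kernel estimator on a grid of `n_bins` equispaced
points spanning [0, 1]: at grid point z the kernel is the Beta pdf with
`a = 1 + z/bw`, `b = 1 + (1−z)/bw`, averaged over the data. The beta
kernel is supported exactly on the unit interval and is nonnegative
everywhere — the property the estimator depends on, and the reason
Gaussian kernels (which leak mass past the boundaries and can go negative
in fast polynomial approximations) are excluded from the estimation path.
A caveat discovered during validation: the kernel's integral over the
evaluation grid is not exactly 1 and drifts with bandwidth (≈0.8–1.22 at
bw = 0.5); near the bandwidths the selector actually chooses (≲0.06 at
these sample sizes) mass is conserved to within 5%.

Since D_u = αD_p + (1−α)D_n with D_n ≥ 0, every admissible α satisfies
αD_p ≤ D_u, bounding α by α_max = min_i D_u[i]/D_p[i] over bins with
D_p[i] > 0. The estimator scans

    f(α) = log(|min(D_u − αD_p)| + ε),
    ε = |min(D_p)| if min(D_p) ≠ 0 else 1e-10,

over α ∈ [0, 1] in steps of 1e-4. As α crosses the admissible boundary
the minimum difference passes through zero and f dips sharply. The
reported α̂ is the grid point where the finite-difference slope of f
changes most (`max_slope_change`); for curves with several dips, the
first slope-change peak whose magnitude is at least half the global
maximum (`first_sharp_change`) — any later dip implies a negative implied
negative-density D_u − αD_p. The slope change is a second difference
attributed to the grid point between its two slope segments, so α̂ = 0 is
never returned; ties break toward the smaller α.

### Numerical choices

- **Bin count.** Five classical rules are implemented (square root,
  Sturges, Rice, Scott, Freedman–Diaconis); counts are rounded up and
  floored at 2, and Scott/FD fall back to the square-root rule on zero
  spread. The package default is **Scott's rule**. On bimodal PU score
  distributions Scott gives a coarse (~15–25 bin) histogram whose
  MSE-matched bandwidth lands mid-range (~0.03–0.06), producing the
  smooth densities the method's geometry needs; the square-root rule at
  n ≈ 8,000 gives ~90 noisy bins, drives the bandwidth to its 0.01 floor,
  and makes the bin-wise minimum ratio erratic.
- **Bandwidth.** Chosen in [0.01, 0.5] by seeded differential evolution
  (population 8, ≤20 iterations, tolerance 0.01 — ample for a 1-D,
  smooth objective) minimizing the mean squared error between the
  beta-kernel density and the histogram density on the shared grid. The
  Jensen–Shannon distance is available as an alternative error metric but
  is not used by default. If the optimizer reports non-convergence the
  best-seen bandwidth is returned with a warning.
- **Grid convention.** The shared grid includes both endpoints 0 and 1;
  the histogram density is evaluated at a grid point by taking the
  density of the bin containing it (bins right-open, the last
  right-closed).
- **Far-tail masking.** The bin-wise minimum (and hence ε and α_max) is
  evaluated only at grid points where D_p is at least 5% of its own
  peak. Bins below that floor are far-tail kernel extrapolation; when
  the labeled positives' score tail extends past the largest unlabeled
  score — common in clustered sub-problems with a few hundred positives
  against thousands of unlabeled examples — the near-zero ratios in
  those bins would collapse both the admissible α and the noise floor ε,
  letting a spurious near-zero dip win the selection. Bins with
  substantial D_p are always kept, including ones where D_u is genuinely
  near zero: there the vanishing ratio is exactly the evidence that no
  positives hide in that score range. Grid-level entry points retain
  full-grid behavior unless a mask is supplied.
- **Classifier defaults.** 100 trees, depth 6, learning rate 0.1, `hist`
  tree method, single-threaded. The learning rate is set below the
  library default because α estimation consumes the score *distribution*:
  coarse fits leave the distribution lumpy and roughly triple the
  per-seed scatter of α̂ at large α. No tuning beyond these fixed
  defaults is performed.
- **Degenerate inputs.** If both classes' scores each collapse into a
  single histogram bin the estimator raises (no usable signal). All-zero
  gain vectors and single-class calibration labels degrade to warnings
  with well-defined outputs.

## SNAR estimation

Clustering converts a SNAR problem into several approximately-SCAR
sub-problems. A boosted-tree model fit on the full PU labels supplies
per-feature gain scores; labeled positives are represented by the
features with positive gain, each scaled by its gain, and clustered with
full-covariance Gaussian mixtures (EM, ≤250 iterations, 3 seeded
initializations). Candidate counts 1..max_c (default 25) are scored by
BIC, and the count is chosen at the **knee** of the BIC curve: for each
interior candidate, the bend π − angle between the vectors to its two
neighbours in (count, min-max-normalized BIC) space, restricted to
concave (positive-second-difference) points; the sharpest bend wins, ties
toward fewer clusters, and a curve with no concave interior point falls
back to 2. Because the first candidate cannot form a knee the procedure
never returns one cluster — on genuinely SCAR data this overestimates α
(each near-identical positive subtype is counted more than once), which
is inherent to the design.

Clusters smaller than 20 members are merged into their nearest cluster
(by centroid distance in the scaled space) rather than dropped, keeping
the α sum meaningful.

Each cluster then gets a full SCAR run — classifier retrained with
five-fold CV on that cluster's positives plus *all* unlabeled examples,
bandwidth re-estimated from those scores — and the total is the sum
α̂ = Σ_j α̂_j (reported raw even if > 1; clipped only where a probability
is required). Per-cluster runs default to `first_sharp_change` selection:
their objective curves are the multi-dip case by construction, since the
unlabeled set still contains every *other* subclass's hidden positives,
which produce later, larger dips that the max-slope-change rule would
double-count across clusters.

## Calibration

Scores from a PU-trained classifier underestimate p(y=1|x) because every
unlabeled example was treated as negative. Given α̂, calibration flips
round(α̂|U|) unlabeled labels from 0 to 1 so the flipped set matches the
labeled positives' score histogram over 100 equispaced bins: per-bin
targets α̂|U| × (positive bin mass), integerized by largest-remainder
apportionment so the total is exact; bins are processed from the top
score bin downward, flips within a bin drawn uniformly at random
(seeded), and demand exceeding a bin's population carries into the next
lower bin. If demand survives below the lowest populated bin (possible
when the positive histogram has mass where no unlabeled example sits) it
is placed on the highest-score unflipped examples, keeping the flip count
exact. An isotonic (default) or logistic fit of the flipped labels on the
raw scores yields calibrated probabilities; isotonic regression preserves
the training-label mean, so calibrated probabilities sum to ≈ α̂|U| over
the unlabeled set (scope "U") or ≈ |P| + α̂|U| when positives are
included in the fit (scope "PU").

Under SNAR each cluster calibrates the unlabeled scores against its own
α̂_j, and an unlabeled example's c per-cluster probabilities combine as
p = 1 − Π_j(1 − p_j) — one minus the probability of belonging to none of
the subclasses. Labeled positives use only their own cluster's
calibrator.

## Classification improvement

With calibrated unlabeled probabilities in hand, the top round(α̂|U|)
unlabeled examples are relabeled as probable positives (ties at the
cutoff break by row order) and a second classifier of the same
configuration is retrained with five-fold CV on the updated labels. When
ground truth is available the retrained out-of-fold probabilities are
scored with accuracy, AUC-ROC, Brier score, F1, Matthews correlation,
and average precision; thresholded metrics use 0.5 by default
(configurable, and echoed in every report). The retraining fold split
reuses the caller's seed, so α = 0 reproduces the plain baseline exactly.

## Synthetic data

The generators emulate the hypercube-cluster construction used by
standard classification-benchmark generators, fully specified in-repo:
every class (negative, and each positive subclass) is a Gaussian cluster
whose centroid is a distinct random vertex of
{−class_sep, +class_sep}^n_informative; each cluster's informative block
is multiplied by its own random uniform[−1, 1] mixing matrix (giving each
cluster a distinct full covariance); remaining features are unit noise.
Defaults: 50 features, 30 informative, class_sep 0.3 — the study's
"difficult" setting. The per-cluster covariances are essential: with
identity covariances the five SNAR subclasses are unrecoverable by
full-covariance GMM at class_sep 0.3 (BIC increases monotonically,
no knee), whereas distinct covariance shapes are exactly what model-based
clustering detects.

SCAR datasets hide k% of the unlabeled set as positives from the same
cluster as the labeled positives. SNAR datasets split labeled positives
equally across subclasses while hidden positives follow the proportions
1/31, 2/31, 4/31, 8/31, 16/31 (largest-remainder integerized, which
reproduces the canonical worked example 39/77/155/310/619 hidden
positives and 4,800 negatives for |U| = 6,000, k = 20). Benchmark-style
injection flips m = round(k|U|/(100−k)) positives into the unlabeled set
so the final hidden fraction is k%.

What the generator does **not** emulate: real tabular quirks —
missingness, mixed types, label noise inside the positive set, covariate
shift between labeled and hidden positives beyond the subclass mechanism.
Passing tests therefore demonstrate correct behavior of the estimators
under their stated assumptions, not robustness to assumption violations.

## Problem sizes used by the test suite

The validation experiments use the standard recipe of 2,000 labeled
positives and 6,000 unlabeled examples at class_sep 0.3. Reducing the
data size is not a safe way to shorten these experiments: at half scale
the SCAR estimator's sampling scatter alone exceeds the tolerance being
checked at large fractions, and 1,000 labeled positives are too few for
full-covariance BIC to resolve the five subclasses (the knee collapses
to two clusters). The suite therefore keeps the full recipe scale and
meets its runtime budget through seed counts: ten seeds for the
cluster-structure batch at the 20% fraction, six seeds for the SCAR and
SNAR recovery means at the other fractions, and five for the
classification-lift comparison, which runs at moderately reduced sizes
(800/4,000 SCAR, 1,000/2,500 SNAR) since it checks a direction, not a
tolerance. Exact sizes are in `tests/test_acceptance.py`.

## Known limitations

- PULSCAR's α̂ is an upper-bound-style estimate; finite samples and
  support gaps between labeled and hidden positives push it up or down a
  few hundredths, with larger *relative* error at small α.
- Over-clustering is only partially benign. When the mixture model is
  forced past the true subclass count, a subclass split across two
  clusters is double-counted — two near-identical positive groups cannot
  be told apart, and each claims the subclass's hidden mass. On the
  five-subclass recipe, forcing two extra clusters raised the summed
  estimate by ~0.08. The BIC knee normally prevents this by not
  over-splitting, but a forced or mis-detected count inflates α.
- The knee procedure never returns one cluster, so SNAR estimation on
  SCAR data overestimates; choosing between the two estimators is the
  caller's responsibility.
- The calibration sum constraints hold exactly only for isotonic fits;
  logistic calibration matches means only approximately.
- Confidence intervals come from repeated seeded runs (normal
  approximation, mean ± 1.96·SE) at the CLI level; single runs carry no
  uncertainty estimate.
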