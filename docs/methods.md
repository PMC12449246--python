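# Methods

## The selection problem

Quantitative omics matrices carry a large fraction of features that barely
vary across the samples of a given system. Their per-feature variance
distribution is right-skewed: a dominant near-zero mode (invariant
features, driven by sparse expression) and a long right tail. All methods in
this package treat the boundary of that near-zero peak as the natural,
data-driven selection cutoff; everything below it is noise for clustering
and classification purposes.

Scores are computed on a features × samples matrix with complete rows
(rows containing missing values are dropped at load, with a logged count)
and at least two samples. Variance uses the unbiased n−1 denominator.

## MAD cutoff

`cutoff = median(x) + mads × MAD`, with `MAD = median(|x_i − median(x)|)`.

* `mads` (default 2) plays the role of the "2 standard deviations" in
  classical outlier flagging; larger values push the cutoff further into
  the tail.
* The MAD is used with scale constant 1.0 — the literal robust-scale
  definition. `scale_constant=1.4826` recovers R's normal-consistent
  `mad()`; the default is the plain formula because the cutoff is a
  distributional landmark, not a normal-theory scale estimate.
* Selection keeps scores **strictly greater** than the cutoff, uniformly
  across all methods: ties at the cutoff sit at the edge of the near-zero
  peak and excluding them is the conservative reading. With a degenerate
  peak (median = MAD = 0) the cutoff is 0 and exactly the non-constant
  features survive.
* Medians of even-length vectors are the mean of the two central order
  statistics.

## Two-component mixture and the intersection cutoff

A univariate two-component normal mixture is fitted by EM. Initialization is
deterministic — means at the 10th/90th percentiles, equal weights, pooled
SD — so identical inputs give bit-identical fits; the seed only perturbs the
up-to-3 restarts triggered when a component SD collapses below the floor
1e−6 × robust data scale (1.4826 × MAD, falling back to the plain SD when
the MAD is zero). The floor is based on a robust scale because heavy-tailed
scores — ε-floored bio/tech ratios in particular — inflate the plain SD by
orders of magnitude, which would place the collapse floor above the
near-zero component's legitimate width and abort sound fits. Convergence is declared when the log-likelihood improves by less than
`tol` (default 1e−8, max 1000 iterations); the log-likelihood is
non-decreasing by EM construction. Components are relabelled so μ₁ ≤ μ₂
(component 1 = near-zero peak).

The cutoff solves λ₁·φ(x; μ₁, σ₁) = λ₂·φ(x; μ₂, σ₂). In log form this is the
quadratic A·x² + B·x + C = 0 (coefficients in the README); when |A| < 1e−12
the variances are treated as equal and the linear solution
(μ₁+μ₂)/2 + σ²·ln(λ₁/λ₂)/(μ₂−μ₁) is used — the quadratic solution converges
to it continuously, which the tests check at σ-ratios 1 ± 1e−5.

Design choices:

* **Root selection.** Two crossings can exist; only the one inside
  (μ₁, μ₂) separates the two populations, so that root is the cutoff. If no
  real root lies in the open interval, the method raises an explicit
  no-intersection error carrying both roots (one component dominates the
  whole interval; the MAD cutoff is the suggested fallback). Equal means
  are rejected — such a mixture carries no boundary information.
* **Scale of fitting.** Default is the raw scores. An optional `log1p`
  transform (back-transformed with `expm1`) is available for very
  heavy-tailed variance distributions; off by default because the raw-scale
  fit is the primary definition of the method.
* The mixture assumes exactly two normal components; data with more
  structure (several variable regimes) will fold them into the tail
  component.

## Elbow and knee thresholds

* **Elbow**: scores ranked decreasingly, discrete second difference
  d[i] = s[i+1] − 2·s[i] + s[i−1] evaluated at every interior rank, elbow at
  the argmax (first index on ties), cutoff = score at the elbow rank.
  Decreasing ranking places the near-zero mass at the tail of the curve so
  the maximum-convexity criterion lands on the boundary of that mass.
* **Knee**: the Kneedle algorithm on the rank-vs-score curve: min–max
  normalize both axes, transform to canonical increasing-concave shape
  (convex/concave auto-detected by comparing the curve to its chord),
  compute the difference curve against the diagonal, and accept the first
  local maximum confirmed by the sensitivity-adjusted threshold
  (T = d(lmx) − S·mean(Δx), default sensitivity S = 1, the algorithm's
  published default). A curve with no confirmed local maximum (e.g. a
  straight line) yields an explicit no-knee result: the recorded cutoff is
  the minimum score, nothing is filtered, and `knee_found: false` is set in
  the provenance — the one deliberate exception to the strictly-greater
  selection rule.

## Mean–variance trend model

For each feature, mean and total variance are computed; a lowess regression
of variance on mean (span = fraction of features per local fit, default
0.3) is fitted across features, clamped at zero, and evaluated at each
feature's mean to give the technical component; the biological component is
the residual, so bio + tech = total exactly. The one-sided test of
H₀: bio ≤ 0 uses the delta-method standard error of a sample variance under
normality, SE = tech·√(2/(n−1)); where the trend is exactly zero the sign of
bio decides (p = 0 / 0.5 / 1). FDR is Benjamini–Hochberg across features.

This is an approximation of the parametric+loess hybrid used by
scran's `modelGeneVar`, not a replication: the trend family, weighting and
p-value machinery differ, and no numerical agreement with scran is claimed.
What is preserved is the contract: a non-negative smooth trend, an exact
bio/tech decomposition, calibrated null behaviour (under variance
independent of mean, ≈ 0 discoveries at FDR ≤ 0.05) and power against
variance inflation (5× spike-ins at n = 50 are recovered with recall > 0.9
in the tests). The bio/tech ratio uses an ε = 1e−8 floor in the denominator
to avoid infinities at tech = 0. Matrices with negative entries are shifted
so the global minimum is zero before trend fitting (variances are
unaffected).

## Workflow semantics

`madvar` dispatches on input type: 2-D input → filter the matrix and return
the outcome with the filtered matrix; 1-D input → return only the cutoff
value; a 1×n matrix is treated as a matrix with a warning. Must-genes are
retained regardless of score (absent must-genes warn, never fail), kept and
dropped lists preserve input order, and every outcome's provenance record
can reconstruct its cutoff exactly. Exploration mode attaches a Gaussian
KDE (Silverman bandwidth) of the scores on an even grid over [min, max]
with the cutoff annotated — plot-ready data rather than a rendered figure,
so the contract stays testable.

Refiltering an already-filtered matrix with the *same recorded cutoff*
keeps all features; recomputing a cutoff on the filtered matrix generally
moves it (the near-zero peak is gone), which is expected behaviour, not a
bug.

## Synthetic data

The generator emulates the structure the methods assume, with ground truth:

* Matrix: `frac_invariant` (default 0.7) of features are i.i.d.
  N(baseline = 5, 0.05²); the rest draw a true variance from Gamma(2, 1)
  and receive per-group mean offsets ~ N(0, group_effect_sd² = 1) across
  `n_groups = 4` sample groups. Group effects shift means only, so
  invariant/variable labels stay crisp. Default size 1000 × 40.
* Score vector: 60% from a N(0.05, 0.02²) peak truncated at 0, 40% from a
  Gamma(2, 1) tail, n = 5000 — the default conditions of the
  threshold-recovery simulations.

What it does **not** emulate: count noise and VST normalization,
mean–variance coupling of real RNA-seq, batch structure, correlated
features, TMT/phospho acquisition noise. Passing tests therefore show that
the thresholds recover a planted two-population variance structure, not
that they are optimal on any particular real dataset.

## Benchmark harness

Samples are clustered on their feature profiles by Ward hierarchical
clustering (Euclidean; scipy's Ward criterion) or PAM k-medoids
(deterministic classic BUILD + SWAP, written in-package because no
installed library provides PAM). Partitions are scored by:

* **connectivity** (lower better): for each sample, its L nearest
  neighbours (default L = 10, ties broken by sample index) contribute 1/rank
  when assigned to a different cluster.
* **Dunn index** (higher better): min between-cluster distance / max
  within-cluster distance; all-singleton partitions give +∞ with a warning.
* **BHI** (higher better): per cluster with ≥ 2 members, the proportion of
  within-cluster sample pairs sharing an annotation class, averaged over
  qualifying clusters (per-cluster-then-average convention; pooled-pair
  averaging would differ).

Supervised performance is the out-of-bag error of a scikit-learn random
forest (default 100 trees) refitted across 32 seeds; the forest is an
evaluation instrument, not a contribution, hence off-the-shelf.

## Problem sizes and numerical conventions

Simulations in the tests and the acceptance script use n = 5000 score
draws, matrices up to 2000 × 50, 20 seeds for threshold recovery and 32
random-forest seeds — large enough for the stated tolerances while keeping
the whole suite in seconds. Floating-point output is written with 10
significant digits; all randomness flows through explicit integer seeds via
`numpy.random.default_rng`.
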