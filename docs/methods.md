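# Methods

`histolearn` implements an active-learning workflow for classifying
histologic objects (segmented nuclei) from precomputed feature tables, plus
two microvascular phenotype metrics computed from the resulting
classifications: a clustering index for hyperplasia and a principal-curve
hypertrophy index. Segmentation and feature extraction are upstream and out
of scope; the package consumes their outputs (boundary files, an HDF5
feature store, label CSVs).

## Classification and confidence

The classifier is a random forest over the K × F feature store (sklearn's
`RandomForestClassifier` behind `train_forest`). Defaults follow the
configuration the workflow was designed around: N = 100 trees, maximum
depth 10, and mtry = round(√F) features considered per split (7 for the
48-feature panels typical of nuclear morphometry). Classes are encoded
+1 (positive, e.g. vascular endothelial nuclei) and −1.

Prediction confidence for object *i* is the absolute tree-vote margin

    c_i = | Σ_j t_j |,   t_j ∈ {−1, +1},

computed from raw per-tree votes (each tree's leaf-majority class,
extracted via `forest.apply`), **not** from ensemble-averaged
probabilities. c_i ranges over {0, …, N} with the parity of N; it is 0 at a
50/50 vote split and N at unanimity. The normalized form c_i/N ∈ [0, 1] is
used for heatmap thresholds. A tied vote (even N) is predicted negative:
positives are rare in the motivating use, so the conservative call is the
majority class; the confidence there is 0 either way.

Retraining is from scratch each iteration — with ≤ a few hundred labels a
forest fits in milliseconds, and from-scratch training keeps the loop a
pure function of (labels, seed).

## The label-update-predict loop

`run_learning_loop` iterates: train on current labels → predict the whole
store → select the k = 8 least-confident unlabeled objects (ties broken by
object id) → obtain their labels from the oracle → repeat, recording
held-out AUC each iteration when a validation label set is supplied.
Objects labeled IGNORE are excluded from training and never re-presented.
An optional candidate set restricts selection (used to keep held-out
validation slides out of training). A `strategy="random"` baseline draws
the k objects uniformly instead; it exists to quantify the efficiency gain
of uncertainty sampling. One master seed fans out (via
`numpy.random.SeedSequence`) to the forest seed and any sampling, so runs
are reproducible byte-for-byte.

Heatmap-based labeling is served by `build_heatmap`: each slide is binned
into square cells (default 512 px at base resolution) counting objects,
low-confidence objects (normalized confidence ≤ 0.25 by default) and
positive predictions per cell; `rank_slides` orders slides by their
fraction of low-confidence objects. Grid size and threshold are
config-exposed — the binned grid is this package's construction, chosen
over kernel smoothing for exact count conservation (cell counts always sum
to the slide's object count).

ROC/AUC (`evaluate_auc`) scores objects by the continuous positive vote
fraction votes⁺/N and integrates the ROC trapezoidally with tied scores
grouped, which makes the AUC equal to the Mann–Whitney concordance
probability with ties counted ½ (verified against an O(n²) oracle in the
tests).

## Clustering index (CI)

For positive-object positions x_1…x_K on a slide (in microns),

    CI(τ) = (1/K) Σ_i |{ j ≠ i : ‖x_i − x_j‖₂ ≤ τ }|,   τ = 50 µm default.

This is a Ripley's-K-style statistic with the density normalization and
edge corrections deliberately omitted: increased local density *is* the
hyperplasia signal, and objects at tissue edges are a vanishing fraction of
a whole slide. The self-pair (d_ii = 0) is excluded — CI counts
*neighbors*, so a fully dispersed pattern scores 0 — with `include_self`
available for the literal set definition. Patient-level CI pools nuclei
across the patient's slides (neighbors are only sought within a slide,
since slides have independent coordinate frames), i.e. a count-weighted
mean of per-slide indices.

The neighbor search uses `scipy.spatial.cKDTree` fixed-radius queries —
exact, not approximate; tests and the acceptance script verify exact
agreement with an O(K²) double loop up to K = 10⁴.

## Hypertrophy index (HI)

Nuclear hypertrophy is scored along a morphologic continuum modeled by a
principal curve in standardized (area, eccentricity, perimeter) space:

    f_i = g(λ_i) + e_i,

with g a 1-D curve. Each nucleus is scored by the arc length s_i from the
curve origin to its least-squares projection onto g; the curve is oriented
by two anchor nuclei (one normal-appearing, one hypertrophic) so that
larger s_i means more hypertrophic. A patient is summarized by

    HI = − (1/K) Σ (s_i − s̄)³ / [ (1/(K−1)) Σ (s_i − s̄)² ]^{3/2},

the negated sample skewness of its scores. A `literal_exponent` flag
raises the variance term to −3 instead — a published variant that is not
scale-invariant; the default is standard, dimensionless skewness (exponent
−3/2). The metric's orientation (whether larger or smaller HI denotes more
hypertrophy) is deliberately left to the caller; the package computes the
formula and documents the sign convention of the scores.

### Curve fitting

`fit_principal_curve` standardizes the three features to z-scores (they
have incommensurate units), initializes λ by projecting onto the straight
line through the anchors, then performs a Hastie–Stuetzle-style
expectation step: each coordinate is smoothed against the points' ordering
along the curve with a running-lines (local-linear) smoother, window =
`span`·n points (span 0.3 default), computed in O(n) via cumulative sums.
The smoothed sequence is decimated by rank to ≤ 200 vertices, the end
segments are extended by `stretch` (=2) times their own length (so points
beyond the data envelope project onto a real segment instead of piling up
on a terminal vertex), and all points are projected segment-wise onto the
polyline to obtain s_i.

Two deliberate departures from the textbook algorithm, found necessary in
development:

* **Rank abscissa.** The smoother's abscissa is the rank in the ordering,
  not the arc-length value. With a strongly skewed latent (most nuclei
  near the normal end), arc-length windows in dense regions span tiny
  parameter ranges and the local slope estimate destabilizes; rank windows
  give every fit the same leverage.
* **Frozen ordering (default).** The classical alternation re-derives the
  ordering from each new curve. On skewed latent densities this lets the
  curve migrate along itself and fold through the dense bulk: in our
  simulations the latent recovery degraded monotonically from Spearman
  ≈ 0.98 after one pass to ≈ −0.8 at the self-consistent fixed point,
  with local-linear and penalized-spline smoothers alike. Since the
  anchors already pin the continuum's ends, the default
  (`freeze_ordering=True`) keeps the anchor-line ordering for the
  smoothing step; `freeze_ordering=False` restores the classical
  alternation with convergence on the relative change (`tol`) in mean
  squared projection distance, capped at `max_iter` (a non-converged fit
  returns the last iterate with a warning flag).

With the defaults, recovery of a hidden Gamma(4) latent on a quadratic
continuum at noise σ = 0.05 is Spearman 0.975–0.989 across seeds
(n = 2,000); noiseless data on a line is reproduced to machine precision,
and a noiseless curved continuum to Spearman ≥ 0.999 (ties at the curve
ends account for the remainder).

The curve is intended to be fitted once on a pooled cohort's positive
nuclei and then used to score any nucleus against the stored
standardization and polyline — per-patient curves would make scores
incomparable across patients.

## Synthetic data generator

`synthetic_data` produces feature stores, point patterns, labels and
latent-continuum populations with the statistical structure the learner
and metrics assume, so the whole pipeline is testable without any slide
data. What it emulates, and the defaults:

* **Rare positive class.** Prevalence 0.02, inside the 0.02–5.6% band
  observed for vascular endothelial nuclei in real cohorts. Positive count
  per slide is Binomial(n, prevalence).
* **Spatial clustering of positives.** A Neyman–Scott process: Poisson
  cluster parents uniform over the slide (count derived from a mean of 20
  offspring per parent, or from an explicit parent intensity), Gaussian
  offspring with σ = 10 µm — emulating the tight aggregation of
  endothelial nuclei in microvascular structures. Negatives are a
  homogeneous Poisson background. Slides are 10 × 10 mm at 0.5 µm/px.
* **Class-conditional features.** Gaussian with identity covariance; the
  class-mean difference has Mahalanobis norm `class_separation` (default
  3.0) carried by the first 8 of 48 features, mirroring real histomic
  panels where a subset of shape/intensity features separates the positive
  class and most texture features are uninformative. Parameterizing
  separability directly — rather than mimicking real feature marginals —
  is intentional: the learner's behavior depends on separability. At the
  default, the Bayes AUC is Φ(3/√2) ≈ 0.983 and a forest trained on *all*
  truth labels reaches ≈ 0.93–0.96 (majority voting under 2% prevalence
  coarsens the vote-fraction ranking), leaving genuine headroom for the
  labeling-efficiency comparison.
* **Benchmark split.** 5 slides × 10,000 objects; the last slide is held
  out, with a class-balanced validation label set (≤ 100 per class)
  sampled from it. Training-slide truth drives the labeling oracle.
* **Hypertrophy continuum.** λ_i ~ Gamma(shape 4, scale 1/4) — unit mean,
  closed-form skewness 2/√4 = 1, hence an expected HI of −1 for the latent
  itself — mapped through a fixed quadratic curve
  g(λ) = (λ, 0.8λ², 0.5λ − 0.3λ²) with isotropic Gaussian noise σ = 0.05.
  Anchors are the minimum- and maximum-latent nuclei.

Every generator is a pure function of (config, seed).

What the generator does **not** emulate — and therefore what passing tests
do not show about real slides: realistic marginal distributions or
correlations of histomic features, segmentation errors and doublets,
staining/batch variation across slides, label noise from human annotators,
and boundary-polygon geometry (boundaries are synthesized only for format
round-trip tests). Results on the benchmark demonstrate correctness of the
machinery and the ordering of methods (uncertainty vs random sampling),
not absolute performance on tissue.

## Numerical choices and degenerate inputs

* Non-finite feature values are a load-time error, never imputed.
* Training requires both classes; single-class training or validation sets
  are errors with instructions, not silent degeneracies.
* CI of an empty pattern is defined as 0 with a warning; τ ≤ 0 is an error.
* HI requires ≥ 3 scores with nonzero variance.
* Zero-variance features are an error in curve fitting (standardization
  would divide by zero).
* Instance selection ties break by ascending object id; slide-ranking ties
  break lexically; both make runs reproducible.
* Fewer than k unlabeled objects yields all of them with a warning rather
  than an error, so a loop can run to label-set exhaustion.

## Benchmark problem sizes

The efficiency comparison (`histolearn.benchmark`) uses the default
benchmark (50,000 objects, 2% prevalence), 10 paired seeds, a held-out AUC
target of 0.95 and a cap of 40 iterations × 8 labels; a strategy that
never reaches the target is censored at the full budget (329 labels). The
acceptance script and test suite run these sizes end-to-end; brute-force
oracles (CI double loop, AUC concordance) run at K ≤ 10⁴ and n = 200
respectively, where exact comparison is cheap.

## Known limitations

* The forest's vote-fraction score saturates below the Bayes AUC under
  heavy class imbalance; no class weighting or resampling is applied,
  matching the plain-forest design.
* The principal curve is a polyline; curvature between vertices is not
  modeled, and scores for points beyond the stretched ends clamp to the
  curve's endpoints.
* Multi-user annotation merging, browser-based review, and survival or
  enrichment analyses downstream of CI/HI are out of scope.
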