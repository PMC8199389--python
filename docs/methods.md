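# Methods

`emocomp` implements a two-stage procedure for estimating organizational
competitiveness from employee physiology: (1) a from-scratch
one-dimensional convolutional neural network (1D CNN) classifies each
employee observation into one of four emotional states — neutral, happy,
excited, angry — from tabular demographic and wearable-sensor features;
(2) a Kohonen self-organizing map (SOM) with K-means codebook
partitioning groups organizations by their aggregate emotion profiles
and maps each group to a competitiveness category (high / moderate /
low).  Because the underlying study data are not deposited anywhere, the
package also contains a synthetic-data generator that reproduces the
study population's published statistical structure, so the whole
pipeline is testable end to end.

## Synthetic study population

Each observation carries: organizational rank (1–10), subject id,
gender, age (years), height (cm), weight (kg), BMI (kg/m²), blood volume
pulse (BVP, sensor units), galvanic skin response (GSR, sensor units),
skin temperature (SKT, °C), valence and arousal (circumplex scores,
1–10), and an emotion label.

Only per-class marginal moments (mean ± SD of age, BMI, BVP, GSR, SKT,
valence, arousal) and pairwise Pearson correlations were published, so
each emotion class is modeled as a **multivariate Gaussian** with the
published mean/SD vectors and the published correlation matrix.  Printed
pairwise correlations need not form a valid joint correlation matrix, so
the matrix is first projected to the nearest positive-semidefinite (PSD)
correlation matrix by iterated eigenvalue clipping with unit-diagonal
renormalization.  For all four published matrices the minimum
eigenvalues are already positive (0.27, 0.21, 0.47, 0.059), so the
projection is an exact identity and all sampling targets equal the
printed values.

Choices where the study is silent:

* **Class counts** at the default n=1200 are allocated by
  largest-remainder rounding of the published proportions, reproducing
  the published counts (neutral 320, happy 349, excited 295, angry 236)
  exactly.  Ranks follow the published per-rank counts and are shuffled
  independently of emotion.
* **Gender** is Bernoulli with the published male fraction (0.522);
  **height** is N(170, 10) cm and **weight** is back-derived from the
  sampled BMI so that BMI = weight/height² holds exactly (only BMI has
  published statistics).
* **Plausibility clipping** (after sampling): age ∈ [18, 70], GSR > 0,
  SKT ∈ [25, 40] °C, valence/arousal ∈ [1, 10].  Clipping slightly
  biases marginal means; the bias is negligible for every spot-checked
  quantity (< 0.013 for angry-class valence) but reaches ≈ +0.3 years
  for angry-class age, whose published mean (39.72, SD 14.38) puts ~6%
  of the Gaussian mass below 18.  The moment-recovery tests therefore
  compare against the closed-form clipped-Gaussian expectation rather
  than the raw Gaussian mean.
* **Augmentation** to ~5000 records is jittered resampling: added
  records are class-preserving resamples with Gaussian noise of
  0.05 × the empirical per-class per-feature SD, with weight re-derived
  from the jittered BMI.  The per-class share of added records follows
  the base proportions (largest remainder), so class proportions move by
  at most one record per class.
* **Feature encoding**: 13 model inputs in fixed order — rank, one-hot
  gender (2), age, height, weight, BMI, BVP, GSR, SKT, valence, arousal,
  and a scaled subject index — each standardized to zero mean / unit
  variance.  The published column list has 11–12 entries but the input
  layer is stated as 13 nodes; one-hot gender plus the subject index is
  this package's documented reconciliation.

What the generator does *not* emulate: temporal dynamics of emotion,
raw sensor waveforms, non-Gaussian marginal shapes, and any real
dependence between rank and emotion (rank is independent of emotion by
default).  Passing tests therefore demonstrate correctness of the
method's implementation under the published low-order statistics, not
classifier performance on real physiological recordings — the synthetic
classes are considerably more separable than real ones (e.g. happy vs
neutral GSR: 6.19 ± 0.05 vs 4.95 ± 0.07).

## The 1D CNN

The 13 standardized features are treated as a one-dimensional signal.
The network is `depth` convolutional groups — 1D cross-correlation →
ELU → average pooling by integer factor `tt` — followed by fully
connected layers to 4 output scores.  Per-sample loss is the sum of
squared errors against a one-hot target; optimization is plain
mini-batch SGD with learning factor ε.  Backpropagation is derived by
hand: deltas enter a conv group via full zero-padded convolution with
reversed kernels (the adjoint of the forward cross-correlation), pooling
backpropagates by zero-order upsampling scaled 1/tt times the ELU
derivative, weight sensitivities are valid cross-correlations of layer
inputs with deltas, and bias sensitivities are delta sums.  Every path
is validated against central finite differences (relative error < 1e−4)
across padding modes and pool factors.

Defaults and rationale:

| parameter | default | rationale |
|---|---|---|
| depth / kernel / ε | 5 / 7 / 0.0005 | the study's best grid configuration |
| padding | `same` | depth 5 × kernel 7 is geometrically impossible on a 13-sample signal with valid convolution; `valid` remains available and shape-checked |
| pooling | average, tt = 1 | zero-order upsampling in the published backward pass is the average-pooling adjoint; pooling is disabled on signals shorter than 2·tt |
| filters / hidden | 16 per group / one 32-unit layer | unpublished; consistent with the stated "compact network, < 50 neurons" design |
| output layer | affine (no squashing) | scores feed argmax and ROC directly |
| init | seeded uniform ± √(6/(fan_in+fan_out)) | standard for this activation family |
| epochs / batch | 100 / 32 | on the default synthetic data the holdout accuracy saturates by ~epoch 35 (99.8% by 15); 100 epochs leaves margin while keeping a 5-fold CV run to a few minutes on one CPU |
| plateau stop | rel. Δloss < 1e−6 over 20 epochs | guard for long runs |

Cross-validation is stratified 5-fold (scikit-learn `StratifiedKFold`,
seeded), with confusion counts and held-out scores pooled over folds;
one-vs-rest AUC uses the midrank (Mann–Whitney) estimator and the
macro AUC is the unweighted mean over classes present in the truth.
Divergence (non-finite loss) raises with the epoch index; in a grid
search a diverging configuration scores zero instead of aborting the
grid.  Ties in argmax prediction resolve to the lowest class index.

## The SOM and competitiveness categorization

The SOM consumes one 4-dimensional emotion-fraction profile per
organization, built from predicted per-employee emotions (an alternative
per-employee mode — one-hot emotion + scaled rank — is available from
the CLI).  Training presents inputs in a seeded cyclic order for `o`
iterations; at each step the best matching unit (BMU) is the
Euclidean-nearest node (row-major tie-break), and every node moves by
β(t)·γ(t)·(y − x) with β(t) = β₀·e^(−t/λ), α(t) = α₀·e^(−t/λ), and
γ = exp(−e²/2α(t)²) on Euclidean lattice distance e.  No hard
neighborhood cutoff is applied: γ itself suppresses distant updates.
Defaults: 10×10 rectangular lattice, o = 1000·n inputs, α₀ =
max(rows, cols)/2, β₀ = 0.5, λ = o/ln α₀ — standard Kohonen
heuristics.  Weights initialize uniformly inside the data's bounding
box, which, combined with the convex update, keeps weights inside the
input hull.  Quantization error (mean input-to-BMU distance) is recorded
before training and after every full pass.

The trained codebook is partitioned into k = 4 clusters by seeded
K-means (20 restarts, best inertia; delegated to scikit-learn).  Each
organization receives its BMU's cluster, and its category comes from the
dominant emotion of the cluster centroid (mean member profile):
happy/excited → high, neutral → moderate, angry → low, with exact ties
broken pessimistically (angry > neutral > happy > excited).  The
independent rank rule (1–5 high, 6–8 moderate, 9–10 low) provides the
cross-check: on synthetic organizations constructed with rank-consistent
emotion mixes the two categorizations agree for ≥ 95% of organizations.

## Evaluation statistics and comparators

One-way ANOVA and Pearson correlations are delegated to
`scipy.stats`; confusion matrices and the midrank one-vs-rest AUC are
implemented in-package and cross-checked against scikit-learn and an
exhaustive pair-counting oracle.  Two comparator baselines mirror the
study's: a Gaussian-kernel SVM (kernel scale 2.5, i.e. γ = 1/2.5²,
one-vs-rest) and a RUSBoost-style ensemble (random undersampling to the
minority-class size, then AdaBoost over trees with ≤ 30 splits,
20 learners), both via scikit-learn and both evaluated on the same
seeded folds as the CNN.  Their published accuracies (83.5%, 71.4%)
were obtained on the unavailable real data and are not reproduction
targets: on the more separable synthetic data both comparators score
higher.

A statistical caveat worth stating: the published class BMI means
differ slightly (22.50–22.94), which at n = 1200 corresponds to a
noncentral F with λ ≈ 2.2 — a faithful generator draw yields BMI
p < 0.05 roughly 19% of the time even though the study reports BMI as
non-significant (p = 0.48).  The regression test therefore asserts the
stable form of the finding: BMI has the smallest F statistic of all
features and its median p across ten seeds exceeds 0.05.

## Problem sizes and determinism

Headline runs use the study-scale conditions: 1200 base records
augmented to 5000, 5-fold CV, 20000-record per-class samples for the
moment/correlation checks.  Property tests use small constructions
(2-layer networks for gradient checks, 6×6 lattices, ≤ 12-sample AUC
inputs, 1000-replicate ANOVA nulls).  Every stochastic component takes
an explicit seed; the pipeline fans per-stage seeds out of one master
seed via `SeedSequence`, and identical configuration + seed reproduces
byte-identical artifacts (verified by manifest hash in the tests).

## Known limitations

* Gaussian classes with clipping are an idealization; real physiological
  features are skewed and temporally autocorrelated.
* The 13-node input composition and the per-layer filter counts are
  this package's assumptions (the study does not state them), so grid
  accuracies are not comparable row-by-row with the published table.
* The SOM input representation (per-organization profiles) is an
  interpretation of the study's ambiguous description; the per-employee
  mode exists for comparison.
* With only 10 organizations at default settings, the SOM/K-means stage
  is heavily overparameterized (100 nodes for 10 inputs); it functions
  as a faithful mechanism reproduction, not a statistically necessary
  step — the direct dominant-emotion rule gives the same categories.
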