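# Methods

## Problem and design

`fracrisk` builds clinical decision-support classifiers for a heavily
imbalanced outcome: hip/vertebral fracture (≈ 9.7% prevalence) in adult
patients on inhaled corticosteroids, predicted from 20 candidate variables
(sex, age, eight comorbidity flags, and ten corticosteroid dose/duration
variables).  The pipeline is

1. a stratified **independent-training-and-testing (ITT) split**: each
   class contributes `floor(n_class / 2)` records to training; the test
   half keeps the natural class imbalance and is touched exactly once;
2. **undersampling** of the majority (non-fracture) class of the training
   half — random, cluster-based kNN, or one-sided selection;
3. a **genetic-algorithm wrapper** that simultaneously selects a feature
   subset and tunes a soft-margin RBF-kernel classifier, scored by a
   cost-sensitive cross-validated objective;
4. **evaluation** on the untouched imbalanced test half (AC, SE, SP,
   G-mean = √(SE·SP), AUC).

## Undersampling

All three samplers leave minority records byte-identical and operate in
Euclidean distance on features standardised to zero mean/unit variance over
the input table; binary flags are standardised identically so that the
dose columns (range ~10³) cannot dominate.  Nearest-neighbour and
nearest-to-centroid ties break toward the lowest record index, and a record
is never its own nearest neighbour; among duplicated feature vectors the
lowest index is the neighbour.  These conventions make every sampler
deterministic given its seed.

* **Random**: m majority records drawn uniformly without replacement
  (m = minority count) — a balanced 2m-record set.  When the majority does
  not outnumber the minority the input is returned unchanged (with a
  warning if it is actually smaller).
* **Cluster-based kNN**: the M majority records are partitioned into
  exactly m clusters of size ⌊M/m⌋ or ⌊M/m⌋+1.  No off-the-shelf clustering
  enforces that size constraint, so the partition is built as seeded
  k-means++ (scikit-learn) followed by a deterministic repair: the r = M
  mod m currently-largest clusters receive capacity ⌊M/m⌋+1 and the rest
  ⌊M/m⌋; each over-full cluster then gives up its farthest-from-centroid
  members, one at a time, to the nearest cluster with spare capacity, with
  centroids held fixed during the repair.  The record nearest each final
  cluster's centre of gravity is kept.
* **One-sided selection** (Kubat–Matwin): grow a 1-NN-consistent subset
  from all minority records plus one seed-chosen majority record, scanning
  majority records in input order and adding the misclassified ones; then
  remove every majority member of a Tomek link (cross-class mutual nearest
  neighbours) of the condensed subset.  The Tomek step re-standardises
  within the condensed subset, since that subset is the table the link
  definition sees.

## The wrapper

A chromosome is a 20-bit feature mask plus two bounded real genes decoded
as base-2 exponents: cost C = 2^α and RBF width γ = 2^g, α, g ∈ [−25, 25].
The exponent reading is interpretive — published optimal values such as
25.0/−25.0 sit exactly at that bound — and gives the search a scale-free
hyperparameter space.  Fitness is the objective evaluated on the *pooled*
held-out predictions of a stratified ten-fold plan that is frozen per
search, so all chromosomes face identical folds and fitnesses are
comparable; per-fold standardisation is learned on the nine training folds
only.  The two objectives are

* `OB1 = AC − |SE − SP|` — accuracy penalised by the
  sensitivity–specificity gap (the balance-seeking objective), and
* `OB2 = AUC` of the pooled continuous decision values.

Each generation fully replaces the population: n/2 offspring from uniform
mask crossover with random convex combination of the real genes, and n/2
mutants (per-bit flip rate 0.05, additive N(0, 1) on real genes, clipped to
bounds), parents chosen by binary tournament.  Empty masks are repaired by
setting one random bit.  The best-so-far chromosome is archived outside
the population; its trace is therefore non-decreasing, and the archive
defines the final model, refitted on the whole (undersampled) training set.
Defaults: population 10, stop after 500 generations without improvement or
100 000 generations in total.

Numerical choices: the classifier backend is scikit-learn's `SVC`;
predictions are defined as the sign of the decision value (threshold 0), so
predicted labels and ranking scores are always consistent; the libsvm
iteration count is capped at 5000 so extreme-cost chromosomes (C up to
2^25) cost bounded time — at the training sizes used here the cap binds
only in the degenerate corner of the search space.  Duplicate chromosomes
within one search are memoised.

## Synthetic cohorts

The study extract is not public, so a generator emulates its published
class-conditional structure: Bernoulli labels (prevalence 0.097),
class-conditional Bernoulli sex/comorbidity flags, truncated-normal age on
[20, 100] (means 58.5/70.5, SDs 18.1/12.5 by class), and log-normal
dose/duration variables with (μ, σ) solved from each published (median,
mean) pair: μ = ln median, σ = √(2 ln(mean/median)).  The published SD is
treated as a diagnostic only — a two-parameter family cannot match mean,
median and SD at once.  One published row (fracture-class ICS follow-up
duration) prints a median above its mean, which no log-normal admits; its
default median is instead the value implied by the published (mean, SD)
under the log-normal family, 1533.9 days.

The four daily-dose columns are computed as dose/duration ratios, never
sampled, matching their definitions.  The two durations of a drug are
driven by one shared standard-normal draw per record (comonotone
coupling): both log-normal marginals are preserved exactly while
exposed ≤ follow-up holds almost surely (the < 1% upper-tail crossings are
clipped).  Naive per-record rejection would bias the exposed-duration mean
by ~50% and was rejected for that reason.

An effect-size multiplier rescales the fracture-class parameter of chosen
columns toward the non-fracture value (`yes' = no + multiplier·(yes −
no)`); at 0 the classes are exchangeable and no classifier can beat
AUC 0.5.  Only sampled columns are dialable — the daily-dose ratios
inherit their gap from dose and duration, so dialling them directly would
be ill-defined.

What the generator does *not* emulate: any dependence between variables
beyond class-conditioning (only marginals are published), longitudinal
prescription structure, and coding noise.  Because features are
class-conditionally independent, the synthetic cohort is considerably
*more* separable than the real one (test AUC ≈ 0.92–0.96 versus the
published ≈ 0.75), so passing behavioural tests demonstrate the pipeline's
mechanics — balance-seeking of OB1, failure modes of one-sided selection,
feature recovery — not real-data performance levels.

`validate_cohort` audits a generated table against every generator target
(prevalence, per-class proportions, age means, dose/duration means and
medians) with tolerances of five standard errors of each estimator
(delta-method SE for log-normal medians), plus a 2% relative floor for the
heavy-tailed means.

## Statistical comparisons

Group tables (fracture vs non-fracture) use Pearson's chi-square without
continuity correction for binary variables and the unpaired equal-variance
Student's t-test for continuous ones, significance at p < 0.05.  Both
choices follow the original analysis naming; the uncorrected chi-square is
stated explicitly so small printed-p discrepancies are explainable.

## Problem sizes and reproducibility

Everything is deterministic given seeds: the split, the samplers, the fold
plan, the GA stream, and libsvm.  The test and acceptance runs use
scaled-down study conditions chosen once: 2000-patient cohorts (≈ 97
minority training records after the split, balanced sets of ≈ 194), GA
population 10, at most 300 generations with early stop after 25 unimproved
generations, ten-fold fitness throughout; the generator audit runs at
n = 20 000.  At these sizes one GA search takes roughly half a minute on a
single CPU.

Known limitations: the GA is a stochastic heuristic — different seeds give
different feature subsets of similar fitness (the published models also
disagree across samplers); the independence assumption above; and OB1's
gap penalty can prefer trivially balanced random-like models when the data
carry no signal at all.
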