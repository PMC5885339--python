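# fracrisk

Clinical decision support for a heavily imbalanced outcome: predicting
hip/vertebral fracture in adult patients treated with inhaled
corticosteroids (ICS), where only ≈ 9.7% of patients are cases.  The
package is aimed at biostatisticians and ML practitioners working with
imbalanced clinical tables: it implements the full design pipeline —
undersampling, wrapper-based model search, cost-sensitive fitness, and
independent-test evaluation — together with a synthetic cohort generator
that emulates the published class-conditional structure of the original
(non-public) national-insurance extract, so everything is runnable and
testable without any data download.

## Method

Patients are described by 20 candidate predictors (sex, age, 8 comorbidity
flags, and 10 corticosteroid dose/duration variables).  The pipeline:

1. **ITT split** — a stratified 50/50 split; the test half keeps the
   natural 1:9 imbalance and is evaluated exactly once.
2. **Undersampling** of the majority class of the training half:
   *random* (m majority records drawn uniformly, m = minority count),
   *cluster-based kNN* (majority partitioned into m equal-size clusters,
   ⌊M/m⌋ or ⌊M/m⌋+1 records each; the record nearest each centre of
   gravity is kept), or *one-sided selection* (1-NN condensation plus
   Tomek-link cleaning; minority records are never touched).
3. **GA–SVM wrapper** — a genetic algorithm over chromosomes
   (20-bit feature mask, α, γ ∈ [−25, 25]) decoding to a feature subset
   and an RBF soft-margin classifier with cost C = 2^α and kernel width
   2^γ.  Fitness is a ten-fold cross-validated objective on pooled
   held-out predictions:

   * `OB1 = AC − |SE − SP|` — accuracy penalised by the
     sensitivity–specificity gap,
   * `OB2 = AUC`.

   Each generation replaces the population with n/2 crossover offspring
   and n/2 mutants (n = 10); the search stops after 500 unimproved or
   100 000 total generations (defaults).
4. **Evaluation** — AC, SE, SP, G-mean = √(SE·SP) and AUC on the untouched
   imbalanced test half; Table-style reports; chi-square / t-test group
   comparison utilities for cohort description.

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

```python
from fracrisk import (default_params, generate_cohort, itt_split,
                      random_undersample, GAParams, ga_search,
                      evaluate_model, fmt_pct, fmt_frac)

params = default_params(seed=5)          # published-table defaults
params.n_patients = 2000                 # scaled-down cohort
cohort = generate_cohort(params)
split = itt_split(cohort, 0.5, seed=5)   # stratified 50/50
balanced = random_undersample(split.train, seed=5).sampled

model = ga_search(balanced, "OB1",
                  GAParams(population_n=10, max_not_improved=25,
                           max_iteration=300, seed=5))
m = evaluate_model(model, split.test)
print(f"selected {len(model.selected_features)} features, "
      f"alpha={model.alpha:.1f}, gamma_exp={model.gamma_exp:.1f}")
print(f"test AC% {fmt_pct(m.ac)}  SE% {fmt_pct(m.se)}  SP% {fmt_pct(m.sp)}  "
      f"G-mean {fmt_frac(m.gmean)}  AUC {fmt_frac(m.auc)}")
```

prints

```
selected 11 features, alpha=17.3, gamma_exp=-10.7
test AC% 88.11  SE% 91.67  SP% 87.68  G-mean 0.8965  AUC 0.9627
```

i.e. the OB1-trained model keeps sensitivity and specificity close
together on the imbalanced test half (91.7% of true fracture cases found
at 87.7% specificity).  Synthetic cohorts are substantially easier than
the real extract because features are sampled independently given the
class — absolute numbers are therefore higher than those published for
real data; the qualitative behaviour (balanced SE/SP under OB1, balanced
2m training sets, one-sided selection's failure to balance overlapping
data) is what carries over.

The same steps are available from the shell:

```sh
fracrisk generate --n 2000 --seed 5 --out cohort.csv
fracrisk sample --method random --seed 5 --in cohort.csv --out balanced.csv
fracrisk train --in cohort.csv --sampler random --objective ob1 --seed 5 \
               --max-not-improved 25 --max-iteration 300 --model-out model.pkl
fracrisk evaluate --model model.pkl --test cohort.csv
fracrisk compare --in cohort.csv --variables Age,COPD,OCS_dose
```

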