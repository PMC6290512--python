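# Methods

## Classification model

`hiermc` frames three-class severity staging under extreme imbalance as a
hierarchy of two subtasks.

**Coarse step (majority vs combined minority).** Let N₃ be the number of
stage-3 training records and N₄₊₅ the combined stage-4/5 count. The
partition count is `M = max(1, ⌊N₃ / N₄₊₅⌋)`. The stage-3 records are
shuffled once (seeded) and the first `M·N₄₊₅` of them are chunked into M
disjoint blocks; each block is paired with the complete minority set,
giving M balanced two-class sets. One base classifier is fitted per set —
model j seeded `seed + j` — and every record is re-represented as the
M-vector of the base classifiers' hard labels. A categorical naïve-Bayes
meta-classifier over these M label features makes the coarse decision.
With priors `P(c) = N_c/N` and Laplace-smoothed conditionals

    P(Cⱼ = v | c) = (count(Cⱼ = v, class c) + α) / (N_c + α·|V|),  α = 1,

the prediction is the argmax of `log P(c) + Σⱼ log P(Cⱼ = v | c)`,
computed in log space. Exact ties resolve to the combined minority class:
in risk stratification the false negative (missing an advanced-stage
case) is the costly error.

**Refinement step (4 vs 5).** Records the coarse step assigns to the
combined class are split by a single two-class classifier trained on the
*true* stage-4/5 training records, under the original feature vectors.
The residual 4:5 imbalance (≈2:1) is mild and left untouched by default;
`balance=True` reuses the balanced-partition + naïve-Bayes machinery
between the two stages instead.

**Base classifiers.** Four families are supported (random forest,
logistic regression, Gaussian naïve Bayes, decision tree), delegated to
scikit-learn. The default is a 100-tree random forest with unlimited
depth — the family that dominates the alternatives in our benchmark runs
as well. The ensemble architecture, the label re-representation and the
meta naïve Bayes are implemented in this package; base classifiers are
deliberately ordinary.

**Meta-training data.** The naïve-Bayes meta-classifier is trained on the
label vectors of the full (imbalanced) training set, including majority
records left over when N₃ is not divisible by M·N₄₊₅. Base classifiers
are therefore applied to records they may have seen during their own
training, which can make the meta features optimistic. No held-out
meta-training split is used by default; an `out_of_fold` mode replaces,
for each majority record in block j, the in-sample entry j with the
prediction of model (j+1) mod M. Minority records appear in every
balanced subset, so strict out-of-fold labels do not exist for them —
this residual optimism is a known limitation of the out-of-fold mode.

**Partitioning variants.** Disjoint partitioning is the default; a
`resample` mode draws each majority block independently without
replacement (blocks may then overlap across subsets). The two schemes
coincide in expectation for the balanced-set sizes but differ in how
majority information is spread across base classifiers.

## Comparator strategies

All strategies share one fit/predict contract:

- `baseline_oaa` — one multiclass classifier, no imbalance handling.
  Logistic regression is decomposed one-against-all; forests, naïve Bayes
  and trees use their native multiclass handling.
- `under_sampling` — every class down-sampled without replacement to the
  smallest class size (a flag restricts down-sampling to the majority
  class only, to the combined minority size).
- `smote` — minority classes over-sampled to the majority size by SMOTE
  in its original published form: each synthetic record is
  `x + u·(x′ − x)` with `u ~ U(0,1)` and `x′` one of the k = 5 nearest
  within-class neighbours of `x` under Euclidean distance. Implemented
  here directly (neighbour search via scikit-learn); a class smaller than
  k+1 records is rejected with a pointer to a smaller k.
- `simple_mc` — the non-hierarchical meta-classifier: the same balanced
  partition (majority vs pooled rest), but base classifiers keep the
  three original labels and the naïve Bayes predicts directly among
  {3, 4, 5} (ties toward the more severe stage).

## Evaluation

Metrics are one-vs-rest per class: specificity TN/(TN+FP), sensitivity
TP/(TP+FN), precision TP/(TP+FP), F-measure 2PS/(P+S). A 0/0 denominator
returns 0 with a logged warning — conservative, and keeps aggregates
defined when a tiny test set lacks a class. "Average" values are the
unweighted macro mean over the three stages; the published tables do not
state their averaging convention, and macro was chosen because single
three-class sensitivity/specificity/F triples are reported. Experiment
protocols refit each strategy `repeats` times with seeds
`base_seed + r`, re-drawing the balanced partition each time, against a
test set that never varies; means and standard deviations are reported
across repeats. The truncation protocol repeats the comparison for a
sequence of training windows that prune early years one at a time,
keeping the test year fixed.

## Synthetic cohort generator

The generator emulates the documented structure of the motivating EHR
cohort so the imbalance phenomenon is reproducible without clinical data:

| parameter | default | rationale |
|---|---|---|
| record-level stage proportions | 23/26, 2/26, 1/26 | the documented 23:2:1 ratio |
| visits per patient | 1 + Poisson(16) | mean 17 visits |
| age | Normal(70, 12) truncated to [18, 100] | documented mean (SD) |
| sex | 60% female | documented |
| visit years | uniform over a random active span in 2007–2015 | nine-year window, last year reserved for testing |
| features | 4 demographics + 4 vitals + 447 binary conditions | the 455 retained features |
| condition prevalences | log-uniform on [0.001, 0.2] | long tail of rare diagnosis codes |
| class signal | 30 conditions at odds ×4 for stages 4–5; 15 further at odds ×3 for stage 5; vitals shifted +0.8 SD (stages 4–5) and +0.5 SD more (stage 5) | makes the coarse and refinement tasks learnable but imperfect |
| incomplete-record rate | 0.228 | 27,521 of 120,739 records incomplete |

Stage is sampled per record (not per patient) so record-level proportions
are directly controllable; disease progression over a patient's visits is
deliberately not modelled. Missingness is MCAR: a selected record gets
1–3 blanked cells among the retained features. Setting the odds
multipliers to 1 and the vital shifts to 0 produces a null cohort with no
class signal. With `include_flagged_features` the schema carries the raw
495-feature layout: 33 medication columns and the seven disease-indicator
conditions, both flagged for exclusion (in the generator they are given
strong stage dependence — which is precisely why such features must be
excluded from a predictive model).

`study_replica` instead enforces the published per-year, per-stage
complete-record counts exactly (the per-year values are differences of
the published cumulative training windows), adds the documented number of
incomplete records by largest-remainder allocation across year×stage
cells, and synthesises features with the same machinery. It validates
splitting, counting and partition arithmetic against printed numbers; its
feature values remain synthetic, so no classifier metric measured on it
says anything about the original data.

The generator does **not** emulate: correlated comorbidity structure,
real diagnosis vocabularies, informative missingness, within-patient
stage progression, or calendar drift in coding practice. Passing tests on
synthetic cohorts therefore demonstrate the mechanics and the qualitative
imbalance phenomenon, not clinical performance.

## Reference benchmark and problem sizes

The standing demonstration (`hiermc.experiments.imbalance_benchmark`)
uses 1,200 patients (~20k records, ~16k after complete-case filtering),
training on 2007–2014 and testing on the fixed 2015 records, with 20
seeded repeats of each strategy — a desk-scale cohort chosen so the full
benchmark runs in minutes on one CPU while leaving the imbalance ratio,
visit structure and feature dimensionality at their documented values. On
this cohort the hierarchical meta-classifier's stage-4 and stage-5
sensitivities exceed the plain baseline's by a wide margin while the
across-repeat macro-metric standard deviation stays small; the exact
numbers for any seed come from `scripts/acceptance.py`. The published
headline metrics of the motivating study were measured on its private
clinical dataset and are not reproduced by this package.

## Numerical and degenerate-input choices

- Features are float32; binary indicators stored as 0.0/1.0. CSV
  round-trips preserve values exactly at float32 precision.
- Naïve-Bayes scores are summed in log space; no underflow for any M.
- Tie-breaking: combined class (coarse), stage 5 > 4 > 3 (simple MC).
- Empty test years are representable (a valid split) but rejected by the
  evaluation protocols.
- `compute_num_partitions` requires a nonempty minority and a majority at
  least as large; `build_balanced_sets` reports the exact shortfall when
  M disjoint blocks do not fit.
- Complete-case filtering judges missingness only on retained features; a
  record missing only excluded (medication / disease-indicator) values is
  kept.
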