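# hypoge

Grammar-guided evolution of interpretable hypoglycemia prediction rules
from continuous glucose monitoring (CGM) and smartwatch activity data.

## The problem

People with type 1 diabetes need to anticipate hypoglycemia — blood glucose
below 70 mg/dL — early enough to act. Black-box classifiers predict it well
but cannot be inspected, edited or explained to a clinician. `hypoge`
instead evolves **white-box if-then-else rules** over the last two hours of
four 5-minute-sampled channels (glucose `gluc`, heart rate `hr`, step count
`steps`, calories burned `cal`), predicting the class

&nbsp;&nbsp;&nbsp;&nbsp;`hyp(t + ph)` with `hyp ⇔ gluc(t + ph) < 70 mg/dL`,
`ph ∈ {30, 60, 90, 120}` minutes,

from lagged variables `gluc_s(t) ≡ gluc(t − s)`, `s ∈ {0, 5, …, 120}` min
(and likewise for the other channels). A decoded model is a boolean
condition such as

```
(2·gluc_0 − gluc_10 − steps_15 / gluc_5 < 86.861) && (1.654 > cal_0 − (cal_60 + 0.934/cal_60))
```

— readable, editable, re-testable.

## Method

Candidate rules are bred by **structured grammatical evolution (SGE)** and
its dynamic variant (**DSGE**). A BNF grammar defines the rule language;
the genotype is one integer list per nonterminal, each gene selecting a
production in leftmost depth-first derivation order.

* **SGE** removes recursion from the grammar up to a fixed *recursive
  depth* (levelled rule copies), sizes each list to the worst-case
  reference count of its nonterminal, and decodes deterministically.
* **DSGE** decodes on the recursive grammar, appending random genes on
  demand (repair) and capping derivation-tree depth: at the cap, recursive
  nonterminals are forced onto their shortest terminal completion.

Training minimises `fitness = 1 − WA` on a class-balanced training set,
where

&nbsp;&nbsp;&nbsp;&nbsp;`WA = 0.5·Accuracy + 0.5·F1`,&nbsp;&nbsp;
`F1 = 2·Precision·Recall / (Precision + Recall)`.

Reported test metrics are the per-class recalls `TPR = TP/positives` and
`TNR = TN/negatives` (hypoglycemia is the positive class). The data
pipeline follows the study design: per-timestamp 2-hour windows, discard of
any window with missing values, stratified 70/30 train/test split, random
undersampling of the training majority class to exactly 50/50.

Three model scopes share this recipe: **PM** (personal: one patient's
data), **GM** (general: all patients pooled) and **CM** (cluster: pooled
within K-means clusters of patients, characterised by the 4-vector of
average glucose rates of change `roc(w) = mean_t[(gluc(t) − gluc(t−w))/w]`
for `w ∈ {30, 60, 90, 120}` min, with elbow/silhouette/Davies–Bouldin
diagnostics for choosing k).

Because the original clinical data is not public, the package ships a
synthetic-cohort generator (5-minute grids, meal excursions,
activity-coupled glucose decline, sensor dropouts, controllable
hypoglycemia prevalence, optionally labels planted from a known rule) so
the whole pipeline is testable offline. See `docs/methods.md` for the
model details and design choices.

## Worked example

Evolve a rule for a synthetic patient whose hypoglycemia labels follow a
planted activity rule (`steps_0 > 150`, exercise-induced hypoglycemia):

```python
from hypoge.synthetic import SyntheticConfig, generate_cohort_with_planted_rule
from hypoge.expressions import parse_phenotype, default_grammar
from hypoge.glucodata import (SplitSpec, build_windows, stratified_split,
                              undersample_balance)
from hypoge.engines import EvolutionConfig, evolve
from hypoge.metrics import confusion

cfg = SyntheticConfig(n_patients=1, days_per_patient=14, seed=7)
cohort, rule = generate_cohort_with_planted_rule(
    cfg, parse_phenotype("steps_0>150.000"), ph=30)
ds = build_windows(cohort[0], ph=30)
train, test = stratified_split(ds, SplitSpec(seed=7))
balanced = undersample_balance(train, seed=7)
best, trace = evolve(balanced, default_grammar(),
                     EvolutionConfig(algorithm="DSGE", population_size=50,
                                     generations=100, seed=100))
rep = confusion(test.y, parse_phenotype(best.phenotype).predict(test.arrays()))
print("best rule:", best.phenotype)
print("train fitness:", round(best.fitness, 4))
print(f"held-out TPR={rep.tpr:.3f} TNR={rep.tnr:.3f} WA={rep.wa:.3f}")
```

Output:

```
best rule: steps_0>=117.676
train fitness: 0.0
held-out TPR=1.000 TNR=0.995 WA=0.983
```

The 14-day trace yields 3015 complete windows (7.3% hypoglycemia); the
balanced training set has 306 windows. The search recovers a step-count
threshold inside the planted margin: train fitness 0 means the rule splits
the balanced training set perfectly, and on the untouched test windows it
finds every hypoglycemia event (TPR 1.0) with 0.5% false alarms
(TNR 0.995).

The same workflow is available from the shell:

```bash
hypoge synth    --out raw --n-patients 24 --days 14 --seed 1
hypoge prepare  --data-dir raw --out prep --horizon 30 --seed 1
hypoge train    --data-dir prep --out models --scope GM --runs 30 --seed 1
hypoge evaluate --models-dir models --data-dir prep --out eval
hypoge report   --metrics-file eval/metrics.csv
```

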