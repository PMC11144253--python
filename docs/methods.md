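# Methods

This note documents the models, algorithms and design choices in `hypoge`,
in the order the pipeline runs them: rule language → decoding engines →
fitness → data pipeline → model scopes → synthetic cohorts → what the
tests do and do not show.

## The rule language

A classifier is a boolean condition over lagged clinical variables; a
window satisfying it is classified hypoglycemia. The default grammar
(`hypoge/data/hypo_grammar.bnf`, built by `expressions.default_grammar`)
generates fully parenthesised conditions:

* logical operators `&&`, `||` over
* relational comparisons `<`, `>`, `<=`, `>=` between
* arithmetic expressions `+`, `−`, `*`, `/` over variables and constants.

**Variable subsets.** Offering all 100 lagged variables (4 channels × 25
lags) would dilute the search, so each channel exposes a subset: glucose
keeps the prediction-time value and the previous 25 minutes on the 5-minute
grid (`gluc_0 … gluc_25`) — the newest trend carries most of the signal —
while heart rate, steps and calories keep a spread over the full 2-hour
history (`0, 15, 30, 60, 90, 120` min), where slower phenomena (a meal's
worth of calories, an exercise bout an hour ago) matter more than the last
sample. Subsets are caller-configurable, and
`expressions.select_lags_by_correlation` offers a data-driven alternative:
scan lags in increasing order and drop any lag whose absolute Pearson
correlation with an already-kept lag exceeds a threshold (default 0.9).

**Constants.** Constants are three-decimal literals assembled from digit
productions inside the grammar: a unit-scale shape `d.ddd` in [0, 10) and a
glucose-scale shape up to `hdd.ddd` in [0, 400), both available in every
numeric context (the grammar does not track which channel an operand came
from). Digit encoding was chosen over drawing random constants during
decoding because (a) decoding must be a pure function of the genotype —
both for reproducibility of a run and for the caching of fitness by
phenotype — and (b) integer-flip mutation on digit genes gives local moves
on constant values (flip the tens digit of a threshold), which is how
evolved thresholds are refined in practice.

**Protected division.** `x/0 → 1.0`. Steps and calories are legitimately
zero at rest and evolved expressions routinely divide by them; with this
guard every expression is total and finite on finite inputs.

**Precedence.** The serialized phenotype is fully parenthesised, so the
parser's precedence (`* /` over `+ −`, relational over `&&` over `||`)
only matters for hand-written rules; it follows the conventional rules.

## Decoding engines

Both engines map one integer list per nonterminal to a derivation,
consuming each nonterminal's genes in leftmost depth-first order.

**SGE** operates on the recursion-removed grammar. `remove_recursion(g, d)`
replicates every rule on a reference cycle into level copies `1..d`
(internal names `<expr@1>`; they never reach phenotypes); same-cycle
references at level `i` point to level `i+1`, and the deepest copy keeps
only the productions that leave the cycle. Mutual recursion is handled by
levelling every rule of the cycle component. The transformed grammar
generates exactly the derivations of the original that nest at most `d`
recursive expansions — this is checked against an exhaustive enumeration
oracle. List lengths come from `compute_stats`: `max_references[nt]` is the
worst-case number of expansions of `nt` in any single derivation (a
dynamic program over the acyclic grammar), so every gene vector decodes
without exhausting a list; unused tail genes are legal and simply never
read.

**DSGE** operates on the original grammar with growable lists. A missing
gene is appended uniformly at random and recorded (`appended`), so an
empty genotype decodes into a random full derivation — this is also the
population initialiser. Recursion is capped by `tree_depth`, counted as
nesting levels from the start symbol at depth 0: at the cap, a recursive
nonterminal is forced onto the production with the minimum derivation
height to an all-terminal string (ties broken by the run's generator), and
the forced gene is written into the genotype. A minimum-height production
can never re-enter its own cycle (it would then exceed the height of the
escape production), so forced decoding always terminates. Height is
computed by fixed-point iteration and cached per grammar object.

**Classic GE** (`decode_ge`, codon list + modulus rule with wrapping) is
included as a reference decoder for cross-checking, not used in training.

## Variation and the evolutionary loop

* **Mutation** — integer flip: each eligible gene is independently
  resampled uniformly over its valid range with probability 0.05. For DSGE
  only genes read during the last decode are eligible (mutating never-read
  tail genes would be silent); an individual fresh from crossover, whose
  usage is unknown, treats its whole lists as eligible.
* **Crossover** — applied with probability 0.7; a binary mask over
  nonterminals swaps whole per-nonterminal lists between the parents, each
  nonterminal with the *change probability*: 0.6 for SGE ("structured"),
  0.2 for DSGE ("uniform"). The per-nonterminal gene multiset across the
  pair is conserved.
* **Selection** — tournaments of size 2, lowest fitness wins, ties
  uniform.
* **Replacement** — elitist (μ+λ): the next population is the best
  `population_size` of parents plus offspring; fitness ties prefer
  offspring to inject novelty. Consequently the best-fitness trace is
  non-increasing.
* **Defaults** — population 100; 500 generations for 30/60-minute
  horizons and 800 for 90/120; recursive depth 3; tree depth 7; 30
  independent runs per training, run `r` seeded `seed + r`. All randomness
  flows through one numpy generator per run, so runs are bit-reproducible
  across processes.
* **Caching** — fitness is memoised by phenotype string within a run
  (identical re-decoded phenotypes are not re-evaluated); this is purely a
  performance device.

## Fitness

`fitness = 1 − WA`, `WA = 0.5·Accuracy + 0.5·F1`, minimised on the
balanced training windows. F1 is defined as 0 when the rule produces no
true positives, which keeps degenerate individuals comparable; genuinely
undefined ratios (precision with no predicted positives, TPR on a test set
without positives) are reported as NaN. On balanced data a constant
classifier scores WA = 0.25 (all-negative) or ≈ 0.58 (all-positive), so
selection pressure away from constants exists from the first generation.

## Data pipeline

Windows are built per timestamp with stride one sample (5 min): a window
at `t` needs the complete 2-hour history of all four channels and a
glucose value at `t + ph`; any missing value discards the window
(imputation is deliberately not performed). The label is
`gluc(t+ph) < 70`; exactly 70 mg/dL is non-hypoglycemia (the positive
class is *below* 70). Splitting is stratified 70/30 (scikit-learn);
undersampling keeps every minority window and subsamples the majority to
the minority count, giving exactly 50% positives. HbA1c is converted to
estimated average glucose by the ADAG regression
`eAG = 28.7·HbA1c − 46.7` mg/dL, rounded half-to-even (6.0% → 125,
7.0% → 154, 9.7% → 232).

## Model scopes

PM trains on one patient; GM pools all patients; CM pools within K-means
clusters. Pooling happens **after** per-patient balancing so each patient
contributes a 50/50 class mix regardless of prevalence. Patients are
clustered on the standardised 4-vector `(roc(30), roc(60), roc(90),
roc(120))`; standardisation prevents the longest window from dominating
Euclidean distances. `roc(w)` averages `(gluc(t) − gluc(t−w))/w` over the
pairs where both samples exist, and is computed on raw series from the
training period only. k is chosen as the smallest k minimising the summed
ranks of elbow curvature, silhouette (higher better) and Davies–Bouldin
(lower better); because that choice is ultimately judgment, `k` can be
overridden. Evaluation applies each of the 30 run-best rules to each
relevant patient's untouched, naturally imbalanced test split; suites
retain the training-window index so train/test disjointness is asserted at
evaluation time. With a single all-patient cluster and equal seeds, CM is
bit-identical to GM (same pooled data, same seed sequence) — a structural
regression check.

## Synthetic cohorts

The generator is phenomenological, not a physiological simulator; its
contract is statistical shape sufficient to exercise the pipeline:

* **Glucose** = baseline + circadian ripple + meal excursion kernels
  (linear 30-min rise, 90-min exponential decay, ~3 jittered meals/day,
  amplitude ≈ 70 ± 15 mg/dL) − activity-coupled decline (0.04 mg/dL per
  step, 40-min decay) + AR(1) noise (sd 20 mg/dL, 45-min correlation),
  clamped to [40, 400]; an optional linear drift models deteriorating or
  improving control.
* **Activity**: Poisson exercise bouts (~3/day, ~30 min, ~400 steps per
  5-min sample) plus light daytime movement; **heart rate** = 70 bpm +
  circadian ± 8 + 0.05·steps + noise; **calories** = 6 kcal/5 min +
  0.04·steps + noise.
* **Prevalence control**: the baseline is bisected until the fraction of
  time below 70 mg/dL hits a per-patient target; cohort targets span
  3–22%, matching a population in which some patients spend under 4% and
  others over 20% of time in hypoglycemia. Prevalence is monotone in the
  baseline, which the tests check.
* **Missingness**: contiguous all-channel dropout blocks (mean 40 min),
  matching how CGM sensors actually fail and exercising the discard rule.

**Planted rules.** `generate_cohort_with_planted_rule` nudges
`gluc(t + ph)` across the 70 mg/dL boundary so window labels follow a
known rule, returning the rule as a recovery target. Nudged values
re-enter later windows as history, so nudging iterates to a fixed point;
rules over lagged glucose can cascade (a nudged-low target becomes a
later `gluc_0` that re-fires the rule), which is why the recovery
experiments plant rules on the activity channel — `steps_0 > 150`,
exercise-induced hypoglycemia, whose bimodal distribution (rest ≈ 0–80
vs bouts ≈ 300+) also makes the planted concept identifiable with a wide
margin. The heterogeneous-cohort experiment plants contradictory
immediate- vs delayed-exercise rules (`steps_0 > 150` vs
`steps_60 > 150`) in two sub-cohorts with opposite glucose drifts
(±25 mg/dL/day over 14 days), so that roc clustering separates the groups
and per-cluster models can fit what no single general rule can.

**What passing tests do not show.** The generator has no insulin or
carbohydrate dynamics, no sensor error model beyond dropouts, and its
planted labels are (near-)noise-free; recovery results therefore
demonstrate correctness and identifiability of the machinery, not
clinical performance on real CGM data.

## Problem sizes and numerical choices

Test experiments are scaled to a laptop-class budget as the package's own
choice: recovery uses 2 patients × 14 days (≈ 600 balanced training
windows), DSGE with population 50 for 100 generations and 10 runs; the
cluster-vs-general contrast uses 4 patients and 2 runs per target. The
exhaustive decoder checks cover all genotypes of five ≤ 4-rule grammars;
DSGE fuzzing covers 1,000 random recursive grammars. Degenerate inputs
are rejected early with specific errors: single-class training sets,
classes with fewer than two windows (unstratifiable), k = 1 clustering
(silhouette undefined), recursive rules with no terminal escape (empty
language at finite depth). Ties are broken deterministically unless a
seeded generator is supplied (shortest-completion ties, tournament ties).

## Known limitations

* The grammar emits fully parenthesised conditions; evolved rules are not
  algebraically simplified, so readable-but-redundant subexpressions
  (`0.374 < steps_90`-style tautologies on clamped channels) survive.
* `roc` features are nearly zero-mean on stationary traces; clustering
  real cohorts on them is only informative when patients differ in drift,
  which the original study's private data apparently did and the synthetic
  contrast experiment reproduces explicitly.
* DSGE mutation is restricted to used genes; whether unused genes should
  also mutate is left as a documented choice (flag `used` on
  `Individual`).
* The CLI trains one scope per invocation and holds all windows in
  memory; cohorts of hundreds of patient-years would need chunked
  windowing.
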