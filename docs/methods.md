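# Methods

This note documents the model, the numerical choices, the synthetic data
generator, and the limits of what the test suite demonstrates.

## Model and loss

The network is `f_W(x, M) = tanh(tanh(x·(W1⊙M))·W2)` with `W1 ∈ R₊^{G×P}`,
`W2 ∈ R^{P×1}`. The hidden layer has one unit per pathway; masking the first
layer by the pathway incidence M makes each hidden pre-activation a
non-negatively weighted combination of that pathway's member genes — a
learned pathway activity. The non-negativity constraint encodes the modeling
assumption that a pathway's members act in a common direction on its
activity; protective vs deleterious orientation is carried by the sign of
the second-layer weight.

The training loss is the negative log Cox partial likelihood in its
sum-over-events form with the inclusive risk set `{j : T_j ≥ T_i}` (the
Breslow convention for ties). `neg_log_partial_likelihood` exposes a
`mean=True` option that divides by the event count, but the optimizer uses
the sum: the relative weight of the fixed-scale penalties (λ, μ below)
depends on this choice, and the defaults are calibrated against the sum
form.

Two phases:

* **Pre-training** (100 epochs): mask M, objective `l + λ·Std(W1⊙M)` with
  λ = 1. The Std term is the *population* standard deviation pooled over the
  mask-1 entries of W1 only. Structural zeros are excluded on purpose:
  including them would penalize the mere existence of weights and contradict
  the equal-importance rationale of the penalty.
* **Training / expansion** (100 epochs): mask E (all ones), objective
  `l + μ·‖W1⊙(1−M)‖₁` with μ = 1. Non-prior entries of W1 enter this phase
  at exactly 0 (they received no gradient in phase 1), so every non-prior
  link must earn its way in against the L1 toll.

## Optimization

Full-batch Adam (β = 0.9/0.999, ε = 1e-8), learning rate 0.05, fixed epoch
budgets, no schedule and no early stopping. After every step W1 is projected
onto the non-negative orthant (`max(W1, 0)`), which is both the constraint
mechanism and the source of *exact* zeros — the expansion stage's occurrence
indicator `O = 1[W1 > 0]` is meaningful only because 0 is exactly
attainable.

The L1 term is handled by default as its one-sided subgradient: a constant
+μ added to the gradient of every non-prior entry (one-sided because W1 is
confined to the non-negative orthant). Under Adam's per-entry normalization
this gives a clean selection semantics: an entry at zero starts growing only
while its raw likelihood gradient is below −μ, and an active entry whose
gradient has faded drifts back to zero and is clamped there. A proximal
alternative (`TrainConfig(l1_mode="proximal")`: soft-threshold non-prior
entries by μ·lr after each step) is available; in side-by-side runs on
synthetic cohorts it suppresses informative links more than noise links and
yields a weaker expansion-phase gain, so it is not the default.

Two initialization choices matter and are deliberate:

* W1 starts at U(0, 0.1) on the masked entries, 0 elsewhere (non-negative
  start inside the feasible set).
* **W2 starts positive**, U(0, 1/√P). With W1 ≥ 0 and tanh units, a pathway
  whose output weight starts negative drives its entire W1 column to zero
  within a few steps, after which the unit is dead: zero activity, hence
  zero gradient to either layer, permanently. Symmetric W2 initialization
  reproducibly killed pathway units at birth (pre-train C-index 0.62 vs 0.71
  with the positive start on the default synthetic cohort, whose oracle
  risk scores ≈ 0.69). A pathway may still learn a negative W2 during
  training; only the start is constrained.

Adam state is re-initialized between the phases: phase 2 optimizes a
different objective over different connectivity, and carrying first/second
moment estimates across that switch has no principled interpretation.

Degenerate inputs: a dataset with zero events, a pathway with no member
genes in the expression panel, and a non-finite loss (reported with its
epoch) are all hard errors, not warnings.

## Evaluation

The concordance index counts ordered pairs (i, j) with `T_j < T_i` and
`δ_j = 1`; risk ties receive 0.5 credit by default, and `ties="strict"`
reproduces the pure indicator definition (ties score 0). Summaries print
C-index as a percentage; everything internal is on [0, 1]. Cross-validation
partitions samples into k seeded folds (default 10, i.e. 9:1 train/test),
trains per fold, and reports held-out concordance per fold. Kaplan–Meier
curves and the two-group log-rank test are delegated to lifelines behind
thin wrappers that fix the package's conventions (curves evaluated at event
times; χ²₁ statistic with upper-tail p).

## Pathway expansion

100 (default) two-phase fits on seeded 90% subsamples drawn without
replacement, per-run seed = base seed + run index. `S = mean_k O⁽ᵏ⁾`;
selection keeps exactly `n* = ⌊(1+α)K + ½⌋` pairs by descending S with
deterministic tie-breaking (higher ensemble-mean weight, then lower gene
index, then lower pathway index). Prior pairs are *not* force-included; in
practice they have S ≈ 1, and any prior pair that falls below the cut is
reported in the diagnostics rather than silently restored. Ranked per-
pathway gene lists for pre-ranked enrichment use the ensemble-mean W1
column, not a single fit.

The leave-one-out recoverability test removes one prior pair (i, j) at a
time, reruns the subsampled ensemble with the reduced mask, and records the
recovering probability S(i, j) plus the rank of that probability within
pathway j's candidate pool (all pairs absent from the reduced mask). The
baseline distribution is each true non-prior pair's occurrence probability
averaged over the same runs; the two distributions are compared with the
asymptotic two-sample Kolmogorov–Smirnov test. The default is 20 runs per
removed gene — the separation being tested is distributional, and it is
already decisive at that depth (KS p ≈ 3·10⁻⁵ on the default synthetic
cohort); deeper ensembles sharpen the per-gene probabilities, not the
conclusion.

## Synthetic cohorts

`SyntheticSpec` defaults: n = 300 samples, G = 150 genes, three pathways
with 10 prior + 2 hidden members each, per-pathway effect 1.5, residual
log-risk noise sd 0.5, target censoring 0.3, exponential baseline hazard
(Weibull available via `baseline="weibull"`).

Expression is i.i.d. standard normal, emulating z-scored input. Pathway
activity is the *mean* expression of the pathway's true members — prior plus
hidden — so hidden genes matter through the same mechanism as prior members
(the prior sets are incomplete, not wrong). Log-risk = effect·Σ activities
+ N(0, noise_sd²); event times are proportional-hazards exponential;
censoring times are exponential with the rate solved (by bisection on the
expected censored fraction given the realized event times) to hit the
target, re-drawn up to 10 times if the realized fraction strays beyond
±0.1. Residual noise at 0.5 — about half the structured-risk scale — and
30% censoring were chosen as typical of mid-sized tumor cohorts.

What the generator does **not** emulate: gene–gene correlation
(co-expression), heavy-tailed or count-scale expression, pathway overlap,
and informative censoring. Passing tests therefore demonstrate the
machinery's correctness and its behavior under honest low-signal conditions,
not performance on real transcriptomes — where correlated co-members make
supplement genes substantially easier to find.

### Statistical power of the default recovery scenario

With activity as a 12-member mean, each hidden gene's marginal log-hazard
coefficient is 1.5/12 = 0.125 per sd of expression (hazard ratio ≈ 1.13),
i.e. a univariate Cox score of z ≈ 0.125·√(#events) ≈ 1.7 at ~190 events.
The ~414 null gene–pathway pairs produce a maximum chance score of ≈ 2.5–2.9
on any single cohort, so no selector — the network's or an oracle's — can
reliably place a majority of the hidden pairs into the six supplement slots
of a single default-scale dataset; on the default seed, half the hidden
genes have realized z ≈ 0. Subsample ensembling cannot remove this noise
floor because chance correlation lives in the data, which the subsamples
share. What *is* achievable, and what the test suite asserts, is
distribution-level separation: hidden and left-out prior genes attain
systematically higher occurrence probabilities than the non-prior background
(KS p < 0.05). On strong-signal scenarios (per-gene effect a few times
larger), the same machinery ranks planted genes at occurrence probabilities
up to 0.9 and recovers them outright.

## Preprocessing

For count-scale input: log2(x+1), keep genes whose across-sample standard
deviation (sample sd, ddof = 1; strict comparison) exceeds the threshold
(default 1), then z-score each retained gene. Normalization is computed on
the full matrix before any train/test split — convenient and conventional
for this kind of analysis, but a mild information leak into held-out folds;
fold-internal normalization would be the stricter alternative.

## Known limitations

* The tanh output saturates as the partial likelihood inflates risk
  separation; late in training most samples sit in the flat region and
  gradient information concentrates on a shrinking subset. This blunts the
  expansion phase's selection signal at weak effect sizes.
* Attribution across pathways is ambiguous when the log-risk is a sum of
  activities: a supplement gene can surface in a sibling pathway's column
  (observed in the worked example: a gene planted in one pathway was
  selected into another).
* The L1 selection applies no multiplicity control; occurrence probabilities
  are descriptive statistics of the resampled fits, not p-values.
* Single-gene Kaplan–Meier analysis with a median split discards effect
  size and is sensitive only to rank-level association (by design — it is
  invariant to monotone transforms of expression).
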