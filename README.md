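# pathsurv

Pathway-expanding neural survival analysis: fit a biologically informed
neural Cox model whose first layer is masked by prior pathway membership,
then let the model *explore beyond* the prior gene sets under an L1 penalty
and nominate **supplement genes** — genes the curated pathways are missing
but that carry survival signal through those pathways.

The package is aimed at computational biologists who have a gene-expression
cohort with right-censored outcomes (e.g. a TCGA-style cancer cohort), a set
of disease-associated prior pathways (GMT), and want both a competitive risk
model and an interpretable, pathway-anchored gene-discovery procedure.

## The model

A three-layer network maps an expression profile x ∈ R^{1×G} to a scalar
log-risk,

    f_W(x, M) = tanh( tanh( x · (W1 ⊙ M) ) · W2 ),

with W1 ∈ R₊^{G×P} (non-negative gene→pathway weights), W2 ∈ R^{P×1}, and a
binary mask M ∈ {0,1}^{G×P} encoding pathway membership. Training minimizes
the negative log Cox partial likelihood

    l(W) = − Σ_{i: δ_i=1} [ f_W(x_i) − log Σ_{j: T_j ≥ T_i} exp(f_W(x_j)) ]

in two phases:

1. **pre-training** (mask = M): loss l + λ·Std(W1⊙M), where the
   standard-deviation penalty pulls the prior genes of the modules toward
   equal importance;
2. **training / expansion** (mask = E, all ones): loss l + μ·‖W1⊙(1−M)‖₁,
   so that non-prior gene→pathway links enter only if they pay for an L1
   toll.

Defaults are full-batch Adam, learning rate 0.05, 100 + 100 epochs,
λ = μ = 1. Because W1 is projected onto the non-negative orthant after every
step, "link absent" is the exact value W1(i,j) = 0.

**Pathway expansion** then runs the two-phase fit on (by default) 100 random
90% subsamples of the cohort, records the binary occurrence matrices
O⁽ᵏ⁾ = 1[W1⁽ᵏ⁾ > 0], averages them into an occurrence-probability matrix S,
and keeps the ⌊(1+α)K + ½⌋ gene–pathway pairs with the highest S (K = number
of prior pairs, α = 0.2), i.e. a supplement of about 20% of K. Model quality
is scored by the concordance index (C-index); downstream validation includes
leave-one-out recoverability testing (with a two-sample KS test) and
median-split single-gene Kaplan–Meier analysis.

## Worked example

Everything below runs on a synthetic cohort with a known ground truth: 300
samples, 150 genes, three pathways of 10 prior members each, plus 2 *hidden*
members per pathway that the prior sets omit.

```python
from pathsurv import (PathwaySurvivalNet, SyntheticSpec, TrainConfig, generate,
                      occurrence_probability, select_expanded, supplement_genes)

data, prior, truth = generate(SyntheticSpec())
model = PathwaySurvivalNet(data, prior, TrainConfig(seed=1))
res = model.fit()          # two-phase training
print(res.summary())
```

```
Pathway survival network results
========================================
method:            two_phase
samples / events:  300 / 209
genes × pathways:  150 × 3
prior pairs (K):   30
epochs trained:    200
final train C-index [pretrain]: 70.92%
final train C-index [train]: 73.77%
active non-prior links: 46
```

The pre-training phase reaches C ≈ 71% (the generating risk itself scores
≈ 69% on this cohort — the fit is at the signal ceiling) and the expansion
phase adds ~3 points by recruiting genes outside the prior sets. Expanding
the pathways with a 20-run ensemble:

```python
ens = model.fit_ensemble(runs=20)
S = occurrence_probability(ens)
exp = select_expanded(S, prior, alpha=0.2, mean_weight=ens.mean_weights())
print(supplement_genes(exp, prior))
```

```
prior pairs K = 30, selected = 36
supplement[PW1]: G0046, G0056, G0146
supplement[PW2]: G0148, G0040, G0069, G0122
supplement[PW3]: G0065, G0090
```

With K = 30 and α = 0.2 the rule keeps ⌊1.2·30 + ½⌋ = 36 pairs — the 30
prior pairs (occurrence ≈ 1) plus 6 supplement slots. Here one selected
supplement (G0090) is a truly planted hidden gene; at this sample size each
hidden gene carries a weak marginal signal (hazard ratio ≈ 1.13 per sd), so
chance-correlated genes compete for the remaining slots — see
`docs/methods.md` for the power analysis. A planted gene validates cleanly
in single-gene survival analysis:

```python
from pathsurv import single_gene_km
curve_hi, curve_lo, stat, p = single_gene_km(data, "G0035")
print(stat, p)    # log-rank 14.53, p = 0.000138
```

## Command line

The same pipeline is scriptable:

```sh
pathsurv simulate --out bundle/                 # or bring your own TSV + GMT
pathsurv preprocess --expression e.tsv --survival s.tsv --gmt p.gmt --out bundle/
pathsurv train   --bundle bundle/ --out fit/    # weights, history, curve plot
pathsurv expand  --bundle bundle/ --runs 100 --alpha 0.2 --out expansion/
pathsurv recover --bundle bundle/ --runs-per-gene 20 --out recovery/
pathsurv km      --bundle bundle/ --gene G0035 --out km/
```

`expand` writes the occurrence-probability matrix (TSV), the expanded
pathways (GMT), the supplement gene table, and per-pathway ranked gene lists
(RNK) for pre-ranked enrichment tools. Every command stamps a
`manifest.json` with its seed and input hashes.

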