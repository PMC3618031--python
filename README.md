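# orthomix

Cross-species differential-expression analysis for paired microarray (or any
log-scale expression) data, built around a sign-constrained nine-component
bivariate normal mixture.

## The problem

When the same disease is studied in two species — here, diffuse
large-B-cell lymphoma (DLBCL) in dogs and humans, with its two molecular
subtypes ABC (activated B-cell-like) and GCB (germinal-center B-cell-like) —
each orthologous gene pair carries two treatment effects, one per species.
Genes whose expression separates the subtypes *in both species* are far more
likely to be biologically relevant than genes flagged by a single-species
screen, and a much shorter list of them suffices to classify patients.

## The model

For ortholog pair *i*, per-gene linear models in each species

```
X_aij = β0_ai + β1_ai T_aj + e_aij ,   e_aij ~ N(0, σ_a²)
X_hil = β0_hi + β1_hi T_hl + e_hil ,   e_hil ~ N(0, σ_h²)
```

give OLS effect estimates (β̂1_ai, β̂1_hi) — with a {0,1} subtype indicator
these are just differences of class means.  The paired estimates are modelled
as a nine-component bivariate normal mixture, one component per joint
differential-expression state (NDE / pDE / nDE in each species):

| k | state (a, h) | mean constraints | corr |
|---|--------------|------------------|------|
| 0 | NDE, NDE | μ_a = μ_h = 0 | 0 |
| 1 | pDE, pDE | μ_a ≥ 0, μ_h ≥ 0 | ρ₁ |
| 2 | nDE, nDE | μ_a ≤ 0, μ_h ≤ 0 | ρ₂ |
| 3 | pDE, nDE | μ_a ≥ 0, μ_h ≤ 0 | ρ₃ |
| 4 | nDE, pDE | μ_a ≤ 0, μ_h ≥ 0 | ρ₄ |
| 5 | NDE, pDE | μ_a = 0, μ_h ≥ 0 | 0 |
| 6 | NDE, nDE | μ_a = 0, μ_h ≤ 0 | 0 |
| 7 | pDE, NDE | μ_a ≥ 0, μ_h = 0 | 0 |
| 8 | nDE, NDE | μ_a ≤ 0, μ_h = 0 | 0 |

Fitting is by EM with the constraints enforced at every M-step; gene
membership is the maximum-posterior component.  Standard errors come from a
parametric bootstrap (multinomial category counts, simulate, refit).  Genes
in categories 1–4 ("differentially expressed in both species") feed a
2-means nearest-centroid subtype classifier evaluated by leave-one-out
cross-validation in which the held-out subject never touches effect
estimation, mixture fitting, gene selection or centroid training.  A
single-species t-test + Benjamini–Hochberg FDR baseline is included for
comparison.

Because the original canine dataset is not public, the package ships a
synthetic-data generator that emulates the study design (14 dogs 9 GCB/5 ABC,
156 humans 79 GCB/77 ABC, 6,566 ortholog pairs) with effect pairs drawn from
the mixture, so every stage is testable end to end with known ground truth.

## Worked example

```python
import numpy as np
from orthomix import fit_em, reference_mixture, simulate_effect_pairs

truth = reference_mixture()                      # published fitted parameters
pairs, _ = simulate_effect_pairs(truth, 6566, seed=7)
fit = fit_em(pairs, seed=7)
counts = np.bincount(fit.categories, minlength=9)
print(f"converged: {fit.converged} after {fit.n_iter} iterations")
print(f"fitted null weight Pi_0 = {fit.params.weights[0]:.3f}  (truth 0.823)")
print(f"expected null pairs    = {round(6566 * fit.params.weights[0])}")
print("category counts:", counts.tolist())
print("genes DE in both species (categories 1-4):", counts[1:5].sum())
```

prints

```
converged: True after 304 iterations
fitted null weight Pi_0 = 0.825  (truth 0.823)
expected null pairs    = 5419
category counts: [5592, 10, 5, 6, 3, 108, 62, 701, 79]
genes DE in both species (categories 1-4): 24
```

i.e. the EM recovers the dominant null weight (≈82% of ortholog pairs are
uninteresting), most genes land in category 0, and only a couple of dozen
pairs show evidence of differential expression in both species — the short
list the classifier is built on.

There is also a CLI covering each stage and a full pipeline driver:

```sh
orthomix simulate --out-dir data --seed 1
orthomix estimate-effects --expr-a data/expression_a.tsv --meta-a data/samples_a.tsv \
    --expr-h data/expression_h.tsv --meta-h data/samples_h.tsv \
    --orthologs data/orthologs.tsv --out pairs.tsv
orthomix fit-mixture --pairs pairs.tsv --out-params params.json --out-categories cats.tsv
orthomix bootstrap-se --pairs pairs.tsv --params params.json -B 200 --seed 1 --out se.json
orthomix loocv --expr-a ... --selection both-species --seed 1 --out-dir loocv/
orthomix run --config pipeline.yaml        # everything, with a JSON report
```

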