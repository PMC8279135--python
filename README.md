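# regeval

Which single number should you trust when judging a regression model?
`regeval` is a small library and CLI for comparing the behaviour of seven
regression evaluation rates — the coefficient of determination (R²), MSE,
RMSE, MAE, MAPE, SMAPE and the complementary normalized SMAPE (cnSMAPE) —
on the same predictions. It is aimed at biostatisticians and machine-learning
practitioners who need to pick an evaluation metric for ordinal or
continuous clinical targets and want to see, concretely, where bounded rates
such as R² and SMAPE diverge.

## The metrics

For ground truth `Y_1..Y_m` and predictions `X_1..X_m`, with
`Ȳ = (1/m) Σ Y_i` and `MST = (1/m) Σ (Y_i − Ȳ)²`:

| rate | definition | range | best |
|---|---|---|---|
| R² | `1 − Σ(X_i−Y_i)² / Σ(Y_i−Ȳ)²` | (−∞, 1] | 1 |
| MSE | `(1/m) Σ (X_i−Y_i)²` | [0, ∞) | 0 |
| RMSE | `√MSE` | [0, ∞) | 0 |
| MAE | `(1/m) Σ |X_i−Y_i|` | [0, ∞) | 0 |
| MAPE | `(1/m) Σ |Y_i−X_i| / |Y_i|` | [0, ∞) | 0 |
| SMAPE | `(1/m) Σ |X_i−Y_i| / ((|X_i|+|Y_i|)/2)` | [0, 2] | 0 |
| cnSMAPE | `1 − SMAPE/2` | [0, 1] | 1 |

Key identities: `R² = 1 − MSE/MST`, so within one test set R², MSE and RMSE
always order models identically; R² is invariant under a common affine
rescaling of both vectors, SMAPE is not; a SMAPE term reaches its maximum 2
whenever prediction and truth have strictly opposite signs.

Degenerate inputs have explicit semantics: R² raises an
`UndefinedMetricError` when the actual vector is constant (MST = 0), MAPE is
flagged undefined when any actual value is zero (never silently dropped),
and a SMAPE term with both values exactly zero counts as zero error.

## What's in the box

- `regeval.metrics` — the seven rates, `PairedSeries`/`MetricReport`
  containers, CSV I/O.
- `regeval.use_cases` — five constructions (UC1–UC5) plus two fixed worked
  examples in which R² and cnSMAPE give sharply different verdicts: growing
  numbers of zeroed points, position-sensitive zeroing, an overfit
  polynomial interpolant on a noisy line, a constant prediction that SMAPE
  scores as 88.1% correct, and the exhaustive 5⁵ prediction grid against
  (1,2,3,4,5).
- `regeval.scenarios` — a seeded generator of EHR-like regression datasets
  with an ordinal target (hepatitis-staging-like and obesity-level-like
  presets with exact class counts 540/24/21/30 and
  272/287/351/297/324/290/290), optional missingness and mean imputation.
- `regeval.pipeline` — repeated 80/20 holdout evaluation of competing
  regressors (linear / decision tree / random forest by default), per-metric
  ranking tables and ranking-agreement summaries.
- `regeval.cli` — `regeval uc1|uc2|uc3|uc4|uc5|worked-examples|scenario|verify`,
  each writing CSVs plus a JSON manifest.

## Worked example

The seven actual values `(1, 1, 1, 1, 1, 2, 3)` predicted constantly as 1 —
a regressor that has learned nothing beyond the majority value:

```python
from regeval import PairedSeries, evaluate_all

rep = evaluate_all(PairedSeries([1, 1, 1, 1, 1, 2, 3], [1, 1, 1, 1, 1, 1, 1]))
print(f"R^2      = {rep.r_squared:+.3f}")
print(f"SMAPE    = {rep.smape:.3f}  ({rep.smape_pct:.1f}%)")
print(f"cnSMAPE  = {rep.cn_smape:.3f}  ({rep.cn_smape_pct:.1f}% correctness)")
```

prints

```
R^2      = -0.346
SMAPE    = 0.238  (23.8%)
cnSMAPE  = 0.881  (88.1% correctness)
```

R² is negative — the prediction fits worse than the horizontal line through
the mean, flagging the failure — while SMAPE reads as 88.1% correct because
each pointwise relative error is small. This is the core disagreement the
use cases map out.

The ranking pipeline on the imbalanced hepatitis-like preset shows the same
effect at the model-comparison level:

```sh
regeval scenario --preset hepatitis-like --n-runs 100 --seed 1 -o out/
```

prints a mean-metric table over 100 holdout runs in which R², MSE and RMSE
rank random forest > linear regression > decision tree, while SMAPE promotes
the decision tree to first place — six rates, more than one ranking
(`out/ranking.csv` holds the full table, `out/ranking_agreement.csv` the
pairwise inversion counts).

`regeval verify` recomputes every use-case quantity through the metric
pipeline and checks it against independent closed forms, printing one
PASS/FAIL line per check.

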