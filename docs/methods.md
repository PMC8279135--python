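# Methods

## Scope and model

`regeval` implements seven regression evaluation rates and studies their
disagreement on two levels: deterministic desk-scale constructions
(`use_cases`) in which every number is reproducible exactly, and a
stochastic repeated-holdout pipeline (`scenarios` + `pipeline`) in which
only distributional and ordering properties are claimed.

All rates are functions of one `PairedSeries` — ground truth `Y` and
prediction `X` of common length `m`, both finite. The package normalizes
both `MSE` and `MST` by `1/m`, so the identity `R² = 1 − MSE/MST` holds
with the stored constants exactly as written (the `1/m` factors cancel in
the ratio, so this choice does not change R² itself). SMAPE is stored on
the fraction scale `[0, 2]`; the percentage scale (`200% = 2`) is exposed
as a derived view (`smape_pct`), never as separate state, since the two are
computationally equivalent.

## Degenerate-input semantics

These cases are decided explicitly, because silent conventions here change
what a "perfect" or "undefined" score means:

- **SMAPE term at `X_i = Y_i = 0`** — defined as 0. The term is formally
  0/0, but an exact match carrying zero error is the only convention that
  preserves "SMAPE = 0 ⇔ prediction identical to truth", which the package
  asserts as an invariant.
- **MAPE with a zero actual value** — a hard undefined-metric outcome.
  Dropping offending points would silently change `m` and make MAPE
  incomparable with the other rates computed on the full series. Inside
  `evaluate_all` the undefinedness is recorded on the report (`NaN` value
  plus reason) rather than raised, so one zero target does not abort a
  multi-metric evaluation; the standalone `mape()` raises.
- **R² with a constant actual vector** — `UndefinedMetricError`. With
  `MST = 0` no finite value is defensible, and a report whose headline
  metric is undefined is not useful, so `evaluate_all` propagates this one.
- **cnSMAPE input domain** — strictly `[0, 2]`; out-of-range inputs are a
  caller error, not clamped.

## Use-case constructions

- **UC1** (`j` zeroed points on the 1..100 line, positions ≡ 1 mod 5,
  1-based): closed forms `cnSMAPE(j) = 1 − j/100` (each zeroed point
  contributes the maximal term 2) and
  `R²(j) = 1 − Σ_{k<j}(5k+1)²/83325` are implemented independently of the
  metric pipeline and cross-checked against it; 83325 is the sum of squared
  deviations of 1..100 around 50.5.
- **UC2**: the three variants zero exactly ten points (positions 1–10,
  51–60, 91–100). The start variant is defined as ten zeroed points, which
  is the extent consistent with both reported summary values for that
  variant (R² = 0.995 and cnSMAPE = 0.9); a nine-point reading would yield
  cnSMAPE = 0.91.
- **UC3**: 20 points `i + ε_i` with `ε_i ~ N(0, 0.5²)` i.i.d. under a fixed
  default seed (2021). The noise model and seed are package choices — only
  "small zero-mean noise" is inherent to the construction — so the exact
  wrong-model magnitudes are seed-dependent and only the structural
  properties are asserted: the interpolant is exact on its 10-point fitting
  window (R² = cnSMAPE = 1 for prefixes N ≤ 10), wrong-model cnSMAPE lies
  in `[10/N, 1]` beyond it (first 10 terms are 0, the rest at most 2, and
  the divergence saturates the bound), and wrong-model R² decreases
  strictly in N once the divergence dominates. Ten distinct points
  determine a unique interpolant of degree ≤ 9; it is evaluated with the
  barycentric Lagrange scheme (scipy) for stability, with the node
  permutation pinned so evaluation is bit-deterministic.
- **UC5**: all 5⁵ = 3125 integer predictions of (1,2,3,4,5), in
  lexicographic order so row indices are stable; the non-negative-R²
  filtered view is the scatter data for the R²-vs-cnSMAPE comparison. No
  smoothing curve is computed — that is a plotting concern.
- **Worked examples** ship as in-repo CSV fixtures holding the exact
  printed digits (a 10-point pair with MSE = MST ≈ 1051.511, hence
  R² ≈ 10⁻⁷ at this precision, and an all-opposite-signs pair attaining
  SMAPE = 200% exactly).

## Synthetic scenario generator

The generator stands in for two real EHR cohorts; it reproduces only the
structure the ranking pipeline exercises, not the cohorts' covariate
distributions:

- **Class composition**: per-level counts are fixed by largest-remainder
  apportionment of `n_samples × proportions` (ties to the earlier level),
  so the presets realize the documented counts exactly — 615 = 540/24/21/30
  over levels 0..3 (hepatitis-like) and 2111 = 272/287/351/297/324/290/290
  over levels 1..7 (obesity-like).
- **Features**: class-conditionally Gaussian, feature mean
  `level_index × class_separation`, unit sd. `class_separation` (default
  1.0, in sd units) is the single learnability dial: 0 means no signal
  (a consistent regressor's held-out R² → 0), larger values monotonically
  improve every consistent regressor. This is deliberately simplistic —
  no feature correlations, no heteroscedasticity, no label noise — so
  passing tests demonstrate properties of the metrics and the pipeline
  mechanics, not performance claims about real clinical data.
- **Missingness**: independent per-cell masking (MCAR) of features only;
  the hepatitis-like preset defaults to rate 0.01, a free parameter since
  the real cohort's missingness rate is not part of the recipe.
  Imputation is plain column-mean — an intentionally simple stand-in for
  model-based schemes such as predictive mean matching, and documented as
  such wherever it appears so it cannot be mistaken for one.
- The ordinal target is treated as a plain numeric regression target
  (level codes), matching how such staged diagnoses are used as regression
  outcomes.

All generation is a pure function of `(config, seed)`; dataset draws and
missingness masks use seeds derived from the config seed.

## Evaluation pipeline

Each run: one shared shuffle and 80/20 split (train size
`floor(0.8 n)`; the rounding is a package choice), each model fit on the
train side, all seven rates computed on the held-out predictions. Runs use
counter-based seeds (`SeedSequence([master, run])`, reduced below 2³¹), so
they are mutually independent yet reproducible from one master seed.

Targets coded from 0 (hepatitis-like preset) are shifted by +1 before
evaluation so MAPE is defined on every test set; the shift is additive and
common, so residual-based rates and all orderings are unaffected, and it is
logged at run time.

Rankings are computed twice: from per-run values (where the R²/MSE/RMSE
ordering identity is a theorem for each fixed test set, and is asserted
across ≥ 100 runs) and from across-run means (the tabulated view). The
identity is only asserted per run, since averaging R² across splits with
different MSTs can in principle break the monotone relation. Ties in a
ranking break lexicographically on the method name; methods with undefined
metric values are excluded from that metric's ordering with a logged
warning. Agreement between two orderings is summarized as identity plus
the number of pairwise inversions (Kendall-style count, reported raw).

The three default learners (ordinary least squares, CART tree, random
forest) are consumed through the `ModelSpec` contract and bound to
scikit-learn implementations; tree count and depth are surfaced as
configuration because the rankings are sensitive to them and no canonical
values are inherent to the comparison.

## Numerical and testing choices

- Printed-precision comparisons in tests use absolute tolerance `5·10⁻ᵖ`
  for a value printed with `p` decimals, avoiding round-half ambiguity.
- Exact-by-construction quantities (SMAPE = 2 under opposite signs,
  cnSMAPE = 1 − j/100, UC5 entry R² = 0) are asserted at 10⁻¹² or exact
  equality, not at printed precision.
- Every metric is cross-checked against an independently coded naive-loop
  oracle (pure Python, no numpy) on short series, both property-based and
  exhaustively over the UC5 grid.
- Problem sizes in the stochastic tests (e.g. 300-sample scenarios,
  10-tree forests, 100 runs for the ranking-identity property; 20 seeds ×
  3 separations for the monotonicity property) are chosen as the smallest
  sizes at which the asserted properties are stable, keeping the default
  suite fast while still exercising the full pipeline; the CLI defaults
  remain at the full preset sizes (615/2111 samples, 100-tree forests,
  100 runs).

## Known limitations

- The generator's feature model is far simpler than real EHR covariates;
  ranking results on it characterize the metrics, not the learners.
- Mean imputation distorts feature variances and correlations; it is a
  plumbing stand-in, not a recommended missing-data strategy.
- SMAPE here is one of several formulas in circulation (the half-sum
  denominator variant); results do not transfer to other SMAPE variants.
- Adjusted R², partial determination, and robust losses (Huber, LogCosh,
  quantile) are out of scope.
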