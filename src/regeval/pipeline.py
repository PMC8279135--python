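"""Repeated-holdout multi-model evaluation and per-metric ranking.

The procedure: shuffle the records, hold out 20% as a test set, fit each
competing regressor on the remaining 80%, score its test predictions with
all seven rates, repeat ``n_runs`` times with fresh splits, then average
per metric per model and read off the model ordering each metric induces.
Different metrics can — and on imbalanced ordinal targets do — induce
different orderings of the same models; :func:`ranking_agreement`
quantifies the disagreement in pairwise inversions.

Within any single run (one fixed test set) the orderings induced by
R², MSE and RMSE necessarily coincide, because R² = 1 − MSE/MST with MST
fixed by the test set and RMSE = √MSE: both relations are monotone.
Averaging across runs can in principle break this for R² (each run has its
own MST), so orderings are reported both from the per-run records and from
the means.

Learners are supplied through the :class:`ModelSpec` contract — a name plus
a seed-accepting factory returning any object with sklearn-style
``fit(X, y)`` / ``predict(X)``.  The default set binds ordinary least
squares, a CART regression tree and a random forest.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.tree import DecisionTreeRegressor

from .metrics import MetricReport, PairedSeries, evaluate_all
from .scenarios import (
    ScenarioConfig,
    ScenarioDataset,
    generate_dataset,
    impute_simple,
    shuffle_split,
)

__all__ = [
    "ModelSpec",
    "RankingTable",
    "PIPELINE_METRICS",
    "METRIC_POLARITY",
    "default_models",
    "run_single",
    "run_repeated",
    "run_repeated_on_dataset",
    "rank_methods",
    "ranking_agreement",
    "derive_run_seed",
]

logger = logging.getLogger(__name__)

# Table column order: the six rates reported by the ranking tables.
PIPELINE_METRICS = ("r_squared", "mae", "mse", "smape", "rmse", "mape")

# Ordering direction per metric: R² rewards larger values, every error
# rate rewards smaller ones.
METRIC_POLARITY = {
    "r_squared": "higher_better",
    "mae": "lower_better",
    "mse": "lower_better",
    "smape": "lower_better",
    "rmse": "lower_better",
    "mape": "lower_better",
}

TRAIN_FRACTION = 0.8
DEFAULT_N_RUNS = 100


@dataclass(frozen=True)
class ModelSpec:
    """A named competing regressor.

    ``factory(seed)`` must return a fresh estimator exposing sklearn-style
    ``fit(X, y)`` and ``predict(X)``; stochastic learners should consume the
    seed so each run is reproducible.
    """

    name: str
    factory: Callable[[int], object]


def default_models(n_trees: int = 100, max_depth: Optional[int] = None) -> List[ModelSpec]:
    """The standard three-way comparison: linear regression, decision tree,
    random forest.  Hyperparameters are surfaced rather than hidden since
    they materially affect the rankings."""
    return [
        ModelSpec("Linear regression (LR)", lambda seed: LinearRegression()),
        ModelSpec(
            "Decision tree (DT)",
            lambda seed: DecisionTreeRegressor(random_state=seed, max_depth=max_depth),
        ),
        ModelSpec(
            "Random forests (RF)",
            lambda seed: RandomForestRegressor(
                n_estimators=n_trees, random_state=seed, max_depth=max_depth
            ),
        ),
    ]


def derive_run_seed(master_seed: int, run_index: int) -> int:
    """Counter-based per-run seed: independent across runs, reproducible
    from the master seed, and always below 2^31."""
    ss = np.random.SeedSequence([int(master_seed), int(run_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def _shift_positive_target(ds: ScenarioDataset) -> Tuple[ScenarioDataset, float]:
    """Shift target codes so the minimum level is 1 when any level is 0.

    MAPE divides by the actual value, so level codes starting at 0 would
    leave it undefined on every test set containing the base level.  The
    shift is rank- and residual-preserving (a common additive constant),
    leaves MAE/MSE/RMSE untouched, and is logged so no reader mistakes the
    evaluated target for the raw coding.
    """
    if not np.any(ds.target == 0.0):
        return ds, 0.0
    shift = 1.0 - float(ds.target.min())
    logger.info(
        "target contains level 0; shifting all levels by +%g before evaluation "
        "so MAPE is defined",
        shift,
    )
    return ScenarioDataset(ds.features, ds.target + shift), shift


def run_single(
    ds: ScenarioDataset,
    models: Sequence[ModelSpec],
    split_seed: int,
) -> Dict[str, MetricReport]:
    """One shuffle → 80/20 split → fit → test cycle shared by all models.

    Every model sees the identical split; targets containing level 0 are
    shifted to start at 1 (see :func:`_shift_positive_target`) so MAPE is
    defined.  Returns one :class:`MetricReport` per model name.
    """
    if np.isnan(ds.features).any():
        raise ValueError("dataset contains missing values; impute before evaluation")
    ds, _ = _shift_positive_target(ds)
    train, test = shuffle_split(ds, TRAIN_FRACTION, seed=split_seed)
    reports: Dict[str, MetricReport] = {}
    for spec in models:
        try:
            est = spec.factory(split_seed)
            est.fit(train.features, train.target)
            pred = np.asarray(est.predict(test.features), dtype=float)
        except Exception as exc:  # noqa: BLE001 - re-raise with model context
            raise RuntimeError(f"model {spec.name!r} failed: {exc}") from exc
        reports[spec.name] = evaluate_all(PairedSeries(test.target, pred))
    return reports


@dataclass(frozen=True)
class RankingTable:
    """Per-method metric means/sds over runs and the induced orderings.

    ``mean_values`` and ``sd_values`` are method × metric frames;
    ``orderings`` maps each metric to its method list, best first, computed
    from the means under the metric's polarity; ``per_run`` holds the raw
    per-run, per-method metric values (columns ``run, method, <metrics>``).
    """

    methods: Tuple[str, ...]
    mean_values: pd.DataFrame
    sd_values: pd.DataFrame
    orderings: Dict[str, List[str]]
    per_run: pd.DataFrame = field(compare=False)

    def to_csv(self, path: Union[str, Path]) -> None:
        """Ranking-table CSV: one row per method with the six metric
        columns, then a rankings block (1st/2nd/… per metric)."""
        main = self.mean_values.copy()
        main.insert(0, "method", main.index)
        rank_rows = []
        n_ranked = max((len(v) for v in self.orderings.values()), default=0)
        for pos in range(n_ranked):
            row = {"method": f"rank_{pos + 1}"}
            for metric in self.mean_values.columns:
                order = self.orderings.get(metric, [])
                row[metric] = order[pos] if pos < len(order) else ""
            rank_rows.append(row)
        out = pd.concat([main, pd.DataFrame(rank_rows)], ignore_index=True)
        out.to_csv(path, index=False)

    def sd_to_csv(self, path: Union[str, Path]) -> None:
        """Companion CSV of per-metric standard deviations across runs."""
        out = self.sd_values.copy()
        out.insert(0, "method", out.index)
        out.to_csv(path, index=False)


def rank_methods(
    values: Mapping[str, float], polarity: str
) -> List[str]:
    """Order method names by value under ``polarity`` (``higher_better`` or
    ``lower_better``); ties break lexicographically on the method name, and
    methods with NaN values are excluded with a logged warning."""
    if polarity not in ("higher_better", "lower_better"):
        raise ValueError(f"unknown polarity {polarity!r}")
    usable = {k: v for k, v in values.items() if np.isfinite(v)}
    dropped = sorted(set(values) - set(usable))
    if dropped:
        logger.warning("excluding method(s) with undefined metric value: %s", dropped)
    sign = -1.0 if polarity == "higher_better" else 1.0
    return sorted(usable, key=lambda name: (sign * usable[name], name))


def run_repeated(
    config: ScenarioConfig,
    models: Sequence[ModelSpec],
    n_runs: int = DEFAULT_N_RUNS,
) -> RankingTable:
    """``n_runs`` independent shuffle/split/fit/evaluate cycles on one
    generated dataset, summarized as a :class:`RankingTable`.

    The dataset is generated once from ``config`` (and mean-imputed if it
    carries missingness); each run draws its own split seed from the config
    seed via :func:`derive_run_seed`.  Orderings come from the per-metric
    means; the per-run records remain available for run-level analyses.
    """
    ds = generate_dataset(config)
    if np.isnan(ds.features).any():
        ds = impute_simple(ds)
    return run_repeated_on_dataset(ds, models, n_runs=n_runs, master_seed=config.seed)


def run_repeated_on_dataset(
    ds: ScenarioDataset,
    models: Sequence[ModelSpec],
    n_runs: int = DEFAULT_N_RUNS,
    master_seed: int = 0,
) -> RankingTable:
    """As :func:`run_repeated`, but on an already-materialized dataset
    (e.g. one loaded from CSV)."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    records = []
    for run in range(n_runs):
        split_seed = derive_run_seed(master_seed, run)
        reports = run_single(ds, models, split_seed=split_seed)
        for name, rep in reports.items():
            rec = {"run": run, "method": name}
            for metric in PIPELINE_METRICS:
                rec[metric] = getattr(rep, metric)
            records.append(rec)
    per_run = pd.DataFrame(records)
    method_names = [m.name for m in models]
    grouped = per_run.groupby("method", sort=False)
    mean_values = grouped[list(PIPELINE_METRICS)].mean().reindex(method_names)
    sd_values = grouped[list(PIPELINE_METRICS)].std(ddof=0).reindex(method_names)
    orderings = {
        metric: rank_methods(mean_values[metric].to_dict(), METRIC_POLARITY[metric])
        for metric in PIPELINE_METRICS
    }
    return RankingTable(
        methods=tuple(method_names),
        mean_values=mean_values,
        sd_values=sd_values,
        orderings=orderings,
        per_run=per_run,
    )


def _pairwise_inversions(order_a: Sequence[str], order_b: Sequence[str]) -> int:
    """Number of method pairs ranked in opposite relative order."""
    common = [m for m in order_a if m in set(order_b)]
    pos_b = {m: i for i, m in enumerate(order_b)}
    count = 0
    for i, j in itertools.combinations(range(len(common)), 2):
        if pos_b[common[i]] > pos_b[common[j]]:
            count += 1
    return count


def ranking_agreement(table: RankingTable) -> pd.DataFrame:
    """Pairwise agreement between the orderings the metrics induce.

    One row per unordered metric pair with whether the two orderings are
    identical and how many pairwise inversions separate them.
    """
    metrics = [m for m in PIPELINE_METRICS if m in table.orderings]
    rows = []
    for a, b in itertools.combinations(metrics, 2):
        oa, ob = table.orderings[a], table.orderings[b]
        rows.append(
            {
                "metric_a": a,
                "metric_b": b,
                "identical": oa == ob,
                "inversions": _pairwise_inversions(oa, ob),
            }
        )
    return pd.DataFrame(rows)
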