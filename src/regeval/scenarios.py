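"""Synthetic EHR-like regression datasets with an ordinal numeric target.

Stand-ins for two tabular electronic-health-record datasets used to compare
metric-induced model rankings: a hepatitis-C staging cohort (615 records,
ordinal diagnosis over 4 levels with very imbalanced proportions
540/24/21/30, some missing laboratory values) and an obesity-level cohort
(2111 records, 7 roughly balanced levels 272/287/351/297/324/290/290, no
missingness).  Neither real dataset is downloaded; the generator emulates
only the structural features the ranking pipeline depends on — an ordinal
target with fixed class counts and a block of numeric features whose
class-conditional means separate by a tunable amount.

Per-level counts are fixed by largest-remainder apportionment of
``n_samples × proportions``, so the realized composition matches the recipe
exactly rather than in expectation.  Features are class-conditionally
Gaussian: feature ``f`` of a sample at target-level index ``k`` is drawn
from ``N(k * class_separation, 1)``; ``class_separation = 0`` therefore
yields features carrying no signal about the target.

All generation is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "ScenarioConfig",
    "ScenarioDataset",
    "largest_remainder_counts",
    "generate_dataset",
    "inject_missingness",
    "impute_simple",
    "shuffle_split",
    "hepatitis_like",
    "obesity_like",
    "preset",
    "PRESETS",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Recipe for one synthetic ordinal-target regression dataset.

    Parameters
    ----------
    n_samples : total number of records.
    class_proportions : one positive fraction per ordinal level, summing to 1.
    target_levels : numeric code of each ordinal level (same length).
    n_features : number of numeric covariates.
    class_separation : distance between consecutive class-conditional feature
        means, in units of the (unit) feature standard deviation; 0 = no
        signal.
    missing_rate : probability that a feature cell is masked, in [0, 1).
    seed : base seed making generation deterministic.
    """

    n_samples: int
    class_proportions: Tuple[float, ...]
    target_levels: Tuple[float, ...]
    n_features: int
    class_separation: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "class_proportions", tuple(float(p) for p in self.class_proportions)
        )
        object.__setattr__(
            self, "target_levels", tuple(float(t) for t in self.target_levels)
        )
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if self.n_features < 1:
            raise ValueError("n_features must be positive")
        if len(self.class_proportions) != len(self.target_levels):
            raise ValueError("class_proportions and target_levels length mismatch")
        if any(p <= 0 for p in self.class_proportions):
            raise ValueError("class proportions must be positive")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.class_separation < 0:
            raise ValueError("class_separation must be non-negative")


@dataclass(frozen=True)
class ScenarioDataset:
    """Realized dataset: an ``n × p`` feature matrix (NaN marks a missing
    cell) and an ``n``-vector of numeric ordinal target codes."""

    features: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.features, dtype=float)
        t = np.asarray(self.target, dtype=float)
        if f.ndim != 2 or t.ndim != 1 or f.shape[0] != t.size:
            raise ValueError("features must be n x p and target length n")
        object.__setattr__(self, "features", f)
        object.__setattr__(self, "target", t)

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"x{j + 1}": self.features[:, j] for j in range(self.n_features)}
        cols["target"] = self.target
        return pd.DataFrame(cols)

    def to_csv(self, path: Union[str, Path]) -> None:
        # missing cells serialize as empty fields
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "ScenarioDataset":
        df = pd.read_csv(path)
        if "target" not in df.columns:
            raise ValueError(f"{path}: no 'target' column")
        target = df.pop("target").to_numpy(dtype=float)
        return cls(df.to_numpy(dtype=float), target)


def largest_remainder_counts(n: int, proportions: Sequence[float]) -> np.ndarray:
    """Integer class counts summing to ``n``, proportional to ``proportions``.

    Floors the exact quotas, then distributes the leftover units to the
    classes with the largest fractional remainders (ties to the earlier
    class, so the allocation is deterministic).
    """
    quotas = n * np.asarray(proportions, dtype=float)
    counts = np.floor(quotas).astype(int)
    short = n - counts.sum()
    remainders = quotas - counts
    # stable argsort descending on remainder; earlier index wins ties
    order = np.argsort(-remainders, kind="stable")
    counts[order[:short]] += 1
    return counts


def generate_dataset(config: ScenarioConfig) -> ScenarioDataset:
    """Draw one dataset from a :class:`ScenarioConfig` (pure in config+seed).

    Rows are emitted level-by-level (level order as configured), then
    missingness is injected at ``config.missing_rate`` with a seed derived
    from the config seed.
    """
    counts = largest_remainder_counts(config.n_samples, config.class_proportions)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    blocks, targets = [], []
    for level_index, (count, level) in enumerate(zip(counts, config.target_levels)):
        mean = level_index * config.class_separation
        blocks.append(rng.normal(mean, 1.0, size=(count, config.n_features)))
        targets.append(np.full(count, level, dtype=float))
    ds = ScenarioDataset(np.vstack(blocks), np.concatenate(targets))
    if config.missing_rate > 0:
        ds = inject_missingness(ds, config.missing_rate, seed=config.seed + 1)
    return ds


def inject_missingness(ds: ScenarioDataset, rate: float, seed: int) -> ScenarioDataset:
    """Mask each feature cell independently with probability ``rate``
    (missing completely at random); the target is never masked."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0.0:
        return ds
    rng = np.random.default_rng(seed)
    mask = rng.random(ds.features.shape) < rate
    features = ds.features.copy()
    features[mask] = np.nan
    return ScenarioDataset(features, ds.target.copy())


def impute_simple(ds: ScenarioDataset) -> ScenarioDataset:
    """Column-mean imputation: each missing cell is replaced by the mean of
    its column's observed values.

    This is a deliberately simple stand-in for model-based imputation
    schemes (e.g. predictive mean matching); it removes missingness without
    attempting to preserve multivariate structure.

    Raises
    ------
    ValueError
        If any column is entirely missing (no observed value to average).
    """
    features = ds.features.copy()
    all_missing = np.isnan(features).all(axis=0)
    if all_missing.any():
        bad = np.flatnonzero(all_missing) + 1
        raise ValueError(f"column(s) {bad.tolist()} are entirely missing")
    col_means = np.nanmean(features, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(features))
    features[nan_r, nan_c] = col_means[nan_c]
    return ScenarioDataset(features, ds.target.copy())


def shuffle_split(
    ds: ScenarioDataset, train_fraction: float, seed: int
) -> Tuple[ScenarioDataset, ScenarioDataset]:
    """Random exact partition into train/test under a uniform permutation.

    Train size is ``floor(n * train_fraction)``; the remaining rows form the
    test set.  The two index sets are disjoint and jointly exhaustive.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n = ds.n_samples
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    n_train = int(np.floor(n * train_fraction))
    if n_train == 0 or n_train == n:
        raise ValueError(f"train_fraction {train_fraction} leaves an empty side")
    perm = np.random.default_rng(seed).permutation(n)
    tr, te = perm[:n_train], perm[n_train:]
    return (
        ScenarioDataset(ds.features[tr], ds.target[tr]),
        ScenarioDataset(ds.features[te], ds.target[te]),
    )


def hepatitis_like(seed: int = 0, missing_rate: float = 0.01,
                   class_separation: float = 1.0) -> ScenarioConfig:
    """Preset mimicking the hepatitis-C staging cohort: 615 records over 4
    ordinal levels coded 0..3 with counts 540/24/21/30 (87.8% controls),
    12 numeric features, a small amount of missingness."""
    counts = (540, 24, 21, 30)
    return ScenarioConfig(
        n_samples=615,
        class_proportions=tuple(c / 615 for c in counts),
        target_levels=(0.0, 1.0, 2.0, 3.0),
        n_features=12,
        class_separation=class_separation,
        missing_rate=missing_rate,
        seed=seed,
    )


def obesity_like(seed: int = 0, class_separation: float = 1.0) -> ScenarioConfig:
    """Preset mimicking the obesity-level cohort: 2111 records over 7
    ordinal levels coded 1..7 with counts 272/287/351/297/324/290/290,
    16 numeric features, no missingness."""
    counts = (272, 287, 351, 297, 324, 290, 290)
    return ScenarioConfig(
        n_samples=2111,
        class_proportions=tuple(c / 2111 for c in counts),
        target_levels=(1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0),
        n_features=16,
        class_separation=class_separation,
        missing_rate=0.0,
        seed=seed,
    )


PRESETS = {"hepatitis-like": hepatitis_like, "obesity-like": obesity_like}


def preset(name: str, seed: int = 0, **overrides) -> ScenarioConfig:
    """Look up a preset config by name and reseed/override it."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[name](seed=seed)
    return replace(cfg, **overrides) if overrides else cfg
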