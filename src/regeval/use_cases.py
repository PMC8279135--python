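"""Constructed use cases where R-squared and SMAPE disagree.

Five programmatic constructions (UC1–UC5) plus two small worked examples
expose how the two bounded regression rates respond differently to the
same prediction errors:

* **UC1** — the identity line 1..100 with a growing number *j* of points
  (those at positions congruent to 1 mod 5) predicted as 0.  cnSMAPE decays
  linearly (``1 - j/100``) while R² collapses much faster.
* **UC2** — ten zeroed points placed at the start, middle or end of the
  1..100 line: cnSMAPE is 0.9 in all three cases, R² is sharply
  position-sensitive.
* **UC3** — a noisy identity line of 20 points; a "correct" model predicts
  the clean line, a "wrong" model is the polynomial interpolant through the
  first 10 noisy points, which explodes beyond its fitting window.  Metrics
  are tracked on growing prefixes.
* **UC4** — a seven-point series with a constant (and useless) prediction
  that SMAPE nevertheless scores at 88.1% correctness.
* **UC5** — exhaustive enumeration of all 5^5 integer predictions of
  (1,2,3,4,5), giving the full joint distribution of R² and cnSMAPE.

The worked examples are fixed 10-point vectors: one with MSE equal to the
total sum of squares (hence R² ≈ 0), one with all-opposite signs (hence
SMAPE at its maximum 200%).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Iterable, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import BarycentricInterpolator

from .metrics import (
    MetricReport,
    PairedSeries,
    cn_smape,
    evaluate_all,
    read_paired_csv,
)

__all__ = [
    "UseCaseResult",
    "build_uc1",
    "uc1_r_squared_closed_form",
    "uc1_cn_smape_closed_form",
    "table_uc1",
    "UC2_VARIANTS",
    "build_uc2",
    "table_uc2",
    "interpolating_polynomial",
    "build_uc3",
    "evaluate_prefix",
    "table_uc3",
    "build_uc4",
    "enumerate_uc5",
    "worked_example_r2_zero",
    "worked_example_smape_max",
    "DEFAULT_UC3_SEED",
    "DEFAULT_UC3_NOISE_SD",
]

UC2_VARIANTS = ("start", "middle", "end")

# UC3 noise defaults: the construction only requires "a small amount" of
# zero-mean noise on an integer-valued line, so sd 0.5 keeps points visibly
# off the line without reordering them; the seed pins the realization.
DEFAULT_UC3_NOISE_SD = 0.5
DEFAULT_UC3_SEED = 2021

# Sum of squared deviations of 1..100 around its mean 50.5: the shared
# R² denominator of UC1 and UC2.
_SST_1_TO_100 = 83325.0


@dataclass(frozen=True)
class UseCaseResult:
    """One evaluated use-case configuration.

    ``case_id`` identifies the construction (``UC1`` … ``UC5``,
    ``WE_R2_ZERO``, ``WE_SMAPE_MAX``); ``configuration`` is the
    case-specific parameter record (e.g. ``{"j": 12}`` for UC1).  The series
    is regenerable bit-identically from ``case_id + configuration`` (plus
    the seed for UC3).
    """

    case_id: str
    configuration: dict
    series: PairedSeries
    report: MetricReport


def _line_1_to_100() -> np.ndarray:
    return np.arange(1, 101, dtype=float)


def build_uc1(j: int) -> PairedSeries:
    """UC1 series: actual 1..100; predicted zeroes the first ``j`` points at
    1-based positions 1, 6, 11, … (congruent to 1 mod 5), 0 <= j <= 20."""
    if not 0 <= j <= 20:
        raise ValueError(f"j={j} outside [0, 20]")
    actual = _line_1_to_100()
    predicted = actual.copy()
    positions = 5 * np.arange(j) + 1  # 1-based: 1, 6, ..., 5(j-1)+1
    predicted[positions - 1] = 0.0
    return PairedSeries(actual, predicted)


def uc1_r_squared_closed_form(j: int) -> float:
    """R² of UC1 by direct summation: ``1 - sum_{k<j} (5k+1)^2 / 83325``."""
    return 1.0 - sum((5 * k + 1) ** 2 for k in range(j)) / _SST_1_TO_100


def uc1_cn_smape_closed_form(j: int) -> float:
    """cnSMAPE of UC1: each zeroed point contributes the maximal SMAPE term
    2 and every other point 0, so cnSMAPE = 1 - j/100 exactly."""
    return 1.0 - j / 100.0


def table_uc1(j_values: Iterable[int] = range(5, 21)) -> pd.DataFrame:
    """Per-``j`` R² and cnSMAPE for UC1, one row per ``j``."""
    rows = []
    for j in j_values:
        rep = evaluate_all(build_uc1(j))
        rows.append({"j": j, "r_squared": rep.r_squared, "cn_smape": rep.cn_smape})
    return pd.DataFrame(rows)


def build_uc2(variant: str) -> PairedSeries:
    """UC2 series: actual 1..100 with ten points predicted as 0 — positions
    1–10 (``start``), 51–60 (``middle``) or 91–100 (``end``)."""
    zero_ranges = {"start": (1, 10), "middle": (51, 60), "end": (91, 100)}
    if variant not in zero_ranges:
        raise ValueError(f"unknown variant {variant!r}; expected one of {UC2_VARIANTS}")
    lo, hi = zero_ranges[variant]
    actual = _line_1_to_100()
    predicted = actual.copy()
    predicted[lo - 1 : hi] = 0.0
    return PairedSeries(actual, predicted)


def table_uc2() -> pd.DataFrame:
    """R² and cnSMAPE for the three UC2 variants, one row each."""
    rows = []
    for variant in UC2_VARIANTS:
        rep = evaluate_all(build_uc2(variant))
        rows.append(
            {"variant": variant, "r_squared": rep.r_squared, "cn_smape": rep.cn_smape}
        )
    return pd.DataFrame(rows)


def interpolating_polynomial(
    xs: Sequence[float], ys: Sequence[float]
) -> Callable[[float], float]:
    """Unique minimal-degree polynomial interpolant through ``(xs, ys)``.

    Evaluated with the barycentric Lagrange scheme for numerical stability;
    for ``n`` points the interpolant has degree at most ``n - 1``.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size != ys.size:
        raise ValueError("xs and ys must have the same length")
    if np.unique(xs).size != xs.size:
        raise ValueError("interpolation nodes must be pairwise distinct")
    # pin the internal node permutation so evaluation is deterministic
    interp = BarycentricInterpolator(xs, ys, rng=np.random.default_rng(0))

    def evaluator(x):
        return interp(x)

    return evaluator


def build_uc3(
    noise_sd: float = DEFAULT_UC3_NOISE_SD, seed: int = DEFAULT_UC3_SEED
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """UC3 construction: noisy line, correct predictions, wrong predictions.

    Returns ``(real, correct, wrong)`` where ``real[i-1] = i + eps_i`` with
    i.i.d. Gaussian noise ``eps_i ~ N(0, noise_sd^2)`` for i = 1..20,
    ``correct`` is the clean line (1, …, 20), and ``wrong`` is the
    polynomial interpolant through the first 10 noisy points evaluated at
    x = 1..20.  The wrong model therefore reproduces the noisy data exactly
    on 1..10 and diverges wildly beyond.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    x = np.arange(1, 21, dtype=float)
    real = x + rng.normal(0.0, noise_sd, size=20)
    correct = x.copy()
    f = interpolating_polynomial(x[:10], real[:10])
    wrong = np.asarray(f(x), dtype=float)
    return real, correct, wrong


def evaluate_prefix(
    actual: Sequence[float], predicted: Sequence[float], n: int
) -> MetricReport:
    """Metric report restricted to the first ``n`` pairs (2 <= n <= length)."""
    series = PairedSeries(actual, predicted)
    if not 2 <= n <= series.m:
        raise ValueError(f"N={n} outside [2, {series.m}]")
    return evaluate_all(series.prefix(n))


def table_uc3(
    noise_sd: float = DEFAULT_UC3_NOISE_SD, seed: int = DEFAULT_UC3_SEED
) -> pd.DataFrame:
    """Prefix-wise R² and cnSMAPE for the correct and wrong UC3 models.

    One row per prefix length N = 2..20, columns
    ``N, r2_correct, cnsmape_correct, r2_wrong, cnsmape_wrong``.
    """
    real, correct, wrong = build_uc3(noise_sd=noise_sd, seed=seed)
    rows = []
    for n in range(2, 21):
        rep_c = evaluate_prefix(real, correct, n)
        rep_w = evaluate_prefix(real, wrong, n)
        rows.append(
            {
                "N": n,
                "r2_correct": rep_c.r_squared,
                "cnsmape_correct": rep_c.cn_smape,
                "r2_wrong": rep_w.r_squared,
                "cnsmape_wrong": rep_w.cn_smape,
            }
        )
    return pd.DataFrame(rows)


def build_uc4() -> PairedSeries:
    """UC4 series: actual (1,1,1,1,1,2,3) against the constant prediction 1."""
    return PairedSeries([1, 1, 1, 1, 1, 2, 3], [1, 1, 1, 1, 1, 1, 1])


def enumerate_uc5(nonnegative_only: bool = False) -> pd.DataFrame:
    """Evaluate every prediction in {1..5}^5 against the actual (1,2,3,4,5).

    Returns a 3125-row frame in lexicographic order with columns
    ``p1..p5, r_squared, cn_smape``; with ``nonnegative_only`` the view is
    filtered to entries with R² >= 0 (the scatter data of the R² vs cnSMAPE
    comparison).
    """
    actual = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    rows = []
    for combo in itertools.product(range(1, 6), repeat=5):
        rep = evaluate_all(PairedSeries(actual, np.asarray(combo, dtype=float)))
        rows.append(combo + (rep.r_squared, rep.cn_smape))
    df = pd.DataFrame(
        rows, columns=["p1", "p2", "p3", "p4", "p5", "r_squared", "cn_smape"]
    )
    if nonnegative_only:
        df = df[df["r_squared"] >= 0.0].reset_index(drop=True)
    return df


def _load_fixture(name: str) -> PairedSeries:
    ref = resources.files("regeval.data").joinpath(name)
    with resources.as_file(ref) as path:
        return read_paired_csv(path)


def worked_example_r2_zero() -> PairedSeries:
    """Fixed 10-point pair whose MSE equals its total sum of squares
    (1051.511), hence R² ≈ 0: every prediction sits near the actual mean."""
    return _load_fixture("worked_example_r2_zero.csv")


def worked_example_smape_max() -> PairedSeries:
    """Fixed 10-point pair with strictly opposite signs at every position,
    attaining the SMAPE maximum of 2 (200%) regardless of magnitudes."""
    return _load_fixture("worked_example_smape_max.csv")


def evaluate_case(case_id: str, **configuration) -> UseCaseResult:
    """Build and evaluate one use-case configuration by identifier.

    Accepted identifiers and parameters: ``UC1`` (``j``), ``UC2``
    (``variant``), ``UC3`` (``model`` in {correct, wrong}, ``n``, optional
    ``noise_sd``/``seed``), ``UC4``, ``WE_R2_ZERO``, ``WE_SMAPE_MAX``.
    UC5 is an enumeration, not a single series; use :func:`enumerate_uc5`.
    """
    if case_id == "UC1":
        series = build_uc1(configuration["j"])
    elif case_id == "UC2":
        series = build_uc2(configuration["variant"])
    elif case_id == "UC3":
        noise_sd = configuration.get("noise_sd", DEFAULT_UC3_NOISE_SD)
        seed = configuration.get("seed", DEFAULT_UC3_SEED)
        real, correct, wrong = build_uc3(noise_sd=noise_sd, seed=seed)
        preds = {"correct": correct, "wrong": wrong}[configuration["model"]]
        n = configuration.get("n", 20)
        series = PairedSeries(real[:n], preds[:n])
    elif case_id == "UC4":
        series = build_uc4()
    elif case_id == "WE_R2_ZERO":
        series = worked_example_r2_zero()
    elif case_id == "WE_SMAPE_MAX":
        series = worked_example_smape_max()
    else:
        raise ValueError(f"unknown case_id {case_id!r}")
    return UseCaseResult(
        case_id=case_id,
        configuration=dict(configuration),
        series=series,
        report=evaluate_all(series),
    )
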