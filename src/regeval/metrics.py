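"""Regression evaluation metrics with fully specified degenerate-input semantics.

All metrics operate on a :class:`PairedSeries` — an aligned pair of
ground-truth values ``Y_i`` and predicted values ``X_i`` of common length
``m``.  Seven rates are provided:

* ``r_squared`` — coefficient of determination, ``1 - SSE/SST``; range
  ``(-inf, 1]``, 1 = perfect fit, 0 = the trivial mean predictor.
* ``mse``, ``rmse``, ``mae`` — quadratic / rooted-quadratic / absolute mean
  errors; range ``[0, inf)``.
* ``mape`` — mean absolute percentage error relative to the actual value;
  undefined whenever any actual value is zero.
* ``smape`` — symmetric mean absolute percentage error, per-point absolute
  error divided by the half-sum of absolute actual and predicted values,
  averaged; bounded in ``[0, 2]`` on the canonical fraction scale
  (``200%`` on the percentage scale).
* ``cn_smape`` — complementary normalized SMAPE, ``1 - SMAPE/2``; range
  ``[0, 1]``, 1 = perfect.

Degenerate inputs are resolved explicitly rather than left to floating-point
accidents: a constant actual vector makes ``r_squared`` undefined (raises
:class:`UndefinedMetricError`), a zero actual value makes ``mape``
undefined, and a SMAPE term with both values exactly zero contributes zero
error (an exact match), preserving ``smape == 0`` iff prediction equals
truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "PairedSeries",
    "MetricReport",
    "UndefinedMetricError",
    "mean_actual",
    "mst",
    "r_squared",
    "mse",
    "rmse",
    "mae",
    "mape",
    "smape_term",
    "smape",
    "cn_smape",
    "evaluate_all",
    "read_paired_csv",
    "write_paired_csv",
]

NA_TOKEN = "NA"


class UndefinedMetricError(ValueError):
    """A metric is mathematically undefined for the given input.

    Carries the metric name and the cause so callers can report both.
    """

    def __init__(self, metric: str, reason: str):
        self.metric = metric
        self.reason = reason
        super().__init__(f"{metric} is undefined: {reason}")


@dataclass(frozen=True)
class PairedSeries:
    """Aligned ground-truth (``actual``) and prediction (``predicted``) vectors.

    Both vectors are coerced to 1-D float arrays of identical length
    ``m >= 1`` and must contain only finite values; violations raise
    ``ValueError`` at construction, so every downstream metric may assume a
    valid series.
    """

    actual: np.ndarray
    predicted: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.actual, dtype=float).ravel()
        p = np.asarray(self.predicted, dtype=float).ravel()
        if a.size != p.size:
            raise ValueError(
                f"actual and predicted differ in length ({a.size} vs {p.size})"
            )
        if a.size == 0:
            raise ValueError("series must contain at least one pair")
        if not (np.isfinite(a).all() and np.isfinite(p).all()):
            raise ValueError("series entries must be finite (no NaN/inf)")
        a.setflags(write=False)
        p.setflags(write=False)
        object.__setattr__(self, "actual", a)
        object.__setattr__(self, "predicted", p)

    @property
    def m(self) -> int:
        """Number of paired observations."""
        return int(self.actual.size)

    def prefix(self, n: int) -> "PairedSeries":
        """The sub-series of the first ``n`` pairs (1 <= n <= m)."""
        if not 1 <= n <= self.m:
            raise ValueError(f"prefix length {n} outside [1, {self.m}]")
        return PairedSeries(self.actual[:n], self.predicted[:n])


@dataclass(frozen=True)
class MetricReport:
    """All seven metric values plus the two shared constants for one series.

    ``mst`` is stored mean-normalized, i.e. ``(1/m) * sum (Y_i - Ybar)^2``,
    matching the mean-normalized ``mse`` so that the identity
    ``r_squared == 1 - mse/mst`` holds whenever ``mst > 0`` (the ``1/m``
    factors cancel in the ratio).  ``smape`` is on the canonical fraction
    scale ``[0, 2]``; ``smape_pct = 100 * smape`` gives the percentage view.
    ``mape`` is ``nan`` with a non-empty ``mape_undefined_reason`` when any
    actual value is zero.
    """

    y_bar: float
    mst: float
    r_squared: float
    mse: float
    rmse: float
    mae: float
    mape: float
    smape: float
    cn_smape: float
    mape_undefined_reason: str = field(default="", compare=False)

    @property
    def smape_pct(self) -> float:
        """SMAPE on the percentage scale, in [0, 200]."""
        return 100.0 * self.smape

    @property
    def cn_smape_pct(self) -> float:
        """cnSMAPE expressed as a percentage of correctness, in [0, 100]."""
        return 100.0 * self.cn_smape

    def to_dict(self, na_token: str = NA_TOKEN) -> dict:
        """Flat mapping; undefined metrics become ``na_token`` plus a reason."""
        d = {
            "y_bar": self.y_bar,
            "mst": self.mst,
            "r_squared": self.r_squared,
            "mse": self.mse,
            "rmse": self.rmse,
            "mae": self.mae,
            "mape": na_token if math.isnan(self.mape) else self.mape,
            "smape": self.smape,
            "cn_smape": self.cn_smape,
            "mape_reason": self.mape_undefined_reason,
        }
        return d


def mean_actual(series: PairedSeries) -> float:
    """Arithmetic mean of the actual (ground-truth) values, ``Ybar``."""
    return float(np.mean(series.actual))


def mst(series: PairedSeries) -> float:
    """Mean total sum of squares, ``(1/m) * sum (Y_i - Ybar)^2``.

    The variance-like normalizer in the denominator of ``r_squared``; zero
    exactly when the actual vector is constant.
    """
    y = series.actual
    return float(np.mean((y - y.mean()) ** 2))


def mse(series: PairedSeries) -> float:
    """Mean squared error, ``(1/m) * sum (X_i - Y_i)^2``."""
    d = series.predicted - series.actual
    return float(np.mean(d * d))


def rmse(series: PairedSeries) -> float:
    """Root mean squared error, ``sqrt(mse)``."""
    return math.sqrt(mse(series))


def mae(series: PairedSeries) -> float:
    """Mean absolute error, ``(1/m) * sum |X_i - Y_i|``."""
    return float(np.mean(np.abs(series.predicted - series.actual)))


def r_squared(series: PairedSeries) -> float:
    """Coefficient of determination, ``1 - sum (X_i-Y_i)^2 / sum (Y_i-Ybar)^2``.

    Always <= 1; negative whenever the fit is worse than the horizontal
    line at ``Ybar``.  Invariant under common affine rescaling of both
    vectors.

    Raises
    ------
    UndefinedMetricError
        If the actual vector is constant (total sum of squares is zero).
    """
    sst = mst(series)
    if sst == 0.0:
        raise UndefinedMetricError(
            "r_squared", "actual values are constant (zero total sum of squares)"
        )
    return 1.0 - mse(series) / sst


def mape(series: PairedSeries) -> float:
    """Mean absolute percentage error, ``(1/m) * sum |Y_i - X_i| / |Y_i|``.

    Raises
    ------
    UndefinedMetricError
        If any actual value is zero — the metric is restricted to data with
        non-zero ground truth; points are never silently dropped.
    """
    y = series.actual
    if np.any(y == 0.0):
        raise UndefinedMetricError(
            "mape", "actual vector contains zero values (division by |Y_i|)"
        )
    # tiny |Y_i| can legitimately overflow the ratio to inf
    with np.errstate(over="ignore"):
        return float(np.mean(np.abs((y - series.predicted) / y)))


def smape_term(a: float, b: float) -> float:
    """Single SMAPE term ``|a - b| / ((|a| + |b|)/2)`` for prediction ``a``
    and actual ``b``, in ``[0, 2]``.

    The ``a == b == 0`` case is defined as 0: an exact match contributes no
    error, which keeps ``smape == 0`` equivalent to a perfect prediction.
    Whenever ``a`` and ``b`` have strictly opposite signs the term attains
    its maximum 2 regardless of magnitudes.
    """
    denom = abs(a) + abs(b)
    if denom == 0.0:
        return 0.0
    return abs(a - b) / (denom / 2.0)


def smape(series: PairedSeries) -> float:
    """Symmetric mean absolute percentage error on the fraction scale [0, 2].

    Mean of :func:`smape_term` over all pairs.  Multiply by 100 for the
    percentage view (200% = worst).
    """
    a = series.predicted
    b = series.actual
    denom = np.abs(a) + np.abs(b)
    terms = np.zeros_like(denom)
    nz = denom > 0.0
    terms[nz] = np.abs(a[nz] - b[nz]) / (denom[nz] / 2.0)
    return float(np.mean(terms))


def cn_smape(smape_value: float) -> float:
    """Complementary normalized SMAPE, ``1 - smape/2``; 1 = perfect, 0 = worst.

    Raises
    ------
    ValueError
        If the input lies outside [0, 2].
    """
    if not 0.0 <= smape_value <= 2.0:
        raise ValueError(f"SMAPE value {smape_value!r} outside [0, 2]")
    return 1.0 - smape_value / 2.0


def evaluate_all(series: PairedSeries) -> MetricReport:
    """Compute every metric for one series in a single :class:`MetricReport`.

    ``mape`` undefinedness (zero actuals) is recorded in the report rather
    than raised; a constant actual vector, however, propagates the
    ``r_squared`` :class:`UndefinedMetricError` since no field of the report
    would be meaningful as a goodness-of-fit summary.
    """
    r2 = r_squared(series)  # raises on constant actuals
    try:
        mape_val, mape_reason = mape(series), ""
    except UndefinedMetricError as exc:
        mape_val, mape_reason = math.nan, exc.reason
    smape_val = smape(series)
    return MetricReport(
        y_bar=mean_actual(series),
        mst=mst(series),
        r_squared=r2,
        mse=mse(series),
        rmse=rmse(series),
        mae=mae(series),
        mape=mape_val,
        smape=smape_val,
        cn_smape=cn_smape(smape_val),
        mape_undefined_reason=mape_reason,
    )


def read_paired_csv(path: Union[str, Path]) -> PairedSeries:
    """Read a two-column CSV with header ``actual,predicted`` into a series."""
    df = pd.read_csv(path)
    missing = {"actual", "predicted"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return PairedSeries(df["actual"].to_numpy(), df["predicted"].to_numpy())


def write_paired_csv(series: PairedSeries, path: Union[str, Path]) -> None:
    """Write a series as a two-column ``actual,predicted`` CSV."""
    pd.DataFrame(
        {"actual": series.actual, "predicted": series.predicted}
    ).to_csv(path, index=False)
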