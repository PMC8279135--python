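"""Unit and property tests for the seven regression rates."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from naive_oracle import (
    naive_mae,
    naive_mape,
    naive_mean,
    naive_mse,
    naive_mst,
    naive_r_squared,
    naive_rmse,
    naive_smape,
)
from regeval.metrics import (
    MetricReport,
    PairedSeries,
    UndefinedMetricError,
    cn_smape,
    evaluate_all,
    mae,
    mape,
    mean_actual,
    mse,
    mst,
    r_squared,
    read_paired_csv,
    rmse,
    smape,
    smape_term,
    write_paired_csv,
)

# The two 10-point vectors whose MSE equals the total sum of squares
WE_Y = [90.317571, 40.336481, 5.619065, 44.529437, 71.192687,
        32.036909, 6.977097, 66.425010, 95.971166, 5.756337]
WE_X = [45.02545, 43.75556, 41.18064, 42.09511, 44.85773,
        44.09390, 41.58419, 43.25487, 44.27568, 49.75250]

UC4 = PairedSeries([1, 1, 1, 1, 1, 2, 3], [1, 1, 1, 1, 1, 1, 1])


class TestPairedSeries:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            PairedSeries([1, 2], [1, 2, 3])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            PairedSeries([], [])

    @pytest.mark.parametrize("bad", [np.nan, np.inf, -np.inf])
    def test_nonfinite_rejected(self, bad):
        with pytest.raises(ValueError, match="finite"):
            PairedSeries([1.0, bad], [1.0, 2.0])

    def test_prefix(self):
        s = PairedSeries([1, 2, 3], [4, 5, 6])
        p = s.prefix(2)
        assert p.m == 2 and p.actual.tolist() == [1, 2]


class TestPointExamples:
    """Hand-derived and tabulated single-series values."""

    def test_mean_actual(self):
        assert mean_actual(PairedSeries([1, 2, 3, 4, 5], [0] * 5)) == 3.0
        assert mean_actual(PairedSeries(WE_Y, WE_X)) == pytest.approx(45.91618, abs=5e-6)
        assert mean_actual(PairedSeries([7.5] * 4, [0] * 4)) == 7.5

    def test_mst(self):
        assert mst(PairedSeries([1, 2, 3, 4, 5], [0] * 5)) == 2.0
        assert mst(PairedSeries([7.5] * 4, [0] * 4)) == 0.0
        assert mst(PairedSeries(WE_Y, WE_X)) == pytest.approx(1051.511, abs=5e-4)

    def test_mse_worked_example(self):
        assert mse(PairedSeries(WE_Y, WE_X)) == pytest.approx(1051.511, abs=5e-4)

    def test_r_squared_worked_example_near_zero(self):
        assert abs(r_squared(PairedSeries(WE_Y, WE_X))) <= 1e-6

    def test_mse_hand(self):
        assert mse(PairedSeries([0, 2], [1, 1])) == 1.0
        assert rmse(PairedSeries([0, 2], [1, 1])) == 1.0

    def test_rmse_worked_example(self):
        assert rmse(PairedSeries(WE_Y, WE_X)) == pytest.approx(32.4270, abs=5e-5)

    def test_mae_hand(self):
        assert mae(UC4) == pytest.approx(3 / 7, rel=1e-12)
        s = PairedSeries([1, 2, 3], [1 - 2.5, 2 - 2.5, 3 - 2.5])
        assert mae(s) == pytest.approx(2.5, rel=1e-12)

    def test_mape_hand(self):
        assert mape(PairedSeries([1, 2, 4], [2, 1, 2])) == pytest.approx(2 / 3, rel=1e-12)
        assert mape(PairedSeries([1, 2], [1, 2])) == 0.0

    def test_mape_zero_actual_undefined(self):
        with pytest.raises(UndefinedMetricError, match="mape"):
            mape(PairedSeries([1, 0, 2], [1, 1, 1]))

    def test_uc4_values(self):
        rep = evaluate_all(UC4)
        assert rep.r_squared == pytest.approx(-0.346, abs=5e-4)
        assert rep.smape == pytest.approx(0.238, abs=5e-4)
        assert rep.cn_smape_pct == pytest.approx(88.1, abs=0.05)

    def test_uc5_borderline_entry(self):
        rep = evaluate_all(PairedSeries([1, 2, 3, 4, 5], [1, 2, 3, 5, 2]))
        assert rep.r_squared == pytest.approx(0.0, abs=1e-12)
        assert round(rep.cn_smape, 2) == 0.89

    def test_r_squared_constant_actual_undefined(self):
        with pytest.raises(UndefinedMetricError, match="r_squared"):
            r_squared(PairedSeries([3, 3, 3], [1, 2, 3]))


class TestSmapeTerm:
    def test_exact_match_is_zero(self):
        assert smape_term(5.0, 5.0) == 0.0
        assert smape_term(0.0, 0.0) == 0.0  # 0/0 resolved as no error

    def test_zero_prediction_nonzero_actual_is_maximal(self):
        assert smape_term(0.0, 7.0) == 2.0
        assert smape_term(0.0, -7.0) == 2.0

    def test_opposite_signs_maximal(self):
        assert smape_term(-3.0, 800.0) == 2.0
        assert smape_term(0.001, -0.001) == 2.0

    def test_same_sign_below_maximum(self):
        assert smape_term(5.0, 1.0) < 2.0


class TestOppositeSignSmape:
    def test_printed_opposite_sign_vectors_reach_200_percent(self):
        actual = [1, -2, 3, -4, 5, -6, 7, -8, 9, -10]
        predicted = [-307.18, 636.16, -469.99, 671.53, -180.55,
                     838.23, -979.18, 455.16, -8.32, 366.80]
        s = PairedSeries(actual, predicted)
        assert smape(s) == 2.0
        rep = evaluate_all(s)
        assert rep.smape_pct == 200.0 and rep.cn_smape == 0.0

    def test_negated_prediction_same_signs_below_maximum(self):
        actual = [1, -2, 3, -4, 5, -6, 7, -8, 9, -10]
        predicted = [307.18, -636.16, 469.99, -671.53, 180.55,
                     -838.23, 979.18, -455.16, 8.32, -366.80]
        assert smape(PairedSeries(actual, predicted)) < 2.0


class TestCnSmape:
    @pytest.mark.parametrize(
        "value,expected", [(0.0, 1.0), (2.0, 0.0), (0.238, 0.881), (1.0, 0.5)]
    )
    def test_values(self, value, expected):
        assert cn_smape(value) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [-0.1, 2.1, 100.0])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            cn_smape(bad)


class TestEvaluateAll:
    def test_perfect_prediction(self):
        rep = evaluate_all(PairedSeries([1, 2, 3], [1, 2, 3]))
        assert rep.r_squared == 1.0
        assert rep.mse == rep.rmse == rep.mae == rep.mape == rep.smape == 0.0
        assert rep.cn_smape == 1.0

    def test_mape_flagged_not_raised(self):
        rep = evaluate_all(PairedSeries([0, 1, 2], [0, 1, 2]))
        assert math.isnan(rep.mape)
        assert rep.mape_undefined_reason
        assert rep.to_dict()["mape"] == "NA"

    def test_constant_actual_raises(self):
        with pytest.raises(UndefinedMetricError):
            evaluate_all(PairedSeries([2, 2, 2], [1, 2, 3]))

    def test_report_identities(self, rng):
        from conftest import random_series

        for m in (2, 5, 30):
            a, p = random_series(rng, m)
            rep = evaluate_all(PairedSeries(a, p))
            assert rep.rmse**2 == pytest.approx(rep.mse, rel=1e-8)
            assert rep.r_squared == pytest.approx(1 - rep.mse / rep.mst, rel=1e-8)
            assert rep.cn_smape == 1 - rep.smape / 2


class TestCsvRoundTrip:
    def test_round_trip(self, tmp_path):
        s = PairedSeries([1.5, -2.25, 3.125], [0.5, 0.0, -7.0])
        path = tmp_path / "series.csv"
        write_paired_csv(s, path)
        back = read_paired_csv(path)
        assert np.array_equal(back.actual, s.actual)
        assert np.array_equal(back.predicted, s.predicted)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("actual,other\n1,2\n")
        with pytest.raises(ValueError, match="predicted"):
            read_paired_csv(path)


# -- property tests -----------------------------------------------------

finite = st.floats(min_value=-1e6, max_value=1e6, allow_nan=False,
                   allow_infinity=False)


@st.composite
def paired_series(draw, min_size=2, max_size=10):
    m = draw(st.integers(min_size, max_size))
    actual = draw(
        st.lists(finite, min_size=m, max_size=m).filter(lambda v: max(v) > min(v))
    )
    predicted = draw(st.lists(finite, min_size=m, max_size=m))
    series = PairedSeries(actual, predicted)
    # huge-magnitude near-ties can make the variance round to exactly zero
    assume(mst(series) > 0)
    return series


@settings(derandomize=True, max_examples=200)
@given(paired_series())
def test_oracle_equivalence_short_series(series):
    """Vectorized metrics match the naive-loop oracle to 12 significant digits."""
    a, p = series.actual.tolist(), series.predicted.tolist()
    assert mean_actual(series) == pytest.approx(naive_mean(a), rel=1e-12, abs=1e-15)
    assert mst(series) == pytest.approx(naive_mst(a), rel=1e-12, abs=1e-15)
    assert mse(series) == pytest.approx(naive_mse(a, p), rel=1e-12, abs=1e-15)
    assert rmse(series) == pytest.approx(naive_rmse(a, p), rel=1e-12, abs=1e-15)
    assert mae(series) == pytest.approx(naive_mae(a, p), rel=1e-12, abs=1e-15)
    assert r_squared(series) == pytest.approx(naive_r_squared(a, p), rel=1e-12, abs=1e-12)
    assert smape(series) == pytest.approx(naive_smape(a, p), rel=1e-12, abs=1e-15)
    if all(y != 0 for y in a):
        assert mape(series) == pytest.approx(naive_mape(a, p), rel=1e-12, abs=1e-15)


@settings(derandomize=True, max_examples=200)
@given(paired_series())
def test_metric_bounds(series):
    rep = evaluate_all(series)
    assert rep.r_squared <= 1.0
    assert rep.mse >= 0 and rep.rmse >= 0 and rep.mae >= 0
    assert 0.0 <= rep.smape <= 2.0
    assert 0.0 <= rep.cn_smape <= 1.0


@settings(derandomize=True, max_examples=100)
@given(paired_series())
def test_smape_zero_iff_identity(series):
    if smape(series) == 0.0:
        assert np.array_equal(series.actual, series.predicted)
    if np.array_equal(series.actual, series.predicted):
        assert smape(series) == 0.0


@settings(derandomize=True, max_examples=100)
@given(
    paired_series(),
    st.floats(min_value=0.1, max_value=50).filter(lambda a: abs(a) > 1e-3),
    st.floats(min_value=-100, max_value=100),
    st.booleans(),
)
def test_r_squared_affine_invariance(series, scale, shift, negate):
    """R² is invariant under y -> a*y + b applied to both vectors (a != 0)."""
    a = -scale if negate else scale
    transformed = PairedSeries(a * series.actual + shift, a * series.predicted + shift)
    assert r_squared(transformed) == pytest.approx(r_squared(series), rel=1e-8, abs=1e-8)


def test_smape_not_affine_invariant_witness():
    """A concrete witness: shifting both vectors changes SMAPE."""
    base = PairedSeries([1, 2, 3], [2, 3, 4])
    shifted = PairedSeries([11, 12, 13], [12, 13, 14])
    assert smape(base) != pytest.approx(smape(shifted), rel=1e-6)


def test_ranking_by_r2_mirrors_mse_and_rmse(rng):
    """Against one actual vector, sorting predictions by R² descending equals
    sorting by MSE or RMSE ascending."""
    actual = rng.normal(size=25)
    preds = [actual + rng.normal(scale=s, size=25) for s in (0.1, 0.5, 1.0, 2.0, 5.0)]
    rng.shuffle(preds)
    series = [PairedSeries(actual, p) for p in preds]
    by_r2 = sorted(range(5), key=lambda i: -r_squared(series[i]))
    by_mse = sorted(range(5), key=lambda i: mse(series[i]))
    by_rmse = sorted(range(5), key=lambda i: rmse(series[i]))
    assert by_r2 == by_mse == by_rmse
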