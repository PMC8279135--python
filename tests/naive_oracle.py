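"""Independent naive-loop reference implementations of every metric.

Pure-Python loops over pairs using only the ``math`` module — deliberately
free of numpy and of any code path shared with the package — used as the
oracle that the vectorized implementations must match.
"""

import math


def naive_mean(values):
    total = 0.0
    for v in values:
        total += v
    return total / len(values)


def naive_mst(actual):
    ybar = naive_mean(actual)
    total = 0.0
    for y in actual:
        total += (y - ybar) ** 2
    return total / len(actual)


def naive_mse(actual, predicted):
    total = 0.0
    for y, x in zip(actual, predicted):
        total += (x - y) ** 2
    return total / len(actual)


def naive_rmse(actual, predicted):
    return math.sqrt(naive_mse(actual, predicted))


def naive_mae(actual, predicted):
    total = 0.0
    for y, x in zip(actual, predicted):
        total += abs(x - y)
    return total / len(actual)


def naive_mape(actual, predicted):
    total = 0.0
    for y, x in zip(actual, predicted):
        if y == 0:
            raise ZeroDivisionError("actual value is zero")
        total += abs((y - x) / y)
    return total / len(actual)


def naive_r_squared(actual, predicted):
    ybar = naive_mean(actual)
    sse = 0.0
    sst = 0.0
    for y, x in zip(actual, predicted):
        sse += (x - y) ** 2
        sst += (ybar - y) ** 2
    return 1.0 - sse / sst


def naive_smape(actual, predicted):
    total = 0.0
    for y, x in zip(actual, predicted):
        denom = abs(x) + abs(y)
        if denom > 0:
            total += abs(x - y) / (denom / 2.0)
    return total / len(actual)


def naive_cn_smape(actual, predicted):
    return 1.0 - naive_smape(actual, predicted) / 2.0
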