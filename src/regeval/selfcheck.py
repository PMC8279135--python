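"""End-to-end consistency checks runnable from the command line.

Each check recomputes a use-case quantity through the full metric pipeline
and compares it against an independent closed form or exact hand-derived
fraction (no stored pipeline output is reused), so a pass means the
construction, the metric implementations and their interaction are all
consistent.
"""

from __future__ import annotations

import math
from typing import List, NamedTuple

from .metrics import evaluate_all
from .use_cases import (
    UC2_VARIANTS,
    build_uc2,
    build_uc4,
    enumerate_uc5,
    table_uc1,
    uc1_cn_smape_closed_form,
    uc1_r_squared_closed_form,
    worked_example_r2_zero,
    worked_example_smape_max,
)

__all__ = ["CheckResult", "run_self_checks"]


class CheckResult(NamedTuple):
    name: str
    passed: bool
    detail: str


def _check(name: str, passed: bool, detail: str) -> CheckResult:
    return CheckResult(name, bool(passed), detail)


def run_self_checks() -> List[CheckResult]:
    """Run every consistency check; returns one result per check."""
    results: List[CheckResult] = []

    # UC1: pipeline vs closed forms for every tabulated j
    tab = table_uc1(range(0, 21))
    worst = 0.0
    for _, row in tab.iterrows():
        j = int(row["j"])
        worst = max(
            worst,
            abs(row["r_squared"] - uc1_r_squared_closed_form(j)),
            abs(row["cn_smape"] - uc1_cn_smape_closed_form(j)),
        )
    results.append(
        _check("uc1_closed_forms", worst < 1e-10, f"max |pipeline - closed form| = {worst:.2e}")
    )

    # UC2: cnSMAPE constant at 0.9, R² strictly position-sensitive,
    # R² matching the direct sum-of-squares form
    reports = {v: evaluate_all(build_uc2(v)) for v in UC2_VARIANTS}
    cn_ok = all(abs(r.cn_smape - 0.9) < 1e-12 for r in reports.values())
    results.append(
        _check("uc2_cnsmape_constant", cn_ok, "cnSMAPE = 0.9 in all three variants")
    )
    r2 = {v: reports[v].r_squared for v in UC2_VARIANTS}
    zero_ranges = {"start": range(1, 11), "middle": range(51, 61), "end": range(91, 101)}
    direct = {
        v: 1.0 - sum(i**2 for i in rng) / 83325.0 for v, rng in zero_ranges.items()
    }
    r2_ok = (
        r2["start"] > r2["middle"] > r2["end"]
        and all(abs(r2[v] - direct[v]) < 1e-10 for v in UC2_VARIANTS)
    )
    results.append(
        _check(
            "uc2_r2_position_sensitivity",
            r2_ok,
            f"R² start/middle/end = {r2['start']:.4f}/{r2['middle']:.4f}/{r2['end']:.4f}",
        )
    )

    # UC4: exact fractions R² = -9/26, SMAPE = 5/21, cnSMAPE = 37/42
    rep4 = evaluate_all(build_uc4())
    uc4_ok = (
        abs(rep4.r_squared - (-9.0 / 26.0)) < 1e-12
        and abs(rep4.smape - 5.0 / 21.0) < 1e-12
        and abs(rep4.cn_smape - 37.0 / 42.0) < 1e-12
    )
    results.append(
        _check(
            "uc4_exact_fractions",
            uc4_ok,
            f"R² = {rep4.r_squared:.6f}, SMAPE = {rep4.smape:.6f}",
        )
    )

    # UC5: full enumeration size, the R² = 0 borderline entry, unique optimum
    df5 = enumerate_uc5()
    entry = df5[(df5.p1 == 1) & (df5.p2 == 2) & (df5.p3 == 3) & (df5.p4 == 5) & (df5.p5 == 2)]
    perfect = df5[df5.r_squared >= 1.0 - 1e-12]
    uc5_ok = (
        len(df5) == 3125
        and len(entry) == 1
        and abs(float(entry.r_squared.iloc[0])) < 1e-12
        and abs(float(entry.cn_smape.iloc[0]) - 281.0 / 315.0) < 1e-12
        and len(perfect) == 1
        and tuple(perfect.iloc[0][["p1", "p2", "p3", "p4", "p5"]]) == (1, 2, 3, 4, 5)
    )
    results.append(
        _check("uc5_enumeration", uc5_ok, f"{len(df5)} grid entries, unique perfect fit")
    )

    # Worked examples: MSE ≈ MST (R² ≈ 0) and the SMAPE maximum
    we1 = evaluate_all(worked_example_r2_zero())
    results.append(
        _check(
            "worked_example_r2_zero",
            abs(we1.r_squared) < 1e-6 and abs(we1.mse / we1.mst - 1.0) < 1e-6,
            f"R² = {we1.r_squared:.2e}, MSE = {we1.mse:.3f}, MST = {we1.mst:.3f}",
        )
    )
    we2 = evaluate_all(worked_example_smape_max())
    results.append(
        _check(
            "worked_example_smape_max",
            math.isclose(we2.smape, 2.0, rel_tol=0, abs_tol=1e-12) and we2.cn_smape == 0.0,
            f"SMAPE = {we2.smape_pct:.1f}%",
        )
    )
    return results
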