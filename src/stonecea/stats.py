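"""Between-arm cohort comparisons from summary data.

Categorical outcomes (stone location shares, complication / clearance /
re-intervention / re-admission rates) are compared with the pooled
two-proportion z-test without continuity correction — the test that
reproduces the published stone-location p-values from the printed counts.
Continuous characteristics reported as mean (SD) per arm are compared with
a two-sample t-test computed from the summary statistics; the pooled
equal-variance variant is the default, Welch is available by flag.

Only marginal summaries are compared; no regression or multiplicity
adjustment is involved.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportions_ztest

from .cea import round_probability

__all__ = [
    "ProportionComparison",
    "SummaryComparison",
    "TestResult",
    "two_proportion_z_test",
    "summary_t_test",
    "cohort_comparison_table",
]


@dataclass(frozen=True)
class ProportionComparison:
    """Counts of an outcome in two arms, e.g. 18/100 vs 4/20."""

    successes_1: int
    n_1: int
    successes_2: int
    n_2: int
    label: str = ""

    def __post_init__(self):
        for x, n, arm in ((self.successes_1, self.n_1, 1), (self.successes_2, self.n_2, 2)):
            if n < 1:
                raise ValueError(f"{self.label or 'comparison'}: arm {arm} has n < 1")
            if not (0 <= x <= n):
                raise ValueError(
                    f"{self.label or 'comparison'}: arm {arm} successes {x} outside [0, {n}]"
                )


@dataclass(frozen=True)
class SummaryComparison:
    """Mean (SD) summaries of a continuous variable in two arms."""

    mean_1: float
    sd_1: float
    n_1: int
    mean_2: float
    sd_2: float
    n_2: int
    label: str = ""

    def __post_init__(self):
        if self.sd_1 < 0 or self.sd_2 < 0:
            raise ValueError(f"{self.label or 'comparison'}: negative SD")
        if self.n_1 < 2 or self.n_2 < 2:
            raise ValueError(f"{self.label or 'comparison'}: each arm needs n >= 2")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: Optional[float] = None  # absent for z-tests
    degenerate: bool = False  # zero-variance input


def two_proportion_z_test(cmp: ProportionComparison) -> TestResult:
    """Pooled two-proportion z-test, no continuity correction, two-sided.

    z = (p1 - p2) / sqrt(p_pool (1 - p_pool) (1/n1 + 1/n2)) with
    p_pool = (x1 + x2) / (n1 + n2).  When the pooled proportion is 0 or 1
    the variance is degenerate and the p-value is reported as 1.
    """
    pooled = (cmp.successes_1 + cmp.successes_2) / (cmp.n_1 + cmp.n_2)
    if pooled in (0.0, 1.0):
        return TestResult(0.0, 1.0, "two-proportion z (pooled)", degenerate=True)
    stat, p = proportions_ztest(
        count=np.array([cmp.successes_1, cmp.successes_2]),
        nobs=np.array([cmp.n_1, cmp.n_2]),
        alternative="two-sided",
        prop_var=False,
    )
    return TestResult(float(stat), float(p), "two-proportion z (pooled)")


def summary_t_test(cmp: SummaryComparison, variant: str = "pooled") -> TestResult:
    """Two-sample t-test from summary statistics.

    ``pooled`` uses the classical equal-variance statistic with
    df = n1 + n2 - 2; ``welch`` uses the Welch-Satterthwaite df.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    method = f"two-sample t ({variant})"
    if cmp.sd_1 == 0.0 and cmp.sd_2 == 0.0:
        if cmp.mean_1 == cmp.mean_2:
            return TestResult(0.0, 1.0, method, degenerate=True)
        return TestResult(np.inf if cmp.mean_1 > cmp.mean_2 else -np.inf, 0.0,
                          method, degenerate=True)
    stat, p = sps.ttest_ind_from_stats(
        cmp.mean_1, cmp.sd_1, cmp.n_1,
        cmp.mean_2, cmp.sd_2, cmp.n_2,
        equal_var=(variant == "pooled"),
    )
    if variant == "pooled":
        df = float(cmp.n_1 + cmp.n_2 - 2)
    else:
        v1, v2 = cmp.sd_1**2 / cmp.n_1, cmp.sd_2**2 / cmp.n_2
        df = (v1 + v2) ** 2 / (v1**2 / (cmp.n_1 - 1) + v2**2 / (cmp.n_2 - 1))
    return TestResult(float(stat), float(p), method, df=df)


Row = Union[ProportionComparison, SummaryComparison]


def cohort_comparison_table(rows: Sequence[Row], t_variant: str = "pooled") -> pd.DataFrame:
    """One row per comparison: arm summaries, test method, rounded p-value.

    p-values are rounded to 3 decimal places, half up, for presentation;
    the unrounded value is kept in ``p_value_raw``.
    """
    records: List[dict] = []
    for row in rows:
        if isinstance(row, ProportionComparison):
            res = two_proportion_z_test(row)
            arm1 = f"{row.successes_1}/{row.n_1}"
            arm2 = f"{row.successes_2}/{row.n_2}"
            value1 = row.successes_1 / row.n_1
            value2 = row.successes_2 / row.n_2
        elif isinstance(row, SummaryComparison):
            res = summary_t_test(row, t_variant)
            arm1 = f"{row.mean_1} ({row.sd_1})"
            arm2 = f"{row.mean_2} ({row.sd_2})"
            value1, value2 = row.mean_1, row.mean_2
        else:
            raise TypeError(f"unsupported comparison row {row!r}")
        records.append({
            "label": row.label,
            "arm1": arm1,
            "arm2": arm2,
            "value1": value1,
            "value2": value2,
            "method": res.method,
            "statistic": res.statistic,
            "df": res.df,
            "p_value": round_probability(res.p_value, 3),
            "p_value_raw": res.p_value,
        })
    columns = ["label", "arm1", "arm2", "value1", "value2", "method",
               "statistic", "df", "p_value", "p_value_raw"]
    return pd.DataFrame.from_records(records, columns=columns)
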