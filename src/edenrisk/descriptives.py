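"""Bivariate cohort description: cross-tabs, chi-square tests, age t-test.

Reproduces the usual "Table 1" layout: for every categorical covariate, the
count and row percentage of each category by outcome status with a Pearson
chi-square test over the full cross-tab, plus mean (SD) age by outcome with
a Welch two-sample t-test, and companion unadjusted odds ratios for 2x2
exposure tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CATEGORIES, COGNITION_CUTOFF, CohortTable

__all__ = ["TableOne", "table_one", "unadjusted_or", "OddsRatioCI"]

#: Table-1 variables in display order; cognition appears as its dichotomy.
_TABLE_VARIABLES = (
    "race", "gender", "education", "smoking", "dental_visit_2y", "alcohol",
    "cognition_lt23", "self_rated_health", "income", "lonely",
)


def _categorical_series(cohort: CohortTable, var: str) -> tuple[pd.Series, tuple[str, ...]]:
    if var == "cognition_lt23":
        score = cohort.data["cognition_score"].astype(float)
        values = pd.Series(
            np.where(score < COGNITION_CUTOFF, "Lt23", "Ge23"),
            index=cohort.data.index,
        )
        return values, ("Lt23", "Ge23")
    return cohort.data[var], CATEGORIES[var]


@dataclass
class TableOne:
    """Cohort description by outcome status."""

    rows: pd.DataFrame      # per (variable, category): counts and row pcts
    tests: pd.DataFrame     # per variable: chi-square statistic, df, p, valid
    age: dict               # mean/SD by outcome, Welch t statistic and p
    n: int

    def to_frame(self) -> pd.DataFrame:
        """Rendered table with percentages at 1 decimal."""
        out = self.rows.copy()
        out["pct_dentate"] = out["pct_dentate"].round(1)
        out["pct_edentulous"] = out["pct_edentulous"].round(1)
        return out


def table_one(cohort: CohortTable, yates_2x2: bool = False) -> TableOne:
    """Frequency distribution of baseline characteristics by outcome.

    Percentages are row percentages within each category. Chi-square tests
    are Pearson without continuity correction by default (`yates_2x2`
    applies Yates' correction to 2x2 tables only). A variable whose
    cross-tab contains an expected count of zero has its test flagged
    invalid rather than reported.
    """
    y = cohort.outcome
    rows = []
    tests = []
    for var in _TABLE_VARIABLES:
        values, levels = _categorical_series(cohort, var)
        table = np.array(
            [
                [int(((values == lv) & (y == 0)).sum()),
                 int(((values == lv) & (y == 1)).sum())]
                for lv in levels
            ]
        )
        totals = table.sum(axis=1)
        for lv, (n0, n1), tot in zip(levels, table, totals):
            rows.append(
                (var, lv, n0, 100.0 * n0 / tot if tot else np.nan,
                 n1, 100.0 * n1 / tot if tot else np.nan)
            )
        expected = np.outer(totals, table.sum(axis=0)) / table.sum()
        if np.any(expected == 0):
            tests.append((var, np.nan, np.nan, np.nan, False))
            continue
        correction = yates_2x2 and table.shape == (2, 2)
        chi2, p, df, _ = stats.chi2_contingency(table, correction=correction)
        tests.append((var, float(chi2), int(df), float(p), True))

    age = cohort.data["age"].astype(float)
    age0, age1 = age[y == 0], age[y == 1]
    t_stat, t_p = stats.ttest_ind(age1, age0, equal_var=False)
    age_row = {
        "mean_dentate": float(age0.mean()),
        "sd_dentate": float(age0.std(ddof=1)),
        "mean_edentulous": float(age1.mean()),
        "sd_edentulous": float(age1.std(ddof=1)),
        "t_statistic": float(t_stat),
        "p_value": float(t_p),
    }
    return TableOne(
        rows=pd.DataFrame(
            rows,
            columns=["variable", "category", "n_dentate", "pct_dentate",
                     "n_edentulous", "pct_edentulous"],
        ),
        tests=pd.DataFrame(
            tests, columns=["variable", "chi2", "df", "p_value", "valid"]
        ).set_index("variable"),
        age=age_row,
        n=len(cohort),
    )


@dataclass(frozen=True)
class OddsRatioCI:
    odds_ratio: float
    lower: float
    upper: float
    valid: bool = True

    def __iter__(self):
        return iter((self.odds_ratio, self.lower, self.upper))


def unadjusted_or(table, confidence: float = 0.95) -> OddsRatioCI:
    """Unadjusted odds ratio with a Woolf (log-scale) confidence interval.

    `table` is a 2x2 count array [[a, b], [c, d]] with exposure in rows and
    outcome in columns; OR = (a·d) / (b·c). When any single cell is zero,
    0.5 is added to every cell (Haldane-Anscombe); a table with an empty row
    or column is undefined and returned flagged invalid.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be a 2x2 array of non-negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return OddsRatioCI(np.nan, np.nan, np.nan, valid=False)
    if np.any(t == 0):
        t = t + 0.5
    a, b, c, d = t.ravel()
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    return OddsRatioCI(
        float(np.exp(log_or)),
        float(np.exp(log_or - z * se)),
        float(np.exp(log_or + z * se)),
    )
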