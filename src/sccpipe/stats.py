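"""Group-level statistics for treatment effects.

Unpaired two-sample t-test (pooled variance), Hedges' g effect size with the
exact small-sample bias correction, unbalanced two-way ANOVA with a
cell-type x treatment interaction (Type III sums of squares, sum-to-zero
coding), and the dose-response summary of percent reductions.

All two-group statistics are computable either from raw values or directly
from printed (mean, SD, n) summaries, so published summary tables can be
reanalyzed without the raw data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

import statsmodels.api as sm
import statsmodels.formula.api as smf

from .exceptions import DegenerateInputError, ValidationError

__all__ = [
    "GroupSummary",
    "GroupComparison",
    "AnovaTable",
    "summarize",
    "two_sample_t",
    "two_sample_t_from_summaries",
    "hedges_g",
    "two_way_anova_unbalanced",
    "dose_response_summary",
]


@dataclass(frozen=True)
class GroupSummary:
    """(mean, SD, n) of one group, in percent-of-pre units."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError(f"group {self.label}: need n >= 2, got {self.n}")
        if self.sd < 0:
            raise ValidationError(f"group {self.label}: sd must be >= 0")


@dataclass(frozen=True)
class GroupComparison:
    summary_a: GroupSummary
    summary_b: GroupSummary
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    hedges_g: float


def summarize(values, label: str = "") -> GroupSummary:
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValidationError(f"group {label}: need n >= 2, got {len(values)}")
    return GroupSummary(
        label=label, n=len(values), mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
    )


def _pooled_sd(a: GroupSummary, b: GroupSummary) -> float:
    df = a.n + b.n - 2
    return math.sqrt(((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df)


def two_sample_t_from_summaries(a: GroupSummary, b: GroupSummary) -> GroupComparison:
    """Pooled-variance unpaired two-sample t-test from group summaries."""
    df = a.n + b.n - 2
    sp = _pooled_sd(a, b)
    diff = a.mean - b.mean
    if sp == 0:
        if diff == 0:
            return GroupComparison(a, b, 0.0, df, 1.0, 0.0)
        raise DegenerateInputError("zero pooled variance with unequal means")
    t = diff / (sp * math.sqrt(1.0 / a.n + 1.0 / b.n))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    g = hedges_g(a, b)
    return GroupComparison(a, b, float(t), df, p, g)


def two_sample_t(a, b, labels: tuple = ("a", "b")) -> GroupComparison:
    """Pooled-variance t-test from raw values (each group needs n >= 2)."""
    return two_sample_t_from_summaries(
        summarize(a, labels[0]), summarize(b, labels[1])
    )


def _correction_exact(df: int) -> float:
    # J(df) = Gamma(df/2) / (sqrt(df/2) * Gamma((df-1)/2))
    return math.exp(gammaln(df / 2.0) - gammaln((df - 1) / 2.0)) / math.sqrt(df / 2.0)


def _correction_approx(df: int) -> float:
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def hedges_g(a: GroupSummary, b: GroupSummary, exact: bool = True) -> float:
    """Bias-corrected standardized mean difference (mean_a - mean_b) / s_pooled.

    ``exact`` uses the gamma-function small-sample correction; otherwise the
    1 - 3/(4 df - 1) approximation.  With the convention control first,
    positive g means treatment reduced the biomarker retention.
    """
    if a.n + b.n < 4:
        raise ValidationError("hedges_g requires n_a + n_b >= 4")
    sp = _pooled_sd(a, b)
    diff = a.mean - b.mean
    if sp == 0:
        if diff == 0:
            return 0.0
        raise DegenerateInputError("zero pooled SD with unequal means")
    df = a.n + b.n - 2
    J = _correction_exact(df) if exact else _correction_approx(df)
    return J * diff / sp


@dataclass(frozen=True)
class AnovaTable:
    """Per-factor sum of squares, df, F and p for the 2x2 factorial model."""

    factors: dict  # name -> {"sum_sq": .., "df": .., "F": .., "p": ..}

    def __getitem__(self, factor: str) -> dict:
        return self.factors[factor]


def two_way_anova_unbalanced(effects: pd.DataFrame) -> AnovaTable:
    """Factorial ANOVA with interaction on an (unbalanced) 2x2 design.

    ``effects`` needs columns value / cell_type / treatment.  The linear
    model uses sum-to-zero factor coding and Type III sums of squares, the
    appropriate test for unbalanced factorial designs.
    """
    for col in ("value", "cell_type", "treatment"):
        if col not in effects.columns:
            raise ValidationError(f"effects table lacks column {col!r}")
    counts = effects.groupby(["cell_type", "treatment"]).size()
    if (effects["cell_type"].nunique() < 2) or (effects["treatment"].nunique() < 2):
        raise ValidationError("both factors need two levels present")
    if (counts >= 2).sum() < 3:
        raise ValidationError("need >= 2 observations in at least 3 of the 4 cells")
    model = smf.ols(
        "value ~ C(cell_type, Sum) * C(treatment, Sum)", data=effects
    ).fit()
    table = sm.stats.anova_lm(model, typ=3)
    mapping = {
        "C(cell_type, Sum)": "cell_type",
        "C(treatment, Sum)": "treatment",
        "C(cell_type, Sum):C(treatment, Sum)": "interaction",
        "Residual": "residual",
    }
    factors = {}
    for row_name, name in mapping.items():
        row = table.loc[row_name]
        factors[name] = {
            "sum_sq": float(row["sum_sq"]),
            "df": int(row["df"]),
            "F": float(row["F"]) if np.isfinite(row["F"]) else float("nan"),
            "p": float(row["PR(>F)"]) if np.isfinite(row["PR(>F)"]) else float("nan"),
        }
    return AnovaTable(factors)


DOSE_ORDER = ["control", "treated_1x", "treated_2x"]


def dose_response_summary(effects_by_group: dict) -> pd.DataFrame:
    """Per-arm mean +/- SD of percent reduction (100 - percent_of_pre).

    ``effects_by_group`` maps a group label to a sequence of percent_of_pre
    values; arms are ordered by dose.  Empty groups are omitted.
    """
    if not any(len(v) for v in effects_by_group.values()):
        raise ValidationError("at least one group must be non-empty")
    rows = []
    order = [g for g in DOSE_ORDER if g in effects_by_group] + [
        g for g in effects_by_group if g not in DOSE_ORDER
    ]
    for group in order:
        values = np.asarray(effects_by_group[group], dtype=float)
        if len(values) == 0:
            continue
        reduction = 100.0 - values
        rows.append(
            {
                "group": group,
                "n": len(values),
                "mean_reduction_pct": float(reduction.mean()),
                "sd_reduction_pct": float(reduction.std(ddof=1)) if len(values) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["group", "n", "mean_reduction_pct", "sd_reduction_pct"])
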