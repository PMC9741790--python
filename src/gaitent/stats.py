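"""Balanced fixed-effects two-way ANOVA and split-plot mixed ANOVA.

The sensitivity analysis compares entropy across processing Type and
template length m with a two-way fixed-effects ANOVA per walking condition,
and compares walking conditions at fixed m with a mixed ANOVA: walking
velocity within-subjects, processing method between-subjects. Both designs
are balanced by construction (equal cell counts), which is also what makes
the F-test robust to mild normality violations; unbalanced or incomplete
tables are rejected rather than approximated.

For the study's full design the degrees of freedom reproduce the familiar
patterns: 4 Types x 5 m-levels x 23 subjects gives effect dfs (3, 440),
(4, 440), (12, 440); the mixed design with 4 Types x 23 subjects x 2
velocities gives (3, 88) between and (1, 88) within.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from gaitent.errors import BalanceError, PairingError


@dataclass
class EffectResult:
    """One ANOVA effect: F statistic, dfs, p-value and its sum of squares."""

    F: float
    df1: int
    df2: int
    p: float
    ss: float
    ms: float


@dataclass
class AnovaResult:
    """Per-effect F tests plus the error strata, with a design descriptor."""

    effects: dict[str, EffectResult]
    error_ss: dict[str, float]
    error_df: dict[str, int]
    total_ss: float
    design: str

    def to_dict(self) -> dict:
        return {
            "design": self.design,
            "effects": {
                k: {"F": e.F, "df1": e.df1, "df2": e.df2, "p": e.p, "ss": e.ss}
                for k, e in self.effects.items()
            },
            "error_ss": self.error_ss,
            "error_df": self.error_df,
            "total_ss": self.total_ss,
        }


def _check_complete_balanced(table: pd.DataFrame, factors: list[str], value: str) -> int:
    """Return the common cell count n; raise BalanceError otherwise."""
    import itertools

    counts = table.groupby(factors, observed=True)[value].count()
    expected = set(itertools.product(*[table[f].unique() for f in factors]))
    present = {i if isinstance(i, tuple) else (i,) for i in counts.index}
    if present != expected:
        missing = sorted(expected - present, key=str)
        raise BalanceError(f"incomplete design: empty cells {missing}", cells=missing)
    if counts.nunique() != 1:
        bad = counts[counts != counts.mode().iloc[0]]
        raise BalanceError(
            f"unbalanced design: cell counts vary ({sorted(counts.unique())})",
            cells=list(bad.index),
        )
    return int(counts.iloc[0])


def two_way_anova(
    table: pd.DataFrame,
    value: str = "sampen_value",
    factor_a: str = "type_tag",
    factor_b: str = "m",
) -> AnovaResult:
    """Balanced two-way fixed-effects ANOVA with interaction.

    Classical sums-of-squares decomposition on cell means; requires a
    complete, balanced table with at least 2 replicates per cell. Effects
    are keyed by the factor column names plus ``"<a>:<b>"``.
    """
    for col in (value, factor_a, factor_b):
        if col not in table.columns:
            raise BalanceError(f"missing column {col!r}")
    n = _check_complete_balanced(table, [factor_a, factor_b], value)
    if n < 2:
        raise BalanceError("need >= 2 replicates per cell for an error term")
    if table[factor_a].nunique() < 2 or table[factor_b].nunique() < 2:
        raise BalanceError("each factor needs >= 2 levels")

    y = table[value].to_numpy(dtype=float)
    grand = y.mean()
    a_levels = table[factor_a].nunique()
    b_levels = table[factor_b].nunique()

    mean_a = table.groupby(factor_a, observed=True)[value].mean()
    mean_b = table.groupby(factor_b, observed=True)[value].mean()
    mean_ab = table.groupby([factor_a, factor_b], observed=True)[value].mean()

    ss_a = b_levels * n * float(((mean_a - grand) ** 2).sum())
    ss_b = a_levels * n * float(((mean_b - grand) ** 2).sum())
    cell_dev = (
        mean_ab
        - mean_a.reindex(mean_ab.index.get_level_values(0)).to_numpy()
        - mean_b.reindex(mean_ab.index.get_level_values(1)).to_numpy()
        + grand
    )
    ss_ab = n * float((cell_dev**2).sum())
    cell_of_row = mean_ab.loc[
        list(zip(table[factor_a], table[factor_b]))
    ].to_numpy()
    ss_err = float(((y - cell_of_row) ** 2).sum())
    ss_tot = float(((y - grand) ** 2).sum())

    df_a, df_b = a_levels - 1, b_levels - 1
    df_ab = df_a * df_b
    df_err = a_levels * b_levels * (n - 1)
    ms_err = ss_err / df_err

    def effect(ss, df):
        ms = ss / df
        F = ms / ms_err if ms_err > 0 else (0.0 if ss == 0 else np.inf)
        return EffectResult(F=float(F), df1=df, df2=df_err, p=float(f_dist.sf(F, df, df_err)), ss=ss, ms=ms)

    return AnovaResult(
        effects={
            factor_a: effect(ss_a, df_a),
            factor_b: effect(ss_b, df_b),
            f"{factor_a}:{factor_b}": effect(ss_ab, df_ab),
        },
        error_ss={"error": ss_err},
        error_df={"error": df_err},
        total_ss=ss_tot,
        design=f"two-way fixed ({a_levels}x{b_levels}, n={n})",
    )


def mixed_anova(
    table: pd.DataFrame,
    value: str = "sampen_value",
    within: str = "condition",
    between: str = "type_tag",
    unit: str = "unit_id",
) -> AnovaResult:
    """Balanced split-plot (mixed) ANOVA: one within- and one between-factor.

    Each unit (subject, or subject x processing method when the method is
    treated as a between-subjects factor) must appear exactly once per level
    of the within-factor, and the between-groups must hold equally many
    units. Between effects are tested against unit-within-group variation;
    within effects against the residual unit x within interaction.
    """
    for col in (value, within, between, unit):
        if col not in table.columns:
            raise BalanceError(f"missing column {col!r}")

    w_levels = sorted(table[within].unique())
    w = len(w_levels)
    per_unit = table.groupby(unit, observed=True)[within].agg(["count", "nunique"])
    bad = per_unit[(per_unit["count"] != w) | (per_unit["nunique"] != w)]
    if len(bad):
        raise PairingError(
            f"units missing a {within} level or duplicated: {list(bad.index[:5])}"
        )
    unit_between = table.groupby(unit, observed=True)[between].nunique()
    if (unit_between != 1).any():
        raise PairingError("each unit must belong to exactly one between-group")
    group_sizes = table.drop_duplicates(unit).groupby(between, observed=True)[unit].count()
    if group_sizes.nunique() != 1:
        raise BalanceError(
            f"between-groups unbalanced: sizes {dict(group_sizes)}", cells=list(group_sizes.index)
        )

    g = table[between].nunique()
    s = int(group_sizes.iloc[0])

    y = table[value].to_numpy(dtype=float)
    grand = y.mean()
    ss_tot = float(((y - grand) ** 2).sum())

    unit_means = table.groupby(unit, observed=True)[value].mean()
    group_means = table.groupby(between, observed=True)[value].mean()
    within_means = table.groupby(within, observed=True)[value].mean()
    gw_means = table.groupby([between, within], observed=True)[value].mean()

    ss_between_units = w * float(((unit_means - grand) ** 2).sum())
    ss_b = s * w * float(((group_means - grand) ** 2).sum())
    ss_units_within = ss_between_units - ss_b

    ss_w = g * s * float(((within_means - grand) ** 2).sum())
    dev = (
        gw_means
        - group_means.reindex(gw_means.index.get_level_values(0)).to_numpy()
        - within_means.reindex(gw_means.index.get_level_values(1)).to_numpy()
        + grand
    )
    ss_bw = s * float((dev**2).sum())
    ss_err_within = ss_tot - ss_between_units - ss_w - ss_bw

    df_b = g - 1
    df_units = g * (s - 1)
    df_w = w - 1
    df_bw = df_b * df_w
    df_err_w = g * (s - 1) * (w - 1)

    ms_units = ss_units_within / df_units
    ms_err_w = ss_err_within / df_err_w

    def effect(ss, df, ms_err, df_err):
        ms = ss / df
        F = ms / ms_err if ms_err > 0 else (0.0 if ss == 0 else np.inf)
        return EffectResult(F=float(F), df1=df, df2=df_err, p=float(f_dist.sf(F, df, df_err)), ss=ss, ms=ms)

    return AnovaResult(
        effects={
            between: effect(ss_b, df_b, ms_units, df_units),
            within: effect(ss_w, df_w, ms_err_w, df_err_w),
            f"{within}:{between}": effect(ss_bw, df_bw, ms_err_w, df_err_w),
        },
        error_ss={"units_within_groups": ss_units_within, "within_residual": ss_err_within},
        error_df={"units_within_groups": df_units, "within_residual": df_err_w},
        total_ss=ss_tot,
        design=f"mixed: {between} between ({g} groups x {s} units), {within} within ({w} levels)",
    )
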