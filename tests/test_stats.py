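"""ANOVA df structure, SS decomposition, and agreement with external oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gaitent.errors import BalanceError, PairingError
from gaitent.stats import mixed_anova, two_way_anova


def make_two_way(a_levels, b_levels, n, rng, effect=None):
    rows = []
    for a, b, s in itertools.product(range(a_levels), range(b_levels), range(n)):
        y = rng.normal()
        if effect:
            y += effect(a, b)
        rows.append({"type_tag": f"T{a}", "m": b, "subject_id": s, "sampen_value": y})
    return pd.DataFrame(rows)


def make_mixed(groups, units_per_group, rng, cond_effect=0.0):
    rows = []
    for g, u in itertools.product(range(groups), range(units_per_group)):
        base = rng.normal()
        for cond in ("Vpref", "Vmax"):
            rows.append(
                {
                    "type_tag": f"T{g}",
                    "unit_id": f"T{g}-U{u}",
                    "condition": cond,
                    "sampen_value": base + rng.normal(scale=0.5)
                    + (cond_effect if cond == "Vmax" else 0.0),
                }
            )
    return pd.DataFrame(rows)


class TestTwoWay:
    def test_study_design_df_pattern(self, rng):
        """4 Types x 5 m-levels x 23 subjects -> dfs (3,440), (4,440), (12,440)."""
        df = make_two_way(4, 5, 23, rng)
        res = two_way_anova(df)
        assert (res.effects["type_tag"].df1, res.effects["type_tag"].df2) == (3, 440)
        assert (res.effects["m"].df1, res.effects["m"].df2) == (4, 440)
        assert (res.effects["type_tag:m"].df1, res.effects["type_tag:m"].df2) == (12, 440)

    def test_all_equal_values_give_zero_f(self, rng):
        df = make_two_way(3, 4, 5, rng)
        df["sampen_value"] = 1.5
        res = two_way_anova(df)
        assert all(e.F == 0.0 for e in res.effects.values())

    def test_agrees_with_statsmodels(self, rng):
        statsmodels = pytest.importorskip("statsmodels")
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        df = make_two_way(2, 2, 5, rng, effect=lambda a, b: 0.8 * a + 0.3 * a * b)
        res = two_way_anova(df)
        fit = ols("sampen_value ~ C(type_tag) * C(m)", df).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        assert res.effects["type_tag"].F == pytest.approx(tab.loc["C(type_tag)", "F"], abs=1e-8)
        assert res.effects["m"].F == pytest.approx(tab.loc["C(m)", "F"], abs=1e-8)
        assert res.effects["type_tag:m"].F == pytest.approx(
            tab.loc["C(type_tag):C(m)", "F"], abs=1e-8
        )

    def test_ss_decomposition_identity(self, rng):
        df = make_two_way(4, 5, 7, rng)
        res = two_way_anova(df)
        parts = sum(e.ss for e in res.effects.values()) + res.error_ss["error"]
        assert parts == pytest.approx(res.total_ss, abs=1e-8)

    def test_constant_shift_leaves_f_unchanged(self, rng):
        df = make_two_way(3, 3, 4, rng)
        res1 = two_way_anova(df)
        df2 = df.assign(sampen_value=df["sampen_value"] + 100.0)
        res2 = two_way_anova(df2)
        for k in res1.effects:
            assert res1.effects[k].F == pytest.approx(res2.effects[k].F, rel=1e-9)

    def test_unbalanced_table_rejected(self, rng):
        df = make_two_way(2, 3, 4, rng).iloc[:-1]
        with pytest.raises(BalanceError):
            two_way_anova(df)

    def test_incomplete_design_rejected(self, rng):
        df = make_two_way(2, 3, 4, rng)
        df = df[~((df["type_tag"] == "T1") & (df["m"] == 2))]
        with pytest.raises(BalanceError):
            two_way_anova(df)


class TestMixed:
    def test_study_design_df_pattern(self, rng):
        """4 Types x 23 subject-units x 2 velocities -> (3,88) and (1,88)."""
        df = make_mixed(4, 23, rng)
        res = mixed_anova(df)
        assert (res.effects["type_tag"].df1, res.effects["type_tag"].df2) == (3, 88)
        assert (res.effects["condition"].df1, res.effects["condition"].df2) == (1, 88)
        assert (res.effects["condition:type_tag"].df1, res.effects["condition:type_tag"].df2) == (3, 88)

    def test_identical_conditions_give_zero_velocity_f(self, rng):
        df = make_mixed(3, 6, rng)
        wide = df.pivot_table(index=["unit_id", "type_tag"], columns="condition",
                              values="sampen_value").reset_index()
        wide["Vmax"] = wide["Vpref"]
        df = wide.melt(id_vars=["unit_id", "type_tag"], var_name="condition",
                       value_name="sampen_value")
        res = mixed_anova(df)
        assert res.effects["condition"].F == pytest.approx(0.0, abs=1e-20)

    def test_agrees_with_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        df = make_mixed(3, 8, rng, cond_effect=0.4)
        res = mixed_anova(df)
        tab = pg.mixed_anova(
            df, dv="sampen_value", within="condition", between="type_tag", subject="unit_id"
        ).set_index("Source")
        assert res.effects["type_tag"].F == pytest.approx(tab.loc["type_tag", "F"], abs=1e-8)
        assert res.effects["condition"].F == pytest.approx(tab.loc["condition", "F"], abs=1e-8)
        assert res.effects["condition:type_tag"].F == pytest.approx(
            tab.loc["Interaction", "F"], abs=1e-8
        )

    def test_ss_decomposition_identity(self, rng):
        df = make_mixed(4, 10, rng, cond_effect=0.3)
        res = mixed_anova(df)
        parts = sum(e.ss for e in res.effects.values()) + sum(res.error_ss.values())
        assert parts == pytest.approx(res.total_ss, abs=1e-8)

    def test_power_of_designed_within_effect(self):
        """An injected velocity effect of 1 SD is detected (p < 0.05) in at
        least 90% of 100 simulated small designs."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            df = make_mixed(2, 5, rng, cond_effect=1.0)
            res = mixed_anova(df)
            hits += res.effects["condition"].p < 0.05
        assert hits >= 90

    def test_missing_condition_rejected(self, rng):
        df = make_mixed(2, 4, rng)
        df = df[~((df["unit_id"] == "T0-U0") & (df["condition"] == "Vmax"))]
        with pytest.raises(PairingError):
            mixed_anova(df)

    def test_unbalanced_groups_rejected(self, rng):
        df = make_mixed(2, 4, rng)
        df = df[df["unit_id"] != "T0-U3"]
        with pytest.raises(BalanceError):
            mixed_anova(df)
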