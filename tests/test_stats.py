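"""Factorial statistics: two-way ANOVA, Tukey HSD, Cohen's f."""

import itertools

import numpy as np
import pandas as pd
import pytest

from emgcycle import (
    CoactivationAnova,
    anova_f_from_table,
    classify_effect_size,
    cohens_f,
    significance_stars,
    tukey_hsd,
    two_way_anova,
)
from emgcycle.errors import ConfigurationError
from emgcycle.stats import INTERACTION_ROW, PHASE_ROW, RESIDUAL_ROW, SPEED_ROW

PHASES = ["Acc_Flex", "Dec_Flex", "Acc_Ext", "Dec_Ext"]
SPEEDS = [42, 60, 78]


def balanced_table(cell_mean, noise_sd=0.0, n_subjects=10, seed=0):
    """One observation per subject x speed x phase cell with optional noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for s, sp, ph in itertools.product(range(n_subjects), SPEEDS, PHASES):
        rows.append(
            {
                "subject": s,
                "speed": sp,
                "phase": ph,
                "cc": cell_mean(ph, sp) + noise_sd * rng.standard_normal(),
            }
        )
    return pd.DataFrame(rows)


class TestAnovaArithmetic:
    def test_f_recomputed_from_tabulated_ss_and_df(self):
        # published-table audit: F = (SS/df) / (SS_err/df_err)
        out = anova_f_from_table(
            effect_ss={"Phase": 7336.39, "Speed": 26.54, "Phase x Speed": 242.10},
            effect_df={"Phase": 3, "Speed": 2, "Phase x Speed": 6},
            residual_ss=35816.19,
            residual_df=188,
        )
        assert round(out.loc["Phase", "F"], 2) == 12.84
        assert round(out.loc["Speed", "F"], 2) == 0.07
        assert round(out.loc["Phase x Speed", "F"], 2) == 0.21

    def test_constant_observations_give_zero_effects(self):
        table = two_way_anova(balanced_table(lambda ph, sp: 30.0)).table
        for row in (PHASE_ROW, SPEED_ROW, INTERACTION_ROW):
            assert table.loc[row, "SS"] == pytest.approx(0.0, abs=1e-8)
            assert table.loc[row, "F"] == 0.0

    def test_two_by_two_matches_brute_force_decomposition(self):
        # direct sum-of-squares oracle on a balanced 2x2 design
        rng = np.random.default_rng(5)
        levels_a, levels_b, n = ["p1", "p2"], [1, 2], 8
        rows = []
        for a, b in itertools.product(levels_a, levels_b):
            mu = {("p1", 1): 10, ("p1", 2): 12, ("p2", 1): 15, ("p2", 2): 13}[(a, b)]
            for _ in range(n):
                rows.append({"phase": a, "speed": b, "cc": mu + rng.standard_normal()})
        df = pd.DataFrame(rows)
        y = df["cc"].to_numpy()
        grand = y.mean()
        ss_a = sum(
            len(g) * (g["cc"].mean() - grand) ** 2 for _, g in df.groupby("phase")
        )
        ss_b = sum(
            len(g) * (g["cc"].mean() - grand) ** 2 for _, g in df.groupby("speed")
        )
        ss_cells = sum(
            len(g) * (g["cc"].mean() - grand) ** 2
            for _, g in df.groupby(["phase", "speed"])
        )
        ss_ab = ss_cells - ss_a - ss_b
        ss_err = sum(
            ((g["cc"] - g["cc"].mean()) ** 2).sum()
            for _, g in df.groupby(["phase", "speed"])
        )
        table = two_way_anova(df).table
        assert table.loc[PHASE_ROW, "SS"] == pytest.approx(ss_a, rel=1e-9)
        assert table.loc[SPEED_ROW, "SS"] == pytest.approx(ss_b, rel=1e-9)
        assert table.loc[INTERACTION_ROW, "SS"] == pytest.approx(ss_ab, rel=1e-9)
        assert table.loc[RESIDUAL_ROW, "SS"] == pytest.approx(ss_err, rel=1e-9)

    def test_ss_additivity_on_balanced_design(self):
        df = balanced_table(lambda ph, sp: 25 + 3 * PHASES.index(ph), noise_sd=4.0)
        table = two_way_anova(df).table
        total = ((df["cc"] - df["cc"].mean()) ** 2).sum()
        assert table["SS"].sum() == pytest.approx(total, rel=1e-9)

    def test_f_invariant_to_constant_shift(self):
        df = balanced_table(lambda ph, sp: 25 + 3 * PHASES.index(ph), noise_sd=4.0)
        shifted = df.assign(cc=df["cc"] + 500.0)
        a = two_way_anova(df).table
        b = two_way_anova(shifted).table
        assert a.loc[PHASE_ROW, "F"] == pytest.approx(b.loc[PHASE_ROW, "F"], rel=1e-9)

    def test_empty_cell_reported_by_name(self):
        df = balanced_table(lambda ph, sp: 30.0, n_subjects=2)
        df = df[~((df["phase"] == "Dec_Flex") & (df["speed"] == 78))]
        with pytest.raises(ConfigurationError, match="Dec_Flex"):
            two_way_anova(df)

    def test_single_level_factor_rejected(self):
        df = balanced_table(lambda ph, sp: 30.0, n_subjects=2)
        with pytest.raises(ConfigurationError):
            two_way_anova(df[df["speed"] == 60])


class TestTukey:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "phase": np.repeat(PHASES, 20),
                "cc": np.tile(30 + rng.standard_normal(20), 4),
            }
        )
        out = tukey_hsd(df, factor="phase")
        assert (out["p_adj"] > 0.99).all()
        assert not out["reject"].any()

    def test_inflated_flexion_deceleration_separates_from_lowest_group(self):
        # Dec_Flex pushed far above; Acc_Ext lowest: their contrast has the
        # smallest adjusted p among all pairs
        means = {"Acc_Flex": 28, "Dec_Flex": 55, "Acc_Ext": 20, "Dec_Ext": 28}
        df = balanced_table(lambda ph, sp: means[ph], noise_sd=8.0, n_subjects=20)
        out = tukey_hsd(df, factor="phase")
        pairs = out.set_index(["level_1", "level_2"])["p_adj"]
        target = pairs.loc[("Acc_Ext", "Dec_Flex")]
        assert target == pairs.min()
        assert target < 0.001

    def test_ordering_agrees_with_permutation_oracle(self):
        # tiny 3-group example: the ranking of adjusted p-values matches a
        # label-permutation test's ranking of pairwise mean differences
        rng = np.random.default_rng(11)
        groups = {"a": 10 + rng.standard_normal(6), "b": 11.5 + rng.standard_normal(6),
                  "c": 16 + rng.standard_normal(6)}
        df = pd.DataFrame(
            [{"phase": g, "cc": v} for g, vals in groups.items() for v in vals]
        )
        out = tukey_hsd(df, factor="phase")

        def perm_p(x, y, n_perm=4000):
            pooled = np.concatenate([x, y])
            observed = abs(x.mean() - y.mean())
            prng = np.random.default_rng(0)
            hits = 0
            for _ in range(n_perm):
                prng.shuffle(pooled)
                if abs(pooled[: len(x)].mean() - pooled[len(x):].mean()) >= observed:
                    hits += 1
            return hits / n_perm

        oracle = {
            tuple(sorted(pair)): perm_p(groups[pair[0]], groups[pair[1]])
            for pair in itertools.combinations(groups, 2)
        }
        out = out.assign(pair=list(zip(out["level_1"], out["level_2"])))
        tukey_rank = out.sort_values("p_adj")["pair"].tolist()
        oracle_rank = sorted(oracle, key=oracle.get)
        assert [tuple(sorted(p)) for p in tukey_rank] == oracle_rank

    def test_single_level_rejected(self):
        df = pd.DataFrame({"phase": ["a"] * 5, "cc": np.arange(5.0)})
        with pytest.raises(ConfigurationError):
            tukey_hsd(df, factor="phase")


class TestEffectSize:
    def anova(self, ss_effect, ss_err):
        table = pd.DataFrame(
            {
                "SS": [ss_effect, 1.0, 1.0, ss_err],
                "df": [3, 2, 6, 188],
                "F": np.nan,
                "p": np.nan,
            },
            index=[PHASE_ROW, SPEED_ROW, INTERACTION_ROW, RESIDUAL_ROW],
        )
        from emgcycle.stats import AnovaTable

        return AnovaTable(table=table)

    def test_equal_effect_and_error_give_f_of_one(self):
        assert cohens_f(self.anova(10.0, 10.0), PHASE_ROW).cohen_f == pytest.approx(1.0)

    def test_zero_effect_gives_zero(self):
        assert cohens_f(self.anova(0.0, 10.0), PHASE_ROW).cohen_f == 0.0

    def test_partial_eta_variant_on_published_sums(self):
        # sqrt(7336.39 / 35816.19) = 0.4526 under the partial-eta-squared form
        es = cohens_f(self.anova(7336.39, 35816.19), PHASE_ROW)
        assert es.cohen_f == pytest.approx(0.4526, abs=5e-5)
        assert es.formula_variant == "partial_eta"
        assert es.label == "large"

    def test_zero_residual_is_an_error(self):
        with pytest.raises(ZeroDivisionError):
            cohens_f(self.anova(5.0, 0.0), PHASE_ROW)

    @pytest.mark.parametrize(
        "f,label",
        [
            (0.0, "negligible"),
            (0.099, "negligible"),
            (0.10, "small"),
            (0.249, "small"),
            (0.25, "medium"),
            (0.399, "medium"),
            (0.40, "large"),
            (0.4123, "large"),
        ],
    )
    def test_classification_bands(self, f, label):
        assert classify_effect_size(f) == label

    def test_negative_f_rejected(self):
        with pytest.raises(ValueError):
            classify_effect_size(-0.1)


class TestModelResults:
    def test_fit_exposes_table_posthoc_and_summary(self):
        means = {"Acc_Flex": 28, "Dec_Flex": 37, "Acc_Ext": 20, "Dec_Ext": 28}
        df = balanced_table(lambda ph, sp: means[ph], noise_sd=8.0, n_subjects=20)
        res = CoactivationAnova(df).fit()
        table = res.anova_table
        assert list(table.index) == [PHASE_ROW, SPEED_ROW, INTERACTION_ROW, RESIDUAL_ROW]
        assert table.loc[PHASE_ROW, "p"] < 0.001
        assert table.loc[SPEED_ROW, "p"] > 0.05
        assert res.cohens_f(PHASE_ROW).cohen_f > 0.25
        text = res.summary()
        assert "Tukey" in text and "Cohen's f" in text and "***" in text

    def test_missing_columns_rejected(self):
        with pytest.raises(ConfigurationError):
            CoactivationAnova(pd.DataFrame({"cc": [1.0, 2.0]}))

    def test_stars_convention(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.2) == ""
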