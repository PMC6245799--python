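"""Threshold rules, diagnostic accuracy, and group-comparison statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from spiroprm.stats import (
    adjusted_group_test,
    compare_categorical,
    compare_continuous,
    diagnostic_accuracy,
    dichotomize_symptoms,
    exacerbation_rate,
    threshold_positive,
)


class TestThresholdRules:
    def test_discordant_configuration_splits_the_rules(self):
        # the defining configuration: below 0.70 yet above the LLN
        assert threshold_positive(0.68, 0.65, "fixed_0.70") is True
        assert threshold_positive(0.68, 0.65, "lln") is False

    def test_both_positive_when_clearly_obstructed(self):
        assert threshold_positive(0.60, 0.65, "fixed_0.70") is True
        assert threshold_positive(0.60, 0.65, "lln") is True

    def test_lln_positives_subset_of_fixed_positives(self, rng):
        ratio = rng.uniform(0.4, 0.95, 300)
        lln = rng.uniform(0.60, 0.695, 300)  # everyone's LLN below 0.70
        lln_pos = threshold_positive(ratio, lln, "lln")
        fixed_pos = threshold_positive(ratio, lln, "fixed_0.70")
        assert not np.any(lln_pos & ~fixed_pos)

    def test_unknown_rule_raises(self):
        with pytest.raises(ValueError):
            threshold_positive(0.68, 0.65, "fixed_0.75")


class TestDiagnosticAccuracy:
    def test_perfect_prediction(self):
        truth = np.array([True, True, False, False])
        acc = diagnostic_accuracy(truth, truth)
        assert acc.sensitivity == 1.0 and acc.specificity == 1.0

    def test_toy_table(self):
        pred = [True] * 3 + [False] * 1 + [False] * 8 + [True] * 2
        truth = [True] * 4 + [False] * 10
        acc = diagnostic_accuracy(pred, truth)
        assert (acc.table.tp, acc.table.fn, acc.table.tn, acc.table.fp) == (3, 1, 8, 2)
        assert acc.sensitivity == pytest.approx(0.75)
        assert acc.specificity == pytest.approx(0.80)
        assert acc.table.total == 14

    def test_inverted_prediction(self):
        truth = np.array([True, False, True, False])
        acc = diagnostic_accuracy(~truth, truth)
        assert acc.sensitivity == 0.0 and acc.specificity == 0.0

    def test_undefined_proportions_are_none_not_zero(self):
        acc = diagnostic_accuracy([True, False], [False, False])
        assert acc.sensitivity is None
        acc = diagnostic_accuracy([True, False], [True, True])
        assert acc.specificity is None

    def test_order_invariance(self, rng):
        pred = rng.random(200) < 0.4
        truth = rng.random(200) < 0.3
        perm = rng.permutation(200)
        a1 = diagnostic_accuracy(pred, truth)
        a2 = diagnostic_accuracy(pred[perm], truth[perm])
        assert (a1.sensitivity, a1.specificity) == (a2.sensitivity, a2.specificity)


class TestCompareContinuous:
    def test_null_case(self):
        g = {"a": np.array([1.0, 2, 3, 4]), "b": np.array([1.0, 2, 3, 4])}
        row = compare_continuous(g)
        assert row.statistic == pytest.approx(0.0, abs=1e-12)
        assert row.overall_p_unadjusted == pytest.approx(1.0)

    def test_two_groups_match_textbook_t_test(self):
        a, b = np.array([1.0, 2, 3]), np.array([4.0, 5, 6])
        row = compare_continuous({"a": a, "b": b})
        # Welch formula evaluated independently
        se = np.sqrt(a.var(ddof=1) / 3 + b.var(ddof=1) / 3)
        t = (a.mean() - b.mean()) / se
        df = (a.var(ddof=1) / 3 + b.var(ddof=1) / 3) ** 2 / (
            (a.var(ddof=1) / 3) ** 2 / 2 + (b.var(ddof=1) / 3) ** 2 / 2
        )
        p = 2 * sps.t.sf(abs(t), df)
        assert row.pairwise_p[("a", "b")] == pytest.approx(p)
        assert row.group_summary["a"] == (pytest.approx(2.0), pytest.approx(1.0))

    def test_three_groups_match_sum_of_squares_oracle(self, rng):
        groups = {k: rng.normal(m, 1.0, 40) for k, m in [("a", 0), ("b", 0.3), ("c", 1)]}
        row = compare_continuous(groups)
        # explicit between/within decomposition
        allv = np.concatenate(list(groups.values()))
        gm = allv.mean()
        ssb = sum(len(v) * (v.mean() - gm) ** 2 for v in groups.values())
        ssw = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
        f = (ssb / 2) / (ssw / (len(allv) - 3))
        assert row.statistic == pytest.approx(f)
        assert row.overall_p_unadjusted == pytest.approx(sps.f.sf(f, 2, len(allv) - 3))

    def test_degenerate_group_is_flagged(self):
        row = compare_continuous({"a": np.array([1.0]), "b": np.array([1.0, 2.0])})
        assert row.flagged is not None
        assert row.overall_p_unadjusted is None


class TestCompareCategorical:
    def test_identical_proportions_give_zero_statistic(self):
        g = {k: np.array([True] * 5 + [False] * 5) for k in "abc"}
        row = compare_categorical(g)
        assert row.statistic == pytest.approx(0.0, abs=1e-12)

    def test_two_by_two_matches_pearson_formula(self):
        g = {
            "a": np.array([True] * 10 + [False] * 20),
            "b": np.array([True] * 20 + [False] * 10),
        }
        row = compare_categorical(g)
        # hand Pearson computation: all expected cells are 15
        expected = 15.0
        stat = sum((o - expected) ** 2 / expected for o in (10, 20, 20, 10))
        assert row.statistic == pytest.approx(stat)
        assert row.group_summary["a"] == pytest.approx(100 * 10 / 30)

    def test_sparse_table_warns(self):
        g = {"a": np.array([True] + [False] * 50), "b": np.array([False] * 30)}
        with pytest.warns(UserWarning, match="expected cell"):
            compare_categorical(g)


class TestAdjustedGroupTest:
    def _simulate(self, rng, effect=0.0, n=240):
        group = rng.choice(["g1", "g2", "g3"], n)
        age = rng.uniform(40, 80, n)
        sex = rng.choice(["male", "female"], n)
        race = rng.choice(["caucasian", "african_american"], n)
        pack = rng.exponential(20, n)
        cur = rng.random(n) < 0.4
        y = (
            0.02 * age
            + 0.5 * (sex == "male")
            + 0.01 * pack
            + effect * (group == "g1")
            + rng.normal(0, 1, n)
        )
        return pd.DataFrame(
            {
                "y": y,
                "group": group,
                "age": age,
                "sex": sex,
                "race": race,
                "pack_years": pack,
                "current_smoker": cur,
            }
        )

    def test_linear_reduces_to_anova_ordering_without_covariates(self, rng):
        # LRT p-values must order datasets exactly as one-way ANOVA does
        anova_p, lrt_p = [], []
        for _ in range(8):
            df = self._simulate(rng, effect=rng.uniform(0, 0.6))
            groups = [df.loc[df["group"] == g, "y"].to_numpy() for g in ("g1", "g2", "g3")]
            anova_p.append(sps.f_oneway(*groups).pvalue)
            res = adjusted_group_test(df, "y", covariates=(), family="linear")
            lrt_p.append(res["p_lrt"])
        assert list(np.argsort(anova_p)) == list(np.argsort(lrt_p))

    def test_detects_true_group_effect(self, rng):
        df = self._simulate(rng, effect=1.0)
        res = adjusted_group_test(df, "y", family="linear")
        assert res["p_lrt"] < 1e-4
        assert ("g1", "g2") in res["pairwise_p"]

    def test_logistic_collapsible_case_recovers_log_odds_ratio(self):
        # 2x2 table: 30/100 positive vs 10/100 positive
        df = pd.DataFrame(
            {
                "y": [1] * 30 + [0] * 70 + [1] * 10 + [0] * 90,
                "group": ["a"] * 100 + ["b"] * 100,
            }
        )
        res = adjusted_group_test(df, "y", covariates=(), family="logistic")
        log_or = np.log((30 / 70) / (10 / 90))
        assert res["params"]["group[b]"] == pytest.approx(-log_or, abs=1e-4)
        assert res["p_lrt"] < 0.01

    def test_missing_rows_are_dropped(self, rng):
        df = self._simulate(rng)
        df.loc[:10, "age"] = np.nan
        res = adjusted_group_test(df, "y", family="linear")
        assert res["n_used"] == len(df) - 11


class TestSimpleOutcomes:
    @pytest.mark.parametrize("events,years,expected", [(0, 1, 0.0), (2, 1, 2.0), (3, 2, 1.5)])
    def test_exacerbation_rate(self, events, years, expected):
        assert exacerbation_rate(events, years) == expected

    def test_exacerbation_rate_rejects_negative(self):
        with pytest.raises(ValueError):
            exacerbation_rate(-1, 1.0)

    @pytest.mark.parametrize(
        "mmrc,months,years,dysp,cb",
        [
            (2, 0, 0, True, False),
            (1, 0, 0, False, False),
            (0, 3, 2, False, True),
            (4, 2, 10, True, False),
        ],
    )
    def test_dichotomize_symptoms(self, mmrc, months, years, dysp, cb):
        out = dichotomize_symptoms(mmrc, months, years)
        assert out["dyspnea_mod_severe"] is dysp
        assert out["chronic_bronchitis"] is cb

    def test_mmrc_out_of_range(self):
        with pytest.raises(ValueError):
            dichotomize_symptoms(5, 0, 0)
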