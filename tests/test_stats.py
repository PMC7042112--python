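"""Replication hierarchy, paired log-scale t test, two-way ANOVA + Tukey."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from endoca.stats import aggregate, anova2_tukey, paired_t_log


def _summaries(rows):
    return pd.DataFrame(rows, columns=["animal", "condition", "tech_rep",
                                       "cell_id", "peak_amp", "responder"])


class TestAggregate:
    def test_cells_average_within_replicate(self):
        df = _summaries([(0, "ctl", 0, c, v, True)
                         for c, v in enumerate([1.0, 2.0, 3.0])])
        table = aggregate(df, "peak_amp")
        assert table.animal_means.peak_amp.iloc[0] == pytest.approx(2.0)

    def test_tech_reps_average_within_animal(self):
        rows = []
        for r, v in enumerate([1.0, 2.0, 3.0]):
            rows.append((0, "ctl", r, 0, v, True))
        table = aggregate(_summaries(rows), "peak_amp")
        assert len(table.tech_rep_means) == 3
        assert table.animal_means.peak_amp.iloc[0] == pytest.approx(2.0)

    def test_matches_nested_loop_oracle(self, rng):
        rows = []
        for a in range(5):
            for r in range(3):
                for c in range(30):
                    rows.append((a, "ctl", r, c, rng.random() + 0.5, True))
        df = _summaries(rows)
        table = aggregate(df, "peak_amp")
        # flat nested recomputation
        expected = []
        for a in range(5):
            rep_means = []
            for r in range(3):
                vals = [v for (aa, _, rr, _, v, _) in rows
                        if aa == a and rr == r]
                rep_means.append(sum(vals) / len(vals))
            expected.append(sum(rep_means) / len(rep_means))
        got = table.animal_means.sort_values("animal").peak_amp.to_numpy()
        np.testing.assert_allclose(got, expected)

    def test_order_invariant(self, rng):
        rows = [(a, "ctl", r, c, rng.random(), True)
                for a in range(2) for r in range(2) for c in range(5)]
        df = _summaries(rows)
        shuffled = df.sample(frac=1.0, random_state=1)
        a = aggregate(df, "peak_amp").animal_means.sort_values("animal")
        b = aggregate(shuffled, "peak_amp").animal_means.sort_values("animal")
        np.testing.assert_allclose(a.peak_amp, b.peak_amp)

    def test_exclusion_emptying_group_rejected(self):
        df = _summaries([(0, "ctl", 0, 0, 0.0, False)])
        with pytest.raises(ValueError):
            aggregate(df, "peak_amp", exclude_nonresponders=True)

    def test_missing_metric_rejected(self):
        with pytest.raises(KeyError):
            aggregate(_summaries([(0, "ctl", 0, 0, 1.0, True)]), "nope")


def _table(cond_values: dict):
    rows = []
    for cond, vals in cond_values.items():
        for a, v in enumerate(vals):
            rows.append((a, cond, 0, 0, v, True))
    return aggregate(_summaries(rows), "peak_amp")


class TestPairedTLog:
    def test_identical_arms_null(self):
        table = _table({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        res = paired_t_log(table, "a", "b")
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_textbook_hand_case(self):
        # log differences exactly (1, 1, 2): t = 4.0 with df = 2
        x = [1.0, 1.0, 1.0]
        y = [math.e, math.e, math.e ** 2]
        res = paired_t_log(_table({"a": x, "b": y}), "a", "b")
        assert res.statistic == pytest.approx(4.0)
        assert res.df == 2
        assert res.p_value == pytest.approx(2 * sps.t.sf(4.0, 2))

    def test_backtransform_is_geometric_mean(self):
        res = paired_t_log(_table({"a": [1.0, math.e ** 2],
                                   "b": [2.0, 2.0]}), "a", "b")
        assert res.geometric_means["a"] == pytest.approx(math.e)

    def test_common_rescaling_invariance(self):
        t1 = _table({"a": [1.1, 2.0, 0.7], "b": [1.5, 2.5, 0.9]})
        t2 = _table({"a": [11, 20, 7], "b": [15, 25, 9]})
        r1 = paired_t_log(t1, "a", "b")
        r2 = paired_t_log(t2, "a", "b")
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            paired_t_log(_table({"a": [0.0, 1.0], "b": [1.0, 1.0]}),
                         "a", "b")

    def test_unpaired_animal_rejected(self):
        rows = [(0, "a", 0, 0, 1.0, True), (1, "a", 0, 0, 1.0, True),
                (0, "b", 0, 0, 1.0, True)]
        with pytest.raises(ValueError, match="pairing"):
            paired_t_log(aggregate(_summaries(rows), "peak_amp"), "a", "b")


def _toy_2x2(reps=4, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    effects = {("t1", "s1"): 1.0, ("t1", "s2"): 1.4,
               ("t2", "s1"): 1.8, ("t2", "s2"): 2.6}
    for (f1, f2), mu in effects.items():
        for _ in range(reps):
            rows.append((f1, f2, mu * math.exp(rng.normal(0, 0.1))))
    return pd.DataFrame(rows, columns=["treatment", "stimulus", "value"])


class TestAnovaTukey:
    def test_all_equal_gives_zero_sums_of_squares(self):
        df = pd.DataFrame({"treatment": ["a", "a", "b", "b"] * 3,
                           "stimulus": ["x", "y"] * 6,
                           "value": 2.0})
        res = anova2_tukey(df, "value", "treatment", "stimulus",
                          log_transform=False)
        ss = res.anova_table["sum_sq"].iloc[:3]
        assert np.allclose(ss, 0.0, atol=1e-20)

    def test_sums_of_squares_match_brute_force_decomposition(self):
        df = _toy_2x2()
        res = anova2_tukey(df, "value", "treatment", "stimulus")
        y = np.log(df["value"].to_numpy())
        f1 = df["treatment"].to_numpy()
        f2 = df["stimulus"].to_numpy()
        grand = y.mean()
        ss_a = sum(len(y[f1 == l]) * (y[f1 == l].mean() - grand) ** 2
                   for l in np.unique(f1))
        ss_b = sum(len(y[f2 == l]) * (y[f2 == l].mean() - grand) ** 2
                   for l in np.unique(f2))
        ss_cells = 0.0
        for la in np.unique(f1):
            for lb in np.unique(f2):
                sel = (f1 == la) & (f2 == lb)
                ss_cells += sel.sum() * (y[sel].mean() - grand) ** 2
        ss_int = ss_cells - ss_a - ss_b
        table = res.anova_table
        assert table.loc["C(treatment)", "sum_sq"] == pytest.approx(ss_a)
        assert table.loc["C(stimulus)", "sum_sq"] == pytest.approx(ss_b)
        assert table.loc["C(treatment):C(stimulus)",
                         "sum_sq"] == pytest.approx(ss_int)

    def test_tukey_adjustment_is_conservative(self):
        df = _toy_2x2(reps=5, seed=3)
        res = anova2_tukey(df, "value", "treatment", "stimulus")
        y = np.log(df["value"].to_numpy())
        groups = (df["treatment"] + ":" + df["stimulus"]).to_numpy()
        labels = np.unique(groups)
        k = len(labels)
        n = len(y)
        mse = sum(((y[groups == g] - y[groups == g].mean()) ** 2).sum()
                  for g in labels) / (n - k)
        for row in res.contrasts.itertuples(index=False):
            g1, g2 = str(row.group1), str(row.group2)
            n1, n2 = (groups == g1).sum(), (groups == g2).sum()
            diff = y[groups == g2].mean() - y[groups == g1].mean()
            se = math.sqrt(mse * (1 / n1 + 1 / n2))
            p_unadj = 2 * sps.t.sf(abs(diff) / se, n - k)
            assert float(row.p_adj) >= p_unadj - 1e-9

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame({"treatment": ["a"] * 4,
                           "stimulus": ["x", "y"] * 2, "value": 1.0})
        with pytest.raises(ValueError, match="single level"):
            anova2_tukey(df, "value", "treatment", "stimulus")
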