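"""Statistical procedures against enumeration and closed-form oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eastils.stats import (SeparationError, chi_square_2x2, delong_paired_test,
                           km_logrank, logistic_model, mann_whitney, pearson_r,
                           pool_control_arms, roc_auc, table1_percentages,
                           wilcoxon_signed_rank)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def mw_exact_p_oracle(a, b):
    """Two-sided exact Mann-Whitney p by full enumeration of group labelings."""
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)

    def u_stat(x, y):
        u = 0.0
        for xi in x:
            for yi in y:
                u += 1.0 if xi > yi else (0.5 if xi == yi else 0.0)
        return u

    observed = u_stat(a, b)
    center = n * m / 2.0
    count = 0
    total = 0
    idx = range(n + m)
    for comb in itertools.combinations(idx, n):
        comb = set(comb)
        x = pooled[[i in comb for i in idx]]
        y = pooled[[i not in comb for i in idx]]
        u = u_stat(x, y)
        if abs(u - center) >= abs(observed - center) - 1e-12:
            count += 1
        total += 1
    return count / total


def wilcoxon_exact_p_oracle(d):
    """Two-sided exact signed-rank p by enumerating all 2^n sign flips."""
    d = np.asarray([x for x in d if x != 0], dtype=float)
    n = len(d)
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_plus = ranks[d > 0].sum()
    total_rank = ranks.sum()
    center = total_rank / 2.0
    observed_dev = abs(w_plus - center)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = ranks[np.array(signs, dtype=bool)].sum()
        if abs(w - center) >= observed_dev - 1e-12:
            count += 1
    return count / 2**n


class TestMannWhitney:
    def test_complete_separation_exact(self):
        res = mann_whitney([4, 5, 6], [1, 2, 3])
        # U for group A = 9 (all wins); two-sided exact p = 2/20
        assert res.statistic == 9.0
        assert res.p_value == pytest.approx(0.1, abs=1e-12)

    def test_identical_multisets(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(4.5)
        assert res.p_value == pytest.approx(1.0)

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(4):
            a = rng.normal(size=6)
            b = rng.normal(size=6)
            res = mann_whitney(a, b)
            assert res.p_value == pytest.approx(mw_exact_p_oracle(a, b), abs=1e-12)

    def test_degenerate_constant_data(self):
        res = mann_whitney([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.p_value == 1.0
        assert "degenerate" in res.flags

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestWilcoxon:
    def test_all_decreases_eight_pairs(self):
        pre = np.arange(1.0, 9.0) + 10
        post = pre - 1.0
        res = wilcoxon_signed_rank(pre, post)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2 / 2**8, abs=1e-12)

    def test_matches_sign_flip_enumeration(self):
        rng = np.random.default_rng(1)
        for trial in range(3):
            pre = rng.normal(size=10)
            post = pre + rng.normal(size=10)
            res = wilcoxon_signed_rank(pre, post)
            assert res.p_value == pytest.approx(wilcoxon_exact_p_oracle(post - pre), abs=1e-12)

    def test_antisymmetric_differences_centered(self):
        pre = np.zeros(6)
        post = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])
        res = wilcoxon_signed_rank(pre, post)
        assert res.p_value == pytest.approx(1.0)

    def test_all_zero_differences_flagged(self):
        res = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert res.p_value == 1.0
        assert "degenerate" in res.flags


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1).statistic == pytest.approx(1.0)

    def test_orthogonalized_is_zero(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        x0 = x - x.mean()
        y = (y - y.mean()) - x0 * (x0 @ (y - y.mean())) / (x0 @ x0)
        assert pearson_r(x, y).statistic == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestChiSquare:
    def test_null_table(self):
        res = chi_square_2x2([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_closed_form_hand_computation(self):
        # E = [[12.5, 17.5], [12.5, 17.5]]; sum (O-E)^2/E = 56.25 * 2 * (1/12.5 + 1/17.5)
        res = chi_square_2x2([[20, 10], [5, 25]])
        expected = 56.25 * 2 * (1 / 12.5 + 1 / 17.5)  # = 108/7
        assert res.statistic == pytest.approx(expected, abs=1e-12)
        assert res.statistic == pytest.approx(108 / 7, abs=1e-12)
        from scipy.stats import chi2

        assert res.p_value == pytest.approx(chi2.sf(108 / 7, 1), abs=1e-15)

    def test_statistic_scales_with_counts(self):
        t = np.array([[20, 10], [5, 25]])
        r1 = chi_square_2x2(t)
        r10 = chi_square_2x2(t * 10)
        assert r10.statistic == pytest.approx(10 * r1.statistic)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 5]])


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.statistic == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=2000)
        y = rng.random(2000) < 0.5
        assert abs(roc_auc(s, y).statistic - 0.5) < 0.05

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 5), min_size=2, max_size=30),
           st.lists(st.integers(0, 5), min_size=2, max_size=30))
    def test_auc_u_identity_with_ties(self, pos, neg):
        """AUC equals U/(n1*n0) from the Mann-Whitney statistic, ties counting 1/2."""
        scores = np.array(pos + neg, dtype=float)
        y = np.array([True] * len(pos) + [False] * len(neg))
        auc = roc_auc(scores, y).statistic
        u = mann_whitney(scores[y], scores[~y]).statistic
        assert auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestDeLong:
    def test_identical_scores_p_one(self):
        s = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [0, 1, 0, 1, 0, 1]
        res = delong_paired_test(s, s, y)
        assert res.effect["difference"] == 0.0
        assert res.p_value == 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=60)
        y = rng.random(60) < 0.4
        res = delong_paired_test(a, np.exp(a), y)
        assert res.effect["auc_a"] == pytest.approx(res.effect["auc_b"], abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_variance_matches_bootstrap(self):
        """DeLong SE of the AUC difference agrees with a bootstrap estimate."""
        rng = np.random.default_rng(5)
        n = 500
        latent = rng.normal(size=n)
        y = rng.random(n) < 1 / (1 + np.exp(-latent))
        a = latent + rng.normal(0, 1.0, n)
        b = 0.8 * latent + rng.normal(0, 1.2, n)
        res = delong_paired_test(a, b, y)
        diff = res.effect["difference"]
        se_delong = abs(diff / res.statistic)
        diffs = []
        for _ in range(400):
            idx = rng.integers(0, n, n)
            if y[idx].all() or not y[idx].any():
                continue
            ra = roc_auc(a[idx], y[idx]).statistic
            rb = roc_auc(b[idx], y[idx]).statistic
            diffs.append(ra - rb)
        se_boot = np.std(diffs, ddof=1)
        assert abs(se_delong - se_boot) / se_boot < 0.15


class TestKaplanMeier:
    def test_no_events_flat_curves(self):
        res = km_logrank([5, 6, 7, 8], [0, 0, 0, 0], ["a", "a", "b", "b"])
        assert res.p_value == 1.0
        for curve in res.effect["curves"].values():
            assert np.all(curve["survival"] == 1.0)

    def test_hand_product_limit(self):
        res = km_logrank([1.0, 2.0, 3.0], [1, 1, 1], ["g", "g", "g"])
        curve = res.effect["curves"]["g"]
        s_at_2 = curve["survival"][np.searchsorted(curve["time"], 2.0)]
        assert s_at_2 == pytest.approx(1 / 3)  # (2/3) * (1/2)

    def test_reduces_to_empirical_survivor_without_censoring(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(10, 40).round(3)
        res = km_logrank(t, np.ones(40), ["x"] * 40)
        curve = res.effect["curves"]["x"]
        for time, surv in zip(curve["time"], curve["survival"]):
            assert surv == pytest.approx((t > time).mean(), abs=1e-12)

    def test_duplicated_groups_p_one(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 0, 1, 1]
        res = km_logrank(t + t, e + e, ["a"] * 4 + ["b"] * 4)
        assert res.p_value == pytest.approx(1.0)

    def test_positive_times_required(self):
        with pytest.raises(ValueError):
            km_logrank([0.0, 1.0], [1, 1], ["a", "b"])


class TestLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1] * 30 + [0] * 70)
        df = pd.DataFrame({"pcr": y})
        res = logistic_model(df, "pcr ~ 1")
        assert res.effect["coefficients"].loc["Intercept", "coef"] == pytest.approx(
            np.log(0.3 / 0.7), abs=1e-6
        )

    def test_known_slope_recovered_within_2se(self):
        rng = np.random.default_rng(7)
        n = 2000
        x = rng.gamma(2, 10, n)
        p = 1 / (1 + np.exp(-(-2.0 + 0.05 * x)))
        df = pd.DataFrame({"pcr": rng.random(n) < p, "eastils_percent": x})
        res = logistic_model(df, "pcr ~ eastils_percent")
        c = res.effect["coefficients"].loc["eastils_percent"]
        assert abs(c.coef - 0.05) <= 2 * c.se

    def test_interaction_term_reported(self):
        rng = np.random.default_rng(8)
        n = 400
        df = pd.DataFrame({
            "pcr": rng.random(n) < 0.3,
            "eastils_percent": rng.gamma(2, 10, n),
            "arm": rng.choice(["chemo", "chemo+bev"], n),
        })
        res = logistic_model(df, "pcr ~ eastils_percent * arm")
        assert len(res.effect["interaction_p"]) == 1
        assert 0 <= list(res.effect["interaction_p"].values())[0] <= 1

    def test_complete_separation_detected(self):
        x = np.linspace(0, 1, 40)
        df = pd.DataFrame({"pcr": (x > 0.5).astype(int), "x": x})
        with pytest.raises(SeparationError):
            logistic_model(df, "pcr ~ x")

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=50)
        df = pd.DataFrame({"pcr": rng.random(50) < 0.5, "x": x, "z": 2 * x})
        with pytest.raises(ValueError):
            logistic_model(df, "pcr ~ x + z")


class TestCohortUtilities:
    def test_table1_percentages_printed_precision(self):
        assert table1_percentages([59, 152]).tolist() == [28.0, 72.0]
        assert table1_percentages([33, 80]).tolist() == [29.2, 70.8]
        assert table1_percentages([0, 10]).tolist() == [0.0, 100.0]

    def test_table1_zero_total_rejected(self):
        with pytest.raises(ValueError):
            table1_percentages([0, 0])

    def test_pool_control_arms(self):
        df = pd.DataFrame({"arm": ["chemo", "chemo+bev", "chemo"]})
        pooled = pool_control_arms(df)
        assert set(pooled["arm"]) == {"chemo", "chemo+bev"}
        df2 = pd.DataFrame({"arm": ["taxane-first", "AC-first", "chemo+bev"]})
        pooled2 = pool_control_arms(df2)
        assert list(pooled2["arm"]) == ["chemo", "chemo", "chemo+bev"]

    def test_row_shuffle_invariance(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=30)
        b = rng.normal(size=25)
        r1 = mann_whitney(a, b)
        r2 = mann_whitney(rng.permutation(a), rng.permutation(b))
        assert r1.statistic == r2.statistic and r1.p_value == r2.p_value
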