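"""Agreement battery: limits of agreement, SE ratios, kappa, suite plumbing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from itsmeta import (
    log_se_ratio_loa,
    mean_diff_loa,
    run_comparison_suite,
    scaled_ci_widths,
    significance_agreement,
    tau2_diff_summary,
)
from itsmeta.compare import kappa_adjective
from itsmeta.types import ValidationError


class TestMeanDiffLoA:
    def test_identical_vectors(self):
        assert mean_diff_loa([1, 2, 3], [1, 2, 3]) == (0.0, 0.0, 0.0)

    def test_hand_computed(self):
        m, lo, hi = mean_diff_loa([2, 4, 6], [1, 2, 3])  # diffs 1,2,3
        assert m == pytest.approx(2.0)
        assert lo == pytest.approx(2 - 1.96)
        assert hi == pytest.approx(2 + 1.96)

    def test_antisymmetry(self):
        a, b = np.array([0.3, 1.1, -0.4, 2.0]), np.array([0.1, 0.9, 0.2, 1.5])
        m1, lo1, hi1 = mean_diff_loa(a, b)
        m2, lo2, hi2 = mean_diff_loa(b, a)
        assert m2 == pytest.approx(-m1)
        assert lo2 == pytest.approx(-hi1)
        assert hi2 == pytest.approx(-lo1)

    def test_needs_two_pairs(self):
        with pytest.raises(ValidationError):
            mean_diff_loa([1.0], [2.0])

    def test_loa_contain_most_normal_differences(self, rng):
        d = rng.normal(0.2, 1.3, 10_000)
        m, lo, hi = mean_diff_loa(d, np.zeros_like(d))
        frac = np.mean((d >= lo) & (d <= hi))
        assert 0.94 < frac < 0.96

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=30))
    def test_mean_between_limits(self, a):
        m, lo, hi = mean_diff_loa(a, [0.0] * len(a))
        assert lo <= m <= hi


class TestLogSERatio:
    def test_identical_ses(self):
        assert log_se_ratio_loa([0.2, 0.4], [0.2, 0.4]) == (1.0, 1.0, 1.0)

    def test_constant_ratio(self):
        m, lo, hi = log_se_ratio_loa([0.4, 0.8, 1.2], [0.2, 0.4, 0.6])
        assert m == pytest.approx(2.0)
        assert lo == pytest.approx(2.0)
        assert hi == pytest.approx(2.0)

    def test_hand_computed_three_pairs(self):
        a, b = np.array([0.3, 0.5, 0.7]), np.array([0.2, 0.6, 0.5])
        d = np.log(a) - np.log(b)
        m, s = d.mean(), d.std(ddof=1)
        got = log_se_ratio_loa(a, b)
        assert got[0] == pytest.approx(np.exp(m))
        assert got[1] == pytest.approx(np.exp(m - 1.96 * s))
        assert got[2] == pytest.approx(np.exp(m + 1.96 * s))

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValidationError):
            log_se_ratio_loa([0.0, 0.1], [0.1, 0.1])


class TestScaledCIWidths:
    def test_equal_widths_give_unit_span(self):
        df = scaled_ci_widths([1.0, 2.0], [1.0, 2.0], [0.0, 0.0], [0.0, 0.0])
        assert np.allclose(df["scaled_width"], 1.0)
        assert np.allclose(df["low"], -0.5) and np.allclose(df["high"], 0.5)

    def test_double_width(self):
        df = scaled_ci_widths([1.0], [2.0], [0.0], [0.0])
        assert df["scaled_width"].iloc[0] == pytest.approx(2.0)

    def test_narrower_iff_inside_reference(self):
        df = scaled_ci_widths([1.0, 1.0], [0.6, 1.4], [0.0, 0.0], [0.0, 0.0])
        inside = (df["low"] > -0.5) & (df["high"] < 0.5)
        assert list(inside) == [True, False]

    def test_ranking_is_permutation_with_stable_ties(self, rng):
        w = rng.uniform(0.5, 2.0, 10)
        w[3] = w[7]  # plant a tie
        ids = [f"m{i:02d}" for i in range(10)]
        df = scaled_ci_widths(np.ones(10), w, np.zeros(10), np.zeros(10), meta_ids=ids)
        assert sorted(df["rank"]) == list(range(1, 11))
        tied = df[df["scaled_width"] == w[3]].sort_values("rank")
        assert list(tied["meta_id"]) == sorted(tied["meta_id"])  # ties by meta_id

    def test_zero_reference_flagged(self):
        df = scaled_ci_widths([0.0, 1.0], [1.0, 1.0], [0, 0], [0, 0])
        assert bool(df["excluded_zero_ref"].iloc[0])
        assert np.isnan(df["rank"].iloc[0])


class TestTau2DiffSummary:
    def test_identical(self):
        assert tau2_diff_summary([0.1, 0.2], [0.1, 0.2]) == (0.0, 0.0, 0.0)

    def test_median_with_zeros(self):
        med, _, _ = tau2_diff_summary([0, 0, 0, 1], [0, 0, 0, 0])
        assert med == 0.0

    def test_type7_quartiles(self):
        med, q1, q3 = tau2_diff_summary([1, 2, 3, 4], [0, 0, 0, 0])
        assert med == pytest.approx(2.5)
        assert q1 == pytest.approx(1.75)  # linear interpolation rule
        assert q3 == pytest.approx(3.25)


class TestSignificanceAgreement:
    def test_identical_mixed_patterns(self):
        p = [0.01, 0.2, 0.03, 0.6]
        pct, kappa, label = significance_agreement(p, p)
        assert pct == 100.0 and kappa == 1.0 and label == "almost perfect"

    def test_hand_computed_2x2(self):
        # both-sig 10, both-non 5, discordant 1+1 (n = 17)
        p_a = [0.01] * 11 + [0.5] * 6
        p_b = [0.01] * 10 + [0.5, 0.01] + [0.5] * 5
        pct, kappa, label = significance_agreement(p_a, p_b)
        assert pct == pytest.approx(100 * 15 / 17, abs=0.01)
        po, pe = 15 / 17, 157 / 289
        assert kappa == pytest.approx((po - pe) / (1 - pe), abs=1e-12)
        assert kappa == pytest.approx(0.742, abs=5e-4)
        assert label == "substantial"

    def test_independent_patterns_have_near_zero_kappa(self, rng):
        a = rng.uniform(size=20_000)
        b = rng.uniform(size=20_000)
        _, kappa, _ = significance_agreement(4 * a, 4 * b)  # ~5% significant each
        assert abs(kappa) < 0.05

    def test_degenerate_marginals(self):
        pct, kappa, label = significance_agreement([0.5, 0.6], [0.7, 0.8])
        assert pct == 100.0
        assert np.isnan(kappa) and label == "undefined"

    def test_adjectives(self):
        assert kappa_adjective(0.5) == "moderate"
        assert kappa_adjective(0.7) == "substantial"
        assert kappa_adjective(0.9) == "almost perfect"


def _toy_results(n_meta=5, seed=0):
    """Small synthetic long results table covering all 10 combinations."""
    rng = np.random.default_rng(seed)
    rows = []
    for metric in ("level_change", "slope_change_per_month"):
        for i in range(n_meta):
            base = rng.normal(0.5, 0.2)
            for its in ("OLS", "REML"):
                for mm, model, t2m, cim in [
                    ("fixed", "fixed", "none", "WT"),
                    ("DL+WT", "random", "DL", "WT"),
                    ("DL+HKSJ", "random", "DL", "HKSJ"),
                    ("REML+WT", "random", "REML", "WT"),
                    ("REML+HKSJ", "random", "REML", "HKSJ"),
                ]:
                    est = base + rng.normal(0, 0.01)
                    se = float(rng.uniform(0.05, 0.2))
                    rows.append({
                        "meta_id": f"m{i}", "metric": metric, "its_method": its,
                        "meta_method": mm, "model": model, "tau2_method": t2m,
                        "ci_method": cim, "estimate": est, "se": se,
                        "p_value": float(rng.uniform(0.001, 0.9)),
                        "ci_width": 2 * 1.96 * se,
                        "tau2_hat": float(rng.uniform(0, 0.1)) if model == "random" else np.nan,
                    })
    return pd.DataFrame(rows)


class TestSuite:
    def test_cell_counts(self):
        suite = run_comparison_suite(_toy_results())
        for metric, g in suite.estimates.groupby("metric"):
            assert len(g) == 45
        assert len(suite.tau2) == 2 * 6  # 4 ITS x estimator combos -> C(4,2) per metric
        assert len(suite.bland_altman) == 2 * 45 * 5

    def test_self_comparison_is_exact_agreement(self):
        """Comparing a combination with itself: diff 0, ratio 1, agreement 100%."""
        df = _toy_results()
        col = df[(df.its_method == "OLS") & (df.meta_method == "fixed")
                 & (df.metric == "level_change")]
        m, lo, hi = mean_diff_loa(col["estimate"], col["estimate"])
        r, *_ = log_se_ratio_loa(col["se"], col["se"])
        pct, _, _ = significance_agreement(col["p_value"], col["p_value"])
        assert (m, lo, hi) == (0.0, 0.0, 0.0)
        assert r == 1.0 and pct == 100.0

    def test_missing_combination_named_in_error(self):
        df = _toy_results()
        df = df[~((df.its_method == "REML") & (df.meta_method == "DL+HKSJ"))]
        with pytest.raises(ValidationError, match="REML ITS / DL\\+HKSJ"):
            run_comparison_suite(df)

    def test_restricted_to_fixed_effect(self):
        suite = run_comparison_suite(_toy_results(), meta_methods=("fixed",))
        # only OLS/fixed vs REML/fixed remains -> 1 cell per metric
        assert len(suite.estimates) == 2
        assert suite.tau2.empty

    def test_orientation_is_later_minus_earlier(self):
        df = _toy_results(seed=3)
        suite = run_comparison_suite(df)
        row = suite.estimates[
            (suite.estimates.metric == "level_change")
            & (suite.estimates.combo_a == "OLS ITS / fixed MA")
            & (suite.estimates.combo_b == "REML ITS / fixed MA")
        ].iloc[0]
        sub = df[(df.metric == "level_change") & (df.meta_method == "fixed")]
        piv = sub.pivot(index="meta_id", columns="its_method", values="estimate")
        expect = (piv["REML"] - piv["OLS"]).mean()
        assert row["mean_diff"] == pytest.approx(expect)
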