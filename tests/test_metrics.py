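"""Tubule classification, cohort metrics, Z' and t-tests against hand
computations and independently coded oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tubulequant.metrics import (
    ConditionStats,
    DegenerateTestError,
    UndefinedZPrimeError,
    classify_tubules,
    compare_conditions,
    condition_stats,
    interpret_zprime,
    summarize_cohort,
    zprime,
)


class TestClassifyTubules:
    def test_strict_threshold_hand_example(self):
        res = classify_tubules([25.0, 18.0, 30.0], min_length_px=20)
        assert res.n_tubules == 2
        assert res.has_tubule
        assert res.longest_excess_px == pytest.approx(10.0)

    def test_empty_branch_list(self):
        res = classify_tubules([], min_length_px=20)
        assert res.n_tubules == 0
        assert not res.has_tubule
        assert res.longest_excess_px == 0.0

    def test_exact_threshold_excluded_when_strict(self):
        # "over 20 pixels" read as strictly greater
        assert classify_tubules([20.0], min_length_px=20).n_tubules == 0
        assert classify_tubules([20.0], min_length_px=20, strict=False).n_tubules == 1

    @given(
        st.lists(st.floats(0, 100, allow_nan=False), max_size=30),
        st.floats(1, 50),
        st.floats(0, 49),
    )
    def test_raising_threshold_never_adds_tubules(self, lengths, thr, bump):
        low = classify_tubules(lengths, min_length_px=thr)
        high = classify_tubules(lengths, min_length_px=thr + bump)
        assert high.n_tubules <= low.n_tubules


class TestSummarizeCohort:
    def test_three_image_worked_example(self):
        results = [
            classify_tubules([25.0, 30.0], 20, image_id="A"),
            classify_tubules([], 20, image_id="B"),
            classify_tubules([], 20, image_id="C"),
        ]
        s = summarize_cohort(results, pixel_size_um=0.1)
        assert s.mean_tubules_per_image == pytest.approx(2 / 3, abs=5e-4)
        assert s.pct_images_with_tubule == pytest.approx(100 / 3, abs=0.05)
        assert s.mean_longest_excess_um == pytest.approx(10 / 3 * 0.1, abs=5e-4)
        assert s.n_images == 3

    def test_all_empty_cohort(self):
        results = [classify_tubules([], 20, image_id=str(i)) for i in range(4)]
        s = summarize_cohort(results, 0.1)
        assert (s.mean_tubules_per_image, s.pct_images_with_tubule) == (0.0, 0.0)
        assert s.mean_longest_excess_um == 0.0

    def test_single_image_single_tubule(self):
        s = summarize_cohort([classify_tubules([40.0], 20, image_id="x")], 0.1)
        assert s.mean_tubules_per_image == 1.0
        assert s.pct_images_with_tubule == 100.0
        assert s.mean_longest_excess_um == pytest.approx(2.0)

    def test_exclude_empty_mode(self):
        results = [
            classify_tubules([30.0], 20, image_id="A"),
            classify_tubules([], 20, image_id="B"),
        ]
        assert summarize_cohort(results, 0.1).mean_longest_excess_um == pytest.approx(0.5)
        assert summarize_cohort(
            results, 0.1, empty_images="exclude"
        ).mean_longest_excess_um == pytest.approx(1.0)

    def test_concatenation_equals_weighted_average(self):
        rng = np.random.default_rng(3)
        cohorts = []
        for n in (4, 7):
            cohorts.append(
                [
                    classify_tubules(
                        list(rng.uniform(0, 60, size=rng.integers(0, 5))),
                        20,
                        image_id=f"{n}_{i}",
                    )
                    for i in range(n)
                ]
            )
        a = summarize_cohort(cohorts[0], 0.1)
        b = summarize_cohort(cohorts[1], 0.1)
        both = summarize_cohort(cohorts[0] + cohorts[1], 0.1)
        w = a.n_images + b.n_images
        assert both.mean_tubules_per_image == pytest.approx(
            (a.mean_tubules_per_image * a.n_images + b.mean_tubules_per_image * b.n_images) / w
        )
        assert both.pct_images_with_tubule == pytest.approx(
            (a.pct_images_with_tubule * a.n_images + b.pct_images_with_tubule * b.n_images) / w
        )
        assert both.mean_longest_excess_um == pytest.approx(
            (a.mean_longest_excess_um * a.n_images + b.mean_longest_excess_um * b.n_images) / w
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort([], 0.1)


class TestZPrime:
    def test_zero_spread_gives_one_in_both_modes(self):
        p = ConditionStats(mean=10, sd=0, n=3)
        n = ConditionStats(mean=2, sd=0, n=3)
        assert zprime(p, n, "difference") == pytest.approx(1.0)
        assert zprime(p, n, "as_printed_sum") == pytest.approx(1.0)

    def test_closed_form_values(self):
        p = ConditionStats(mean=10, sd=1, n=3)
        n = ConditionStats(mean=2, sd=0.5, n=3)
        assert zprime(p, n, "difference") == pytest.approx(0.4375)
        assert zprime(p, n, "as_printed_sum") == pytest.approx(0.625)

    def test_equal_means_undefined_in_difference_mode(self):
        p = ConditionStats(mean=5, sd=1, n=3)
        n = ConditionStats(mean=5, sd=1, n=3)
        with pytest.raises(UndefinedZPrimeError):
            zprime(p, n, "difference")

    def test_symmetric_in_condition_labels(self):
        p = ConditionStats(mean=10, sd=1, n=3)
        n = ConditionStats(mean=2, sd=0.5, n=3)
        assert zprime(p, n) == pytest.approx(zprime(n, p))

    @given(
        st.floats(0.01, 5),
        st.floats(0.01, 5),
        st.floats(0.01, 2),
    )
    def test_strictly_decreasing_in_either_sd(self, sd_p, sd_n, bump):
        p = ConditionStats(mean=10, sd=sd_p, n=3)
        n = ConditionStats(mean=2, sd=sd_n, n=3)
        base = zprime(p, n)
        assert zprime(ConditionStats(10, sd_p + bump, 3), n) < base
        assert zprime(p, ConditionStats(2, sd_n + bump, 3)) < base

    @pytest.mark.parametrize(
        "z,label",
        [(0.7, "robust"), (0.51, "robust"), (0.5, "functional_marginal"),
         (0.25, "functional_marginal"), (0.0, "functional_marginal"),
         (-0.1, "unsuitable")],
    )
    def test_interpretation_rubric(self, z, label):
        assert interpret_zprime(z) == label


def hand_t_tests(a, b, paired):
    """Independently coded Student t-test (textbook formulas)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if paired:
        d = a - b
        n = len(d)
        t = d.mean() / (d.std(ddof=1) / math.sqrt(n))
        df = n - 1
    else:
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
    from scipy.special import betainc

    x = df / (df + t * t)
    p = betainc(df / 2, 0.5, x)
    return t, p, df


class TestCompareConditions:
    def test_unpaired_matches_hand_computation(self):
        a, b = [3.0, 4.0, 5.0], [1.0, 1.0, 2.0]
        res = compare_conditions(a, b, paired=False)
        t, p, df = hand_t_tests(a, b, paired=False)
        assert res.statistic == pytest.approx(t, rel=1e-6)
        assert res.pvalue == pytest.approx(p, rel=1e-6)
        assert res.df == df

    def test_paired_matches_hand_computation(self):
        a, b = [3.0, 4.4, 5.1], [1.2, 1.0, 2.3]
        res = compare_conditions(a, b, paired=True)
        t, p, df = hand_t_tests(a, b, paired=True)
        assert res.statistic == pytest.approx(t, rel=1e-6)
        assert res.pvalue == pytest.approx(p, rel=1e-6)

    def test_swapping_conditions_flips_sign_same_p(self):
        a, b = [3.0, 4.0, 5.0], [1.0, 1.5, 2.0]
        r1 = compare_conditions(a, b, paired=False)
        r2 = compare_conditions(b, a, paired=False)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.pvalue == pytest.approx(r2.pvalue)

    def test_identical_paired_inputs_degenerate(self):
        with pytest.raises(DegenerateTestError):
            compare_conditions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)

    def test_too_few_values_degenerate(self):
        with pytest.raises(DegenerateTestError):
            compare_conditions([1.0], [2.0], paired=False)


def test_condition_stats_matches_numpy():
    vals = [1.0, 2.5, 4.0]
    s = condition_stats(vals)
    assert s.mean == pytest.approx(np.mean(vals))
    assert s.sd == pytest.approx(np.std(vals, ddof=1))
    assert s.n == 3
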