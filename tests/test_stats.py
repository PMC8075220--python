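"""Statistical layer: exact-enumeration oracles, correlations, logistic fit,
and Benjamini-Hochberg adjustment."""

from itertools import combinations, product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deltat1.exceptions import DomainError
from deltat1.stats import (
    compare_groups,
    compare_paired,
    correlate,
    dichotomize_by_median,
    fdr_adjust,
    fit_treatment_logistic,
)


def exact_mwu_p(a, b):
    """Brute-force two-sided Mann-Whitney p by enumerating group assignments."""
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n_a = len(a)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    u_all = np.array(
        [
            ranks[list(subset)].sum() - n_a * (n_a + 1) / 2
            for subset in combinations(range(len(pooled)), n_a)
        ]
    )
    p_le = np.mean(u_all <= u_obs + 1e-12)
    p_ge = np.mean(u_all >= u_obs - 1e-12)
    return min(1.0, 2 * min(p_le, p_ge))


class TestPaired:
    def test_wilcoxon_exact_all_positive_differences(self):
        pre = np.zeros(5)
        post = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        _, w = compare_paired(pre, post)
        assert w.p_value == pytest.approx(1 / 16)  # 2 * 1/32 sign patterns

    def test_all_tied_pairs_flagged(self):
        pre = np.array([1.0, 2.0, 3.0, 4.0])
        _, w = compare_paired(pre, pre)
        assert w.flagged and np.isnan(w.p_value)

    def test_zero_variance_differences_degenerate_t(self):
        pre = np.array([1.0, 2.0, 3.0, 4.0])
        t, w = compare_paired(pre, pre + 1.0)
        assert t.flagged
        assert w.p_value == pytest.approx(2 / 16)  # 4 positive signs, exact

    def test_exact_and_approx_agree_at_moderate_n(self, rng):
        for _ in range(50):
            diffs = rng.normal(0.3, 1.0, size=12)
            pre = np.zeros(12)
            _, w_exact = compare_paired(pre, diffs)
            # recompute with the approximation by inflating past the cutover
            from scipy.stats import wilcoxon

            try:
                _, p_approx = wilcoxon(
                    diffs, alternative="two-sided", correction=True, method="approx"
                )
            except TypeError:  # older scipy spells the argument 'mode'
                _, p_approx = wilcoxon(
                    diffs, alternative="two-sided", correction=True, mode="approx"
                )
            assert abs(w_exact.p_value - p_approx) < 0.05

    def test_too_few_pairs_rejected(self):
        with pytest.raises(DomainError):
            compare_paired([1.0, 2.0], [2.0, 3.0])


class TestGroups:
    def test_complete_separation_exact_p(self):
        res = compare_groups([1, 2, 3], [4, 5, 6])
        assert res.estimate == 0.0
        assert res.p_value == pytest.approx(2 / 20)

    def test_identical_multisets_give_p_one(self):
        res = compare_groups([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_approximation_tracks_enumeration(self, rng):
        """Asymptotic p within 0.02 of the exact enumeration at n=6+6."""
        from scipy.stats import mannwhitneyu

        worst = 0.0
        for _ in range(100):
            a = rng.normal(0, 1, 6)
            b = rng.normal(0.5, 1, 6)
            p_exact = exact_mwu_p(a, b)
            _, p_approx = mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic"
            )
            worst = max(worst, abs(p_exact - p_approx))
        assert worst < 0.02

    def test_package_exact_path_matches_oracle(self, rng):
        for _ in range(25):
            a = rng.integers(0, 5, size=5).astype(float)  # ties likely
            b = rng.integers(0, 5, size=6).astype(float)
            res = compare_groups(a, b)
            assert res.p_value == pytest.approx(exact_mwu_p(a, b))

    def test_small_groups_rejected(self):
        with pytest.raises(DomainError):
            compare_groups([1.0], [2.0, 3.0])

    def test_median_dichotomization(self):
        values = np.arange(6, dtype=float)
        scores = np.array([1, 1, 2, 3, 4, 5], dtype=float)
        low, high = dichotomize_by_median(values, scores)
        assert set(low) == {0, 1, 2}  # scores <= median 2.5
        assert set(high) == {3, 4, 5}

    def test_type_one_error_calibrated_under_null(self, rng):
        """Nominal 5% rejection rate within +-2% over 2000 null replicates."""
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            a = rng.standard_normal(20)
            b = rng.standard_normal(20)
            if compare_groups(a, b).p_value < 0.05:
                rejections += 1
        rate = rejections / n_rep
        assert 0.03 <= rate <= 0.07


class TestCorrelate:
    def test_perfect_monotone_spearman(self):
        x = np.arange(6, dtype=float)
        res = correlate(x, x**3, method="spearman")
        assert res.estimate == pytest.approx(1.0)
        assert res.p_value < 0.05

    def test_near_perfect_negative_pearson(self, rng):
        x = rng.random(50)
        res = correlate(x, -x + rng.normal(0, 1e-8, 50), method="pearson")
        assert res.estimate == pytest.approx(-1.0, abs=1e-5)

    def test_orthogonal_covariates_leave_r_unchanged(self, rng):
        n = 64
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        # Build covariates orthogonal to x, y, and the intercept.
        basis = np.column_stack([np.ones(n), x, y])
        raw = rng.standard_normal((n, 2))
        cov = raw - basis @ np.linalg.lstsq(basis, raw, rcond=None)[0]
        plain = correlate(x, y, method="pearson")
        partial = correlate(x, y, method="pearson", covariates=cov)
        assert partial.estimate == pytest.approx(plain.estimate, abs=1e-6)

    def test_partial_removes_confounder(self, rng):
        n = 200
        z = rng.standard_normal(n)
        x = z + 0.3 * rng.standard_normal(n)
        y = z + 0.3 * rng.standard_normal(n)
        plain = correlate(x, y, method="pearson")
        partial = correlate(x, y, method="pearson", covariates=z)
        assert plain.estimate > 0.7
        assert abs(partial.estimate) < 0.3

    def test_constant_input_flagged(self):
        res = correlate(np.ones(10), np.arange(10.0), method="pearson")
        assert res.flagged


class TestLogistic:
    def test_null_association_rarely_significant(self, rng):
        significant = 0
        for _ in range(100):
            delta = rng.normal(-0.13, 0.05, 500)
            treated = (rng.random(500) < 0.6).astype(float)
            fit = fit_treatment_logistic(delta, treated)
            if not fit.flagged and fit.p1 < 0.05:
                significant += 1
        assert significant <= 10

    def test_parameter_recovery(self, rng):
        beta0, beta1 = 1.0, 10.0
        delta = rng.normal(-0.13, 0.06, 2000)
        p = 1 / (1 + np.exp(-(beta0 + beta1 * delta)))
        treated = (rng.random(2000) < p).astype(float)
        fit = fit_treatment_logistic(delta, treated)
        assert not fit.flagged
        assert fit.beta1 == pytest.approx(beta1, rel=0.25)

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            fit_treatment_logistic(np.zeros(10), np.ones(10))

    def test_perfect_separation_flagged(self):
        delta = np.concatenate([np.full(20, -1.0), np.full(20, 1.0)])
        treated = np.concatenate([np.zeros(20), np.ones(20)])
        fit = fit_treatment_logistic(delta, treated)
        assert fit.flagged
        assert np.isnan(fit.beta1)


class TestFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.03]), [0.03])

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            fdr_adjust([0.5, 1.5])

    @settings(max_examples=100, deadline=None)
    @given(
        p=st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=20)
    )
    def test_never_decreases_and_preserves_order(self, p):
        p_arr = np.asarray(p)
        adjusted = fdr_adjust(p_arr)
        assert np.all(adjusted >= p_arr - 1e-15)
        assert np.all((adjusted >= 0) & (adjusted <= 1))
        # monotone map: smaller raw p never gets a larger adjusted p
        order = np.argsort(p_arr, kind="stable")
        assert np.all(np.diff(adjusted[order]) >= -1e-15)
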