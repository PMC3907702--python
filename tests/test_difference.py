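import numpy as np
import pytest

from isckit.core import fisher_z
from isckit.difference import (
    PairedConditionData,
    estimate_pair_covariance,
    fwer_thresholds,
    signflip_null,
    sum_zpf,
    zpf_term,
)
from isckit.synthetic import SyntheticSpec, synth_paired_null, synth_session

from conftest import make_session


def compact_pearson_filon(r12, r34, r13, r14, r23, r24):
    """Independent transcription of the large-sample covariance of two
    nonoverlapping correlations (different algebraic arrangement than the
    implementation's)."""
    return (
        0.5 * r12 * r34 * (r13**2 + r14**2 + r23**2 + r24**2)
        + r13 * r24
        + r14 * r23
        - (r12 * r13 * r14 + r12 * r23 * r24 + r13 * r23 * r34 + r14 * r24 * r34)
    )


def sample_r(x, y):
    return np.corrcoef(x, y)[0, 1]


class TestPairCovariance:
    def test_matches_independent_transcription(self, rng):
        series = rng.standard_normal((4, 10))
        est = estimate_pair_covariance(*series)
        x1, x2, x3, x4 = series
        expected = compact_pearson_filon(
            sample_r(x1, x2),
            sample_r(x3, x4),
            sample_r(x1, x3),
            sample_r(x1, x4),
            sample_r(x2, x3),
            sample_r(x2, x4),
        )
        assert est == pytest.approx(expected, abs=1e-12)

    def test_self_covariance_is_large_sample_variance(self, rng):
        x1, x2 = rng.standard_normal((2, 50))
        est = estimate_pair_covariance(x1, x2, x1.copy(), x2.copy())
        r = sample_r(x1, x2)
        assert est == pytest.approx((1 - r**2) ** 2, abs=1e-12)

    def test_independent_conditions_estimate_shrinks_with_T(self, rng):
        # |estimate| -> 0 as T grows when the two conditions are independent
        means = []
        for T in (50, 800):
            ests = [
                estimate_pair_covariance(*rng.standard_normal((4, T)))
                for _ in range(200)
            ]
            means.append(np.mean(np.abs(ests)))
        assert means[1] < means[0] / 2
        assert means[1] < 0.05

    def test_degenerate_series_rejected(self, rng):
        flat = np.ones(10)
        with pytest.raises(ValueError):
            estimate_pair_covariance(flat, *rng.standard_normal((3, 10)))


class TestSumZPF:
    def test_identical_conditions_give_zero_map(self, tiny_session):
        paired = PairedConditionData(session_a=tiny_session, session_b=tiny_session)
        stats = sum_zpf(paired)
        np.testing.assert_array_equal(stats.sum_map[tiny_session.mask.mask], 0.0)

    def test_label_swap_negates_map(self):
        paired = synth_paired_null(
            SyntheticSpec(n_subjects=3, T=50, rho=0.3, dims=(2, 2, 2), seed=3)
        )
        fwd = sum_zpf(paired)
        rev = sum_zpf(
            PairedConditionData(
                session_a=paired.session_b, session_b=paired.session_a
            )
        )
        np.testing.assert_allclose(fwd.sum_map, -rev.sum_map, atol=1e-10)

    def test_single_pair_summand_closed_form(self):
        # r_a=0.5, r_b=0.2, cov=0, T=103 -> (z(0.5)-z(0.2)) * sqrt(50)
        term = zpf_term(0.5, 0.2, 0.0, 103)
        expected = (fisher_z(0.5) - fisher_z(0.2)) * np.sqrt(50)
        assert term == pytest.approx(expected, abs=1e-12)

    def test_pair_terms_match_summand_formula(self):
        paired = synth_paired_null(
            SyntheticSpec(n_subjects=3, T=40, rho=0.2, dims=(2, 1, 1), seed=9)
        )
        stats = sum_zpf(paired)
        # reassemble each pair term from its ingredients via the summand helper
        ra = {}
        for v in range(2):
            for p, (i, j) in enumerate(stats.pair_index):
                series_a = paired.session_a.masked_series()
                series_b = paired.session_b.masked_series()
                r_a = sample_r(series_a[i, v], series_a[j, v])
                r_b = sample_r(series_b[i, v], series_b[j, v])
                expected = zpf_term(r_a, r_b, stats.cov_ab[v, p], stats.T)
                assert stats.pair_zpf[v, p] == pytest.approx(expected, abs=1e-10)


class TestSignFlipNull:
    def test_all_zero_terms_give_zero_extrema(self, tiny_session):
        paired = PairedConditionData(session_a=tiny_session, session_b=tiny_session)
        ext = signflip_null(sum_zpf(paired), n_perm=50, seed=0)
        np.testing.assert_array_equal(ext.max_stats, 0.0)
        np.testing.assert_array_equal(ext.min_stats, 0.0)

    def test_single_pair_support_is_plus_minus_v(self):
        paired = synth_paired_null(
            SyntheticSpec(n_subjects=2, T=40, rho=0.0, dims=(1, 1, 1), seed=4)
        )
        stats = sum_zpf(paired)
        v = stats.pair_zpf[0, 0]
        assert v != 0
        ext = signflip_null(stats, n_perm=2000, seed=1)
        values = np.unique(ext.max_stats)
        np.testing.assert_allclose(values, sorted([-v, v]), atol=1e-12)
        # the two outcomes occur with equal frequency up to binomial error
        frac = (ext.max_stats == values[1]).mean()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 2000)

    def test_same_seed_reproduces_extrema(self, tiny_session, null_session):
        paired = synth_paired_null(
            SyntheticSpec(n_subjects=3, T=50, rho=0.2, dims=(2, 2, 1), seed=8)
        )
        stats = sum_zpf(paired)
        a = signflip_null(stats, n_perm=200, seed=7)
        b = signflip_null(stats, n_perm=200, seed=7)
        np.testing.assert_array_equal(a.max_stats, b.max_stats)
        np.testing.assert_array_equal(a.min_stats, b.min_stats)

    def test_max_at_least_min(self):
        paired = synth_paired_null(
            SyntheticSpec(n_subjects=3, T=50, rho=0.2, dims=(2, 2, 1), seed=8)
        )
        ext = signflip_null(sum_zpf(paired), n_perm=100, seed=2)
        assert np.all(ext.max_stats >= ext.min_stats)


class TestFWERThresholds:
    def test_symmetric_null_gives_symmetric_thresholds(self):
        paired = synth_paired_null(
            SyntheticSpec(n_subjects=3, T=60, rho=0.3, dims=(3, 3, 1), seed=21)
        )
        ext = signflip_null(sum_zpf(paired), n_perm=4000, seed=3)
        upper, lower = fwer_thresholds(ext, alpha=0.05)
        assert upper > 0 > lower
        assert upper == pytest.approx(-lower, rel=0.25)

    def test_quantile_boundary(self):
        paired = synth_paired_null(
            SyntheticSpec(n_subjects=3, T=60, rho=0.3, dims=(2, 2, 1), seed=5)
        )
        ext = signflip_null(sum_zpf(paired), n_perm=100, seed=0)
        upper, _ = fwer_thresholds(ext, alpha=1 - 1 / 100)
        assert upper <= np.partition(ext.max_stats, 1)[1] + 1e-12

    def test_degenerate_all_zero_extrema(self, tiny_session):
        paired = PairedConditionData(session_a=tiny_session, session_b=tiny_session)
        ext = signflip_null(sum_zpf(paired), n_perm=50, seed=0)
        assert fwer_thresholds(ext, alpha=0.05) == (0.0, 0.0)


class TestPairedValidation:
    def test_unequal_T_rejected(self, rng):
        a = make_session([rng.standard_normal((2, 2, 1, 30)) for _ in range(2)])
        b = make_session([rng.standard_normal((2, 2, 1, 29)) for _ in range(2)])
        with pytest.raises(ValueError, match="equal series length"):
            PairedConditionData(session_a=a, session_b=b)

    def test_subject_order_must_match(self, rng):
        a = make_session([rng.standard_normal((2, 2, 1, 20)) for _ in range(2)])
        b = make_session([rng.standard_normal((2, 2, 1, 20)) for _ in range(2)])
        b.subjects = b.subjects[::-1]
        with pytest.raises(ValueError, match="order"):
            PairedConditionData(session_a=a, session_b=b)
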