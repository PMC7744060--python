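"""Dual-cutoff index estimation: worked example, oracle equivalence, and
order/decomposition invariants."""

import itertools
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mdepriv as md


def matrix_from(b, weights=None, ids=None):
    b = np.asarray(b)
    n, m = b.shape
    return md.DeprivationMatrix(
        b=b,
        sample_weights=np.ones(n) if weights is None else np.asarray(weights, float),
        indicator_ids=ids or [f"ind{j}" for j in range(m)],
        row_ids=[f"r{i}" for i in range(n)],
    )


def equal_weight_codebook(m):
    return md.Codebook(
        [
            md.IndicatorSpec(f"ind{j}", "", {0: "no", 1: "yes"}, frozenset([1]), Fraction(1, m))
            for j in range(m)
        ]
    )


class TestWorkedExample:
    """The five-individual illustration: scores 3/4, 0, 1, 1/2, 1/4."""

    def test_scores(self, codebook, example_matrix):
        sv = md.deprivation_scores(example_matrix, codebook)
        assert sv.scores == [
            Fraction(3, 4),
            Fraction(0),
            Fraction(1),
            Fraction(1, 2),
            Fraction(1, 4),
        ]

    def test_identify_k2_selects_individuals_1_3_4(self, codebook, example_matrix):
        sv = md.deprivation_scores(example_matrix, codebook)
        assert md.identify(sv, 2, 4).tolist() == [True, False, True, True, False]

    def test_hcr_a_m_at_k2(self, codebook, example_matrix):
        sv = md.deprivation_scores(example_matrix, codebook)
        hcr = md.headcount_ratio(sv, 2, 4)
        a = md.average_intensity(sv, 2, 4)
        m_idx = md.adjusted_headcount(sv, 2, 4)
        assert hcr == Fraction(3, 5)
        assert a == Fraction(9, 12)
        assert m_idx == Fraction(9, 20)
        assert m_idx == hcr * a  # product identity, exact

    def test_hcr_sequence_over_k(self, codebook, example_matrix):
        profile = md.af_profile(example_matrix, codebook)
        assert [e.hcr for e in profile] == [4 / 5, 3 / 5, 2 / 5, 1 / 5]

    def test_intensity_at_k1_is_10_16(self, codebook, example_matrix):
        sv = md.deprivation_scores(example_matrix, codebook)
        assert md.average_intensity(sv, 1, 4) == Fraction(10, 16)

    def test_weighted_hcr(self, codebook, example_matrix):
        """Respondent 1 double-weighted: HCR(k=2) becomes 4/6."""
        reweighted = matrix_from(
            example_matrix.b, weights=[2, 1, 1, 1, 1], ids=example_matrix.indicator_ids
        )
        sv = md.deprivation_scores(reweighted, codebook)
        assert md.headcount_ratio(sv, 2, 4) == Fraction(4, 6)

    def test_indicator_rates(self, codebook, example_matrix):
        rates = md.indicator_rates(example_matrix)
        assert rates.tolist() == [2 / 5, 2 / 5, 4 / 5, 2 / 5]


class TestScoresAndIdentification:
    def test_unequal_weights_exact_rational_score(self):
        cb = md.Codebook(
            [
                md.IndicatorSpec("a", "", {0: "n", 1: "y"}, frozenset([1]), Fraction(1, 2)),
                md.IndicatorSpec("b", "", {0: "n", 1: "y"}, frozenset([1]), Fraction(1, 6)),
                md.IndicatorSpec("c", "", {0: "n", 1: "y"}, frozenset([1]), Fraction(1, 6)),
                md.IndicatorSpec("d", "", {0: "n", 1: "y"}, frozenset([1]), Fraction(1, 6)),
            ]
        )
        mat = matrix_from([[1, 0, 0, 1]], ids=["a", "b", "c", "d"])
        sv = md.deprivation_scores(mat, cb)
        assert sv.scores == [Fraction(2, 3)]

    def test_union_identification_on_all_zero_scores(self):
        cb = equal_weight_codebook(3)
        sv = md.deprivation_scores(matrix_from(np.zeros((4, 3), dtype=int)), cb)
        assert not md.identify(sv, 1, 3).any()

    def test_intersection_identification_selects_fully_deprived(self, codebook, example_matrix):
        sv = md.deprivation_scores(example_matrix, codebook)
        assert md.identify(sv, 4, 4).tolist() == [False, False, True, False, False]

    def test_k_out_of_range(self, codebook, example_matrix):
        sv = md.deprivation_scores(example_matrix, codebook)
        with pytest.raises(ValueError, match="cutoff k"):
            md.identify(sv, 0, 4)
        with pytest.raises(ValueError, match="cutoff k"):
            md.identify(sv, 5, 4)

    def test_empty_identified_set_gives_undefined_intensity(self):
        cb = equal_weight_codebook(2)
        sv = md.deprivation_scores(matrix_from([[0, 0], [1, 0]]), cb)
        assert md.average_intensity(sv, 2, 2) is None
        assert md.adjusted_headcount(sv, 2, 2) == 0
        profile = md.af_profile(matrix_from([[0, 0], [1, 0]]), cb)
        assert profile[1].intensity_a is None and profile[1].adjusted_m == 0.0

    def test_intensity_is_one_at_k_equals_m(self, codebook, example_matrix):
        sv = md.deprivation_scores(example_matrix, codebook)
        assert md.average_intensity(sv, 4, 4) == 1

    def test_all_deprived_hcr_one_for_every_k(self):
        cb = equal_weight_codebook(3)
        sv = md.deprivation_scores(matrix_from(np.ones((4, 3), dtype=int)), cb)
        for k in (1, 2, 3):
            assert md.headcount_ratio(sv, k, 3) == 1


class TestOracleEquivalence:
    def test_exhaustive_small_matrices(self, oracle):
        """Exact agreement with censor-and-average enumeration, all 2^(n*m)
        binary matrices with n, m <= 3."""
        for m in (2, 3):
            cb = equal_weight_codebook(m)
            w_ind = [Fraction(1, m)] * m
            for n in (1, 2, 3):
                for bits in itertools.product((0, 1), repeat=n * m):
                    b = np.array(bits).reshape(n, m)
                    mat = matrix_from(b)
                    sv = md.deprivation_scores(mat, cb)
                    for k in range(1, m + 1):
                        hcr, a, m_idx = oracle(b, w_ind, np.ones(n), k)
                        assert md.headcount_ratio(sv, k, m) == hcr
                        assert md.average_intensity(sv, k, m) == a
                        assert md.adjusted_headcount(sv, k, m) == m_idx

    def test_random_weighted_matrices(self, oracle, rng):
        """Random sampling weights: exact via the rational path, 1e-12 for
        the float profile."""
        cb = equal_weight_codebook(4)
        w_ind = [Fraction(1, 4)] * 4
        for _ in range(200):
            n = int(rng.integers(1, 9))
            b = rng.integers(0, 2, size=(n, 4))
            sw = rng.uniform(0.1, 5.0, size=n)
            mat = matrix_from(b, weights=sw)
            sv = md.deprivation_scores(mat, cb)
            profile = md.af_profile(mat, cb)
            for k in range(1, 5):
                hcr, a, m_idx = oracle(b, w_ind, sw, k)
                assert md.headcount_ratio(sv, k, 4) == hcr
                assert md.average_intensity(sv, k, 4) == a
                assert md.adjusted_headcount(sv, k, 4) == m_idx
                est = profile[k - 1]
                assert est.hcr == pytest.approx(float(hcr), abs=1e-12)
                assert est.adjusted_m == pytest.approx(float(m_idx), abs=1e-12)


binary_matrices = st.integers(1, 6).flatmap(
    lambda n: st.lists(
        st.lists(st.integers(0, 1), min_size=4, max_size=4), min_size=n, max_size=n
    )
)


class TestInvariants:
    @settings(max_examples=100, derandomize=True)
    @given(b=binary_matrices, data=st.data())
    def test_order_and_product_invariants(self, codebook, b, data):
        """0 <= M <= HCR <= 1; HCR, M non-increasing and A non-decreasing in
        k; M = HCR * A; scale invariance of all three."""
        b = np.array(b)
        n = b.shape[0]
        sw = data.draw(
            st.lists(
                st.floats(0.1, 10, allow_nan=False), min_size=n, max_size=n
            )
        )
        mat = matrix_from(b, weights=sw, ids=codebook.indicator_ids)
        profile = md.af_profile(mat, codebook)
        hcrs = [e.hcr for e in profile]
        ms = [e.adjusted_m for e in profile]
        as_ = [e.intensity_a for e in profile if e.intensity_a is not None]
        for e in profile:
            assert 0.0 <= e.adjusted_m <= e.hcr <= 1.0
            if e.intensity_a is not None:
                assert e.adjusted_m == pytest.approx(e.hcr * e.intensity_a, abs=1e-12)
                assert e.k / mat.m - 1e-12 <= e.intensity_a <= 1.0 + 1e-12
        assert all(x >= y - 1e-12 for x, y in zip(hcrs, hcrs[1:]))
        assert all(x >= y - 1e-12 for x, y in zip(ms, ms[1:]))
        assert all(x <= y + 1e-12 for x, y in zip(as_, as_[1:]))
        # scale invariance of the estimates under c * weights
        scaled = md.af_profile(
            matrix_from(b, weights=np.asarray(sw) * 7.25, ids=codebook.indicator_ids),
            codebook,
        )
        for e1, e2 in zip(profile, scaled):
            assert e1.hcr == pytest.approx(e2.hcr, abs=1e-12)
            assert e1.adjusted_m == pytest.approx(e2.adjusted_m, abs=1e-12)

    def test_single_fully_deprived_respondent(self, codebook):
        mat = matrix_from(np.ones((1, 4), dtype=int), ids=codebook.indicator_ids)
        for est in md.af_profile(mat, codebook):
            assert est.hcr == est.intensity_a == est.adjusted_m == 1.0
            assert est.se_hcr == est.se_m == 0.0

    def test_at_k_equals_m_intensity_one_m_equals_hcr(self, codebook, rng):
        b = rng.integers(0, 2, size=(50, 4))
        b[0] = 1  # ensure the intersection set is non-empty
        profile = md.af_profile(matrix_from(b, ids=codebook.indicator_ids), codebook)
        top = profile[-1]
        assert top.intensity_a == pytest.approx(1.0, abs=1e-12)
        assert top.adjusted_m == pytest.approx(top.hcr, abs=1e-12)


class TestStandardErrors:
    def test_linearized_hcr_se_reduces_to_binomial_form(self, codebook, rng):
        b = rng.integers(0, 2, size=(400, 4))
        mat = matrix_from(b, ids=codebook.indicator_ids)
        est = md.af_profile(mat, codebook)[1]
        p = est.hcr
        assert est.se_hcr == pytest.approx(np.sqrt(p * (1 - p) / 400), rel=1e-9)

    def test_bootstrap_is_seed_deterministic(self, codebook, rng):
        b = rng.integers(0, 2, size=(120, 4))
        mat = matrix_from(b, ids=codebook.indicator_ids)
        one = md.af_profile(mat, codebook, se_method="bootstrap", bootstrap_reps=200, seed=11)
        two = md.af_profile(mat, codebook, se_method="bootstrap", bootstrap_reps=200, seed=11)
        assert [e.se_hcr for e in one] == [e.se_hcr for e in two]

    def test_bootstrap_rejects_too_few_reps(self, codebook, example_matrix):
        with pytest.raises(ValueError, match="at least 2"):
            md.af_profile(example_matrix, codebook, se_method="bootstrap", bootstrap_reps=1)

    def test_bootstrap_and_linearized_agree_on_moderate_sample(self, codebook):
        config = md.shed_like(seed=99, n=5000, weight_sigma=0.0)
        ds = md.generate_survey(config, codebook)
        mat = md.dichotomize(ds, codebook)
        lin = md.af_profile(mat, codebook, se_method="linearized")
        boot = md.af_profile(mat, codebook, se_method="bootstrap", bootstrap_reps=400, seed=5)
        for e_lin, e_boot in zip(lin, boot):
            assert e_boot.se_hcr == pytest.approx(e_lin.se_hcr, rel=0.2)
            assert e_boot.se_m == pytest.approx(e_lin.se_m, rel=0.2)
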