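import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

from asmqtl.core import (DomainError, InvalidKinshipError, KinshipMatrix,
                         PairCounts, VarianceComponents,
                         collapse_homozygote_approx, exact_homozygote_dist,
                         exact_homozygote_pmf, linear_predictor,
                         standardize_kinship, DesignRow)


class TestStandardizeKinship:
    @pytest.mark.parametrize("mat", [np.eye(5), 2.0 * np.eye(3)])
    def test_scaling_to_unit_diagonal_mean(self, mat):
        K = KinshipMatrix([f"i{j}" for j in range(len(mat))], mat)
        out = standardize_kinship(K)
        np.testing.assert_allclose(out.values, np.eye(len(mat)), atol=1e-12)

    def test_two_by_two(self):
        K = KinshipMatrix(["a", "b"], np.array([[2.0, 1.0], [1.0, 2.0]]))
        out = standardize_kinship(K)
        np.testing.assert_allclose(out.values,
                                   [[1.0, 0.5], [0.5, 1.0]], atol=1e-12)
        assert out.ids == ["a", "b"]

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(6, 6))
        K = KinshipMatrix(list("abcdef"), A @ A.T)
        once = standardize_kinship(K)
        twice = standardize_kinship(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)
        assert abs(np.trace(once.values) / 6 - 1.0) < 1e-10

    def test_psd_repair_clips_negative_eigenvalues(self):
        v = np.eye(4)
        v[0, 1] = v[1, 0] = 1.5      # indefinite
        out = standardize_kinship(KinshipMatrix(list("abcd"), v))
        w = np.linalg.eigvalsh(out.values)
        assert w.min() >= -1e-10
        assert abs(np.trace(out.values) / 4 - 1.0) < 1e-10

    def test_errors(self):
        with pytest.raises(InvalidKinshipError):
            KinshipMatrix(["a", "b"], np.zeros((2, 3)))
        with pytest.raises(InvalidKinshipError):
            standardize_kinship(KinshipMatrix(["a", "b"], -np.eye(2)))
        with pytest.raises(InvalidKinshipError):
            KinshipMatrix(["a", "b"], np.array([[1.0, 0.5], [0.0, 1.0]]))


class TestLinearPredictor:
    @pytest.mark.parametrize("mu,beta,x,g,u,e,expected", [
        (0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0),
        (0.0, 1.0, 1.0, 0.0, 0.0, 0.0, 1.0),
        (-2.0, 1.0, 0.5, 0.3, -0.1, 0.2, -1.1),
    ])
    def test_additive_sum(self, mu, beta, x, g, u, e, expected):
        row = DesignRow(individual_index=0, x=x, y=0, r=1)
        assert linear_predictor(mu, beta, row, g, u, e) == pytest.approx(expected)


class TestExactHomozygotePmf:
    def test_equal_pi_collapses_to_binomial(self):
        for r, p in [(2, 0.5), (7, 0.2), (25, 0.9)]:
            pmf = exact_homozygote_dist(r, p, p)
            np.testing.assert_allclose(pmf, binom.pmf(np.arange(r + 1), r, p),
                                       atol=1e-12)

    def test_point_examples(self):
        assert exact_homozygote_pmf(1, 2, 0.5, 0.5) == pytest.approx(0.5)
        # one read, one fully methylated and one unmethylated allele:
        # the read comes from either allele with probability 1/2
        assert exact_homozygote_pmf(1, 1, 1.0, 0.0) == pytest.approx(0.5)

    def test_against_independent_double_sum(self):
        def brute(y, r, p1, p2):
            tot = 0.0
            for r1 in range(r + 1):
                for y1 in range(max(0, y - (r - r1)), min(r1, y) + 1):
                    tot += (binom.pmf(r1, r, 0.5) * binom.pmf(y1, r1, p1)
                            * binom.pmf(y - y1, r - r1, p2))
            return tot
        for (y, r, p1, p2) in [(2, 3, 0.2, 0.8), (5, 9, 0.65, 0.1),
                               (0, 6, 0.4, 0.4)]:
            assert exact_homozygote_pmf(y, r, p1, p2) == \
                pytest.approx(brute(y, r, p1, p2), abs=1e-12)

    def test_against_monte_carlo(self):
        rng = np.random.default_rng(0)
        r, p1, p2 = 3, 0.2, 0.8
        n = 1_000_000
        r1 = rng.binomial(r, 0.5, size=n)
        y = rng.binomial(r1, p1) + rng.binomial(r - r1, p2)
        freq = np.bincount(y, minlength=r + 1) / n
        np.testing.assert_allclose(exact_homozygote_dist(r, p1, p2), freq,
                                   atol=4e-3)

    @given(r=st.integers(1, 30), p1=st.floats(0.01, 0.99),
           p2=st.floats(0.01, 0.99))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_sums_to_one_and_linear_mean(self, r, p1, p2):
        pmf = exact_homozygote_dist(r, p1, p2)
        ys = np.arange(r + 1)
        assert abs(pmf.sum() - 1.0) < 1e-10
        assert abs(pmf @ ys - r * (p1 + p2) / 2) < 1e-10

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            exact_homozygote_pmf(3, 2, 0.5, 0.5)
        with pytest.raises(DomainError):
            exact_homozygote_pmf(0, 20_000, 0.5, 0.5)


class TestCollapseHomozygote:
    def test_rejects_het_without_flag(self):
        with pytest.raises(ValueError):
            collapse_homozygote_approx(0, 1.0, 3, 10)
        row = collapse_homozygote_approx(0, 1.0, 3, 10, allow_het=True)
        assert row.x == pytest.approx(0.5)

    def test_row_contract(self):
        row = collapse_homozygote_approx(4, 2.0, 3, 10)
        assert (row.individual_index, row.x, row.residual_scale) == (4, 1.0, 0.5)
        assert not row.is_allele

    def test_binomial_moments_match_exact_distribution(self):
        """Conditional on the two allele probabilities, the collapsed
        binomial matches the exact read-split distribution in both mean
        and variance (the basis of the sigma_e^2/2 residual scaling)."""
        for r in (5, 20, 50):
            for p1, p2 in [(0.1, 0.3), (0.5, 0.5), (0.2, 0.8), (0.9, 0.97)]:
                pmf = exact_homozygote_dist(r, p1, p2)
                ys = np.arange(r + 1)
                pbar = (p1 + p2) / 2
                mean = pmf @ ys
                var = pmf @ ys**2 - mean**2
                assert mean == pytest.approx(r * pbar, abs=1e-10)
                assert var == pytest.approx(r * pbar * (1 - pbar), abs=1e-9)


class TestVarianceComponents:
    def test_h2_definition_and_bounds(self):
        vc = VarianceComponents(0.2, 0.1, 0.4)
        assert vc.h2 == pytest.approx(0.2 / (0.2 + 0.1 + 0.2))
        assert VarianceComponents(0.0, 0.0, 0.0).h2 == 0.0
        assert 0.0 <= VarianceComponents(5.0, 0.0, 1e-9).h2 <= 1.0


class TestPairCounts:
    def test_validate_catches_bad_counts(self, toy_pair):
        toy_pair.validate()
        toy_pair.y_total[0] = 20.0
        with pytest.raises(DomainError):
            toy_pair.validate()

    def test_validate_catches_allele_sum_mismatch(self, toy_pair):
        toy_pair.y_allele[1, 0] = 3.0   # 3 + 5 != 7
        with pytest.raises(DomainError):
            toy_pair.validate()

    def test_drop_uninformative(self, toy_pair):
        toy_pair.r_total[2] = 0.0
        out = toy_pair.drop_uninformative()
        assert out.individual_ids == ["a", "b"]
        assert out.n == 2
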