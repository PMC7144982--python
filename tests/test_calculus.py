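"""Moments, characteristic function and closure laws."""

import math

import numpy as np
import pytest
from scipy import integrate

from mvmmn import (
    MMNParams,
    MixingLaw,
    PartitionSpec,
    affine_transform,
    conditional_params,
    marginal_params,
    mmn_char_function,
    mmn_elementwise_second_moment,
    mmn_logpdf,
    mmn_logpdf_numeric,
    mmn_mean,
    mmn_sample,
    mmn_trace_second_moment,
    quadratic_form_mc_check,
    quadratic_form_spec,
    transpose_params,
)

from conftest import FAMILIES, random_params, random_spd


class TestMean:
    def test_zero_skewness(self, rng):
        params = random_params(rng, "exp1").replace(Lambda=np.zeros((2, 3)))
        np.testing.assert_allclose(mmn_mean(params), params.M)

    def test_rsn_all_ones_skewness(self):
        J = np.ones((2, 2))
        params = MMNParams(np.zeros((2, 2)), J, np.eye(2), np.eye(2), MixingLaw.rsn())
        np.testing.assert_allclose(mmn_mean(params), math.sqrt(2 / math.pi) * J)

    def test_weib21_monte_carlo(self, rng):
        params = random_params(rng, "weib21")
        ds = mmn_sample(params, 200_000, seed=11)
        se = ds.observations.std(axis=0, ddof=1) / math.sqrt(ds.N)
        assert np.all(np.abs(ds.mean() - mmn_mean(params)) < 4 * se)


class TestCharFunction:
    def test_at_origin(self, rng):
        params = random_params(rng, "weib21")
        assert mmn_char_function(np.zeros((2, 3)), params) == pytest.approx(1.0)

    def test_zero_skewness_is_matrix_normal_cf(self, rng):
        params = random_params(rng, "rsn").replace(Lambda=np.zeros((2, 3)))
        T = 0.3 * rng.standard_normal((2, 3))
        expected = np.exp(
            1j * np.trace(T.T @ params.M)
            - 0.5 * np.trace(T.T @ params.Sigma @ T @ params.Psi)
        )
        assert mmn_char_function(T, params) == pytest.approx(expected, abs=1e-12)

    def test_hermitian_property(self, rng):
        params = random_params(rng, "exp1")
        T = 0.2 * rng.standard_normal((2, 3))
        assert mmn_char_function(-T, params) == pytest.approx(
            np.conj(mmn_char_function(T, params)), abs=1e-14
        )

    @pytest.mark.parametrize("family", FAMILIES)
    def test_matches_empirical_cf(self, family, rng):
        params = random_params(rng, family)
        T = 0.15 * rng.standard_normal((2, 3))
        draws = mmn_sample(params, 200_000, seed=5).observations
        phases = np.exp(1j * np.einsum("pn,ipn->i", T, draws))
        emp = phases.mean()
        se = phases.std(ddof=1) / math.sqrt(draws.shape[0])
        assert abs(mmn_char_function(T, params) - emp) < 5 * se


class TestSecondMoments:
    def test_matrix_normal_diagonal_case(self, rng):
        params = random_params(rng, "rsn").replace(
            M=np.zeros((2, 3)), Lambda=np.zeros((2, 3))
        )
        val = mmn_elementwise_second_moment(params, 1, 2, 1, 2)
        assert val == pytest.approx(params.Sigma[1, 1] * params.Psi[2, 2])

    def test_trace_formula_plugin(self):
        # rsn, 2x2 identity scales, all-ones skewness: E tr(YY') = 1*4 + 2*2
        params = MMNParams(
            np.zeros((2, 2)), np.ones((2, 2)), np.eye(2), np.eye(2), MixingLaw.rsn()
        )
        assert mmn_trace_second_moment(params) == pytest.approx(8.0)

    def test_trace_formula_requires_zero_location(self, rng):
        params = random_params(rng, "rsn")
        with pytest.raises(ValueError, match="M = 0"):
            mmn_trace_second_moment(params)

    def test_monte_carlo_agreement(self, rng):
        params = random_params(rng, "exp1").replace(M=np.zeros((2, 3)))
        draws = mmn_sample(params, 200_000, seed=21).observations
        tr = np.einsum("ipn,ipn->i", draws, draws)
        se = tr.std(ddof=1) / math.sqrt(tr.size)
        assert tr.mean() == pytest.approx(mmn_trace_second_moment(params), abs=4 * se)
        # elementwise check on one entry pair
        prod = draws[:, 0, 1] * draws[:, 1, 2]
        se2 = prod.std(ddof=1) / math.sqrt(prod.size)
        assert prod.mean() == pytest.approx(
            mmn_elementwise_second_moment(params, 0, 1, 1, 2), abs=4 * se2
        )


class TestTranspose:
    def test_involution(self, rng):
        params = random_params(rng, "weib21")
        back = transpose_params(transpose_params(params))
        np.testing.assert_array_equal(back.M, params.M)
        np.testing.assert_array_equal(back.Sigma, params.Sigma)
        np.testing.assert_array_equal(back.Psi, params.Psi)

    def test_density_invariance(self, rng):
        params = random_params(rng, "rsn", p=2, n=3)
        Y = rng.standard_normal((2, 3))
        assert mmn_logpdf(Y.T, transpose_params(params)) == pytest.approx(
            mmn_logpdf(Y, params), abs=1e-12
        )

    def test_symmetric_instance_is_fixed_point(self, rng):
        S = random_spd(rng, 2)
        M = np.array([[1.0, 2.0], [2.0, -1.0]])
        params = MMNParams(M, M, S, S, MixingLaw.exp1())
        t = transpose_params(params)
        np.testing.assert_array_equal(t.M, params.M)
        np.testing.assert_array_equal(t.Sigma, params.Sigma)


class TestAffineAndMarginal:
    def test_identity_transform(self, rng):
        params = random_params(rng, "rsn")
        out = affine_transform(params, np.eye(2), np.eye(3))
        np.testing.assert_allclose(out.M, params.M)
        np.testing.assert_allclose(out.Sigma, params.Sigma)
        np.testing.assert_allclose(out.Psi, params.Psi)

    def test_sampling_check_moments(self, rng):
        params = random_params(rng, "exp1")
        B = rng.standard_normal((2, 2))
        D = rng.standard_normal((3, 2))
        out = affine_transform(params, B, D)
        direct = np.einsum(
            "qp,ipn,nm->iqm", B, mmn_sample(params, 100_000, seed=3).observations, D
        )
        trans = mmn_sample(out, 100_000, seed=4).observations
        se = np.sqrt(
            direct.var(axis=0) / direct.shape[0] + trans.var(axis=0) / trans.shape[0]
        )
        assert np.all(np.abs(direct.mean(axis=0) - trans.mean(axis=0)) < 5 * se)

    def test_scalar_transform_matches_1d_quadrature(self, rng):
        params = random_params(rng, "weib21")
        B = rng.standard_normal((1, 2))
        D = rng.standard_normal((3, 1))
        out = affine_transform(params, B, D)
        y = float((B @ params.M @ D).item()) + 0.4
        assert mmn_logpdf([[y]], out) == pytest.approx(
            mmn_logpdf_numeric([[y]], out), abs=1e-8
        )

    def test_full_axis_marginal_is_identity(self, rng):
        params = random_params(rng, "rsn")
        out = marginal_params(params, PartitionSpec(row_split=1), block="11")
        np.testing.assert_allclose(out.Psi, params.Psi)
        np.testing.assert_allclose(out.Sigma, params.Sigma[:1, :1])

    def test_marginal_matches_numeric_integration(self, rng):
        # 1x2 law, keep the first coordinate: the marginal density must equal
        # the joint integrated over the discarded coordinate
        params = random_params(rng, "rsn", p=1, n=2, lam_scale=0.7)
        marg = marginal_params(params, PartitionSpec(col_split=1), block="11")
        y1 = params.M[0, 0] + 0.4

        def joint(y2):
            return math.exp(mmn_logpdf(np.array([[y1, y2]]), params))

        hw = 10.0 * math.sqrt(params.Sigma[0, 0] * params.Psi[1, 1]) + 5.0
        val, _ = integrate.quad(
            joint, params.M[0, 1] - hw, params.M[0, 1] + hw, epsabs=1e-11, limit=300
        )
        assert mmn_logpdf([[y1]], marg) == pytest.approx(math.log(val), abs=1e-6)

    def test_marginal_of_marginal(self, rng):
        params = random_params(rng, "exp1", p=3, n=3)
        two = marginal_params(params, PartitionSpec(row_split=2), block="11")
        one_step = marginal_params(two, PartitionSpec(row_split=1), block="11")
        direct = marginal_params(params, PartitionSpec(row_split=1), block="11")
        np.testing.assert_allclose(one_step.Sigma, direct.Sigma)
        np.testing.assert_allclose(one_step.M, direct.M)

    def test_invalid_partitions_rejected(self, rng):
        params = random_params(rng, "rsn")
        with pytest.raises(ValueError):
            marginal_params(params, PartitionSpec())
        with pytest.raises(ValueError):
            marginal_params(params, PartitionSpec(row_split=2))  # p = 2


class TestConditional:
    def test_zero_skewness_schur_conditional(self, rng):
        params = random_params(rng, "rsn", p=3, n=2).replace(Lambda=np.zeros((3, 2)))
        part = PartitionSpec(row_split=1)
        Y1 = params.M[:1] + rng.standard_normal((1, 2))
        cond = conditional_params(params, part, Y1)
        S = params.Sigma
        reg = S[1:, :1] @ np.linalg.inv(S[:1, :1])
        np.testing.assert_allclose(cond.M, params.M[1:] + reg @ (Y1 - params.M[:1]))
        np.testing.assert_allclose(cond.Sigma, S[1:, 1:] - reg @ S[:1, 1:], atol=1e-12)
        np.testing.assert_allclose(cond.Lambda, 0.0, atol=1e-12)

    def test_conditional_mixing_prior_at_zero_marginal_skewness(self, rng):
        params = random_params(rng, "rsn", p=2, n=2)
        params = params.replace(Lambda=np.vstack([np.zeros((1, 2)),
                                                  params.Lambda[1:]]))
        cond = conditional_params(
            params, PartitionSpec(row_split=1), params.M[:1]
        )
        assert cond.mixing.family == "truncnorm"
        mu, sigma = cond.mixing.nu
        assert mu == pytest.approx(0.0, abs=1e-12)
        assert sigma == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("family", ["rsn", "exp1", "weib21"])
    def test_bayes_reconstruction(self, family, rng):
        # joint logpdf = marginal logpdf + conditional logpdf
        params = random_params(rng, family, p=2, n=2, lam_scale=0.7)
        part = PartitionSpec(row_split=1)
        Y = params.M + rng.standard_normal((2, 2))
        marg = marginal_params(params, part, block="11").replace(
            Psi=params.Psi, M=params.M[:1], Lambda=params.Lambda[:1]
        )
        cond = conditional_params(params, part, Y[:1])
        joint = mmn_logpdf(Y, params)
        split = mmn_logpdf(Y[:1], marg) + mmn_logpdf_numeric(Y[1:], cond)
        assert joint == pytest.approx(split, abs=1e-7)

    def test_column_conditioning_via_transpose(self, rng):
        params = random_params(rng, "rsn", p=2, n=3)
        Y = params.M + rng.standard_normal((2, 3))
        cond = conditional_params(params, PartitionSpec(col_split=1), Y[:, :1])
        assert cond.M.shape == (2, 2)
        # density of the remaining columns must reconstruct the joint
        row_marg = MMNParams(
            params.M[:, :1], params.Lambda[:, :1], params.Sigma,
            params.Psi[:1, :1], params.mixing,
        )
        joint = mmn_logpdf(Y, params)
        split = mmn_logpdf(Y[:, :1], row_marg) + mmn_logpdf_numeric(Y[:, 1:], cond)
        assert joint == pytest.approx(split, abs=1e-7)


class TestQuadraticForm:
    def test_inverse_psi_gives_unit_deltas(self, rng):
        params = random_params(rng, "rsn")
        spec = quadratic_form_spec(params, np.linalg.inv(params.Psi), w=1.0)
        np.testing.assert_allclose(spec.deltas, np.ones(3), atol=1e-10)

    def test_zero_matrix_gives_empty_decomposition(self, rng):
        params = random_params(rng, "exp1")
        spec = quadratic_form_spec(params, np.zeros((3, 3)), w=0.5)
        assert spec.deltas.size == 0

    def test_asymmetric_matrix_rejected(self, rng):
        params = random_params(rng, "rsn")
        A = np.triu(np.ones((3, 3)))
        with pytest.raises(ValueError, match="symmetric"):
            quadratic_form_spec(params, A, w=1.0)

    def test_monte_carlo_distributional_identity(self, rng):
        params = random_params(rng, "weib21", p=2, n=3)
        A = random_spd(rng, 3) - 2.0 * np.eye(3)  # symmetric, mixed sign
        report = quadratic_form_mc_check(params, A, w=1.0, n_draws=100_000, seed=17)
        assert report["agrees_4se"], report
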