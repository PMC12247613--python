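"""Forward-model correctness: Kärger kernel vs matrix-exponential oracle,
spherical-mean quadrature, Rician-mean transform vs Monte Carlo, nesting."""

import math

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.special import erf, hyp1f1

from nexikit import (ModelVariant, NoiseModel, TissueParameters,
                     connectom_protocol, exchange_validity_times,
                     karger_compartment_signal, laguerre_half, model_predict,
                     nexi_dot_powder_signal, nexi_powder_signal,
                     rician_mean_transform)
from nexikit.models import predict_batch

from conftest import random_params


def karger_expm_oracle(u, b, t_d, p):
    """Independent evaluation of 1ᵀ·exp(−M·t_d)·p₀ via scipy's generic
    matrix exponential."""
    q2 = b / t_d
    k_ie = (1 - p.f) / p.t_ex
    k_ei = p.f / p.t_ex
    M = np.array([[q2 * p.D_i * u * u + k_ie, -k_ei],
                  [-k_ie, q2 * p.D_e + k_ei]])
    return float(np.ones(2) @ expm(-M * t_d) @ np.array([p.f, 1 - p.f]))


class TestKargerKernel:
    def test_no_weighting_gives_unity(self):
        p = TissueParameters(40, 3, 1, 0.4)
        for u in (0.0, 0.3, 1.0):
            assert karger_compartment_signal(u, 0.0, 20.0, p) == pytest.approx(1.0)

    def test_empty_extra_pool_reduces_to_stick(self):
        # f → 1: single stick, S = exp(−b·D_i·u²)
        p = TissueParameters(50, 3, 1, 1 - 1e-12)
        got = karger_compartment_signal(0.5, 2.0, 20.0, p)
        assert got == pytest.approx(math.exp(-1.5), abs=1e-9)

    def test_matches_matrix_exponential_oracle(self, rng):
        # frozen spot check from the oracle
        p = TissueParameters(40, 3, 1, 0.4)
        assert karger_compartment_signal(0.7, 4.0, 29.0, p) == pytest.approx(
            karger_expm_oracle(0.7, 4.0, 29.0, p), abs=1e-12)
        # random sweep over the broad parameter box
        for q in random_params(rng, 1000):
            u = rng.uniform(0, 1)
            b = rng.uniform(0, 7.5)
            t_d = rng.uniform(20, 49)
            assert karger_compartment_signal(u, b, t_d, q) == pytest.approx(
                karger_expm_oracle(u, b, t_d, q), abs=1e-10)

    def test_infinite_exchange_time_decouples_pools(self):
        p = TissueParameters(1e6, 3, 1, 0.4)
        u, b, t_d = 0.6, 5.0, 30.0
        expected = (p.f * math.exp(-b * p.D_i * u * u)
                    + (1 - p.f) * math.exp(-b * p.D_e))
        assert karger_compartment_signal(u, b, t_d, p) == pytest.approx(
            expected, abs=1e-8)

    @pytest.mark.parametrize("bad", [dict(u=-0.1), dict(u=1.5),
                                     dict(b=-1.0), dict(t_d=0.0)])
    def test_domain_errors(self, bad):
        p = TissueParameters(40, 3, 1, 0.4)
        kw = dict(u=0.5, b=2.0, t_d=20.0)
        kw.update(bad)
        with pytest.raises(ValueError):
            karger_compartment_signal(kw["u"], kw["b"], kw["t_d"], p)

    def test_zero_exchange_time_rejected(self):
        with pytest.raises(ValueError):
            TissueParameters(0.0, 3, 1, 0.4)


class TestPowderSignal:
    def test_b0_is_exactly_one(self):
        p = TissueParameters(40, 3, 1, 0.4)
        assert nexi_powder_signal(p, 0.0, 20.0) == 1.0

    def test_stick_spherical_mean_closed_form(self):
        # f→1, t_ex→∞: S̄ = √(π/(4bD))·erf(√(bD)); bD = 9
        p = TissueParameters(1e9, 2.25, 1.0, 1 - 1e-12)
        expected = math.sqrt(math.pi) / (2 * 3) * erf(3.0)
        assert nexi_powder_signal(p, 4.0, 20.0) == pytest.approx(
            expected, abs=1e-9)

    def test_signal_decreases_with_diffusion_time(self, rng):
        # exchange signature: longer t_d → lower spherical mean
        for _ in range(50):
            p = TissueParameters(rng.uniform(1, 110), rng.uniform(2.5, 3.5),
                                 rng.uniform(0.5, 1.5), rng.uniform(0.3, 0.5))
            assert (nexi_powder_signal(p, 6.0, 49.0)
                    <= nexi_powder_signal(p, 6.0, 20.0) + 1e-12)

    def test_quadrature_converged_at_default_order(self, rng, protocol):
        b, t_d = protocol.shell_table()
        for p in random_params(rng, 25):
            lo = predict_batch(p.to_array()[None], b, t_d, quad_order=64)
            hi = predict_batch(p.to_array()[None], b, t_d, quad_order=501)
            assert np.abs(lo - hi).max() < 1e-9

    def test_low_quadrature_order_rejected(self):
        p = TissueParameters(40, 3, 1, 0.4)
        with pytest.raises(ValueError):
            nexi_powder_signal(p, 2.0, 20.0, quad_order=4)


class TestDotCompartment:
    def test_zero_dot_fraction_is_exact_nesting(self, rng):
        for p in random_params(rng, 20):
            assert nexi_dot_powder_signal(p, 5.0, 30.0) == pytest.approx(
                nexi_powder_signal(p, 5.0, 30.0), abs=1e-15)

    def test_b0_and_high_b_asymptote(self):
        # the exchanging part of the powder average decays ∝ b^{−1/2}
        # (stick tail), so the approach to f_dot follows that rate
        p = TissueParameters(40, 3, 1, 0.4, f_dot=0.03)
        assert nexi_dot_powder_signal(p, 0.0, 20.0) == pytest.approx(1.0)
        for b, tol in ((1e4, 5e-3), (1e6, 5e-4)):
            assert nexi_dot_powder_signal(p, b, 20.0) == pytest.approx(
                0.03, abs=tol)


class TestLaguerreHalf:
    def test_at_zero(self):
        assert laguerre_half(0.0) == pytest.approx(1.0)

    def test_matches_hypergeometric_series(self):
        # 200-term power series of ₁F₁(−1/2, 1, x)
        def series(x):
            total, term = 1.0, 1.0
            a, c = -0.5, 1.0
            for k in range(200):
                term *= (a + k) / (c + k) * x / (k + 1)
                total += term
            return total

        for x in (-8.0, -2.0, -0.5, 0.7):
            assert laguerre_half(x) == pytest.approx(series(x), abs=1e-10)

    def test_scipy_hyp1f1_cross_check(self):
        xs = np.array([-50.0, -8.0, -1.0, 0.0])
        assert np.allclose(laguerre_half(xs), hyp1f1(-0.5, 1, xs), atol=1e-10)

    def test_no_overflow_at_extreme_argument(self):
        v = laguerre_half(-1e8)
        assert np.isfinite(v)


class TestRicianMean:
    SIGMA = 0.03

    def mc_oracle(self, s, sigma, n=10_000_000, seed=7):
        rng = np.random.default_rng(seed)
        n1 = rng.normal(0, sigma, n)
        n2 = rng.normal(0, sigma, n)
        return np.sqrt((s + n1) ** 2 + n2 ** 2).mean()

    def test_floor_at_zero_signal(self):
        assert rician_mean_transform(0.0, self.SIGMA) == pytest.approx(
            math.sqrt(math.pi / 2) * self.SIGMA, rel=1e-12)

    def test_identity_regime_high_snr(self):
        out = rician_mean_transform(1.0, self.SIGMA)
        assert out == pytest.approx(1.00045, abs=5e-4)
        assert abs(out - 1.0) / 1.0 < 1e-3
        # asymptotic identity at SNR = 1000
        s = 1000 * self.SIGMA
        assert rician_mean_transform(s, self.SIGMA) / s == pytest.approx(
            1.0, abs=1e-5)

    @pytest.mark.parametrize("s", [0.03, 0.05, 0.3])
    def test_matches_monte_carlo(self, s):
        assert rician_mean_transform(s, self.SIGMA) == pytest.approx(
            self.mc_oracle(s, self.SIGMA), abs=1e-3)

    def test_bias_positive_decreasing_and_vanishing(self):
        s = np.linspace(0.0, 1.0, 200)
        bias = rician_mean_transform(s, self.SIGMA) - s
        assert np.all(bias >= 0)
        assert np.all(np.diff(bias) <= 1e-12)
        # high-SNR tail follows the σ²/(2S) law, hence vanishes ∝ 1/SNR²
        tail = s >= 20 * self.SIGMA
        assert np.allclose(bias[tail], self.SIGMA ** 2 / (2 * s[tail]),
                           rtol=0.01)
        sigma = 0.002
        s2 = np.linspace(20 * sigma, 1.0, 50)
        assert np.all(rician_mean_transform(s2, sigma) - s2 <= 1e-4)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            rician_mean_transform(0.5, 0.0)


class TestModelPredict:
    def test_shape_and_monotonicity(self, midpoint_d2, protocol):
        v = model_predict("nexi", midpoint_d2, protocol)
        assert v.shape == (20,)
        assert np.all((v > 0) & (v < 1))
        b, t_d = protocol.shell_table()
        for dd in np.unique(t_d):
            sel = t_d == dd
            assert np.all(np.diff(v[sel]) < 0)  # decreasing along b

    def test_rician_mean_dominates_noise_free(self, midpoint_d2, protocol):
        noise = NoiseModel(0.03)
        plain = model_predict("nexi", midpoint_d2, protocol)
        rm = model_predict("nexi_rm", midpoint_d2, protocol, noise)
        assert np.all(rm >= plain)

    def test_dot_variants_nest_at_zero_fdot(self, midpoint_d2, protocol):
        noise = NoiseModel(0.03)
        p0 = midpoint_d2.with_dot(0.0)
        assert np.abs(model_predict("nexi_dot", p0, protocol)
                      - model_predict("nexi", p0, protocol)).max() <= 1e-12
        assert np.abs(model_predict("nexi_dot_rm", p0, protocol, noise)
                      - model_predict("nexi_rm", p0, protocol, noise)
                      ).max() <= 1e-12

    def test_rm_requires_sigma(self, midpoint_d2, protocol):
        with pytest.raises(ValueError):
            model_predict("nexi_rm", midpoint_d2, protocol)

    def test_variant_bookkeeping(self):
        assert ModelVariant.parse("NEXI_dot,RM") is ModelVariant.NEXI_DOT_RM
        assert ModelVariant.NEXI.n_free_params == 4
        assert ModelVariant.NEXI_DOT_RM.n_free_params == 5
        assert not ModelVariant.NEXI_DOT.needs_sigma


class TestKernelImplementations:
    def test_compiled_and_reference_paths_agree(self, rng, protocol):
        # the numba kernel and the numpy reference implement identical
        # arithmetic, for both the signal and its analytic Jacobian
        from nexikit.models import (_HAVE_NUMBA, _gauss_legendre_01,
                                    _powder_batch_numba, _powder_batch_numpy,
                                    _powder_jac_numba, _powder_jac_numpy)
        if not _HAVE_NUMBA:
            pytest.skip("numba not installed; only the reference path exists")
        b, t_d = protocol.shell_table()
        nodes, weights = _gauss_legendre_01(64)
        params = np.column_stack([
            rng.uniform(1, 150, 30), rng.uniform(0.1, 3.5, 30),
            rng.uniform(0.1, 3.5, 30), rng.uniform(0.1, 0.9, 30),
            rng.uniform(0, 0.3, 30)])
        s_nb = _powder_batch_numba(params, b, t_d, nodes, weights)
        s_np = _powder_batch_numpy(params, b, t_d, nodes, weights)
        assert np.abs(s_nb - s_np).max() < 1e-13
        sj_nb, j_nb = _powder_jac_numba(params, b, t_d, nodes, weights)
        sj_np, j_np = _powder_jac_numpy(params, b, t_d, nodes, weights)
        assert np.abs(sj_nb - sj_np).max() < 1e-13
        assert np.abs(j_nb - j_np).max() < 1e-12

    def test_analytic_jacobian_matches_finite_differences(self, rng,
                                                          protocol):
        from nexikit.models import predict_batch_with_jacobian
        b, t_d = protocol.shell_table()
        params = np.column_stack([
            rng.uniform(5, 140, 10), rng.uniform(0.3, 3.4, 10),
            rng.uniform(0.3, 3.4, 10), rng.uniform(0.15, 0.85, 10),
            rng.uniform(0.0, 0.25, 10)])
        for sigma in (None, 0.03):
            _, jac = predict_batch_with_jacobian(params, b, t_d, sigma=sigma)
            for k, scale in enumerate((150.0, 1.0, 1.0, 1.0, 1.0)):
                h = 1e-6 * scale
                pp, pm = params.copy(), params.copy()
                pp[:, k] += h
                pm[:, k] -= h
                fd = (predict_batch(pp, b, t_d, sigma=sigma)
                      - predict_batch(pm, b, t_d, sigma=sigma)) / (2 * h)
                assert np.abs(jac[:, :, k] - fd).max() < 1e-7


class TestValidityTimes:
    def test_intra_neurite_quarter_millisecond(self):
        # d = 1 µm, D_i = 2 µm²/ms → 0.25 ms
        p = TissueParameters(40, 2.0, 0.7, 0.3)
        t_ci, _ = exchange_validity_times(1.0, p)
        assert t_ci == pytest.approx(0.25)

    def test_scaling_laws(self):
        p1 = TissueParameters(40, 1.0, 0.7, 0.3)
        p2 = TissueParameters(40, 2.0, 0.7, 0.3)
        assert exchange_validity_times(1.0, p1)[0] == pytest.approx(0.5)
        assert exchange_validity_times(2.0, p2)[0] == pytest.approx(1.0)

    def test_extra_neurite_order_of_magnitude(self):
        # the convention chosen reproduces ≈7.5 ms for cortical values
        p = TissueParameters(40, 2.0, 0.7, 0.3)
        _, t_ce = exchange_validity_times(1.0, p)
        assert t_ce == pytest.approx(7.5, rel=0.01)
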