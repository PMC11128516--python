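"""Homodyned-K theory, lookup table, and XU parameter recovery.

Independent oracles: closed-form K-limit moments recomputed by adaptive
quadrature over the compound (gamma x exponential) representation, and a
Monte-Carlo oracle drawn with the envelope sampler.
"""

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import expon, gamma as gamma_dist

import qusmap as q
from qusmap.homodyned_k import EULER_GAMMA, EstimationError, _gamma_matching_x


def k_limit_oracle(alpha):
    """X/U for the K distribution (gamma-mixed exponential intensity) by
    direct numerical integration, independent of the implementation."""
    # I = w * e with w ~ Gamma(alpha, 1), e ~ Exp(1), so the log-moments
    # separate into 1-D integrals against the two densities.
    e_ln_w = integrate.quad(
        lambda w: np.log(w) * gamma_dist.pdf(w, alpha), 0, np.inf, limit=200
    )[0]
    e_w_ln_w = integrate.quad(
        lambda w: w * np.log(w) * gamma_dist.pdf(w, alpha), 0, np.inf, limit=200
    )[0]
    e_ln_e = integrate.quad(lambda e: np.log(e) * expon.pdf(e), 0, np.inf, limit=200)[0]
    e_e_ln_e = integrate.quad(
        lambda e: e * np.log(e) * expon.pdf(e), 0, np.inf, limit=200
    )[0]
    mu = alpha  # E[w] * E[e]
    mean_ln_i = e_ln_w + e_ln_e
    mean_i_ln_i = e_w_ln_w * 1.0 + alpha * e_e_ln_e
    return mean_i_ln_i / mu - mean_ln_i, np.log(mu) - mean_ln_i


class TestXUSampleStatistics:
    def test_constant_samples_have_zero_log_moments(self):
        st = q.xu_sample_statistics(np.full(100, 3.7))
        assert st.X == pytest.approx(0.0, abs=1e-12)
        assert st.U == pytest.approx(0.0, abs=1e-12)

    def test_two_point_hand_arithmetic(self):
        # A = {1, sqrt(e)} => I = {1, e}
        st = q.xu_sample_statistics([1.0, np.exp(0.5)])
        e = np.e
        assert st.X == pytest.approx(e / (1 + e) - 0.5, abs=1e-12)
        assert st.U == pytest.approx(np.log((1 + e) / 2) - 0.5, abs=1e-12)

    def test_rayleigh_limits(self):
        a = q.sample_hk_envelope(0.0, 2**-0.5, 5000.0, 10**6, seed=8)
        st = q.xu_sample_statistics(a)
        assert st.X == pytest.approx(1.0, abs=0.01)
        assert st.U == pytest.approx(EULER_GAMMA, abs=0.01)

    def test_scale_invariance(self):
        a = q.sample_hk_envelope(1.0, 0.5, 4.0, 20_000, seed=2)
        st1 = q.xu_sample_statistics(a)
        for c in (1e-3, 0.1, 17.0, 1e4):
            st2 = q.xu_sample_statistics(c * a)
            assert st2.X == pytest.approx(st1.X, rel=1e-9)
            assert st2.U == pytest.approx(st1.U, rel=1e-9)
            assert st2.mu == pytest.approx(c**2 * st1.mu, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(EstimationError):
            q.xu_sample_statistics(np.zeros(100))
        with pytest.raises(EstimationError):
            q.xu_sample_statistics([1.0, -1.0])
        with pytest.raises(EstimationError):
            q.xu_sample_statistics([1.0])
        with pytest.raises(EstimationError):  # too many zeros
            q.xu_sample_statistics(np.r_[np.zeros(10), np.ones(90)])


class TestTheoreticalLogMoments:
    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0, 5.0, 10.0, 40.0])
    def test_k_limit_matches_independent_quadrature_oracle(self, alpha):
        x, u = q.hk_theoretical_log_moments(alpha, 0.0)
        x_ref, u_ref = k_limit_oracle(alpha)
        assert x == pytest.approx(x_ref, abs=1e-6)
        assert u == pytest.approx(u_ref, abs=1e-6)

    def test_k_limit_closed_forms(self):
        from scipy.special import psi

        x, u = q.hk_theoretical_log_moments(1.0, 0.0)
        assert x == pytest.approx(2.0, abs=1e-12)
        assert u == pytest.approx(2 * EULER_GAMMA, abs=1e-12)
        x, u = q.hk_theoretical_log_moments(40.5, 0.0)
        assert x == pytest.approx(1 + 1 / 40.5, abs=1e-12)
        assert u == pytest.approx(EULER_GAMMA + np.log(40.5) - psi(40.5), abs=1e-12)

    def test_rayleigh_limit_large_alpha(self):
        x, u = q.hk_theoretical_log_moments(1e6, 0.0)
        assert x == pytest.approx(1.0, abs=1e-5)
        assert u == pytest.approx(EULER_GAMMA, abs=1e-5)

    def test_monte_carlo_oracle_alpha5_gamma1(self):
        x, u = q.hk_theoretical_log_moments(5.0, 1.0)
        # sigma^2 = 0.5 => eps = sqrt(2 sigma^2 gamma) = 1
        a = q.sample_hk_envelope(1.0, 2**-0.5, 5.0, 4_000_000, seed=99)
        st = q.xu_sample_statistics(a)
        assert x == pytest.approx(st.X, abs=2.5e-3)  # ~3 Monte-Carlo SEs
        assert u == pytest.approx(st.U, abs=2.5e-3)

    def test_invalid_parameters(self):
        with pytest.raises(q.ParameterError):
            q.hk_theoretical_log_moments(0.0, 1.0)
        with pytest.raises(q.ParameterError):
            q.hk_theoretical_log_moments(1.0, -1.0)


class TestLookupTable:
    def test_grid_node_round_trip(self, hk_table):
        for i in (0, 50, 199):
            for j in (0, 17, 120):
                a = hk_table.alpha_grid[i]
                g = hk_table.gamma_grid[j]
                x, u = hk_table.xu_at(a, g)
                assert x == pytest.approx(hk_table.X[i, j], rel=1e-12)
                assert u == pytest.approx(hk_table.U[i, j], rel=1e-12)

    def test_between_node_query_close_to_direct(self, hk_table):
        for a, g in [(3.3, 0.77), (17.9, 4.4), (0.37, 1.9)]:
            x_i, u_i = hk_table.xu_at(a, g)
            x_d, u_d = q.hk_theoretical_log_moments(a, g)
            assert x_i == pytest.approx(x_d, abs=1e-3)
            assert u_i == pytest.approx(u_d, abs=1e-3)

    def test_k_limit_column(self, hk_table):
        from scipy.special import psi

        alphas = hk_table.alpha_grid
        np.testing.assert_allclose(hk_table.X[:, 0], 1 + 1 / alphas, atol=1e-12)
        np.testing.assert_allclose(
            hk_table.U[:, 0], EULER_GAMMA + np.log(alphas) - psi(alphas), atol=1e-12
        )

    def test_x_and_u_strictly_decreasing_in_gamma(self, hk_table):
        assert np.all(np.diff(hk_table.X, axis=1) < 0)
        assert np.all(np.diff(hk_table.U, axis=1) < 0)

    def test_save_load_round_trip(self, hk_table, tmp_path):
        path = tmp_path / "table.npz"
        hk_table.save(path)
        back = q.HKTheoryTable.load(path)
        np.testing.assert_array_equal(back.X, hk_table.X)
        np.testing.assert_array_equal(back.alpha_grid, hk_table.alpha_grid)

    def test_invalid_grids_rejected(self):
        with pytest.raises(q.ParameterError):
            q.build_hk_lookup_table(alpha_grid=[1.0, 0.5])
        with pytest.raises(q.ParameterError):
            q.build_hk_lookup_table(alpha_grid=[1.0, 50.0])


class TestHKEstimation:
    def test_sampler_round_trip(self, hk_table):
        a = q.sample_hk_envelope(1.0, 0.5, 4.0, 100_000, seed=7)
        p = q.hk_xu_estimate(a, table=hk_table)
        assert p.alpha == pytest.approx(4.0, rel=0.20)
        assert p.mu == pytest.approx(3.0, rel=0.01)
        assert not p.clamped

    def test_rayleigh_saturates_at_alpha_max(self, hk_table):
        a = q.sample_hk_envelope(0.0, 2**-0.5, 5000.0, 10**6, seed=1)
        p = q.hk_xu_estimate(a, table=hk_table)
        assert p.alpha == pytest.approx(40.5, abs=1e-9)
        assert p.clamped

    def test_mean_intensity_identity_exact(self, hk_table, rng):
        for seed in range(5):
            a = q.sample_hk_envelope(0.8, 0.6, 3.0, 5000, seed=seed)
            p = q.hk_xu_estimate(a, table=hk_table)
            mu_reconstructed = p.epsilon**2 + 2 * p.alpha * p.sigma2
            assert mu_reconstructed == pytest.approx(np.mean(a**2), rel=1e-9)
            assert p.k == pytest.approx(p.epsilon / np.sqrt(p.sigma2 * p.alpha), rel=1e-12)
            assert p.gamma == pytest.approx(p.epsilon**2 / (2 * p.sigma2), rel=1e-9)

    def test_near_constant_samples_have_no_hk_solution(self, hk_table, rng):
        a = 1.0 + 1e-9 * rng.standard_normal(1000)
        with pytest.raises(EstimationError):
            q.hk_xu_estimate(a, table=hk_table)

    def test_parameter_recovery_median_error(self, hk_table):
        """Median relative alpha error <= 25% over a (alpha, gamma) sweep."""
        rel_errors = []
        for alpha in (2.0, 5.0, 10.0):
            for gamma in (0.0, 0.5, 2.0):
                eps = np.sqrt(gamma)  # sigma^2 = 0.5
                a = q.sample_hk_envelope(
                    max(eps, 0.0), 2**-0.5, alpha, 100_000,
                    seed=int(1000 * alpha + 100 * gamma),
                )
                p = q.hk_xu_estimate(a, table=hk_table)
                rel_errors.append(abs(p.alpha - alpha) / alpha)
        assert np.median(rel_errors) <= 0.25

    def test_gamma_matching_is_inverse_of_x(self, hk_table):
        x_row, _ = hk_table.rows_at(5.0)
        # any X inside the row's attainable range must invert exactly
        lo, hi = x_row[-1], x_row[0]
        for frac in (0.1, 0.5, 0.9):
            x_target = lo + frac * (hi - lo)
            g = _gamma_matching_x(hk_table, x_row, x_target)
            x_back = hk_table.xu_at(5.0, g)[0]
            assert x_back == pytest.approx(x_target, abs=1e-9)
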