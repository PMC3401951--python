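"""Tests for the three-component von Mises mixture model and its EM fitter."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize

from tests.conftest import make_geometries, simulate_dataset
from vwmprecision.mixture import (
    FitConfig,
    InvalidParamsError,
    MixtureParams,
    TrialGeometry,
    fit_em,
    grid_oracle_fit,
    kappa_from_circular_sd,
    mixture_loglik,
    simulate_responses,
    vonmises_density,
)

TWO_PI = 2 * math.pi


def bessel_i0_series(kappa, terms=80):
    """Modified Bessel I0 by direct series summation (independent oracle)."""
    return sum((kappa / 2.0) ** (2 * k) / math.factorial(k) ** 2 for k in range(terms))


# ---------------------------------------------------------------------------
# parameters and density

class TestMixtureParams:
    def test_valid(self):
        p = MixtureParams(5.0, 0.8, 0.1, 0.1)
        assert p.p_target + p.p_nontarget + p.p_uniform == pytest.approx(1.0)

    def test_simplex_violations(self):
        with pytest.raises(InvalidParamsError):
            MixtureParams(5.0, 0.8, 0.1, 0.2)
        with pytest.raises(InvalidParamsError):
            MixtureParams(5.0, 1.2, -0.1, -0.1)

    def test_kappa_bounds(self):
        with pytest.raises(InvalidParamsError):
            MixtureParams(-1.0, 0.5, 0.25, 0.25)
        with pytest.raises(InvalidParamsError):
            MixtureParams(701.0, 0.5, 0.25, 0.25)


class TestVonMisesDensity:
    def test_uniform_limit(self):
        assert vonmises_density(1.234, 0.0, 0.0) == pytest.approx(1 / TWO_PI, rel=1e-12)

    def test_peak_value_bessel_oracle(self):
        # density at x=mu with kappa=2 is e^2 / (2 pi I0(2))
        expected = math.exp(2.0) / (TWO_PI * bessel_i0_series(2.0))
        assert vonmises_density(0.7, 0.7, 2.0) == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("kappa", [0.5, 5.0, 50.0])
    def test_normalization(self, kappa):
        x = np.linspace(0.0, TWO_PI, 20_001)
        integral = np.trapezoid(vonmises_density(x, 1.0, kappa), x)
        assert integral == pytest.approx(1.0, abs=1e-6)

    def test_overflow_guard(self):
        with pytest.raises(InvalidParamsError):
            vonmises_density(0.0, 0.0, 701.0)
        with pytest.raises(InvalidParamsError):
            vonmises_density(0.0, 0.0, -1.0)

    def test_kappa_from_circular_sd_inverts_bessel_ratio(self):
        from scipy.special import i0e, i1e

        for sd in (0.1, 0.3, 0.8, 1.5):
            k = kappa_from_circular_sd(sd)
            assert i1e(k) / i0e(k) == pytest.approx(math.exp(-0.5 * sd * sd), abs=1e-8)


# ---------------------------------------------------------------------------
# log-likelihood

class TestMixtureLoglik:
    def test_pure_uniform_single_trial(self):
        trial = TrialGeometry(0.5, (1.0, 2.0), 3.0)
        params = MixtureParams(1.0, 0.0, 0.0, 1.0)
        assert mixture_loglik([trial], params) == pytest.approx(math.log(1 / TWO_PI), rel=1e-12)

    def test_all_target_peak(self):
        trial = TrialGeometry(0.5, (1.0, 2.0), 0.5)
        params = MixtureParams(2.0, 1.0, 0.0, 0.0)
        expected = math.log(math.exp(2.0) / (TWO_PI * bessel_i0_series(2.0)))
        assert mixture_loglik([trial], params) == pytest.approx(expected, rel=1e-10)

    def test_permutation_invariance(self):
        params = MixtureParams(4.0, 0.7, 0.2, 0.1)
        trials = simulate_dataset(params, 50, seed=3)
        rng = np.random.default_rng(0)
        shuffled = [trials[i] for i in rng.permutation(len(trials))]
        assert mixture_loglik(shuffled, params) == pytest.approx(
            mixture_loglik(trials, params), rel=1e-12
        )

    def test_beta_requires_nontargets(self):
        trial = TrialGeometry(0.5, (), 0.6)
        with pytest.raises(InvalidParamsError):
            mixture_loglik([trial], MixtureParams(2.0, 0.7, 0.2, 0.1))


# ---------------------------------------------------------------------------
# EM fitting

class TestFitEM:
    def test_parameter_recovery_n5000(self):
        true = MixtureParams(8.0, 0.8, 0.1, 0.1)
        trials = simulate_dataset(true, 5000, seed=42)
        fit = fit_em(trials, FitConfig())
        assert fit.converged
        assert abs(fit.params.p_target - true.p_target) <= 0.03
        assert abs(fit.params.p_nontarget - true.p_nontarget) <= 0.03
        assert abs(fit.params.p_uniform - true.p_uniform) <= 0.03
        assert abs(fit.params.kappa - true.kappa) / true.kappa <= 0.15

    def test_probabilities_always_simplex(self, fast_fit_config):
        for seed in range(5):
            true = MixtureParams(3.0 + seed, 0.7, 0.2, 0.1)
            fit = fit_em(simulate_dataset(true, 150, seed=seed), fast_fit_config)
            s = fit.params.p_target + fit.params.p_nontarget + fit.params.p_uniform
            assert abs(s - 1.0) <= 1e-10
            assert 0.0 <= fit.params.kappa <= 700.0

    def test_uniform_data_flags_kappa(self, fast_fit_config):
        # with gamma = 1 the weight split is not identifiable (a zero-kappa
        # von Mises is also uniform), but the fitted density must be the
        # uniform one and kappa must be flagged unidentifiable
        true = MixtureParams(5.0, 0.0, 0.0, 1.0)
        trials = simulate_dataset(true, 400, seed=9)
        fit = fit_em(trials, fast_fit_config)
        assert fit.log_likelihood == pytest.approx(
            400 * math.log(1 / TWO_PI), rel=0.01
        )
        assert not fit.kappa_identifiable

    def test_em_beats_grid_oracle(self, fast_fit_config):
        kappa_grid = np.linspace(1.0, 15.0, 15)
        alpha_grid = np.linspace(0.0, 1.0, 11)
        beta_grid = np.linspace(0.0, 0.4, 5)
        for seed in range(3):
            true = MixtureParams(6.0, 0.75, 0.15, 0.10)
            trials = simulate_dataset(true, 200, seed=100 + seed)
            em = fit_em(trials, fast_fit_config)
            oracle = grid_oracle_fit(trials, kappa_grid, alpha_grid, beta_grid)
            assert em.log_likelihood >= oracle.log_likelihood - 1e-9

    def test_m0_reduces_to_two_component(self, fast_fit_config):
        # one-item trials: direct 2-parameter ML fit must agree in loglik
        true = MixtureParams(6.0, 0.85, 0.0, 0.15)
        trials = simulate_dataset(true, 500, m=0, seed=11)
        em = fit_em(trials, fast_fit_config)
        d = np.array([t.response - t.target for t in trials])

        from scipy.special import i0e

        def negll(theta):
            kappa, alpha = theta
            vm = np.exp(kappa * (np.cos(d) - 1.0)) / (TWO_PI * i0e(kappa))
            return -np.log(alpha * vm + (1 - alpha) / TWO_PI).sum()

        res = minimize(
            negll, x0=[4.0, 0.8], bounds=[(1e-6, 100.0), (1e-6, 1.0)], method="L-BFGS-B"
        )
        assert em.params.p_nontarget == 0.0
        assert em.log_likelihood == pytest.approx(-res.fun, abs=1e-6)

    def test_min_trials_floor(self, fast_fit_config):
        trials = simulate_dataset(MixtureParams(5.0, 0.8, 0.1, 0.1), 10, seed=0)
        with pytest.raises(InvalidParamsError):
            fit_em(trials, fast_fit_config)

    def test_monotone_loglik_never_raises_over_seeds(self, fast_fit_config):
        # the fitter asserts non-decreasing log-likelihood internally; any
        # violation raises RuntimeError
        for seed in range(8):
            true = MixtureParams(1.0 + 2.0 * seed % 9, 0.6, 0.25, 0.15)
            fit_em(simulate_dataset(true, 120, seed=seed), fast_fit_config)


class TestGridOracle:
    def test_argmax_definition(self):
        true = MixtureParams(5.0, 0.8, 0.1, 0.1)
        trials = simulate_dataset(true, 100, seed=1)
        grid_k = [2.0, 5.0, 10.0]
        grid_a = [0.5, 0.8]
        grid_b = [0.0, 0.1]
        oracle = grid_oracle_fit(trials, grid_k, grid_a, grid_b)
        for k in grid_k:
            for a in grid_a:
                for b in grid_b:
                    p = MixtureParams(k, a, b, round(1 - a - b, 12))
                    assert oracle.log_likelihood >= mixture_loglik(trials, p) - 1e-12

    def test_single_point_grid(self):
        trials = simulate_dataset(MixtureParams(5.0, 0.8, 0.1, 0.1), 50, seed=2)
        oracle = grid_oracle_fit(trials, [3.0], [0.7], [0.1])
        assert oracle.params.kappa == 3.0
        assert oracle.params.p_target == 0.7

    def test_empty_grid(self):
        trials = simulate_dataset(MixtureParams(5.0, 0.8, 0.1, 0.1), 50, seed=2)
        with pytest.raises(InvalidParamsError):
            grid_oracle_fit(trials, [], [0.5])


# ---------------------------------------------------------------------------
# simulation

class TestSimulateResponses:
    def test_noiseless_limit(self):
        geoms = make_geometries(200, seed=0)
        out = simulate_responses(MixtureParams(700.0, 1.0, 0.0, 0.0), geoms, seed=1)
        err = np.array([
            (t.response - t.target + math.pi) % TWO_PI - math.pi for t in out
        ])
        assert np.abs(err).max() < 0.2

    def test_component_fractions(self):
        # fixed geometry: target at 0, non-targets at +/-2pi/3, so windows
        # of half-width pi/3 around the three items tile the circle; at
        # kappa = 50 (SD ~ 0.14 rad) component spill across windows is
        # negligible and uniform mass splits 1/3 per window
        alpha, beta, gamma = 0.6, 0.25, 0.15
        params = MixtureParams(50.0, alpha, beta, gamma)
        n = 100_000
        geoms = [TrialGeometry(0.0, (TWO_PI / 3, 2 * TWO_PI / 3))] * n
        out = simulate_responses(params, geoms, seed=6)
        resp = np.array([t.response for t in out])
        d_t = np.abs((resp + math.pi) % TWO_PI - math.pi)
        in_target = d_t < math.pi / 3
        p_t_expected = alpha + gamma / 3
        se = math.sqrt(p_t_expected * (1 - p_t_expected) / n)
        assert abs(in_target.mean() - p_t_expected) < 3 * se
        p_nt_expected = beta + 2 * gamma / 3
        se_nt = math.sqrt(p_nt_expected * (1 - p_nt_expected) / n)
        assert abs((~in_target).mean() - p_nt_expected) < 3 * se_nt

    def test_uniform_rayleigh(self):
        import pingouin as pg

        params = MixtureParams(5.0, 0.0, 0.0, 1.0)
        non_sig = 0
        runs = 100
        for seed in range(runs):
            out = simulate_responses(params, make_geometries(400, seed=seed), seed=seed)
            resp = np.array([t.response for t in out])
            _, p = pg.circ_rayleigh(resp)
            non_sig += p > 0.01
        assert non_sig >= 95

    def test_deterministic(self):
        params = MixtureParams(5.0, 0.7, 0.2, 0.1)
        geoms = make_geometries(50, seed=3)
        a = simulate_responses(params, geoms, seed=9)
        b = simulate_responses(params, geoms, seed=9)
        assert [t.response for t in a] == [t.response for t in b]

    def test_rejects_responses_present(self):
        params = MixtureParams(5.0, 0.7, 0.2, 0.1)
        out = simulate_responses(params, make_geometries(5, seed=0), seed=0)
        with pytest.raises(InvalidParamsError):
            simulate_responses(params, out, seed=0)
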