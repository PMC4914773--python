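import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import lognorm

from mekerk.population import (
    HyperParams,
    lognormal_from_log_moments,
    moment_match_lognormal,
    population_observables,
    population_simulate,
    sample_cell_parameters,
    total_variance,
    ut_propagate,
)
from mekerk.stochastic import lna_moments


class TestMomentMatch:
    def test_degenerate_point_mass(self):
        assert moment_match_lognormal(1.0, 0.0) == (0.0, 0.0)

    def test_standard_lognormal(self):
        m = math.exp(0.5)
        v = (math.e - 1) * math.e
        mu, s2 = moment_match_lognormal(m, v)
        assert mu == pytest.approx(0.0, abs=1e-12)
        assert s2 == pytest.approx(1.0, abs=1e-12)

    def test_against_numerical_integration(self):
        # independent density oracle: integrate the matched log-normal pdf
        m, v = 2.5, 1.3
        mu, s2 = moment_match_lognormal(m, v)
        dist = lognorm(s=math.sqrt(s2), scale=math.exp(mu))
        mean_num = quad(lambda x: x * dist.pdf(x), 0, np.inf)[0]
        ex2_num = quad(lambda x: x * x * dist.pdf(x), 0, np.inf)[0]
        assert mean_num == pytest.approx(m, rel=1e-8)
        assert ex2_num - mean_num**2 == pytest.approx(v, rel=1e-6)

    @settings(max_examples=100, deadline=None)
    @given(
        m=st.floats(1e-3, 1e3),
        cv=st.floats(0.0, 3.0),
    )
    def test_round_trip(self, m, cv):
        v = (cv * m) ** 2
        mu, s2 = moment_match_lognormal(m, v)
        m2, v2 = lognormal_from_log_moments(mu, s2)
        assert m2 == pytest.approx(m, rel=1e-12)
        assert v2 == pytest.approx(v, rel=1e-9, abs=1e-300)

    def test_rejects_nonpositive_mean(self):
        with pytest.raises(ValueError):
            moment_match_lognormal(0.0, 1.0)
        with pytest.raises(ValueError):
            moment_match_lognormal(1.0, -1.0)


class TestHyperParams:
    def test_from_mean_cv(self, dist_model):
        hyper = HyperParams.from_mean_cv(
            dist_model.param_names,
            {n: 1.0 for n in dist_model.param_names},
            {"k1": 0.5},
        )
        i = hyper.index("k1")
        assert hyper.varies[i]
        assert hyper.var[i] == pytest.approx(0.25)
        assert hyper.varies.sum() == 1

    def test_var_without_varies_rejected(self, dist_model):
        names = dist_model.param_names
        mean = np.ones(len(names))
        var = np.zeros(len(names))
        var[0] = 0.1
        with pytest.raises(ValueError):
            HyperParams(names, mean, var, np.zeros(len(names), dtype=bool))

    def test_restrict_to(self, fixture_ex):
        sub = fixture_ex.hyper.restrict_to(("k1",))
        assert sub.varies.sum() == 1
        assert sub.var[sub.index("k2")] == 0.0
        np.testing.assert_array_equal(sub.mean, fixture_ex.hyper.mean)


class TestSampling:
    def test_zero_variance_identical_rows(self, fixture_ex):
        hyper = fixture_ex.hyper.restrict_to(())
        cells = sample_cell_parameters(hyper, 10, seed=0)
        assert np.all(cells.values == hyper.mean)

    def test_means_match_clt(self, fixture_ex):
        n = 100_000
        cells = sample_cell_parameters(fixture_ex.hyper, n, seed=1)
        hyper = fixture_ex.hyper
        for j in np.flatnonzero(hyper.varies):
            # Epp0 is clipped at E_tot; with Epp0 << E_tot the effect is nil
            se = math.sqrt(hyper.var[j] / n)
            assert abs(cells.values[:, j].mean() - hyper.mean[j]) < 3 * se

    def test_cross_parameter_independence(self, fixture_ex):
        cells = sample_cell_parameters(fixture_ex.hyper, 100_000, seed=2)
        vary = np.flatnonzero(fixture_ex.hyper.varies)
        r = np.corrcoef(cells.values[:, vary].T)
        off = r[~np.eye(len(vary), dtype=bool)]
        assert np.max(np.abs(off)) < 0.02

    def test_log_is_gaussian(self, fixture_ex):
        from scipy.stats import skew

        cells = sample_cell_parameters(fixture_ex.hyper, 100_000, seed=3)
        j = fixture_ex.hyper.index("k1")
        assert abs(skew(np.log(cells.values[:, j]))) < 0.05

    def test_rows_are_valid_parameterizations(self, fixture_ex):
        cells = sample_cell_parameters(fixture_ex.hyper, 50, seed=4)
        for i in range(cells.n_cells):
            cells.row(i)  # raises on invalid


class TestUnscentedTransform:
    def test_degenerate_variance(self, dist_model, fixture_ex, times26):
        from mekerk.models import solve_ode

        hyper = fixture_ex.hyper.restrict_to(())
        mom = ut_propagate(dist_model, hyper, times26, rtol=1e-9, atol=1e-11)
        traj = solve_ode(dist_model, fixture_ex.theta, times26,
                         rtol=1e-9, atol=1e-11)
        np.testing.assert_allclose(mom.mean, traj.observables, rtol=1e-6,
                                   atol=1e-12)
        assert np.all(mom.var == 0.0)

    def test_identity_map_matches_lognormal_moments(self, fixture_ex):
        # The sigma points match the log-space Gaussian exactly, so through
        # the identity map the natural-scale log-normal moments are
        # recovered up to O(CV^2) relative error: 1e-6 precision is reached
        # in the small-CV regime (verified against the closed forms).
        def run(cv):
            hyper = HyperParams.from_mean_cv(
                fixture_ex.hyper.param_names,
                dict(zip(fixture_ex.hyper.param_names, fixture_ex.hyper.mean)),
                {"k1": cv, "k2": cv, "k10": cv},
            )
            vary = np.flatnonzero(hyper.varies)

            def identity(theta):
                return np.array(
                    [theta[hyper.param_names[j]] for j in vary]
                )[None, :]

            mom = ut_propagate(None, hyper, np.array([0.0]), transform=identity)
            return hyper, vary, mom

        hyper, vary, mom = run(1e-3)
        np.testing.assert_allclose(mom.mean[0], hyper.mean[vary], rtol=1e-6)
        np.testing.assert_allclose(mom.var[0], hyper.var[vary], rtol=1e-5)
        hyper, vary, mom = run(0.02)
        np.testing.assert_allclose(mom.mean[0], hyper.mean[vary], rtol=5e-4)
        np.testing.assert_allclose(mom.var[0], hyper.var[vary], rtol=2e-3)

    def test_log_space_moments_exact(self, fixture_ex):
        # in log space the UT weighted moments are exact for any CV
        hyper = HyperParams.from_mean_cv(
            fixture_ex.hyper.param_names,
            dict(zip(fixture_ex.hyper.param_names, fixture_ex.hyper.mean)),
            {"k1": 0.5, "k10": 0.3},
        )
        vary = np.flatnonzero(hyper.varies)

        def log_map(theta):
            return np.log(
                np.array([theta[hyper.param_names[j]] for j in vary])
            )[None, :]

        mom = ut_propagate(None, hyper, np.array([0.0]), transform=log_map)
        mu, s2 = hyper.log_moments()
        np.testing.assert_allclose(mom.mean[0], mu[vary], rtol=1e-12)
        np.testing.assert_allclose(mom.var[0], s2[vary], rtol=1e-10)

    def test_vs_monte_carlo_small_cv(self, dist_model, fixture_ex, times26):
        cv = {"k1": 0.05, "k2": 0.05, "k10": 0.05, "M0": 0.05, "Epp0": 0.05}
        hyper = HyperParams.from_mean_cv(
            fixture_ex.hyper.param_names,
            dict(zip(fixture_ex.hyper.param_names, fixture_ex.hyper.mean)),
            cv,
        )
        mom = ut_propagate(dist_model, hyper, times26)
        cells = sample_cell_parameters(hyper, 5000, seed=5)
        obs = population_observables(dist_model, cells, times26)
        mc_var = obs.var(axis=0, ddof=1)
        ratio = mom.var[1:] / mc_var[1:]
        assert np.all(ratio > 0.85) and np.all(ratio < 1.15)


class TestPopulationSimulate:
    def test_zero_variance_identical_cells(self, dist_model, fixture_ex):
        hyper = fixture_ex.hyper.restrict_to(())
        snap = population_simulate(dist_model, hyper, 5,
                                   np.array([0.0, 10.0]), seed=0)
        for t in snap.times:
            x, y = snap.at_time(t)
            assert np.ptp(x) == 0 and np.ptp(y) == 0

    def test_determinism_contract(self, dist_model, fixture_ex):
        times = np.array([0.0, 10.0])
        a = population_simulate(dist_model, fixture_ex.hyper, 8, times, seed=1)
        b = population_simulate(dist_model, fixture_ex.hyper, 8, times, seed=1)
        c = population_simulate(dist_model, fixture_ex.hyper, 8, times, seed=2)
        assert a.frame.equals(b.frame)
        assert not a.frame.equals(c.frame)

    def test_variance_tracks_ut(self, dist_model, fixture_ex):
        hyper = fixture_ex.hyper.restrict_to(("k1",)).with_variance(
            k1=(0.05 * 1.2) ** 2
        )
        times = np.array([0.0, 6.0, 20.0])
        snap = population_simulate(dist_model, hyper, 3000, times, seed=3)
        mom = ut_propagate(dist_model, hyper, times)
        for k, t in enumerate(times[1:], start=1):
            _, y = snap.at_time(t)
            assert y.var(ddof=1) == pytest.approx(mom.var[k, 1], rel=0.15)

    def test_measurement_noise_inflates_variance(self, dist_model, fixture_ex):
        hyper = fixture_ex.hyper.restrict_to(())
        clean = population_simulate(dist_model, hyper, 200,
                                    np.array([0.0, 10.0]), seed=4)
        noisy = population_simulate(dist_model, hyper, 200,
                                    np.array([0.0, 10.0]), seed=4,
                                    measurement_cv=0.2)
        _, y0 = clean.at_time(10.0)
        _, y1 = noisy.at_time(10.0)
        assert y0.var() < 1e-20
        assert y1.std() / y1.mean() == pytest.approx(0.2, rel=0.35)


class TestTotalVariance:
    def test_zero_extrinsic_reduces_to_lna(self, dist_model, fixture_ex, times26):
        hyper = fixture_ex.hyper.restrict_to(())
        tv = total_variance(dist_model, hyper, 100.0, times26, n_outer=10,
                            seed=0, rtol=1e-8, atol=1e-10)
        mom = lna_moments(dist_model, fixture_ex.theta, 100.0, times26,
                          rtol=1e-8, atol=1e-10)
        obs = mom.observable_moments(dist_model)
        np.testing.assert_allclose(tv.total, obs.var, rtol=1e-6, atol=1e-14)
        assert np.all(tv.var_of_means == 0)

    def test_large_omega_converges_to_extrinsic(self, dist_model, fixture_ex,
                                                times26):
        n = 400
        tv = total_variance(dist_model, fixture_ex.hyper, 1e8, times26,
                            n_outer=n, seed=9)
        cells = sample_cell_parameters(fixture_ex.hyper, n, seed=9)
        obs = population_observables(dist_model, cells, times26)
        ext_var = obs.var(axis=0, ddof=1)
        np.testing.assert_allclose(tv.total[1:], ext_var[1:], rtol=0.05)

    def test_decomposition_nonnegative(self, dist_model, fixture_ex, times26):
        tv = total_variance(dist_model, fixture_ex.hyper, 100.0, times26,
                            n_outer=50, seed=2)
        assert np.all(tv.mean_intrinsic_var >= 0)
        assert np.all(tv.var_of_means >= 0)
        np.testing.assert_allclose(
            tv.total, tv.mean_intrinsic_var + tv.var_of_means
        )
        assert np.all(tv.total >= tv.var_of_means)
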