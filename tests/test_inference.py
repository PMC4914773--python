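import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, lognorm, multivariate_normal, norm

from mekerk.inference import (
    EvidenceResult,
    Prior,
    PriorComponent,
    VERY_STRONG_BF,
    bayes_factor,
    centered_log_uniform,
    loglik_average,
    loglik_extrinsic,
    loglik_intrinsic,
    make_average_loglik,
    make_extrinsic_loglik,
    smc_sample,
)
from mekerk.models import solve_ode
from mekerk.population import (
    SnapshotData,
    moment_match_lognormal,
    ut_propagate,
)
from mekerk.stochastic import lna_moments


def snapshot_from_arrays(times, xs, ys):
    rows = []
    cid = 0
    for t, x, y in zip(times, xs, ys):
        for xi, yi in zip(np.atleast_1d(x), np.atleast_1d(y)):
            rows.append((t, cid, xi, yi))
            cid += 1
    return SnapshotData(
        frame=pd.DataFrame(rows, columns=["time_min", "cell_id", "ppMEK", "ppERK"])
    )


class TestLoglikAverage:
    def test_zero_residuals_26_points(self, dist_model, theta_ref, times26):
        traj = solve_ode(dist_model, theta_ref, times26, rtol=1e-7, atol=1e-9)
        avg = pd.DataFrame(
            {"time_min": times26, "ppMEK": traj.ppmek, "ppERK": traj.pperk}
        )
        ll = loglik_average(dist_model, theta_ref, 1.0, avg)
        assert ll == pytest.approx(-26.0 * math.log(2 * math.pi), rel=1e-6)

    def test_residual_doubling_quadratic_form(self, dist_model, theta_ref, times26):
        # build residuals relative to the solution at the likelihood's own
        # solver tolerance so the quadratic-form identity is exact
        traj = solve_ode(dist_model, theta_ref, times26, rtol=1e-7, atol=1e-9)
        r = 0.1
        v = 2.0
        avg1 = pd.DataFrame(
            {"time_min": times26, "ppMEK": traj.ppmek + r, "ppERK": traj.pperk + r}
        )
        avg2 = pd.DataFrame(
            {"time_min": times26, "ppMEK": traj.ppmek + 2 * r,
             "ppERK": traj.pperk + 2 * r}
        )
        ll1 = loglik_average(dist_model, theta_ref, v, avg1)
        ll2 = loglik_average(dist_model, theta_ref, v, avg2)
        ssq = 2 * 26 * r**2  # sum of squared original residuals
        assert ll1 - ll2 == pytest.approx(3 * ssq / (2 * v), rel=1e-6)

    def test_naive_loop_oracle(self, dist_model, theta_ref, times26):
        rng = np.random.default_rng(0)
        traj = solve_ode(dist_model, theta_ref, times26, rtol=1e-7, atol=1e-9)
        avg = pd.DataFrame(
            {
                "time_min": times26,
                "ppMEK": traj.ppmek + rng.normal(0, 0.1, times26.size),
                "ppERK": traj.pperk + rng.normal(0, 0.1, times26.size),
            }
        )
        v = 0.3
        ll = loglik_average(dist_model, theta_ref, v, avg)
        naive = sum(
            norm.logpdf(avg["ppMEK"][k], traj.ppmek[k], math.sqrt(v))
            + norm.logpdf(avg["ppERK"][k], traj.pperk[k], math.sqrt(v))
            for k in range(times26.size)
        )
        assert ll == pytest.approx(naive, abs=1e-10)

    def test_invalid_variance(self, dist_model, theta_ref, times26):
        avg = pd.DataFrame(
            {"time_min": times26, "ppMEK": np.ones(26), "ppERK": np.ones(26)}
        )
        with pytest.raises(ValueError):
            loglik_average(dist_model, theta_ref, 0.0, avg)

    def test_builder_matches_direct(self, dist_model, theta_ref, times26):
        traj = solve_ode(dist_model, theta_ref, times26)
        avg = pd.DataFrame(
            {"time_min": times26, "ppMEK": traj.ppmek, "ppERK": traj.pperk}
        )
        names, ll = make_average_loglik(dist_model, avg)
        assert names[-1] == "v"
        vec = np.append(theta_ref.as_array(), 1.0)
        assert ll(vec) == pytest.approx(
            loglik_average(dist_model, theta_ref, 1.0, avg), rel=1e-12
        )


class TestLoglikIntrinsic:
    def test_single_cell_at_mean(self, dist_model, theta_ref):
        omega = 100.0
        t = 2.0
        mom = lna_moments(dist_model, theta_ref, omega, np.array([0.0, t]))
        obs = mom.observable_moments(dist_model)
        mx, my = obs.mean[1]
        vx, vy = obs.var[1]
        snap = snapshot_from_arrays([t], [mx], [my])
        ll = loglik_intrinsic(dist_model, theta_ref, omega, snap)
        expected = -0.5 * math.log(2 * math.pi * vx) - 0.5 * math.log(
            2 * math.pi * vy
        )
        assert ll == pytest.approx(expected, rel=1e-6)

    def test_permutation_invariance(self, dist_model, theta_ref):
        rng = np.random.default_rng(1)
        t = 4.0
        x = rng.uniform(1, 3, 20)
        y = rng.uniform(1, 3, 20)
        a = loglik_intrinsic(
            dist_model, theta_ref, 50.0, snapshot_from_arrays([t], [x], [y])
        )
        p = rng.permutation(20)
        b = loglik_intrinsic(
            dist_model, theta_ref, 50.0, snapshot_from_arrays([t], [x[p]], [y[p]])
        )
        assert a == pytest.approx(b, rel=1e-12)

    def test_naive_double_loop_oracle(self, dist_model, theta_ref):
        rng = np.random.default_rng(2)
        omega = 80.0
        times = [2.0, 10.0, 30.0]
        xs = [rng.uniform(1, 3, 5) for _ in times]
        ys = [rng.uniform(0.5, 2, 5) for _ in times]
        snap = snapshot_from_arrays(times, xs, ys)
        ll = loglik_intrinsic(dist_model, theta_ref, omega, snap)
        grid = np.array([0.0] + times)
        obs = lna_moments(dist_model, theta_ref, omega, grid,
                          rtol=1e-6, atol=1e-9).observable_moments(dist_model)
        naive = 0.0
        for k, t in enumerate(times):
            mx, my = obs.mean[k + 1]
            vx, vy = obs.var[k + 1]
            for i in range(5):
                naive += norm.logpdf(xs[k][i], mx, math.sqrt(vx))
                naive += norm.logpdf(ys[k][i], my, math.sqrt(vy))
        assert ll == pytest.approx(naive, abs=1e-8)


class TestLoglikExtrinsic:
    def test_density_matches_scipy_lognorm(self, dist_model, fixture_ex):
        # single observation at one time against an independent lognormal
        # parameterization (change of variables from the matched normal)
        t = 6.0
        mom = ut_propagate(dist_model, fixture_ex.hyper, np.array([0.0, t]))
        mx, vx = mom.mean[1, 0], mom.var[1, 0]
        my, vy = mom.mean[1, 1], mom.var[1, 1]
        x_obs, y_obs = 2.0, 1.5
        snap = snapshot_from_arrays([t], [x_obs], [y_obs])
        ll = loglik_extrinsic(dist_model, fixture_ex.hyper, snap)
        expected = 0.0
        for obs, m, v in ((x_obs, mx, vx), (y_obs, my, vy)):
            mu, s2 = moment_match_lognormal(m, v)
            expected += lognorm(s=math.sqrt(s2), scale=math.exp(mu)).logpdf(obs)
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_nonpositive_observation_rejected(self, dist_model, fixture_ex):
        snap = snapshot_from_arrays([2.0], [-1.0], [1.0])
        with pytest.raises(ValueError, match="positive"):
            loglik_extrinsic(dist_model, fixture_ex.hyper, snap)

    def test_degenerate_variance_limit_finite(self, dist_model, fixture_ex):
        hyper = fixture_ex.hyper.restrict_to(())
        traj = solve_ode(dist_model, hyper.theta_mean(), np.array([0.0, 10.0]))
        snap = snapshot_from_arrays(
            [10.0], [traj.ppmek[1]] * 3, [traj.pperk[1]] * 3
        )
        ll = loglik_extrinsic(dist_model, hyper, snap)
        assert math.isfinite(ll)

    def test_monotone_near_mode(self, dist_model, fixture_ex, small_snapshot):
        ll_truth = loglik_extrinsic(dist_model, fixture_ex.hyper, small_snapshot)
        mean = fixture_ex.hyper.mean.copy()
        mean[fixture_ex.hyper.index("E_tot")] *= 3.0
        far = type(fixture_ex.hyper)(
            fixture_ex.hyper.param_names, mean, fixture_ex.hyper.var,
            fixture_ex.hyper.varies,
        )
        assert loglik_extrinsic(dist_model, far, small_snapshot) < ll_truth

    def test_builder_matches_direct(self, dist_model, fixture_ex, small_snapshot):
        varying = tuple(
            n
            for i, n in enumerate(fixture_ex.hyper.param_names)
            if fixture_ex.hyper.varies[i]
        )
        names, ll = make_extrinsic_loglik(
            dist_model, small_snapshot, varying, fixture_ex.hyper
        )
        vec = np.array(
            [fixture_ex.hyper.mean[fixture_ex.hyper.index(p)] for p in varying]
            + [fixture_ex.hyper.cv[fixture_ex.hyper.index(p)] for p in varying]
        )
        direct = loglik_extrinsic(dist_model, fixture_ex.hyper, small_snapshot)
        assert ll(vec) == pytest.approx(direct, rel=1e-9)


class TestPrior:
    def test_families_and_support(self):
        prior = Prior(
            [
                PriorComponent("a", "log-uniform", 0.1, 10.0),
                PriorComponent("b", "uniform", -1.0, 1.0),
                PriorComponent("c", "normal", 0.0, 2.0),
                PriorComponent("d", "log-normal", 0.0, 1.0),
            ]
        )
        rng = np.random.default_rng(0)
        u = prior.sample(rng, 500)
        theta = prior.to_natural(u)
        assert np.all(theta[:, 0] >= 0.1) and np.all(theta[:, 0] <= 10.0)
        assert np.all(theta[:, 3] > 0)
        assert np.all(np.isfinite(prior.logpdf(u)))

    def test_out_of_bounds_density(self):
        prior = Prior.log_uniform({"x": (1.0, 10.0)})
        assert prior.logpdf(np.array([[math.log(0.5)]]))[0] == -np.inf

    def test_invalid_component(self):
        with pytest.raises(ValueError):
            PriorComponent("x", "log-uniform", -1.0, 2.0)
        with pytest.raises(ValueError):
            PriorComponent("x", "weird", 0.0, 1.0)

    def test_centered_log_uniform_spans_decades(self):
        prior = centered_log_uniform({"x": 1.0}, decades=6.0)
        c = prior.components[0]
        assert c.a == pytest.approx(1e-3)
        assert c.b == pytest.approx(1e3)


class TestSMC:
    def test_conjugate_toy_evidence(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0.7, 1.0, 20)
        n = len(y)

        def ll(v):
            return -0.5 * n * math.log(2 * math.pi) - 0.5 * float(
                np.sum((y - v[0]) ** 2)
            )

        prior = Prior([PriorComponent("theta", "normal", 0.0, 1.0)])
        ps, ev = smc_sample(ll, prior, n_particles=1000, seed=1)
        exact = multivariate_normal.logpdf(
            y, mean=np.zeros(n), cov=np.eye(n) + np.ones((n, n))
        )
        assert abs(ev.log_evidence - exact) < 3 * max(ev.mc_error, 1e-3)
        post_mean = float(np.sum(ps.weights * ps.particles[:, 0]))
        assert post_mean == pytest.approx(y.sum() / (n + 1), abs=0.05)

    def test_flat_likelihood_recovers_prior(self):
        prior = Prior([PriorComponent("theta", "normal", 0.0, 1.0)])
        ps, ev = smc_sample(lambda v: 0.0, prior, n_particles=2000, seed=2)
        assert ev.log_evidence == 0.0
        assert kstest(ps.particles[:, 0], "norm").statistic < 0.05

    def test_determinism(self):
        prior = Prior.log_uniform({"x": (0.1, 10.0)})

        def ll(v):
            return -((math.log(v[0])) ** 2)

        ps1, ev1 = smc_sample(ll, prior, n_particles=64, seed=7)
        ps2, ev2 = smc_sample(ll, prior, n_particles=64, seed=7)
        ps3, ev3 = smc_sample(ll, prior, n_particles=64, seed=8)
        assert np.array_equal(ps1.particles, ps2.particles)
        assert ev1.log_evidence == ev2.log_evidence
        assert ev1.log_evidence != ev3.log_evidence

    def test_seed_spread_consistent_with_mc_error(self):
        rng = np.random.default_rng(11)
        y = rng.normal(0.0, 1.0, 10)
        n = len(y)

        def ll(v):
            return -0.5 * n * math.log(2 * math.pi) - 0.5 * float(
                np.sum((y - v[0]) ** 2)
            )

        prior = Prior([PriorComponent("theta", "normal", 0.0, 1.0)])
        evs = [
            smc_sample(ll, prior, n_particles=256, seed=s)[1] for s in range(4)
        ]
        exact = multivariate_normal.logpdf(
            y, mean=np.zeros(n), cov=np.eye(n) + np.ones((n, n))
        )
        for ev in evs:
            assert abs(ev.log_evidence - exact) < 4 * max(ev.mc_error, 1e-3)

    def test_incompatible_prior_aborts(self):
        prior = Prior.log_uniform({"x": (0.1, 10.0)})
        with pytest.raises(RuntimeError, match="incompatible"):
            smc_sample(lambda v: -np.inf, prior, n_particles=32, seed=0)

    def test_weights_normalized_and_particle_count(self):
        prior = Prior.log_uniform({"x": (0.1, 10.0)})
        ps, _ = smc_sample(lambda v: -v[0], prior, n_particles=64, seed=3)
        assert ps.particles.shape == (64, 1)
        assert np.all(ps.weights >= 0)
        assert ps.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_invalid_settings(self):
        prior = Prior.log_uniform({"x": (0.1, 10.0)})
        with pytest.raises(ValueError):
            smc_sample(lambda v: 0.0, prior, n_particles=8, seed=0)
        with pytest.raises(ValueError):
            smc_sample(lambda v: 0.0, prior, n_particles=32, ess_threshold=1.5,
                       seed=0)


class TestBayesFactor:
    def test_equal_evidences(self):
        a = EvidenceResult(-10.0, 0.1)
        b = EvidenceResult(-10.0, 0.1)
        bf, label = bayes_factor(a, b)
        assert bf == pytest.approx(1.0)
        assert label != "very strong"

    def test_boundary_open_at_30(self):
        base = EvidenceResult(0.0, 0.0)
        at = EvidenceResult(math.log(30.0), 0.0)
        above = EvidenceResult(math.log(30.0) + 1e-9, 0.0)
        assert bayes_factor(at, base)[1] != "very strong"
        assert bayes_factor(above, base)[1] == "very strong"
        assert VERY_STRONG_BF == 30.0

    def test_reciprocity(self):
        a = EvidenceResult(-3.0, 0.0)
        b = EvidenceResult(-7.5, 0.0)
        bf_ab, _ = bayes_factor(a, b)
        bf_ba, _ = bayes_factor(b, a)
        assert bf_ab * bf_ba == pytest.approx(1.0, rel=1e-12)

    def test_graded_labels(self):
        base = EvidenceResult(0.0, 0.0)
        assert bayes_factor(EvidenceResult(math.log(5.0), 0.0), base)[1] == "substantial"
        assert bayes_factor(EvidenceResult(math.log(15.0), 0.0), base)[1] == "strong"
        assert bayes_factor(EvidenceResult(-1.0, 0.0), base)[1] == "negative"
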