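"""Likelihood functions, sequential Monte Carlo sampling, model evidence,
and Bayes-factor model ranking.

Three likelihoods are provided, matching the three data views:

* :func:`loglik_average` — independent Gaussian error around the ODE
  solution for per-time population averages (used for mechanism selection).
* :func:`loglik_intrinsic` — per-cell Gaussian density with LNA means and
  variances (intrinsic-noise model of snapshot data).
* :func:`loglik_extrinsic` — per-cell log-normal density with UT-propagated
  population means and variances (extrinsic-noise model).

The SMC sampler tempers the likelihood adaptively (conditional-ESS
bisection), resamples systematically, and rejuvenates particles with
adaptive Gaussian random-walk Metropolis moves in the sampling space.  Its
by-product is an estimate of the log model evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .models import ModelSpec, ParamVector, SolverError, solve_ode
from .population import (
    HyperParams,
    SnapshotData,
    moment_match_lognormal,
    ut_propagate,
)
from .stochastic import lna_moments

__all__ = [
    "Prior",
    "PriorComponent",
    "WeightedParticles",
    "EvidenceResult",
    "loglik_average",
    "loglik_intrinsic",
    "loglik_extrinsic",
    "smc_sample",
    "bayes_factor",
    "VERY_STRONG_BF",
]

#: Open lower boundary of the "very strong" Bayes-factor band.
VERY_STRONG_BF = 30.0

_LOG2PI = math.log(2.0 * math.pi)
#: Floor applied to log-scale variances in the extrinsic likelihood so the
#: degenerate var->0 limit stays finite.
SIGMA2_LOG_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorComponent:
    """One independent prior marginal.

    family:
      * ``log-uniform``: theta ~ reciprocal on [a, b]; sampled as log theta.
      * ``uniform``: theta ~ U(a, b); sampled on the natural scale.
      * ``log-normal``: log theta ~ N(a, b^2).
      * ``normal``: theta ~ N(a, b^2) (for unconstrained quantities).
    """

    name: str
    family: str
    a: float
    b: float

    def __post_init__(self):
        if self.family not in ("log-uniform", "uniform", "log-normal", "normal"):
            raise ValueError(f"unknown prior family {self.family!r}")
        if self.family in ("log-uniform", "uniform") and not self.a < self.b:
            raise ValueError(f"{self.name}: need a < b")
        if self.family in ("log-normal", "normal") and self.b <= 0:
            raise ValueError(f"{self.name}: scale must be > 0")
        if self.family == "log-uniform" and self.a <= 0:
            raise ValueError(f"{self.name}: log-uniform needs a > 0")

    @property
    def log_scale(self) -> bool:
        return self.family in ("log-uniform", "log-normal")


class Prior:
    """Independent product prior over named components.

    The SMC sampler works in the *sampling space*: log theta for the
    log-scale families, theta itself otherwise.  Densities below are with
    respect to the sampling-space variable.
    """

    def __init__(self, components: list[PriorComponent]):
        if not components:
            raise ValueError("empty prior")
        self.components = list(components)
        self.names = tuple(c.name for c in components)
        self.dim = len(components)

    @classmethod
    def log_uniform(cls, bounds: dict[str, tuple[float, float]]) -> "Prior":
        return cls([PriorComponent(n, "log-uniform", a, b) for n, (a, b) in bounds.items()])

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        u = np.empty((n, self.dim))
        for j, c in enumerate(self.components):
            if c.family == "log-uniform":
                u[:, j] = rng.uniform(math.log(c.a), math.log(c.b), size=n)
            elif c.family == "uniform":
                u[:, j] = rng.uniform(c.a, c.b, size=n)
            elif c.family == "log-normal":
                u[:, j] = rng.normal(c.a, c.b, size=n)
            else:
                u[:, j] = rng.normal(c.a, c.b, size=n)
        return u

    def logpdf(self, u: np.ndarray) -> np.ndarray:
        u = np.atleast_2d(u)
        out = np.zeros(u.shape[0])
        for j, c in enumerate(self.components):
            v = u[:, j]
            if c.family == "log-uniform":
                lo, hi = math.log(c.a), math.log(c.b)
                inside = (v >= lo) & (v <= hi)
                out += np.where(inside, -math.log(hi - lo), -np.inf)
            elif c.family == "uniform":
                inside = (v >= c.a) & (v <= c.b)
                out += np.where(inside, -math.log(c.b - c.a), -np.inf)
            else:  # log-normal / normal: Gaussian in sampling space
                out += -0.5 * _LOG2PI - math.log(c.b) - 0.5 * ((v - c.a) / c.b) ** 2
        return out

    def to_natural(self, u: np.ndarray) -> np.ndarray:
        u = np.atleast_2d(u)
        out = u.copy()
        for j, c in enumerate(self.components):
            if c.log_scale:
                out[:, j] = np.exp(u[:, j])
        return out


# ---------------------------------------------------------------------------
# Likelihoods
# ---------------------------------------------------------------------------

def _norm_logpdf(x, m, v):
    return -0.5 * (_LOG2PI + np.log(v) + (x - m) ** 2 / v)


def loglik_average(model: ModelSpec, theta: ParamVector, v: float, avg_data) -> float:
    """Gaussian log-likelihood of per-time averages around the ODE solution.

    ``avg_data`` is a DataFrame with columns time_min, ppMEK, ppERK, aligned
    to an ascending grid starting at 0; ``v`` is the constant measurement
    variance (inferred jointly with theta when fitting).
    """
    if v <= 0:
        raise ValueError("measurement variance must be > 0")
    times = np.asarray(avg_data["time_min"], dtype=float)
    try:
        traj = solve_ode(model, theta, times, rtol=1e-7, atol=1e-9)
    except SolverError:
        return -np.inf
    rx = np.asarray(avg_data["ppMEK"], dtype=float) - traj.ppmek
    ry = np.asarray(avg_data["ppERK"], dtype=float) - traj.pperk
    n = times.size
    return float(-n * (_LOG2PI + math.log(v)) - (np.sum(rx**2) + np.sum(ry**2)) / (2 * v))


def loglik_intrinsic(
    model: ModelSpec, theta: ParamVector, omega: float, snapshot: SnapshotData,
    ic_dispersion: str = "fixed",
) -> float:
    """Intrinsic-noise log-likelihood: per-cell Gaussians with LNA moments.

    Cross-sectional independence: every cell at every time contributes an
    independent Gaussian factor per observable.  With the default fixed
    initial condition the LNA variance at t=0 is zero and any snapshot
    containing t=0 data yields -inf; ``ic_dispersion='poisson'`` disperses
    the initial molecule numbers so t=0 is informative.
    """
    times = snapshot.times
    grid = times if times[0] == 0.0 else np.concatenate(([0.0], times))
    try:
        obs = lna_moments(model, theta, omega, grid, rtol=1e-6, atol=1e-9,
                          ic_dispersion=ic_dispersion)
    except SolverError:
        return -np.inf
    obs = obs.observable_moments(model)
    mean = obs.mean
    var = obs.var
    total = 0.0
    for k, t in enumerate(grid):
        if t not in times:
            continue
        mx, my = mean[k]
        vx, vy = var[k]
        if vx <= 0 or vy <= 0:
            return -np.inf
        x, y = snapshot.at_time(t)
        total += float(np.sum(_norm_logpdf(x, mx, vx)) + np.sum(_norm_logpdf(y, my, vy)))
    return total


def _lognorm_logpdf(x, m, v):
    """Log-density of the log-normal with natural mean m and variance v."""
    mu, s2 = moment_match_lognormal(m, v)
    s2 = max(s2, SIGMA2_LOG_FLOOR)
    lx = np.log(x)
    return -lx - 0.5 * (_LOG2PI + math.log(s2)) - (lx - mu) ** 2 / (2 * s2)


def loglik_extrinsic(
    model: ModelSpec,
    hyper: HyperParams,
    snapshot: SnapshotData,
    ut_moments=None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> float:
    """Extrinsic-noise log-likelihood: per-cell log-normal densities whose
    natural-scale means/variances come from UT propagation of the parameter
    population.

    All observations must be strictly positive (log-normal support).
    ``ut_moments`` may carry a precomputed :class:`MomentTrajectory` to skip
    the propagation step.
    """
    if (snapshot.frame["ppMEK"] <= 0).any() or (snapshot.frame["ppERK"] <= 0).any():
        bad = snapshot.frame[
            (snapshot.frame["ppMEK"] <= 0) | (snapshot.frame["ppERK"] <= 0)
        ]
        raise ValueError(
            "extrinsic likelihood requires strictly positive intensities; "
            f"offending rows: {list(bad.index[:10])}"
        )
    times = snapshot.times
    if ut_moments is None:
        grid = times if times[0] == 0.0 else np.concatenate(([0.0], times))
        try:
            ut_moments = ut_propagate(model, hyper, grid, rtol=rtol, atol=atol)
        except (SolverError, ArithmeticError):
            return -np.inf
    mean, var = ut_moments.mean, ut_moments.var
    if not (np.all(np.isfinite(mean)) and np.all(np.isfinite(var))):
        return -np.inf
    total = 0.0
    grid = ut_moments.times
    for k, t in enumerate(grid):
        if t not in times:
            continue
        mx, my = mean[k]
        vx, vy = var[k]
        if mx <= 0 or my <= 0 or vx < 0 or vy < 0:
            return -np.inf
        x, y = snapshot.at_time(t)
        total += float(np.sum(_lognorm_logpdf(x, mx, vx)))
        total += float(np.sum(_lognorm_logpdf(y, my, vy)))
    return total


# ---------------------------------------------------------------------------
# SMC sampler
# ---------------------------------------------------------------------------

@dataclass
class WeightedParticles:
    """SMC posterior: particles (natural scale), normalized weights, schedule."""

    names: tuple[str, ...]
    particles: np.ndarray  # (N, d) natural scale
    weights: np.ndarray  # (N,)
    schedule: list = field(default_factory=list)
    sampling: np.ndarray | None = None  # particles in sampling space

    def best(self) -> dict[str, float]:
        """The inferred parameter vector: the highest-weight particle."""
        i = int(np.argmax(self.weights))
        return dict(zip(self.names, self.particles[i]))

    def quantile(self, name: str, q) -> np.ndarray:
        j = self.names.index(name)
        return weighted_quantile(self.particles[:, j], self.weights, q)

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.particles, columns=list(self.names))
        df["weight"] = self.weights
        return df


@dataclass
class EvidenceResult:
    """Log model evidence (nats) with a bootstrap Monte-Carlo error."""

    log_evidence: float
    mc_error: float
    model_id: str = ""
    n_loglik_evals: int = 0

    def __post_init__(self):
        if not math.isfinite(self.log_evidence):
            raise ValueError("log evidence must be finite")
        if self.mc_error < 0:
            raise ValueError("mc_error must be >= 0")


def weighted_quantile(x: np.ndarray, w: np.ndarray, q) -> np.ndarray:
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    cdf = np.cumsum(ws)
    cdf /= cdf[-1]
    return np.interp(np.atleast_1d(q), cdf, xs)


def _systematic_resample(w: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = w.size
    positions = (rng.random() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(w), positions).clip(0, n - 1)


def _cess(logw: np.ndarray, delta: float, ll: np.ndarray) -> float:
    """Conditional ESS of the incremental weights exp(delta * ll)."""
    a = logw + delta * ll
    num = 2.0 * logsumexp(a)
    den = logsumexp(2.0 * a - logw)
    return float(logw.size * math.exp(num - den - logsumexp(logw)))


def smc_sample(
    loglik,
    prior: Prior,
    n_particles: int = 512,
    ess_threshold: float = 0.5,
    move_count: int = 2,
    seed: int = 0,
    cess_target: float | None = None,
    n_bootstrap: int = 200,
    model_id: str = "",
    max_steps: int = 1000,
) -> tuple[WeightedParticles, EvidenceResult]:
    """Likelihood-tempered SMC with adaptive schedule and RWM rejuvenation.

    ``loglik`` maps a natural-scale parameter vector (1-D array ordered as
    ``prior.names``) to a log-likelihood; -inf is allowed.  The tempering
    exponent advances by bisection so the conditional ESS hits
    ``cess_target * N`` (default: ``ess_threshold``); particles are
    resampled systematically when the ESS drops below ``ess_threshold * N``
    and then rejuvenated with ``move_count`` adaptive Gaussian random-walk
    Metropolis sweeps in the sampling space.  Fully deterministic given the
    seed.  Returns the weighted particles and the evidence estimate.
    """
    if n_particles < 16:
        raise ValueError("n_particles must be >= 16")
    if not 0 < ess_threshold < 1:
        raise ValueError("ess_threshold must be in (0, 1)")
    if cess_target is None:
        cess_target = ess_threshold
    rng = np.random.default_rng(seed)
    N, d = n_particles, prior.dim

    u = prior.sample(rng, N)
    theta = prior.to_natural(u)
    ll = np.array([loglik(theta[i]) for i in range(N)])
    n_evals = N
    if np.all(np.isneginf(ll)):
        raise RuntimeError(
            "all particles have zero likelihood at initialization; "
            "prior and model/data are incompatible"
        )
    logw = np.full(N, -math.log(N))
    gamma = 0.0
    log_z = 0.0
    schedule = []
    boot_var = 0.0
    step = 0

    while gamma < 1.0 and step < max_steps:
        step += 1
        ll_safe = np.where(np.isneginf(ll), -1e300, ll)
        remaining = 1.0 - gamma
        target = cess_target * N
        if _cess(logw, remaining, ll_safe) >= target:
            delta = remaining
        else:
            lo, hi = 0.0, remaining
            for _ in range(50):
                mid = 0.5 * (lo + hi)
                if _cess(logw, mid, ll_safe) >= target:
                    lo = mid
                else:
                    hi = mid
            delta = max(lo, remaining * 1e-8)
        gamma += delta

        # evidence increment: log sum_i W_i * L_i^delta
        logW = logw - logsumexp(logw)
        incr = logsumexp(logW + delta * ll_safe)
        log_z += float(incr)
        boot_var += _bootstrap_incr_var(logW, delta * ll_safe, rng, n_bootstrap)

        logw = logW + delta * ll_safe
        logw -= logsumexp(logw)
        ess = math.exp(-logsumexp(2.0 * logw))
        schedule.append({"gamma": gamma, "delta": delta, "ess": ess})

        if ess < ess_threshold * N or gamma >= 1.0:
            idx = _systematic_resample(np.exp(logw), rng)
            u, ll = u[idx].copy(), ll[idx].copy()
            logw = np.full(N, -math.log(N))
            # adaptive RWM rejuvenation at the current temperature
            cov = np.cov(u.T) if d > 1 else np.atleast_2d(np.var(u))
            cov = np.atleast_2d(cov) * (2.38**2 / d) + 1e-10 * np.eye(d)
            L = np.linalg.cholesky(cov)
            lp = prior.logpdf(u)
            for _ in range(move_count):
                prop = u + rng.standard_normal((N, d)) @ L.T
                lp_prop = prior.logpdf(prop)
                ok = np.isfinite(lp_prop)
                ll_prop = np.full(N, -np.inf)
                theta_prop = prior.to_natural(prop)
                for i in np.flatnonzero(ok):
                    ll_prop[i] = loglik(theta_prop[i])
                    n_evals += 1
                ll_prop_safe = np.where(np.isneginf(ll_prop), -1e300, ll_prop)
                log_alpha = (lp_prop + gamma * ll_prop_safe) - (lp + gamma * _ll_safe(ll))
                accept = np.log(rng.random(N)) < log_alpha
                u[accept] = prop[accept]
                ll[accept] = ll_prop[accept]
                lp[accept] = lp_prop[accept]

    w = np.exp(logw - logsumexp(logw))
    particles = WeightedParticles(
        names=prior.names,
        particles=prior.to_natural(u),
        weights=w,
        schedule=schedule,
        sampling=u,
    )
    evidence = EvidenceResult(
        log_evidence=log_z,
        mc_error=math.sqrt(boot_var),
        model_id=model_id,
        n_loglik_evals=n_evals,
    )
    return particles, evidence


def _ll_safe(ll: np.ndarray) -> np.ndarray:
    return np.where(np.isneginf(ll), -1e300, ll)


def _bootstrap_incr_var(
    logW: np.ndarray, dll: np.ndarray, rng: np.random.Generator, n_boot: int
) -> float:
    """Bootstrap variance of one log evidence increment log sum W exp(dll)."""
    if n_boot <= 0:
        return 0.0
    n = logW.size
    w = np.exp(logW)
    a = dll - dll.max()
    vals = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.choice(n, size=n, p=w)
        vals[b] = math.log(np.mean(np.exp(a[idx])) + 1e-300)
    return float(np.var(vals))


# ---------------------------------------------------------------------------
# Likelihood/prior builders for the three fitting modes
# ---------------------------------------------------------------------------

def centered_log_uniform(
    center: dict[str, float], decades: float = 6.0
) -> "Prior":
    """Log-uniform priors spanning ``decades`` orders of magnitude centered
    (in log space) on the given values."""
    half = 10.0 ** (decades / 2.0)
    return Prior.log_uniform({n: (v / half, v * half) for n, v in center.items()})


def make_average_loglik(model: ModelSpec, avg_data):
    """Average-data likelihood over [model params..., v].

    The measurement variance ``v`` is the last sampled coordinate, inferred
    simultaneously with the model parameters.
    """
    names = model.param_names + ("v",)

    def ll(vec: np.ndarray) -> float:
        theta_vals = dict(zip(model.param_names, vec[:-1]))
        try:
            theta = ParamVector(model.param_names, theta_vals)
        except ValueError:
            return -np.inf
        return loglik_average(model, theta, float(vec[-1]), avg_data)

    return names, ll


def _per_time_stats(snapshot: SnapshotData, need_logs: bool):
    """Per-time sufficient statistics for the per-cell Gaussian/log-normal
    factors: (n, sum x, sum x^2, sum ln x, sum (ln x)^2) per observable."""
    times = snapshot.times
    stats = np.empty((times.size, 2, 5))
    for k, t in enumerate(times):
        for j, v in enumerate(snapshot.at_time(t)):
            lv = np.log(v) if need_logs else np.zeros_like(v)
            stats[k, j] = (v.size, v.sum(), (v * v).sum(), lv.sum(), (lv * lv).sum())
    return times, stats


def _gauss_sum(stats_row, m, v):
    n, sx, sxx, _, _ = stats_row
    return -0.5 * n * (_LOG2PI + math.log(v)) - (sxx - 2 * m * sx + n * m * m) / (2 * v)


def _lognorm_sum(stats_row, m, v):
    n, _, _, slx, slxx = stats_row
    mu, s2 = moment_match_lognormal(m, v)
    s2 = max(s2, SIGMA2_LOG_FLOOR)
    return (
        -slx
        - 0.5 * n * (_LOG2PI + math.log(s2))
        - (slxx - 2 * mu * slx + n * mu * mu) / (2 * s2)
    )


def make_intrinsic_loglik(
    model: ModelSpec,
    snapshot: SnapshotData,
    fixed: dict[str, float] | None = None,
    ic_dispersion: str = "poisson",
):
    """Intrinsic likelihood over the free model parameters plus Omega.

    The system size is unidentifiable from intensity-scale data without a
    count calibration, so it is exposed as one extra inferable coordinate.
    Parameters in ``fixed`` are pinned and removed from the sampled vector.
    Initial molecule numbers are Poisson-dispersed by default so that t=0
    snapshots carry likelihood mass (a fixed initial condition makes any
    spread at t=0 impossible under the intrinsic model).
    """
    fixed = fixed or {}
    free = tuple(n for n in model.param_names if n not in fixed)
    names = free + ("omega",)
    times, stats = _per_time_stats(snapshot, need_logs=False)
    grid = times if times[0] == 0.0 else np.concatenate(([0.0], times))
    offset = grid.size - times.size

    def ll(vec: np.ndarray) -> float:
        vals = dict(fixed)
        vals.update(zip(free, vec[:-1]))
        try:
            theta = ParamVector(model.param_names, vals)
        except ValueError:
            return -np.inf
        try:
            obs = lna_moments(model, theta, float(vec[-1]), grid,
                              rtol=1e-6, atol=1e-9,
                              ic_dispersion=ic_dispersion).observable_moments(model)
        except SolverError:
            return -np.inf
        mean, var = obs.mean[offset:], obs.var[offset:]
        if np.any(var <= 0) or not np.all(np.isfinite(mean)):
            return -np.inf
        total = 0.0
        for k in range(times.size):
            total += _gauss_sum(stats[k, 0], mean[k, 0], var[k, 0])
            total += _gauss_sum(stats[k, 1], mean[k, 1], var[k, 1])
        return total

    return names, ll


def make_extrinsic_loglik(
    model: ModelSpec,
    snapshot: SnapshotData,
    varying: tuple[str, ...],
    base_hyper: HyperParams,
):
    """Extrinsic likelihood over [mean_p..., cv_p...] for varying parameters.

    Non-varying parameters keep the means of ``base_hyper`` and zero
    population variance.
    """
    names = tuple(f"mean_{p}" for p in varying) + tuple(f"cv_{p}" for p in varying)
    k = len(varying)
    pnames = base_hyper.param_names
    idx = [pnames.index(p) for p in varying]
    if (snapshot.frame["ppMEK"] <= 0).any() or (snapshot.frame["ppERK"] <= 0).any():
        raise ValueError("extrinsic likelihood requires strictly positive intensities")
    times, stats = _per_time_stats(snapshot, need_logs=True)
    grid = times if times[0] == 0.0 else np.concatenate(([0.0], times))
    offset = grid.size - times.size

    def ll(vec: np.ndarray) -> float:
        mean = base_hyper.mean.copy()
        var = np.zeros_like(mean)
        varies = np.zeros(mean.size, dtype=bool)
        for j, i in enumerate(idx):
            m, cv = float(vec[j]), float(vec[k + j])
            if m <= 0 or cv < 0:
                return -np.inf
            mean[i] = m
            var[i] = (cv * m) ** 2
            varies[i] = cv > 0
        try:
            hyper = HyperParams(pnames, mean, var, varies)
            if hyper.mean[pnames.index("Epp0")] > hyper.mean[pnames.index("E_tot")]:
                return -np.inf
        except ValueError:
            return -np.inf
        try:
            mom = ut_propagate(model, hyper, grid)
        except (SolverError, ArithmeticError):
            return -np.inf
        mean_o, var_o = mom.mean[offset:], mom.var[offset:]
        if not (np.all(np.isfinite(mean_o)) and np.all(np.isfinite(var_o))):
            return -np.inf
        if np.any(mean_o <= 0) or np.any(var_o < 0):
            return -np.inf
        total = 0.0
        for t in range(times.size):
            total += _lognorm_sum(stats[t, 0], mean_o[t, 0], var_o[t, 0])
            total += _lognorm_sum(stats[t, 1], mean_o[t, 1], var_o[t, 1])
        return total

    return names, ll


# ---------------------------------------------------------------------------
# Bayes factors
# ---------------------------------------------------------------------------

def bayes_factor(ev_a: EvidenceResult, ev_b: EvidenceResult) -> tuple[float, str]:
    """Bayes factor of model A over model B and its evidential label.

    The label is "very strong" iff BF strictly exceeds
    :data:`VERY_STRONG_BF` (= 30); smaller values are graded on the
    conventional scale.
    """
    log_bf = ev_a.log_evidence - ev_b.log_evidence
    bf = math.exp(min(log_bf, 700.0))
    if log_bf > math.log(VERY_STRONG_BF):
        label = "very strong"
    elif bf > 10.0:
        label = "strong"
    elif bf > 3.0:
        label = "substantial"
    elif bf > 1.0:
        label = "barely worth mentioning"
    else:
        label = "negative"
    return bf, label
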