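"""Cell-to-cell parameter variability: log-normal parameter populations,
Unscented-Transform moment propagation, population Monte Carlo, and the
law-of-total-variance combination of intrinsic and extrinsic noise.

Parameters vary independently across cells (no cross-parameter correlation);
each varying parameter follows a log-normal distribution parameterized by
its natural-scale population mean and variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .models import ModelSpec, ParamVector, _integrate_states, initial_state
from .stochastic import MomentTrajectory, lna_moments, ssa_simulate

__all__ = [
    "HyperParams",
    "CellParameterSet",
    "SnapshotData",
    "moment_match_lognormal",
    "lognormal_from_log_moments",
    "sample_cell_parameters",
    "ut_propagate",
    "population_observables",
    "population_simulate",
    "TotalVariance",
    "total_variance",
]

OBS_NAMES = ("ppMEK_total", "ppERK_total")


def moment_match_lognormal(m: float, v: float) -> tuple[float, float]:
    """Log-scale (mu, sigma^2) of the log-normal with natural mean m, variance v."""
    if m <= 0:
        raise ValueError(f"natural mean must be > 0, got {m}")
    if v < 0:
        raise ValueError(f"natural variance must be >= 0, got {v}")
    s2 = math.log1p(v / (m * m))
    mu = math.log(m) - 0.5 * s2
    return mu, s2


def lognormal_from_log_moments(mu: float, s2: float) -> tuple[float, float]:
    """Inverse of :func:`moment_match_lognormal`."""
    m = math.exp(mu + 0.5 * s2)
    v = m * m * math.expm1(s2)
    return m, v


@dataclass(frozen=True)
class HyperParams:
    """Population-level mean/variance per parameter plus a varies mask.

    Means and variances are on the natural parameter scale; ``var`` must be
    zero wherever ``varies`` is false.
    """

    param_names: tuple[str, ...]
    mean: np.ndarray
    var: np.ndarray
    varies: np.ndarray  # bool mask

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "var", np.asarray(self.var, dtype=float))
        object.__setattr__(self, "varies", np.asarray(self.varies, dtype=bool))
        if not (len(self.param_names) == self.mean.size == self.var.size == self.varies.size):
            raise ValueError("hyperparameter field lengths disagree")
        if np.any(self.mean <= 0):
            raise ValueError("population means must be > 0")
        if np.any(self.var < 0):
            raise ValueError("population variances must be >= 0")
        if np.any(self.var[~self.varies] != 0):
            raise ValueError("fixed parameters must have var = 0")

    @classmethod
    def from_mean_cv(
        cls,
        param_names: Sequence[str],
        mean: dict[str, float],
        cv: dict[str, float] | None = None,
    ) -> "HyperParams":
        """Build from per-parameter means and coefficients of variation.

        Parameters absent from ``cv`` (or with cv=0) are fixed across cells.
        """
        cv = cv or {}
        names = tuple(param_names)
        m = np.array([float(mean[n]) for n in names])
        c = np.array([float(cv.get(n, 0.0)) for n in names])
        return cls(param_names=names, mean=m, var=(c * m) ** 2, varies=c > 0)

    @property
    def cv(self) -> np.ndarray:
        return np.sqrt(self.var) / self.mean

    def index(self, name: str) -> int:
        return self.param_names.index(name)

    def theta_mean(self) -> ParamVector:
        return ParamVector(self.param_names, dict(zip(self.param_names, self.mean)))

    def restrict_to(self, group: Sequence[str]) -> "HyperParams":
        """Copy with variances zeroed outside ``group`` (Fig-6-style masks)."""
        keep = np.array([n in set(group) for n in self.param_names])
        var = np.where(keep, self.var, 0.0)
        return HyperParams(self.param_names, self.mean.copy(), var,
                           self.varies & keep)

    def with_variance(self, **updates: float) -> "HyperParams":
        var = self.var.copy()
        varies = self.varies.copy()
        for name, v in updates.items():
            i = self.index(name)
            var[i] = v
            varies[i] = v > 0
        return HyperParams(self.param_names, self.mean.copy(), var, varies)

    def log_moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Matched log-scale (mu, sigma^2) per parameter (0 where fixed)."""
        mu = np.empty(self.mean.size)
        s2 = np.empty(self.mean.size)
        for i, (m, v) in enumerate(zip(self.mean, self.var)):
            mu[i], s2[i] = moment_match_lognormal(m, v)
        return mu, s2


@dataclass(frozen=True)
class CellParameterSet:
    """Per-cell parameter values: one ParamVector row per cell."""

    param_names: tuple[str, ...]
    values: np.ndarray  # (n_cells, n_params)
    seed: int | None = None

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def row(self, i: int) -> ParamVector:
        return ParamVector(self.param_names, dict(zip(self.param_names, self.values[i])))


def sample_cell_parameters(
    hyper: HyperParams, n_cells: int, seed: int | np.random.Generator
) -> CellParameterSet:
    """Draw per-cell parameters, independent log-normal per varying parameter.

    ``Epp0`` draws exceeding ``E_tot`` are clipped to ``E_tot`` so every row
    is a valid parameterization.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu, s2 = hyper.log_moments()
    vals = np.tile(hyper.mean, (n_cells, 1))
    for j in np.flatnonzero(hyper.varies):
        vals[:, j] = rng.lognormal(mu[j], math.sqrt(s2[j]), size=n_cells)
    names = hyper.param_names
    if "Epp0" in names and "E_tot" in names:
        je, jt = names.index("Epp0"), names.index("E_tot")
        np.minimum(vals[:, je], vals[:, jt], out=vals[:, je])
    return CellParameterSet(
        param_names=names, values=vals,
        seed=None if isinstance(seed, np.random.Generator) else seed,
    )


# ---------------------------------------------------------------------------
# Unscented Transform
# ---------------------------------------------------------------------------

def ut_sigma_points(
    hyper: HyperParams, alpha: float = 1.0, beta: float = 2.0, kappa: float = 0.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scaled-UT sigma points in parameter space, placed in log space.

    The population is exactly Gaussian in log-parameter space, so the 2d+1
    points are laid out there and mapped through exp.  Returns
    (points: (2d+1, n_params) natural scale, w_mean, w_cov).
    """
    d = int(hyper.varies.sum())
    if d == 0:
        pts = hyper.mean[None, :].copy()
        return pts, np.ones(1), np.ones(1)
    lam = alpha * alpha * (d + kappa) - d
    c = d + lam
    mu, s2 = hyper.log_moments()
    sd = np.sqrt(s2)
    vary_idx = np.flatnonzero(hyper.varies)

    z0 = mu.copy()
    points_log = [z0]
    for j in vary_idx:
        e = np.zeros_like(mu)
        e[j] = math.sqrt(c) * sd[j]
        points_log.append(mu + e)
        points_log.append(mu - e)
    Z = np.vstack(points_log)
    pts = np.tile(hyper.mean, (2 * d + 1, 1))
    pts[:, vary_idx] = np.exp(Z[:, vary_idx])

    w_mean = np.full(2 * d + 1, 1.0 / (2.0 * c))
    w_cov = w_mean.copy()
    w_mean[0] = lam / c
    w_cov[0] = lam / c + (1.0 - alpha * alpha + beta)
    return pts, w_mean, w_cov


def ut_propagate(
    model: ModelSpec,
    hyper: HyperParams,
    times,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    alpha: float = 1.0,
    beta: float = 2.0,
    kappa: float = 0.0,
    transform=None,
) -> MomentTrajectory:
    """Propagate the parameter population through the model dynamics.

    Each sigma point is solved deterministically and projected onto the
    observables; the returned moments approximate the population mean and
    covariance of (ppMEK_total, ppERK_total) at every time.

    ``transform`` overrides the parameter->per-time-output map (used by
    tests to check UT exactness on simple functions); it receives a
    ParamVector and must return an (n_times, k) array.
    """
    times = np.asarray(times, dtype=float)
    pts, w_mean, w_cov = ut_sigma_points(hyper, alpha, beta, kappa)
    names = hyper.param_names
    outputs = []
    for i, row in enumerate(pts):
        theta = ParamVector(names, dict(zip(names, row)))
        if transform is not None:
            Y = np.asarray(transform(theta), dtype=float)
        else:
            states = _integrate_states(model, theta, times, rtol, atol)
            Y = states @ model.observable_matrix.T
        if not np.all(np.isfinite(Y)):
            raise ArithmeticError(f"non-finite output at sigma point {i}")
        outputs.append(Y)
    Y = np.stack(outputs)  # (n_pts, n_times, k)
    mean = np.einsum("p,ptk->tk", w_mean, Y)
    dev = Y - mean[None, :, :]
    cov = np.einsum("p,ptk,ptl->tkl", w_cov, dev, dev)
    k = Y.shape[2]
    names_out = OBS_NAMES if (transform is None and k == 2) else tuple(
        f"y{j}" for j in range(k)
    )
    return MomentTrajectory(times=times, mean=mean, cov=cov, names=names_out)


# ---------------------------------------------------------------------------
# Population Monte Carlo
# ---------------------------------------------------------------------------

@dataclass
class SnapshotData:
    """Cross-sectional single-cell snapshot measurements.

    One row per cell per time; cells are never tracked across time points
    (destructive sampling), so ``cell_id`` values are unique globally.
    """

    frame: pd.DataFrame  # columns: time_min, cell_id, ppMEK, ppERK, ...
    metadata: dict = field(default_factory=dict)

    REQUIRED = ("time_min", "cell_id", "ppMEK", "ppERK")

    def __post_init__(self):
        for col in self.REQUIRED:
            if col not in self.frame.columns:
                raise ValueError(f"snapshot frame missing column {col!r}")

    @property
    def times(self) -> np.ndarray:
        return np.unique(self.frame["time_min"].to_numpy())

    def n_cells(self, t: float) -> int:
        return int((self.frame["time_min"] == t).sum())

    def at_time(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        sub = self.frame[self.frame["time_min"] == t]
        return sub["ppMEK"].to_numpy(dtype=float), sub["ppERK"].to_numpy(dtype=float)

    def averages(self) -> pd.DataFrame:
        """Per-time sample means of both observables (average-data view)."""
        g = self.frame.groupby("time_min")[["ppMEK", "ppERK"]].mean()
        return g.reset_index()

    def __len__(self) -> int:
        return len(self.frame)


def population_observables(
    model: ModelSpec,
    cells: CellParameterSet,
    times,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> np.ndarray:
    """Deterministic observables for every cell on a shared grid: (n, T, 2)."""
    times = np.asarray(times, dtype=float)
    L = model.observable_matrix.T
    out = np.empty((cells.n_cells, times.size, 2))
    for i in range(cells.n_cells):
        theta = cells.row(i)
        out[i] = _integrate_states(model, theta, times, rtol, atol) @ L
    return out


def population_simulate(
    model: ModelSpec,
    hyper: HyperParams,
    n_per_time: int,
    times,
    seed: int,
    intrinsic_omega: float | None = None,
    measurement_cv: float = 0.0,
    dose_label: str = "default",
    rtol: float = 1e-6,
    atol: float = 1e-9,
    ic_dispersion: str = "poisson",
) -> SnapshotData:
    """Simulate a cross-sectional snapshot dataset.

    A fresh cohort of cells is drawn for every time point (destructive
    sampling).  With ``intrinsic_omega`` set, each cell is simulated by SSA
    at that system size; otherwise deterministically.  An optional
    multiplicative log-normal measurement error with the given CV is applied
    (default 0: negligible experimental noise).
    """
    if n_per_time < 1:
        raise ValueError("n_per_time must be >= 1")
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    rows = []
    cell_id = 0
    L = model.observable_matrix.T
    for t in times:
        cells = sample_cell_parameters(hyper, n_per_time, rng)
        for i in range(n_per_time):
            theta = cells.row(i)
            if t == 0.0:
                x0 = initial_state(model, theta)
                if intrinsic_omega is not None and ic_dispersion == "poisson":
                    x0 = rng.poisson(intrinsic_omega * x0) / intrinsic_omega
                obs = x0 @ L
            elif intrinsic_omega is not None:
                samp = ssa_simulate(
                    model, theta, intrinsic_omega, np.array([0.0, t]),
                    seed=int(rng.integers(2**31 - 1)),
                    ic_dispersion=ic_dispersion,
                )
                obs = samp.observables()[-1]
            else:
                states = _integrate_states(model, theta, np.array([0.0, t]), rtol, atol)
                obs = states[-1] @ L
            rows.append((t, cell_id, obs[0], obs[1]))
            cell_id += 1
    df = pd.DataFrame(rows, columns=["time_min", "cell_id", "ppMEK", "ppERK"])
    if measurement_cv > 0:
        mu, s2 = moment_match_lognormal(1.0, measurement_cv**2)
        for col in ("ppMEK", "ppERK"):
            df[col] = df[col] * rng.lognormal(mu, math.sqrt(s2), size=len(df))
    df["dose_label"] = dose_label
    meta = {
        "seed": seed,
        "generation_mode": "ssa" if intrinsic_omega is not None else "ode",
        "intrinsic_omega": intrinsic_omega,
        "measurement_cv": measurement_cv,
        "dose_label": dose_label,
    }
    return SnapshotData(frame=df, metadata=meta)


# ---------------------------------------------------------------------------
# Law of total variance
# ---------------------------------------------------------------------------

@dataclass
class TotalVariance:
    """Per-time decomposition Var_total = E[Var_intrinsic] + Var[E_intrinsic]."""

    times: np.ndarray
    mean_intrinsic_var: np.ndarray  # (T, 2)
    var_of_means: np.ndarray  # (T, 2)

    @property
    def total(self) -> np.ndarray:
        return self.mean_intrinsic_var + self.var_of_means


def total_variance(
    model: ModelSpec,
    hyper: HyperParams,
    omega: float,
    times,
    n_outer: int,
    seed: int,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> TotalVariance:
    """Total observable variance combining extrinsic and intrinsic noise.

    Draws ``n_outer`` parameter sets from the population; for each, the LNA
    gives the within-cell (intrinsic) observable mean and variance.  The law
    of total variance then combines the two layers.
    """
    if n_outer < 2:
        raise ValueError("n_outer must be >= 2")
    times = np.asarray(times, dtype=float)
    if int(hyper.varies.sum()) == 0:
        # no extrinsic variability: total variance is the intrinsic variance
        # at the population-mean parameters, outer term exactly zero
        mom = lna_moments(model, hyper.theta_mean(), omega, times, rtol, atol)
        obs = mom.observable_moments(model)
        return TotalVariance(times=times, mean_intrinsic_var=obs.var.copy(),
                             var_of_means=np.zeros_like(obs.var))
    cells = sample_cell_parameters(hyper, n_outer, seed)
    means = np.empty((n_outer, times.size, 2))
    ivars = np.empty((n_outer, times.size, 2))
    for i in range(n_outer):
        mom = lna_moments(model, cells.row(i), omega, times, rtol, atol)
        obs = mom.observable_moments(model)
        means[i] = obs.mean
        ivars[i] = obs.var
    return TotalVariance(
        times=times,
        mean_intrinsic_var=ivars.mean(axis=0),
        var_of_means=means.var(axis=0, ddof=1),
    )
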