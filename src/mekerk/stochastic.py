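"""Intrinsic-noise engines: exact SSA paths and linear-noise-approximation
moment equations.

The SSA is the gold-standard oracle; the LNA provides the Gaussian means
and (co)variances used by the intrinsic-noise likelihood.  Both work on the
concentration scale with an explicit system size Omega (molecules per
concentration unit); intrinsic variances scale as 1/Omega.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import odeint

from .kernels import lna_rhs, rk45_lna, ssa_run
from .models import ModelSpec, ParamVector, SolverError, initial_state

__all__ = ["JumpSample", "MomentTrajectory", "ssa_simulate", "lna_moments"]


@dataclass
class JumpSample:
    """One SSA path sampled at fixed times (integer copy numbers)."""

    model: ModelSpec
    times: np.ndarray
    counts: np.ndarray  # (n_times, n_species), int64
    system_size: float
    seed: int

    @property
    def concentrations(self) -> np.ndarray:
        return self.counts / self.system_size

    def observables(self) -> np.ndarray:
        """(n_times, 2) total ppMEK / ppERK on the concentration scale."""
        return self.concentrations @ self.model.observable_matrix.T

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.counts, columns=list(self.model.species_names))
        df.insert(0, "time_min", self.times)
        return df


@dataclass
class MomentTrajectory:
    """First two moments over time, for species or projected observables."""

    times: np.ndarray
    mean: np.ndarray  # (n_times, n_vars)
    cov: np.ndarray  # (n_times, n_vars, n_vars)
    names: tuple[str, ...]
    system_size: float | None = None

    @property
    def var(self) -> np.ndarray:
        return np.einsum("tii->ti", self.cov)

    def project(self, L: np.ndarray, names: tuple[str, ...]) -> "MomentTrajectory":
        """Linear projection y = L x of means and covariances."""
        mean = self.mean @ L.T
        cov = np.einsum("ij,tjk,lk->til", L, self.cov, L)
        return MomentTrajectory(
            times=self.times, mean=mean, cov=cov, names=names,
            system_size=self.system_size,
        )

    def observable_moments(self, model: ModelSpec) -> "MomentTrajectory":
        return self.project(model.observable_matrix, ("ppMEK_total", "ppERK_total"))

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.mean, columns=[f"mean_{n}" for n in self.names])
        df.insert(0, "time_min", self.times)
        k = len(self.names)
        for i in range(k):
            for j in range(k):
                df[f"cov_{i}_{j}"] = self.cov[:, i, j]
        return df


def _count_scale_rates(model: ModelSpec, theta: ParamVector, omega: float):
    """Convert concentration-scale rate constants to count-scale propensity
    constants: zeroth order x Omega, unimolecular unchanged, bimolecular / Omega."""
    r1, r2, input_idx = model.reactant_indices()
    rates = model.rate_array(theta)
    rates_c = rates.copy()
    for r in range(model.n_reactions):
        if r == input_idx:
            continue
        order = int(r1[r] >= 0) + int(r2[r] >= 0)
        if order == 0:
            rates_c[r] = rates[r] * omega
        elif order == 2:
            rates_c[r] = rates[r] / omega
    return rates_c, r1, r2, input_idx


def ssa_simulate(
    model: ModelSpec,
    theta: ParamVector,
    omega: float,
    times,
    seed: int,
    ic_dispersion: str = "fixed",
) -> JumpSample:
    """Exact Gillespie path, sampled at ``times`` (ascending, from 0).

    Initial counts are ``round(Omega * initial_state)`` by default;
    ``ic_dispersion='poisson'`` instead draws them Poisson with that mean
    (molecule numbers at stimulus onset are themselves random).  The step
    input is handled exactly by restarting the propensity bookkeeping at
    T_pulse.
    """
    if omega <= 0:
        raise ValueError("omega must be > 0")
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) <= 0) or times[0] < 0:
        raise ValueError("times must be ascending and nonnegative")
    if ic_dispersion == "fixed":
        x0 = np.round(omega * initial_state(model, theta)).astype(np.int64)
    elif ic_dispersion == "poisson":
        rng = np.random.default_rng(seed ^ 0x5F3759DF)
        x0 = rng.poisson(omega * initial_state(model, theta)).astype(np.int64)
    else:
        raise ValueError(f"unknown ic_dispersion {ic_dispersion!r}")
    if x0.sum() == 0 and theta["k1"] == 0 and theta["k10"] == 0:
        warnings.warn("degenerate SSA run: all initial counts zero and no input")
    rates_c, r1, r2, input_idx = _count_scale_rates(model, theta, omega)
    u1 = theta["k1"] * omega
    u2 = theta["k10"] * omega
    counts = ssa_run(
        x0, model.stoich, rates_c, r1, r2, input_idx, u1, u2,
        float(theta["T_pulse"]), times, seed,
    )
    return JumpSample(model=model, times=times, counts=counts,
                      system_size=omega, seed=seed)


def lna_moments(
    model: ModelSpec,
    theta: ParamVector,
    omega: float,
    times,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    input_shape: str = "step",
    ic_dispersion: str = "fixed",
) -> MomentTrajectory:
    """Linear noise approximation: means and species covariances over time.

    The mean solves the macroscopic rate equations; the covariance solves
    dSigma/dt = J Sigma + Sigma J^T + (1/Omega) S diag(f) S^T, integrated
    jointly on the concentration scale (n + n^2 states).

    ``ic_dispersion='poisson'`` starts the covariance at diag(x0)/Omega
    (Poisson-distributed initial molecule numbers) instead of zero.
    """
    if omega <= 0:
        raise ValueError("omega must be > 0")
    times = np.asarray(times, dtype=float)
    if times[0] != 0.0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be ascending from 0")

    n = model.n_species
    S, r1, r2, input_idx = model._solver_arrays
    rates = model.rate_array(theta)
    k1, k10, T = theta["k1"], theta["k10"], theta["T_pulse"]
    inv_omega = 1.0 / omega

    y0 = np.zeros(n + n * n)
    y0[:n] = initial_state(model, theta)
    if ic_dispersion == "poisson":
        y0[n:] = (np.diag(y0[:n]) * inv_omega).ravel()
    elif ic_dispersion != "fixed":
        raise ValueError(f"unknown ic_dispersion {ic_dispersion!r}")

    if input_shape == "step":
        ok, ys = rk45_lna(y0, times, S, rates, r1, r2, input_idx,
                          k1, k10, float(T), inv_omega, rtol, atol)
        if ok and np.all(np.isfinite(ys)):
            mean = ys[:, :n]
            cov = ys[:, n:].reshape(-1, n, n)
            cov = 0.5 * (cov + np.transpose(cov, (0, 2, 1)))
            return MomentTrajectory(times=times, mean=mean, cov=cov,
                                    names=model.species_names, system_size=omega)
        # fall through to the stiff-capable LSODA path

    t_end = float(times[-1])
    mean = np.empty((times.size, n))
    cov = np.empty((times.size, n, n))
    pos = 0
    y = y0
    smooth = input_shape == "smooth"
    if smooth:
        segments = [(0.0, t_end, k1)]
    elif T >= t_end:
        segments = [(0.0, t_end, k1)]
    else:
        segments = [(0.0, float(T), k1), (float(T), t_end, k10)]
    for seg_start, seg_end, u in segments:
        last = seg_end >= t_end
        mask = (times >= seg_start) & ((times <= seg_end) if last else (times < seg_end))
        seg_times = times[mask]
        grid = np.unique(np.concatenate(([seg_start], seg_times, [seg_end])))
        if smooth:
            args = (S, rates, r1, r2, input_idx, k1, k10, T, True, inv_omega)
        else:
            args = (S, rates, r1, r2, input_idx, u, u, np.inf, False, inv_omega)
        ys, info = odeint(
            lna_rhs, y, grid, args=args, rtol=rtol, atol=atol,
            full_output=True, mxstep=50_000,
        )
        if info["message"] != "Integration successful.":
            raise SolverError(f"LNA integration failed: {info['message']}", theta)
        sel = np.searchsorted(grid, seg_times)
        mean[pos : pos + seg_times.size] = ys[sel, :n]
        cov[pos : pos + seg_times.size] = ys[sel, n:].reshape(-1, n, n)
        pos += seg_times.size
        y = ys[-1]
    assert pos == times.size
    # symmetrize against integration round-off
    cov = 0.5 * (cov + np.transpose(cov, (0, 2, 1)))
    return MomentTrajectory(
        times=times, mean=mean, cov=cov,
        names=model.species_names, system_size=omega,
    )
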