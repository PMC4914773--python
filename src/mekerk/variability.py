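"""Source attribution of cell-to-cell variability: variance decomposition by
parameter group, posterior contributor ranking, and the lambda input-output
variability scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import WeightedParticles, weighted_quantile
from .models import ModelSpec
from .population import (
    HyperParams,
    population_observables,
    sample_cell_parameters,
    ut_propagate,
)

__all__ = [
    "PARAM_GROUPS",
    "group_names",
    "variance_by_group",
    "rank_contributors",
    "LambdaScanResult",
    "lambda_scan",
]

_RATE_NAMES = ("a1", "d1", "c1", "a2", "d2", "c2", "a3", "d3", "c3", "a4", "d4", "c4")

#: Named parameter subsets for the distributive model.  ``T_pulse`` is kept
#: out of the varying sets (it is held fixed across cells by default).
PARAM_GROUPS: dict[str, tuple[str, ...]] = {
    "upstream": ("k1", "k2", "k10"),
    "initial_conditions": ("E_tot", "P_tot", "M0", "Epp0"),
    "reaction_rates": _RATE_NAMES,
    "driving": ("k1", "k10"),
    "all": _RATE_NAMES + ("k1", "k2", "k10", "T_pulse", "E_tot", "P_tot", "M0", "Epp0"),
}


def group_names(group: str | tuple[str, ...]) -> tuple[str, ...]:
    if isinstance(group, str):
        try:
            return PARAM_GROUPS[group]
        except KeyError:
            raise KeyError(
                f"unknown group {group!r}; choose from {sorted(PARAM_GROUPS)}"
            ) from None
    return tuple(group)


def variance_by_group(
    model: ModelSpec,
    hyper: HyperParams,
    group: str | tuple[str, ...],
    times,
    engine: str = "ut",
    n_mc: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Observable variances when only ``group`` parameters vary across cells.

    Returns a tidy frame (time_min, group, var_ppMEK, var_ppERK).  The
    ``ut`` engine uses sigma-point propagation; ``mc`` draws ``n_mc`` cells
    and solves each deterministically.
    """
    names = group_names(group)
    if not names:
        raise ValueError("group must be nonempty")
    sub = hyper.restrict_to(names)
    times = np.asarray(times, dtype=float)
    if engine == "ut":
        mom = ut_propagate(model, sub, times)
        var = mom.var
    elif engine == "mc":
        cells = sample_cell_parameters(sub, n_mc, seed)
        obs = population_observables(model, cells, times)
        var = obs.var(axis=0, ddof=1)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    label = group if isinstance(group, str) else "+".join(names)
    return pd.DataFrame(
        {
            "time_min": times,
            "group": label,
            "var_ppMEK": var[:, 0],
            "var_ppERK": var[:, 1],
        }
    )


def rank_contributors(
    particles: WeightedParticles,
    cv_threshold: float = 0.05,
    interval: tuple[float, float] = (0.05, 0.95),
) -> pd.DataFrame:
    """Posterior CV summaries per parameter, ranked by lower credible bound.

    Expects hyperparameter particles whose names follow the ``mean_<p>`` /
    ``cv_<p>`` (or ``var_<p>``) convention produced by the extrinsic fit.
    A parameter is a significant contributor when the lower bound of its CV
    credible interval exceeds ``cv_threshold``.
    """
    lo_q, hi_q = interval
    rows = []
    names = particles.names
    w = particles.weights
    for j, name in enumerate(names):
        if name.startswith("cv_"):
            pname = name[3:]
            cv = particles.particles[:, j]
        elif name.startswith("var_"):
            pname = name[4:]
            mean_j = names.index(f"mean_{pname}")
            cv = np.sqrt(particles.particles[:, j]) / particles.particles[:, mean_j]
        else:
            continue
        lo, med, hi = weighted_quantile(cv, w, [lo_q, 0.5, hi_q])
        rows.append(
            {
                "parameter": pname,
                "cv_median": med,
                "cv_lo": lo,
                "cv_hi": hi,
                "significant": bool(lo > cv_threshold),
            }
        )
    if not rows:
        raise ValueError("no cv_/var_ hyperparameter columns among particle names")
    df = pd.DataFrame(rows).sort_values("cv_lo", ascending=False, kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


@dataclass
class LambdaScanResult:
    """Output-variability ratio lambda over a grid of input SDs.

    lambda(s_k1, s_k10, t) = s(s_k1, s_k10, t) / s(s*_k1, s*_k10, t), where
    s(.) is the population SD of total ppERK and the reference SDs equal the
    population means of k1 and k10 (the maximal input variability).
    """

    sigma_k1: np.ndarray
    sigma_k10: np.ndarray
    times: np.ndarray
    s_values: np.ndarray  # (n_k1, n_k10, n_times) output SDs
    lam: np.ndarray  # same shape
    mode: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s1 in enumerate(self.sigma_k1):
            for j, s10 in enumerate(self.sigma_k10):
                for k, t in enumerate(self.times):
                    rows.append(
                        (s1, s10, t, self.s_values[i, j, k], self.lam[i, j, k])
                    )
        return pd.DataFrame(
            rows, columns=["sigma_k1", "sigma_k10", "time_min", "s", "lambda"]
        )


def lambda_scan(
    model: ModelSpec,
    hyper: HyperParams,
    sigma_k1_grid,
    sigma_k10_grid,
    times,
    mode: str = "driving",
    engine: str = "mc",
    n_mc: int = 10_000,
    seed: int = 0,
) -> LambdaScanResult:
    """Scan the output SD of ppERK against the input variability levels.

    ``mode='driving'`` varies only k1 and k10 across cells (all other
    parameters pinned at their population means); ``mode='full'`` keeps all
    population variances of ``hyper`` and overrides only those of k1/k10.
    The reference point uses sigma*_k1 = mean(k1) and sigma*_k10 = mean(k10).
    """
    if mode not in ("driving", "full"):
        raise ValueError(f"unknown mode {mode!r}")
    times = np.asarray(times, dtype=float)
    s1_grid = np.asarray(sigma_k1_grid, dtype=float)
    s10_grid = np.asarray(sigma_k10_grid, dtype=float)
    mu_k1 = hyper.mean[hyper.index("k1")]
    mu_k10 = hyper.mean[hyper.index("k10")]
    if mu_k1 <= 0 or mu_k10 <= 0:
        raise ValueError("reference SDs (population means of k1, k10) must be > 0")
    if np.any(s1_grid <= 0) or np.any(s1_grid > mu_k1 + 1e-12):
        raise ValueError("sigma_k1 grid must lie in (0, mean_k1]")
    if np.any(s10_grid <= 0) or np.any(s10_grid > mu_k10 + 1e-12):
        raise ValueError("sigma_k10 grid must lie in (0, mean_k10]")

    base = hyper if mode == "full" else hyper.restrict_to(("k1", "k10"))

    def output_sd(s1: float, s10: float) -> np.ndarray:
        h = base.with_variance(k1=s1 * s1, k10=s10 * s10)
        if engine == "ut":
            return np.sqrt(ut_propagate(model, h, times).var[:, 1])
        cells = sample_cell_parameters(h, n_mc, seed)
        obs = population_observables(model, cells, times)
        return obs[:, :, 1].std(axis=0, ddof=1)

    s_ref = output_sd(mu_k1, mu_k10)
    if np.any(s_ref <= 0):
        raise ValueError("reference output SD vanished; lambda undefined")
    s_vals = np.empty((s1_grid.size, s10_grid.size, times.size))
    for i, s1 in enumerate(s1_grid):
        for j, s10 in enumerate(s10_grid):
            if s1 == mu_k1 and s10 == mu_k10:
                s_vals[i, j] = s_ref
            else:
                s_vals[i, j] = output_sd(s1, s10)
    return LambdaScanResult(
        sigma_k1=s1_grid,
        sigma_k10=s10_grid,
        times=times,
        s_values=s_vals,
        lam=s_vals / s_ref[None, None, :],
        mode=mode,
    )
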