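"""Descriptive snapshot statistics (variance / CV / Fano time courses) and a
KDE plug-in mutual-information estimator between ppMEK and ppERK.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .population import SnapshotData

__all__ = [
    "summary_stats",
    "bandwidth_rule",
    "kde_bandwidths",
    "mutual_information",
    "mi_series",
]

#: Normal-reference rule constant for the Gaussian-kernel bandwidth.
BANDWIDTH_CONSTANT = 1.06


def summary_stats(snapshot: SnapshotData) -> pd.DataFrame:
    """Per-time, per-observable mean, variance, CV and Fano factor.

    Uses the unbiased sample variance.  Time points with a single cell are
    flagged (``valid=False``) and their statistics omitted; CV and Fano are
    NaN-flagged where the mean is zero.
    """
    rows = []
    for t in snapshot.times:
        x, y = snapshot.at_time(t)
        for obs_name, v in (("ppMEK", x), ("ppERK", y)):
            if v.size < 2:
                rows.append(
                    {"time_min": t, "observable": obs_name, "n": v.size,
                     "mean": np.nan, "variance": np.nan, "cv": np.nan,
                     "fano": np.nan, "valid": False}
                )
                continue
            m = float(v.mean())
            var = float(v.var(ddof=1))
            cv = math.sqrt(var) / m if m != 0 else np.nan
            fano = var / m if m != 0 else np.nan
            rows.append(
                {"time_min": t, "observable": obs_name, "n": v.size,
                 "mean": m, "variance": var, "cv": cv, "fano": fano,
                 "valid": True}
            )
    return pd.DataFrame(rows)


def bandwidth_rule(sigma: float, n: int) -> float:
    """Normal-reference kernel bandwidth 1.06 * sigma * n^(-1/5)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    return BANDWIDTH_CONSTANT * sigma * n ** (-0.2)


def kde_bandwidths(samples: np.ndarray) -> float:
    """Kernel SD for a 1-D sample via the normal-reference rule.

    ``sigma`` is the sample standard deviation (the rule's scale parameter);
    zero-variance samples are rejected.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D sample with at least 2 points")
    sd = float(x.std(ddof=1))
    if sd <= 0:
        raise ValueError("sample has zero variance")
    return bandwidth_rule(sd, x.size)


def mutual_information(
    x: np.ndarray,
    y: np.ndarray,
    unit: str = "nats",
    log_transform: bool = False,
    chunk: int = 1024,
) -> float:
    """Plug-in KDE estimate of the mutual information between x and y.

    I_hat = (1/N) sum_i ln[ f_XY(x_i, y_i) / (f_X(x_i) f_Y(y_i)) ], with
    product-Gaussian-kernel density estimates whose per-marginal kernel SDs
    follow the normal-reference rule.  The raw value is returned (it may be
    slightly negative for independent data).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 paired samples")
    if unit not in ("nats", "bits"):
        raise ValueError(f"unknown unit {unit!r}")
    if log_transform:
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("log transform requires positive data")
        x, y = np.log(x), np.log(y)
    hx = kde_bandwidths(x)
    hy = kde_bandwidths(y)

    log_fx = np.empty(n)
    log_fy = np.empty(n)
    log_fxy = np.empty(n)
    norm_x = -0.5 * math.log(2 * math.pi) - math.log(hx)
    norm_y = -0.5 * math.log(2 * math.pi) - math.log(hy)
    log_n = math.log(n)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        dx = (x[start:stop, None] - x[None, :]) / hx
        dy = (y[start:stop, None] - y[None, :]) / hy
        lx = norm_x - 0.5 * dx * dx
        ly = norm_y - 0.5 * dy * dy
        # logsumexp over the sample axis
        from scipy.special import logsumexp

        log_fx[start:stop] = logsumexp(lx, axis=1) - log_n
        log_fy[start:stop] = logsumexp(ly, axis=1) - log_n
        log_fxy[start:stop] = logsumexp(lx + ly, axis=1) - log_n
    mi = float(np.mean(log_fxy - log_fx - log_fy))
    if unit == "bits":
        mi /= math.log(2.0)
    return mi


def mi_series(snapshot: SnapshotData, unit: str = "nats",
              log_transform: bool = False) -> pd.DataFrame:
    """Per-time mutual information between ppMEK and ppERK across cells."""
    rows = []
    for t in snapshot.times:
        x, y = snapshot.at_time(t)
        if x.size < 10 or x.std() == 0 or y.std() == 0:
            rows.append({"time_min": t, "mi": np.nan, "n": x.size,
                         "bandwidth_x": np.nan, "bandwidth_y": np.nan})
            continue
        rows.append(
            {
                "time_min": t,
                "mi": mutual_information(x, y, unit=unit, log_transform=log_transform),
                "n": x.size,
                "bandwidth_x": kde_bandwidths(np.log(x) if log_transform else x),
                "bandwidth_y": kde_bandwidths(np.log(y) if log_transform else y),
            }
        )
    return pd.DataFrame(rows)
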