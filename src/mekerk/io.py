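"""Snapshot CSV readers/writers, run configuration, and the end-to-end
pipeline orchestrator.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import (
    EvidenceResult,
    bayes_factor,
    centered_log_uniform,
    make_extrinsic_loglik,
    make_intrinsic_loglik,
    Prior,
    PriorComponent,
    smc_sample,
)
from .information import mi_series, summary_stats
from .models import build_distributive_model, build_processive_model
from .population import SnapshotData
from .synthetic import (
    AcquisitionDesign,
    default_times,
    generate_qic_dataset,
    reference_hyperparameters,
)
from .variability import PARAM_GROUPS, lambda_scan, rank_contributors, variance_by_group

__all__ = [
    "read_snapshot_csv",
    "write_snapshot_csv",
    "RunConfig",
    "run_pipeline",
    "write_json",
]

REQUIRED_COLUMNS = ("time_min", "cell_id", "ppMEK", "ppERK")

MODEL_BUILDERS = {
    "distributive": build_distributive_model,
    "processive": build_processive_model,
}

LIKELIHOODS = ("average", "intrinsic", "extrinsic")


def read_snapshot_csv(path) -> SnapshotData:
    """Read and validate a snapshot CSV.

    Required columns: time_min, cell_id, ppMEK, ppERK.  Unknown columns are
    preserved.  Negative intensities are a validation error naming the rows.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in ("time_min", "ppMEK", "ppERK"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()].tolist()
        if bad:
            raise ValueError(f"{path}: non-numeric values in {col!r} at rows {bad[:10]}")
        df[col] = vals
    neg = df.index[(df["ppMEK"] < 0) | (df["ppERK"] < 0)].tolist()
    if neg:
        raise ValueError(f"{path}: negative intensities at rows {neg[:10]}")
    extra = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    return SnapshotData(frame=df, metadata={"source": str(path), "extra_columns": extra})


def write_snapshot_csv(snapshot: SnapshotData, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    snapshot.frame.to_csv(path, index=False, float_format="%.17g")


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")


def _jsonify(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


@dataclass
class RunConfig:
    """Configuration of one end-to-end analysis run."""

    scenario: str = "extrinsic"  # fixture used when no data file is given
    data: str | None = None  # snapshot CSV path (overrides generation)
    model: str = "distributive"
    likelihoods: tuple[str, ...] = ("intrinsic", "extrinsic")
    cells_per_time: int = 200
    n_particles: int = 128
    ess_threshold: float = 0.5
    move_count: int = 2
    prior_decades: float = 2.0
    seed: int = 0
    out_dir: str = "mekerk_run"
    lambda_grid_size: int = 3
    lambda_n_mc: int = 1000
    mi_max_cells: int = 2000

    def validate(self) -> None:
        if self.model not in MODEL_BUILDERS:
            raise ValueError(f"unknown model {self.model!r}")
        for lik in self.likelihoods:
            if lik not in LIKELIHOODS:
                raise ValueError(f"unknown likelihood {lik!r}")
        if self.scenario not in ("extrinsic", "intrinsic", "driving_only"):
            raise ValueError(f"unknown scenario {self.scenario!r}")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        if "likelihoods" in data:
            data["likelihoods"] = tuple(data["likelihoods"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_toml(self, path) -> None:
        lines = []
        for key, val in asdict(self).items():
            if val is None:
                continue
            if isinstance(val, str):
                lines.append(f'{key} = "{val}"')
            elif isinstance(val, bool):
                lines.append(f"{key} = {str(val).lower()}")
            elif isinstance(val, (list, tuple)):
                body = ", ".join(f'"{v}"' if isinstance(v, str) else repr(v) for v in val)
                lines.append(f"{key} = [{body}]")
            else:
                lines.append(f"{key} = {val!r}")
        Path(path).write_text("\n".join(lines) + "\n")


def fit_snapshot(
    model,
    snapshot: SnapshotData,
    likelihood: str,
    fixture,
    config: RunConfig,
) -> tuple:
    """Run one SMC fit of a snapshot under the requested noise model."""
    center_theta = {n: fixture.hyper.mean[i]
                    for i, n in enumerate(fixture.hyper.param_names)}
    if likelihood == "intrinsic":
        # fix structural constants shared with the extrinsic fit's fixed set
        fixed = {"T_pulse": center_theta["T_pulse"]}
        names, ll = make_intrinsic_loglik(model, snapshot, fixed=fixed)
        center = {n: center_theta[n] for n in names if n != "omega"}
        center["omega"] = 100.0
        prior = centered_log_uniform(center, config.prior_decades)
    elif likelihood == "extrinsic":
        varying = tuple(
            n for i, n in enumerate(fixture.hyper.param_names) if fixture.hyper.varies[i]
        ) or ("k1", "k2", "k10", "M0", "Epp0")
        names, ll = make_extrinsic_loglik(model, snapshot, varying, fixture.hyper)
        comps = []
        for p in varying:
            m = center_theta[p]
            half = 10.0 ** (config.prior_decades / 2.0)
            comps.append(PriorComponent(f"mean_{p}", "log-uniform", m / half, m * half))
        for p in varying:
            comps.append(PriorComponent(f"cv_{p}", "log-uniform", 0.01, 2.0))
        prior = Prior(comps)
    else:
        raise ValueError(f"pipeline fitting for {likelihood!r} not supported")
    particles, evidence = smc_sample(
        ll,
        prior,
        n_particles=config.n_particles,
        ess_threshold=config.ess_threshold,
        move_count=config.move_count,
        seed=config.seed,
        model_id=f"{model.name}:{likelihood}",
    )
    return particles, evidence


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full variability-dissection workflow on one dataset.

    Fits the requested noise models by SMC, compares their evidences, ranks
    extrinsic contributors, decomposes variance by parameter group, and runs
    the MI and lambda analyses.  Writes a JSON report and per-stage CSVs
    under ``config.out_dir``; the run is reproducible from (config, seed).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = MODEL_BUILDERS[config.model]()
    fixture = reference_hyperparameters(config.scenario)
    report: dict = {"config": asdict(config), "stages": {}}

    if config.data:
        snapshot = read_snapshot_csv(config.data)
    else:
        design = AcquisitionDesign(
            times=default_times(), n_per_time=config.cells_per_time, seed=config.seed
        )
        snapshot = generate_qic_dataset(fixture, design)
        write_snapshot_csv(snapshot, out / "snapshot.csv")
    report["stages"]["data"] = {
        "n_rows": len(snapshot), "n_times": snapshot.times.size,
    }

    stats = summary_stats(snapshot)
    stats.to_csv(out / "summary_stats.csv", index=False)

    evidences: dict[str, EvidenceResult] = {}
    for lik in config.likelihoods:
        particles, evidence = fit_snapshot(model, snapshot, lik, fixture, config)
        particles.to_frame().to_csv(out / f"particles_{lik}.csv", index=False)
        evidences[lik] = evidence
        report["stages"][f"fit_{lik}"] = {
            "log_evidence": evidence.log_evidence,
            "mc_error": evidence.mc_error,
            "n_loglik_evals": evidence.n_loglik_evals,
            "n_temper_steps": len(particles.schedule),
        }
        if lik == "extrinsic":
            ranking = rank_contributors(particles)
            ranking.to_csv(out / "contributor_ranking.csv", index=False)
            report["stages"]["contributors"] = ranking.to_dict(orient="records")

    if "intrinsic" in evidences and "extrinsic" in evidences:
        bf, label = bayes_factor(evidences["extrinsic"], evidences["intrinsic"])
        report["stages"]["model_comparison"] = {
            "log_bf_extrinsic_vs_intrinsic": evidences["extrinsic"].log_evidence
            - evidences["intrinsic"].log_evidence,
            "label": label,
            "winner": "extrinsic" if bf > 1 else "intrinsic",
        }

    times = snapshot.times
    frames = [
        variance_by_group(model, fixture.hyper, g, times, engine="ut")
        for g in ("upstream", "initial_conditions", "reaction_rates", "driving", "all")
    ]
    pd.concat(frames).to_csv(out / "variance_by_group.csv", index=False)

    mi = mi_series(_subsample(snapshot, config.mi_max_cells, config.seed))
    mi.to_csv(out / "mi_series.csv", index=False)
    report["stages"]["mi"] = {"max": float(np.nanmax(mi["mi"].to_numpy()))}

    mu1 = fixture.hyper.mean[fixture.hyper.index("k1")]
    mu10 = fixture.hyper.mean[fixture.hyper.index("k10")]
    n_grid = config.lambda_grid_size
    grid1 = mu1 * np.linspace(1.0 / n_grid, 1.0, n_grid)
    grid10 = mu10 * np.linspace(1.0 / n_grid, 1.0, n_grid)
    scan = lambda_scan(
        model, fixture.hyper, grid1, grid10,
        times[times <= 20][:: max(1, times.size // 8)],
        mode="full" if config.scenario == "extrinsic" else "driving",
        n_mc=config.lambda_n_mc, seed=config.seed,
    )
    scan.to_frame().to_csv(out / "lambda_scan.csv", index=False)

    write_json(report, out / "report.json")
    return report


def _subsample(snapshot: SnapshotData, max_cells: int, seed: int) -> SnapshotData:
    if all(snapshot.n_cells(t) <= max_cells for t in snapshot.times):
        return snapshot
    rng = np.random.default_rng(seed)
    parts = []
    for t in snapshot.times:
        sub = snapshot.frame[snapshot.frame["time_min"] == t]
        if len(sub) > max_cells:
            sub = sub.iloc[np.sort(rng.choice(len(sub), max_cells, replace=False))]
        parts.append(sub)
    return SnapshotData(frame=pd.concat(parts, ignore_index=True),
                        metadata=dict(snapshot.metadata))
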