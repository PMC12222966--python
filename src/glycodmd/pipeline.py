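"""End-to-end experiment runners: reconstruction, prediction, classification.

Each runner consumes an :class:`ExperimentConfig`, simulates (or loads)
its inputs, executes the corresponding analysis and returns a plain-dict
report; artifacts are written as CSV/JSON with a provenance header
(config hash, master seed, package version).  A master seed fans out to
per-stage seeds through a fixed counter scheme
(``SeedSequence([master, stage_counter])``) so stages can be re-run
independently and the whole experiment is deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import classify_amplitudes, map_clusters_to_centroids
from .containers import TraceMatrix
from .diagnostics import embedding_scan
from .dmd import (
    build_hankel,
    cell_mode_amplitude_features,
    fit_exact_dmd,
    reconstruct,
)
from .errors import EmbeddingError
from .metrics import trace_fit_metrics
from .oscillators import (
    OscillatorParams,
    PopulationSpec,
    population_analytic_spectrum,
    simulate_population,
)

__all__ = [
    "ExperimentConfig",
    "run_reconstruction_experiment",
    "run_prediction_experiment",
    "run_classification_experiment",
]

log = logging.getLogger("glycodmd")

# stage counters for master-seed fan-out
_STAGE_SIMULATE = 0
_STAGE_CLUSTER = 2


@dataclass
class ExperimentConfig:
    """Configuration of one experiment family.

    ``kind``: 'reconstruction', 'prediction' or 'classification'.
    Population fields configure the synthetic cell population; embedding
    fields the Hankel DMD; prediction/clustering fields their respective
    sweeps.  Serializes to/from a flat YAML file.
    """

    kind: str = "reconstruction"
    # population
    n_cells: int = 100
    v_center: float = 14.5
    v_log_sd: float = 0.065
    v_conditions: tuple = (7.0, 10.0, 15.0)   # classification populations
    noise_sigma: float = 0.01
    n_hill: float = 3.0
    t_end: float = 30.0
    # embedding / truncation
    d_list: tuple = (10, 50, 100, 150)
    l: int = 1
    rank: int = 25
    # prediction sweep
    training_lengths: tuple = (200, 300, 400, 500)
    subsample_factors: tuple = (1, 2, 3)
    prediction_v: float = 12.9
    prediction_d: int = 150
    prediction_rank: int = 8
    prediction_replicates: int = 3
    stabilize_forecast: bool = True
    # classification
    cluster_k: int | None = 4
    cluster_d: int = 100
    cluster_rank: int = 50
    kernel: str = "rbf"
    # bookkeeping
    out_dir: str | None = None
    seed: int = 0
    trace_csvs: tuple = ()        # optional pre-extracted trace matrices

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def provenance(self) -> dict:
        return {"config_hash": self.config_hash(), "seed": self.seed,
                "version": __version__}

    def to_yaml(self, path: str | Path) -> None:
        obj = dataclasses.asdict(self)
        for key, val in obj.items():
            if isinstance(val, tuple):
                obj[key] = list(val)
        Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        obj = yaml.safe_load(Path(path).read_text())
        if not isinstance(obj, dict):
            raise ValueError(f"config file {path} is not a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, val in obj.items():
            if isinstance(val, list):
                obj[key] = tuple(val)
        cfg = cls(**obj)
        for csv in cfg.trace_csvs:
            if not Path(csv).exists():
                raise ValueError(f"referenced trace file missing: {csv}")
        return cfg


def _stage_seed(master: int, stage: int) -> int:
    return int(np.random.SeedSequence([master, stage]).generate_state(1)[0]
               % (2 ** 31))


def _population(config: ExperimentConfig, v_center: float | None = None,
                n_hill: float | None = None, n_cells: int | None = None,
                stage: int = _STAGE_SIMULATE):
    base = OscillatorParams(
        n_hill=config.n_hill if n_hill is None else n_hill,
        noise_sigma=config.noise_sigma, t_end=config.t_end)
    spec = PopulationSpec(
        n_cells=config.n_cells if n_cells is None else n_cells,
        v_log_mean=config.v_center if v_center is None else v_center,
        v_log_sd=config.v_log_sd, base=base,
        seed=_stage_seed(config.seed, stage))
    return simulate_population(spec), base


def _write_df(df: pd.DataFrame, path: Path, provenance: dict) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {json.dumps(provenance, sort_keys=True)}\n")
        df.to_csv(fh, index=False)


# ------------------------------------------------------------ experiments


def run_reconstruction_experiment(config: ExperimentConfig) -> dict:
    """Embedding-depth sweep on a simulated heterogeneous population.

    Simulates the population, runs Hankel DMD over ``d_list`` (at the
    configured delay step), and reports RMSE per depth, the eigenvalue
    spectra, the mean phase distance to the analytic spectrum, and raw
    vs reconstructed attractor coordinates (F6P against F16BP) for a few
    representative cells.
    """
    (f6p, f16bp, v_values), base = _population(config)
    params_list = [base.with_(v=float(v)) for v in v_values]
    analytic = population_analytic_spectrum(params_list, f6p.dt)
    records = embedding_scan(f6p, config.d_list, r=config.rank, l=config.l,
                             analytic=analytic)
    # attractor coordinates from a joint two-species fit at the deepest d
    d_best = records[-1]["d"] if records else 0
    joint = np.vstack([f6p.data, f16bp.data])
    model = fit_exact_dmd(build_hankel(joint, d=d_best, l=config.l,
                                       dt=f6p.dt), r=config.rank)
    recon = reconstruct(model)
    n = f6p.n_cells
    sel = sorted({0, min(9, n - 1), min(39, n - 1), min(84, n - 1)})
    attractors = {
        int(i): {
            "f6p_raw": f6p.data[i].tolist(),
            "f16bp_raw": f16bp.data[i].tolist(),
            "f6p_dmd": recon[i].tolist(),
            "f16bp_dmd": recon[n + i].tolist(),
        }
        for i in sel
    }
    report = {
        "kind": "reconstruction",
        "provenance": config.provenance(),
        "v_values": v_values.tolist(),
        "records": [
            {k: v for k, v in rec.items() if k not in ("model",)}
            for rec in records
        ],
        "attractors": attractors,
    }
    for rec in report["records"]:
        rec["eigenvalues"] = [[z.real, z.imag] for z in rec["eigenvalues"]]
        rec["residuals"] = np.asarray(rec["residuals"]).tolist()
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table = pd.DataFrame(
            [{"d": r["d"], "l": r["l"], "rank": r["r"], "rmse": r["rmse"],
              "r2": r["r2"],
              "accepted_fraction": r["accepted_fraction"],
              "phase_distance_mean": r.get("phase_distance_mean")}
             for r in report["records"]])
        _write_df(table, out / "rmse_vs_d.csv", config.provenance())
        (out / "report.json").write_text(json.dumps(report, sort_keys=True))
    return report


def _stabilized(model):
    """Project unstable eigenvalues onto the unit circle for forecasting."""
    lam = model.eigenvalues
    model.eigenvalues = np.where(np.abs(lam) > 1.0, lam / np.abs(lam), lam)
    return model


def _subsampled_prediction(avg: np.ndarray, dt: float, n_train: int,
                           factor: int, d: int, r: int, test_start: int,
                           stabilize: bool) -> dict | None:
    """Train on the subsampled prefix covering ``n_train`` original points,
    score R2 on the training window and on the fixed held-out segment
    starting at ``test_start`` (original-sample index)."""
    series = avg[::factor]
    split = n_train // factor
    # keep the embedding shallower than half the training window
    d_eff = max(1, min(d // factor, split // 2))
    if split <= d_eff + 2:
        return None
    train = series[:split]
    try:
        emb = build_hankel(train[None, :], d=d_eff, l=1, dt=dt * factor)
    except EmbeddingError:
        return None
    r_eff = min(r, min(emb.H.shape[0], emb.H.shape[1] - 1))
    model = fit_exact_dmd(emb, r=r_eff)
    if stabilize:
        _stabilized(model)
    recon = reconstruct(model, np.arange(series.size))[0]
    ts = test_start // factor
    train_fit = trace_fit_metrics(train, recon[:split])
    test_fit = trace_fit_metrics(series[ts:], recon[ts:])
    return {
        "n_train": n_train, "factor": factor, "d": d_eff, "rank": r_eff,
        "r2_train": train_fit.r2, "r2_test": test_fit.r2,
        "rmse_test": test_fit.rmse,
    }


def run_prediction_experiment(config: ExperimentConfig) -> dict:
    """Forecasting benchmark on population-averaged damped traces.

    For each of ``prediction_replicates`` independently simulated fields,
    cells at ``prediction_v`` (a weakly damped influx, so the held-out
    window still oscillates) are averaged into one trace; the training
    prefix length and sampling factor are swept, and every setting is
    scored on the training window and on a fixed held-out segment that
    starts after the longest training window, so all settings forecast the
    same target data.  Unstable eigenvalues are projected onto the unit
    circle before forecasting when ``stabilize_forecast`` is set.
    Training windows too short for the embedding are skipped with a note.
    """
    averages = []
    for rep_idx in range(config.prediction_replicates):
        (f6p, _, _), _ = _population(
            config, v_center=config.prediction_v,
            stage=_STAGE_SIMULATE + 100 + rep_idx)
        averages.append((f6p.data.mean(axis=0), f6p.dt))
    series_len = averages[0][0].size
    feasible = [t for t in config.training_lengths if t < series_len - 2]
    if not feasible:
        raise ValueError("no training length fits the simulated series")
    test_start = int(max(feasible))
    replicate_rows: list[dict] = []
    skipped = []
    for rep_idx, (avg, _dt) in enumerate(averages):
        for n_train in config.training_lengths:
            if n_train not in feasible:
                skipped.append({"n_train": n_train,
                                "reason": "exceeds series length"})
                continue
            for factor in config.subsample_factors:
                rec = _subsampled_prediction(
                    avg, _dt, int(n_train), int(factor),
                    config.prediction_d, config.prediction_rank,
                    test_start, config.stabilize_forecast)
                if rec is None:
                    skipped.append({"n_train": n_train, "factor": factor,
                                    "reason": "window shorter than embedding"})
                else:
                    rec["replicate"] = rep_idx
                    replicate_rows.append(rec)
    rows = []
    for n_train in config.training_lengths:
        for factor in config.subsample_factors:
            sub = [r for r in replicate_rows
                   if r["n_train"] == n_train and r["factor"] == factor]
            if sub:
                rows.append({
                    "n_train": int(n_train), "factor": int(factor),
                    "d": sub[0]["d"], "rank": sub[0]["rank"],
                    "r2_train": float(np.mean([r["r2_train"] for r in sub])),
                    "r2_test": float(np.mean([r["r2_test"] for r in sub])),
                    "rmse_test": float(np.mean([r["rmse_test"] for r in sub])),
                    "n_replicates": len(sub),
                })
    report = {
        "kind": "prediction",
        "provenance": config.provenance(),
        "test_start": test_start,
        "results": rows,
        "replicates": replicate_rows,
        "skipped": skipped,
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_df(pd.DataFrame(rows), out / "prediction_sweep.csv",
                  config.provenance())
        (out / "report.json").write_text(json.dumps(report, sort_keys=True))
    return report


def run_classification_experiment(config: ExperimentConfig,
                                  centroids: np.ndarray | None = None
                                  ) -> dict:
    """Condition-mixture classification from DMD amplitude features.

    Simulates one population per entry of ``v_conditions`` (or loads the
    trace CSVs listed in the config), concatenates them, fits Hankel DMD
    (defaults d = 100, r = 50), builds per-cell amplitude features and
    clusters them; emits the cluster report, the composition table and,
    when centroids are available, the overlay records.
    """
    if config.trace_csvs:
        matrices = [TraceMatrix.from_csv(p) for p in config.trace_csvs]
        for m in matrices:
            if all(c == "" for c in m.conditions):
                raise ValueError(
                    f"trace matrix lacks condition labels: {m.meta}")
    else:
        matrices = []
        for idx, v in enumerate(config.v_conditions):
            (f6p, _, _), _ = _population(
                config, v_center=float(v), stage=_STAGE_SIMULATE + 10 + idx)
            f6p.conditions = [f"v={v:g}" for _ in range(f6p.n_cells)]
            matrices.append(f6p)
    combined = TraceMatrix.concatenate(matrices)
    emb = build_hankel(combined, d=config.cluster_d, l=config.l)
    model = fit_exact_dmd(emb, r=config.cluster_rank)
    features = cell_mode_amplitude_features(model)
    report_obj = classify_amplitudes(
        features, combined.conditions, k=config.cluster_k,
        seed=_stage_seed(config.seed, _STAGE_CLUSTER), kernel=config.kernel)
    if centroids is None and combined.centroids is not None:
        centroids = combined.centroids
    overlay = (map_clusters_to_centroids(report_obj.labels, centroids)
               if centroids is not None else None)
    report = {
        "kind": "classification",
        "provenance": config.provenance(),
        "k": report_obj.k,
        "labels": report_obj.labels.tolist(),
        "conditions": combined.conditions,
        "silhouette": {str(k): v for k, v in report_obj.silhouette.items()},
        "composition": json.loads(report_obj.composition.to_json()),
        "weak_structure": max(report_obj.silhouette.values()) < 0.5,
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report_obj.meta.update(config.provenance())
        report_obj.to_json(out / "cluster_report.json")
        comp = report_obj.composition.reset_index()
        _write_df(comp, out / "composition.csv", config.provenance())
        if overlay is not None:
            _write_df(overlay, out / "overlay.csv", config.provenance())
        (out / "report.json").write_text(json.dumps(report, sort_keys=True))
    if overlay is not None:
        report["overlay"] = overlay.to_dict(orient="list")
    return report
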