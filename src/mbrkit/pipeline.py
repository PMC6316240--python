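"""End-to-end campaign pipeline: design -> simulate -> preprocess -> diagnose
-> predict -> optimize, with config handling, CSV interchange and a
provenance manifest.

The long-format measurement CSV (``run_id, time_h, variable, value,
replicate, censored``) is the interchange format for all stages; every file
written by :func:`run_pipeline` is recorded in a manifest with its SHA-256
hash, so identical config + seed reproduce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design as design_mod
from . import simulate as sim_mod
from .diagnostics import characterize_clusters, cluster_scores, detect_outliers, fit_pca
from .optimization import extract_optimal_paths, fit_regression_tree, superimpose_targets
from .preprocess import autoscale, batch_wise_unfold, grid_campaign
from .prediction import build_candidates, forward_select_variables, history_sweep

log = logging.getLogger("mbrkit")

__all__ = [
    "PipelineConfig",
    "CampaignReport",
    "run_pipeline",
    "read_measurements",
    "write_measurements",
    "write_unfolded",
]

#: variables of the diagnostics (PCA) block — product activity excluded
PCA_VARIABLES = ("biomass", "glucose", "ethanol", "pH", "DOT", "volume", "base")
#: process variables offered to the PLSR soft sensor
PLSR_VARIABLES = ("biomass", "glucose", "ethanol", "pH", "DOT", "volume")


@dataclass
class PipelineConfig:
    """Serializable configuration of the full pipeline."""

    seed: int = 0
    design: str = "packaged_table1"
    replicates: int = 3
    t_end: float = 48.0
    dt: float = 1.0 / 240.0
    grid_step: float = 2.0
    early_time: float = 26.0  # early target time, h
    late_time: float = 40.0  # late target time, h
    diag_window: tuple = (0.0, 12.0)  # h relative to feed start (first feed phase)
    folds: int = 10
    sweep_horizons: tuple = (16.0, 26.0, 40.0)
    failure_run: int | None = 46
    outlier_alpha: float = 0.01
    n_clusters: int = 2  # after outlier removal
    min_leaf: int = 6
    slack: float = 0.15
    params_override: dict = field(default_factory=dict)
    out_dir: str = "mbr_out"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sweep_horizons"] = list(self.sweep_horizons)
        d["diag_window"] = list(self.diag_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sweep_horizons" in d:
            d["sweep_horizons"] = tuple(float(h) for h in d["sweep_horizons"])
        if "diag_window" in d:
            d["diag_window"] = tuple(float(h) for h in d["diag_window"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# measurement CSV interchange

_MEAS_COLUMNS = ["run_id", "time_h", "variable", "value", "replicate", "censored"]


def write_measurements(table: pd.DataFrame, path) -> None:
    missing = [c for c in _MEAS_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table missing columns {missing}")
    table[_MEAS_COLUMNS].to_csv(path, index=False)


def read_measurements(path) -> pd.DataFrame:
    """Read and validate a long-format measurement CSV.

    Rejects unknown variable names and malformed numeric fields (including
    locale-style decimal commas), reporting offending line numbers.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _MEAS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad_lines = []
    for col in ("time_h", "value"):
        num = pd.to_numeric(df[col], errors="coerce")
        bad = num.isna()
        bad_lines.extend((df.index[bad] + 2).tolist())  # +2: header + 1-based
        df[col] = num
    if bad_lines:
        raise ValueError(
            f"{path}: malformed numeric values at lines {sorted(set(bad_lines))}"
        )
    unknown = sorted(set(df["variable"]) - set(sim_mod.MEASURED_VARIABLES))
    if unknown:
        raise ValueError(f"{path}: unknown variable names {unknown}")
    df["run_id"] = pd.to_numeric(df["run_id"], errors="raise").astype(int)
    df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype(int)
    df["censored"] = df["censored"].astype(str).str.lower().isin(("true", "1"))
    return df[_MEAS_COLUMNS]


def write_unfolded(m, path) -> None:
    """CSV with a two-line header: variable row, then grid-time row."""
    with open(path, "w") as fh:
        fh.write("run_id," + ",".join(v for v, _ in m.columns) + "\n")
        fh.write("time_h," + ",".join(f"{t:g}" for _, t in m.columns) + "\n")
        for rid, row in zip(m.run_ids, m.values):
            fh.write(str(rid) + "," + ",".join(f"{x:.10g}" for x in row) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# the pipeline


@dataclass
class CampaignReport:
    """In-memory results of a pipeline execution plus the output manifest."""

    config: PipelineConfig
    campaign: object
    pca: object = None
    outliers: object = None
    clusters: object = None
    cluster_tree: object = None
    selection: object = None
    sweep: object = None
    optimal_paths: dict = field(default_factory=dict)
    superposition: object = None
    manifest: dict = field(default_factory=dict)
    skipped: list = field(default_factory=list)


def _target_values(gridded: dict, variable: str, t: float) -> pd.Series:
    vals = {}
    for rid, df in gridded.items():
        idx = np.argmin(np.abs(df.index.to_numpy(float) - t))
        vals[rid] = float(df[variable].iloc[idx])
    return pd.Series(vals)


def run_pipeline(config: PipelineConfig, write: bool = True) -> CampaignReport:
    """Execute every stage of the campaign pipeline for one config.

    Stage outputs are written under ``config.out_dir`` and recorded in a
    manifest (file -> SHA-256).  Degenerate inputs degrade gracefully: with
    fewer than 5 runs outlier detection and clustering are skipped and noted
    in ``report.skipped``.
    """
    t_start = time.time()
    cfg = config
    report = CampaignReport(config=cfg, campaign=None)
    out = Path(cfg.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)

    # --- design + simulation ------------------------------------------
    if cfg.design == "packaged_table1":
        table = design_mod.load_design_table()
    else:
        table = design_mod.load_design_table(cfg.design)
    params = sim_mod.KineticParams(**cfg.params_override)
    log.info("simulating campaign: %d conditions x %d replicates",
             len(table), cfg.replicates)
    campaign = sim_mod.generate_campaign(
        table, params, seed=cfg.seed, replicates=cfg.replicates,
        t_end=cfg.t_end, dt=cfg.dt, failure_run=cfg.failure_run,
    )
    report.campaign = campaign
    factors = campaign.design_factors()

    # --- preprocessing -------------------------------------------------
    gridded_diag = grid_campaign(
        campaign, variables=PCA_VARIABLES, grid_step=cfg.grid_step,
        horizon=cfg.t_end,
    )
    gridded_target = grid_campaign(
        campaign, variables=("EAv", "ethanol"), grid_step=cfg.grid_step,
        horizon=cfg.t_end, normalize=False,
    )

    # --- diagnostics ----------------------------------------------------
    # feed-start-aligned window: lines up the feeding responses of runs with
    # different batch lengths before PCA
    gridded_aligned = grid_campaign(
        campaign, variables=PCA_VARIABLES, grid_step=cfg.grid_step,
        align="feed_start", grid_start=cfg.diag_window[0],
        horizon=cfg.diag_window[1],
    )
    n_runs = len(campaign.run_ids)
    kept_runs = list(campaign.run_ids)
    if n_runs >= 5:
        unfolded = batch_wise_unfold(gridded_aligned)
        pca = fit_pca(autoscale(unfolded))
        report.pca = pca
        report.outliers = detect_outliers(pca, alpha=cfg.outlier_alpha)
        flagged = set(report.outliers.flagged_runs())
        kept_runs = [r for r in campaign.run_ids if r not in flagged]
        if len(kept_runs) > cfg.n_clusters + 2:
            sub = autoscale(unfolded.drop_runs(flagged))
            pca2 = fit_pca(sub)
            report.clusters = cluster_scores(pca2, k=cfg.n_clusters,
                                             seed=cfg.seed)
            report.cluster_tree = characterize_clusters(
                report.clusters.assignments, factors)
        else:
            report.skipped.append("clustering: too few runs")
    else:
        report.skipped.append("outlier detection and clustering: <5 runs")

    # --- prediction -----------------------------------------------------
    y_late = _target_values(gridded_target, "EAv", cfg.late_time)
    pred_runs = [r for r in kept_runs if y_late[r] > 0]
    if len(pred_runs) >= cfg.folds:
        unfolded_pred = batch_wise_unfold(
            {r: gridded_diag[r] for r in pred_runs},
            variables=list(PLSR_VARIABLES), horizon=cfg.early_time,
        )
        cands = build_candidates(autoscale(unfolded_pred), factors)
        report.selection = forward_select_variables(
            cands, y_late.loc[unfolded_pred.run_ids], folds=cfg.folds,
            seed=cfg.seed,
        )
        full = batch_wise_unfold(
            {r: gridded_diag[r] for r in pred_runs},
            variables=list(PLSR_VARIABLES), horizon=cfg.t_end,
        )
        report.sweep = history_sweep(
            autoscale(full), y_late.loc[full.run_ids], cfg.sweep_horizons,
            design_factors=factors, folds=cfg.folds, seed=cfg.seed,
        )
    else:
        report.skipped.append("prediction: fewer runs than folds")

    # --- optimization ---------------------------------------------------
    conditions = (
        factors.reset_index()
        .drop_duplicates("condition_id")
        .set_index("condition_id")[["profile", "mu_set", "S0", "hunger_h"]]
    )
    targets = {
        "ethanol_early": ("ethanol", cfg.early_time, "minimize"),
        "ethanol_late": ("ethanol", cfg.late_time, "minimize"),
        "EAv_early": ("EAv", cfg.early_time, "maximize"),
        "EAv_late": ("EAv", cfg.late_time, "maximize"),
    }
    categories = {"profile": set(conditions["profile"].unique())}
    min_runs = 2 * cfg.min_leaf
    paths_by_target = {}
    for name, (var, tt, direction) in targets.items():
        vals = _target_values(gridded_target, var, tt).loc[kept_runs]
        if len(vals) < min_runs:
            report.skipped.append(f"optimization {name}: too few runs")
            continue
        tree = fit_regression_tree(factors.loc[kept_runs], vals,
                                   min_leaf=cfg.min_leaf)
        paths_by_target[name] = extract_optimal_paths(
            tree, direction=direction, slack=cfg.slack, categories=categories)
    report.optimal_paths = paths_by_target
    if len(paths_by_target) == len(targets):
        report.superposition = superimpose_targets(paths_by_target, conditions)

    # --- outputs --------------------------------------------------------
    if write:
        files: dict[str, str] = {}

        def _write(name: str, writer) -> None:
            p = out / name
            writer(p)
            files[name] = _sha256(p)

        _write("measurements.csv",
               lambda p: write_measurements(campaign.measurements, p))
        _write("schedules.csv",
               lambda p: design_mod.schedule_to_frame(campaign.schedules)
               .to_csv(p, index=False))
        if report.pca is not None:
            scores = pd.DataFrame(
                report.pca.scores_,
                index=report.pca.run_ids_,
                columns=[f"PC{i+1}" for i in range(report.pca.n_components_)],
            )
            scores["t2"] = report.outliers.t2
            scores["outlier"] = report.outliers.flags
            _write("pca_scores.csv", lambda p: scores.to_csv(p, index_label="run_id"))
        if report.clusters is not None:
            cl = pd.Series(report.clusters.assignments, name="cluster")
            _write("clusters.csv", lambda p: cl.to_csv(p, index_label="run_id"))
            _write("cluster_tree.txt", lambda p: Path(p).write_text(
                "\n".join(report.cluster_tree.rules()) + "\n"))
        if report.selection is not None:
            sel = pd.DataFrame({
                "step": range(1, len(report.selection.selected) + 1),
                "candidate": [str(c) for c in report.selection.selected],
                "mean_rmsecv": report.selection.rmsecv_trace,
            })
            _write("variable_selection.csv", lambda p: sel.to_csv(p, index=False))
        if report.sweep is not None:
            _write("history_sweep.csv",
                   lambda p: report.sweep.to_frame().to_csv(p, index=False))
        if paths_by_target:
            rows = []
            for tgt, paths in paths_by_target.items():
                for path_ in paths:
                    cons = path_.constraints
                    def _fmt(f):
                        kind, c = cons[f]
                        if kind == "any":
                            return "-"
                        if kind == "interval":
                            lo, hi = c
                            return (f"({lo:g},{hi:g}]" if np.isfinite(lo) and np.isfinite(hi)
                                    else f"<= {hi:g}" if np.isfinite(hi)
                                    else f"> {lo:g}")
                        return "/".join(sorted(map(str, c)))
                    rows.append((tgt, _fmt("mu_set"), _fmt("profile"),
                                 _fmt("S0"), _fmt("hunger_h"),
                                 path_.n_runs, path_.mean, path_.sd))
            t3 = pd.DataFrame(rows, columns=[
                "target", "feed_rate", "profile", "S0", "hunger",
                "n_runs", "mean", "sd"])
            _write("optimal_conditions.csv", lambda p: t3.to_csv(p, index=False))
        if report.superposition is not None:
            sp = report.superposition
            payload = {
                "per_target_conditions": {
                    k: sorted(int(c) for c in v)
                    for k, v in sp.per_target_conditions.items()},
                "intersection": sorted(int(c) for c in sp.intersection),
                "common_levels": {k: (v if isinstance(v, str) else float(v))
                                  for k, v in sp.common_levels.items()},
            }
            _write("superposition.json", lambda p: Path(p).write_text(
                json.dumps(payload, indent=2, sort_keys=True) + "\n"))
        manifest = {
            "config": cfg.to_dict(),
            "files": files,
            "skipped": report.skipped,
            "n_runs": n_runs,
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        report.manifest = manifest
    log.info("pipeline done in %.1f s", time.time() - t_start)
    return report
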