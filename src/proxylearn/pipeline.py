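"""End-to-end pipeline: simulate -> fit -> select -> retention -> stats -> report.

Each stage reads its inputs from, and writes delimited-text outputs to, the
configured output directory, so stages can be run individually from the CLI
and re-runs can resume from cached intermediates. One global seed
deterministically derives a child seed per stage through
``numpy.random.SeedSequence(seed).spawn``; with a fixed seed the whole run
is bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .fitting import FitConfig, MultiRateModel, ProxyProcessModel, WashoutDecayModel
from .io import PipelineConfig, read_trial_table, write_trial_table
from .selection import cross_validate
from .simulate import generate_dataset
from .stats import WeightedSample, default_weights, parameter_table, washout_table
from .structures import ProxyModelParams, get_spec, steady_state_error

__all__ = ["STAGES", "RunManifest", "run_pipeline"]

STAGES = ("simulate", "fit", "select", "retention", "stats", "report")

_CURVE_KEYS = ["subject", "task", "direction"]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stage_seeds: Dict[str, int]
    version: str = __version__
    stages: List[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "stage_seeds": self.stage_seeds,
                "version": self.version,
                "stages": self.stages,
            },
            indent=2,
        )

    def write(self, outdir: Path) -> None:
        (outdir / "manifest.json").write_text(self.to_json() + "\n")


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage_seeds(seed: int) -> Dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {name: int(c.generate_state(1)[0] % (2**31))
            for name, c in zip(STAGES, children)}


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, lineterminator="\n")


def _stage_simulate(config: PipelineConfig, outdir: Path, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    df = generate_dataset(
        design=config.design,
        ground_truth=config.resolved_ground_truth(),
        washout_tau=config.resolved_washout_tau(),
        rng=rng,
    )
    write_trial_table(df, outdir / "trials.csv")
    return {"rows": len(df), "outputs": ["trials.csv"]}


def _iter_learning_curves(trials: pd.DataFrame):
    learning = trials[trials["phase"] == "learning"]
    yield from learning.groupby(_CURVE_KEYS, sort=True)


def _stage_fit(config: PipelineConfig, outdir: Path, seed: int) -> dict:
    trials = read_trial_table(outdir / "trials.csv")
    fit_cfg = FitConfig(n_starts=config.n_starts, seed=seed)
    spec = get_spec("2.1")
    rows = []
    for (s, t, d), curve in _iter_learning_curves(trials):
        res = ProxyProcessModel.from_curve(curve, spec).fit(fit_cfg)
        first = curve.loc[curve["trial"] == 0].iloc[0]
        rows.append({
            "subject": s, "task": t, "direction": d,
            "ea_gain": int(first["ea_gain"]), "ea_offset": int(first["ea_offset"]),
            "e0": res.model.e0,
            **{k: v for k, v in res.params.as_dict().items()},
            "sse": res.sse, "rmse": res.rmse, "r2": res.rsquared,
            "r2adj": res.rsquared_adj, "diverged": res.diverged,
        })
    df = pd.DataFrame(rows)
    _write_csv(df, outdir / "proxy_fits.csv")
    return {"rows": len(df), "outputs": ["proxy_fits.csv"]}


def _stage_select(config: PipelineConfig, outdir: Path, seed: int) -> dict:
    trials = read_trial_table(outdir / "trials.csv")
    fit_cfg = FitConfig(n_starts=config.n_starts, seed=seed)
    outputs = []
    n_rows = 0
    for grouping in ("subjects", "tasks"):
        report = cross_validate(trials, grouping=grouping, specs=config.cv_specs,
                                config=fit_cfg, alpha=config.cv_alpha)
        _write_csv(report.partition_values, outdir / f"cv_{grouping}_rmse.csv", index=True)
        _write_csv(report.matrix, outdir / f"cv_{grouping}_matrix.csv", index=True)
        (outdir / f"cv_{grouping}_summary.txt").write_text(report.summary() + "\n")
        outputs += [f"cv_{grouping}_rmse.csv", f"cv_{grouping}_matrix.csv",
                    f"cv_{grouping}_summary.txt"]
        n_rows += report.partition_values.size
    return {"rows": n_rows, "outputs": outputs}


def _stage_retention(config: PipelineConfig, outdir: Path, seed: int) -> dict:
    trials = read_trial_table(outdir / "trials.csv")
    proxy = pd.read_csv(outdir / "proxy_fits.csv")
    fit_cfg = FitConfig(n_starts=config.n_starts, seed=seed)
    proxy = proxy.set_index(_CURVE_KEYS)
    rows = []
    for (s, t, d), curve in _iter_learning_curves(trials):
        p = proxy.loc[(s, t, d)]
        params = ProxyModelParams.from_dict(
            "2.1", a=p["a"], b1=p["b1"], b2=p["b2"], sigma=p["sigma"]
        )
        res = MultiRateModel.from_curve(curve, params).fit(fit_cfg)
        rows.append({
            "subject": s, "task": t, "direction": d,
            "ea_gain": int(p["ea_gain"]), "ea_offset": int(p["ea_offset"]),
            **res.params.as_dict(),
            "sse": res.sse, "rmse": res.rmse, "r2": res.rsquared,
            "diverged": res.diverged,
        })
    df = pd.DataFrame(rows)
    _write_csv(df, outdir / "dpxmrml_fits.csv")
    return {"rows": len(df), "outputs": ["dpxmrml_fits.csv"]}


def _samples_by_coord(df: pd.DataFrame, column: str) -> Dict[tuple, WeightedSample]:
    out = {}
    for (g, o), grp in df.groupby(["ea_gain", "ea_offset"]):
        out[(int(g), int(o))] = WeightedSample(
            grp[column].to_numpy(dtype=float),
            default_weights(np.maximum(grp["rmse"].to_numpy(dtype=float), 1e-12)),
            (int(g), int(o)),
        )
    return out


def _stage_stats(config: PipelineConfig, outdir: Path, seed: int) -> dict:
    proxy = pd.read_csv(outdir / "proxy_fits.csv")
    mr_path = outdir / "dpxmrml_fits.csv"
    mr = pd.read_csv(mr_path) if mr_path.exists() else None
    B = config.bootstrap_B
    alpha = config.stats_alpha
    tables = []

    plan = [("a", 0.0), ("b1", 0.0), ("b2", 0.0), ("sigma", config.sigma_null)]
    for i, (param, null) in enumerate(plan):
        tbl = parameter_table(_samples_by_coord(proxy, param), null_value=null,
                              alpha=alpha, B=B, seed=seed + i)
        tbl.insert(0, "table", f"proxy_{param}")
        tables.append(tbl.reset_index())

    # steady-state errors implied by the fitted second-order coefficients
    ss_rows = []
    for _, row in proxy.iterrows():
        params = ProxyModelParams.from_dict("2.1", a=row["a"], b1=row["b1"],
                                            b2=row["b2"], sigma=0.0)
        ss = steady_state_error(params.spec, params, row["e0"],
                                n=config.design.n_trials)
        if not ss.diverged:
            ss_rows.append({"ea_gain": row["ea_gain"], "ea_offset": row["ea_offset"],
                            "value": ss.value, "rmse": row["rmse"]})
    if ss_rows:
        ssdf = pd.DataFrame(ss_rows)
        tbl = parameter_table(_samples_by_coord(ssdf, "value"), null_value=0.0,
                              alpha=alpha, B=B, seed=seed + 10)
        tbl.insert(0, "table", "steady_state")
        tables.append(tbl.reset_index())

    if mr is not None and not mr.empty:
        mr_plan = [("Bf", 0.0), ("Bs", 0.0), ("Af", -1.0), ("Af", 0.0),
                   ("As", 1.0), ("As", 0.0)]
        for i, (param, null) in enumerate(mr_plan):
            tbl = parameter_table(_samples_by_coord(mr, param), null_value=null,
                                  alpha=alpha, B=B, seed=seed + 20 + i)
            tbl.insert(0, "table", f"mr_{param}_vs_{null:g}")
            tables.append(tbl.reset_index())

    combined = pd.concat(tables, ignore_index=True)
    _write_csv(combined, outdir / "stats_tables.csv")
    return {"rows": len(combined), "outputs": ["stats_tables.csv"]}


def _stage_report(config: PipelineConfig, outdir: Path, seed: int) -> dict:
    trials = read_trial_table(outdir / "trials.csv")
    fit_cfg = FitConfig(n_starts=min(config.n_starts, 25), seed=seed)
    washout = trials[trials["phase"] == "washout"]
    rows = []
    for (s, g, o), grp in washout.groupby(["subject", "ea_gain", "ea_offset"]):
        # per-subject average magnitude profile over washout trials
        mags = grp.groupby("trial")["error"].apply(lambda e: float(np.mean(np.abs(e))))
        if mags.size < 3:
            continue
        # offset term absorbs the non-zero mean of the magnitude noise floor
        fit = WashoutDecayModel(mags.to_numpy(), offset=True).fit(fit_cfg)
        rows.append({"subject": s, "ea_gain": int(g), "ea_offset": int(o),
                     "amplitude": fit.amplitude, "tau": fit.tau, "sse": fit.sse,
                     "flagged": fit.flagged})
    wdf = pd.DataFrame(rows)
    outputs = []
    if not wdf.empty:
        _write_csv(wdf, outdir / "washout_fits.csv")
        outputs.append("washout_fits.csv")
        ok = wdf[~wdf["flagged"] & np.isfinite(wdf["tau"])]
        by_coord = {
            (int(g), int(o)): WeightedSample(grp["tau"].to_numpy(dtype=float),
                                             label=(int(g), int(o)))
            for (g, o), grp in ok.groupby(["ea_gain", "ea_offset"])
            if len(grp) > 0
        }
        if len(by_coord) >= 2:
            tbl = washout_table(by_coord, alpha=config.stats_alpha,
                                B=config.bootstrap_B, seed=seed)
            _write_csv(tbl.reset_index(), outdir / "washout_table.csv")
            outputs.append("washout_table.csv")

    lines = [f"proxylearn pipeline report (seed {config.seed})"]
    for name in ("cv_subjects_summary.txt", "cv_tasks_summary.txt"):
        p = outdir / name
        if p.exists():
            lines += ["", p.read_text().rstrip()]
    if not wdf.empty:
        med = wdf.groupby(["ea_gain", "ea_offset"])["tau"].median()
        lines += ["", "washout time-constant medians (trials):"]
        for (g, o), v in med.items():
            lines.append(f"  EA{{gain {g}, offset {o}}}: {v:.3g}")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    outputs.append("summary.txt")
    return {"rows": len(wdf), "outputs": outputs}


_STAGE_OUTPUTS = {
    "simulate": ["trials.csv"],
    "fit": ["proxy_fits.csv"],
    "select": ["cv_subjects_summary.txt", "cv_tasks_summary.txt"],
    "retention": ["dpxmrml_fits.csv"],
    "stats": ["stats_tables.csv"],
    "report": ["summary.txt"],
}

_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "fit": _stage_fit,
    "select": _stage_select,
    "retention": _stage_retention,
    "stats": _stage_stats,
    "report": _stage_report,
}


def run_pipeline(
    config: PipelineConfig,
    stages: Optional[List[str]] = None,
    resume: bool = False,
) -> RunManifest:
    """Run the pipeline stages in order, writing outputs and a manifest.

    ``stages`` restricts the run (prerequisite files must already exist in
    the output directory); with ``resume`` a stage whose outputs all exist
    is skipped. Any stage failure aborts with the stage name; the partial
    manifest is written first.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    wanted = list(stages) if stages else list(STAGES)
    unknown = set(wanted) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    seeds = _stage_seeds(config.seed)
    manifest = RunManifest(config_hash=config.config_hash(), seed=config.seed,
                           stage_seeds=seeds)
    for name in STAGES:
        manifest.stages.append({"name": name, "status": "pending"})
    manifest.write(outdir)
    config.to_yaml(outdir / "config.yaml")

    for name in STAGES:
        entry = next(e for e in manifest.stages if e["name"] == name)
        if name not in wanted:
            entry["status"] = "not requested"
            continue
        if resume and all((outdir / f).exists() for f in _STAGE_OUTPUTS[name]):
            entry["status"] = "cached"
            continue
        func = _STAGE_FUNCS[name]
        t0 = time.perf_counter()
        try:
            info = func(config, outdir, seeds[name])
        except Exception as exc:
            entry["status"] = "failed"
            entry["error"] = str(exc)
            manifest.write(outdir)
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        entry["status"] = "ok"
        entry["seconds"] = round(time.perf_counter() - t0, 3)
        entry["rows"] = info.get("rows", 0)
        entry["outputs"] = {
            f: _file_hash(outdir / f) for f in info.get("outputs", [])
        }
        manifest.write(outdir)
    return manifest
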