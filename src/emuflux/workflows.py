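"""Config-driven analysis pipelines and report assembly.

These functions are the scripted face of the library: each one loads its
inputs from paths in a :class:`RunConfig`, executes the corresponding
module pipeline, and writes plain-text artifacts plus a ``run.log``
recording the seed and inputs so every output is regenerable.  They raise
:class:`emuflux.constraint.InfeasibleError` /
:class:`emuflux.estimate.EstimationError` instead of returning exit codes.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as efio
from .constraint import FluxBounds, fba, fva
from .emu import parse_emu
from .estimate import (DilutionSpec, FitResults, make_fit_problem, solve,
                       solve_inst, solve_with_confidence_intervals)
from .network import read_network
from .simulate import simulate_inst, simulate_steady_state
from .stats import (chi2_test, contribution_matrix,
                    local_confidence_intervals, sensitivity_matrix)

__all__ = ["RunConfig", "run_fba", "run_fva", "run_simulate", "run_fit",
           "run_fit_mc", "run_stats", "report"]


@dataclass
class RunConfig:
    """Paths and options of one analysis run."""

    model: str
    out_dir: str
    tracer: Optional[str] = None
    mdv_measurements: Optional[str] = None
    flux_measurements: Optional[str] = None
    bounds: Optional[str] = None
    fluxes: Optional[str] = None            # flux table for simulation
    pools: Optional[str] = None             # TSV metabolite_id, size
    targets: Sequence[str] = ()
    timegrid: Sequence[float] = ()
    mode: str = "ss"
    objective: Optional[str] = None
    sense: str = "max"
    gamma: float = 0.0
    dilution: Sequence[str] = ()            # "met" or "met:pool"
    n_starts: int = 10
    n_runs: int = 100
    n_jobs: int = 1
    seed: Optional[int] = None
    tol: float = 1e-9
    max_iter: int = 500
    alpha: float = 0.05
    substrates: Sequence[str] = ()
    excreted: Sequence[str] = ()


def _prepare(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _log_run(cfg: RunConfig, out: Path, extra: Optional[dict] = None) -> None:
    entries = {"timestamp": time.strftime("%Y-%m-%d %H:%M:%S"),
               "seed": cfg.seed, "config": asdict(cfg)}
    model = Path(cfg.model)
    if model.exists():
        entries["model_sha256"] = hashlib.sha256(model.read_bytes()).hexdigest()
    if extra:
        entries.update(extra)
    with open(out / "run.log", "a") as fh:
        fh.write(json.dumps(entries, default=str) + "\n")


def _load_network(cfg: RunConfig):
    return read_network(cfg.model, substrates=cfg.substrates,
                        excreted=cfg.excreted)


def _load_bounds(cfg: RunConfig) -> FluxBounds:
    return efio.read_flux_bounds(cfg.bounds) if cfg.bounds else FluxBounds()


def run_fba(cfg: RunConfig):
    net = _load_network(cfg)
    res = fba(net, _load_bounds(cfg), cfg.objective, cfg.sense)
    out = _prepare(cfg)
    pd.DataFrame([{"flux_id": f, "value": v} for f, v in res.fluxes.items()]
                 ).to_csv(out / "fba_fluxes.tsv", sep="\t", index=False)
    _log_run(cfg, out, {"objective_value": res.objective_value})
    return res


def run_fva(cfg: RunConfig):
    net = _load_network(cfg)
    res = fva(net, _load_bounds(cfg), cfg.objective, cfg.gamma, cfg.sense)
    out = _prepare(cfg)
    pd.DataFrame([{"flux_id": f, "min": lo, "max": hi}
                  for f, (lo, hi) in res.ranges.items()]
                 ).to_csv(out / "fva_ranges.tsv", sep="\t", index=False)
    _log_run(cfg, out)
    return res


def run_simulate(cfg: RunConfig):
    net = _load_network(cfg)
    strategy = efio.read_tracer_yaml(cfg.tracer)
    fluxes = pd.read_csv(cfg.fluxes, sep="\t")
    v = dict(zip(fluxes["flux_id"].astype(str), fluxes["value"].astype(float)))
    out = _prepare(cfg)
    if cfg.mode == "inst":
        pools_df = pd.read_csv(cfg.pools, sep="\t")
        pools = dict(zip(pools_df["metabolite_id"].astype(str),
                         pools_df["size"].astype(float)))
        traj = simulate_inst(net, v, pools, strategy, list(cfg.targets),
                             list(cfg.timegrid))
        traj.to_dataframe().to_csv(out / "trajectory.tsv", sep="\t",
                                   index=False)
        _log_run(cfg, out)
        return traj
    res = simulate_steady_state(net, v, strategy, list(cfg.targets))
    rows = []
    for emu, m in res.items():
        row = {"emu_id": emu.name, "t": "ss"}
        row.update({f"M{i}": x for i, x in enumerate(m.values)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "mdv.tsv", sep="\t", index=False)
    _log_run(cfg, out)
    return res


def _make_problem(cfg: RunConfig, net, strategy):
    meas = efio.read_mdv_measurements(cfg.mdv_measurements)
    fmeas = efio.read_flux_measurements(cfg.flux_measurements)
    dil = []
    for d in cfg.dilution:
        if ":" in d:
            met, scope = d.split(":", 1)
            dil.append(DilutionSpec(met, scope))
        else:
            dil.append(DilutionSpec(d))
    pools_init = None
    if cfg.pools:
        df = pd.read_csv(cfg.pools, sep="\t")
        pools_init = dict(zip(df["metabolite_id"].astype(str),
                              df["size"].astype(float)))
    return make_fit_problem(net, meas, fmeas, strategy, cfg.mode,
                            dilution=dil, pools_init=pools_init)


def _write_fit_artifacts(fit: FitResults, out: Path,
                         ci: Optional[pd.DataFrame] = None) -> None:
    prob = fit.problem
    rows = []
    for rid in prob.reaction_ids:
        row = {"reaction_id": rid, "net": fit.net_fluxes[rid],
               "exchange": fit.exchange_fluxes.get(rid, 0.0)}
        if ci is not None:
            row["ci_lo"] = ci.loc[f"net:{rid}", "ci_lo"]
            row["ci_hi"] = ci.loc[f"net:{rid}", "ci_hi"]
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "fluxes.tsv", sep="\t", index=False)
    if fit.pool_estimates:
        pd.DataFrame([{"metabolite_id": m, "size": c}
                      for m, c in fit.pool_estimates.items()]
                     ).to_csv(out / "pools.tsv", sep="\t", index=False)
    if fit.g_estimates:
        pd.DataFrame([{"pool": m, "G": g} for m, g in fit.g_estimates.items()]
                     ).to_csv(out / "gvalues.tsv", sep="\t", index=False)
    fit.compare_measurements().to_csv(out / "residuals.tsv", sep="\t",
                                      index=False)
    stats = chi2_test(fit)
    with open(out / "fit_report.json", "w") as fh:
        json.dump({"phi": fit.phi, "dof": fit.dof, "converged": fit.converged,
                   "n_starts": fit.n_starts, "seed": fit.seed,
                   "chi2_lo": stats.chi2_lo, "chi2_hi": stats.chi2_hi,
                   "chi2_accepted": stats.accepted,
                   "normality_p": stats.normality_p}, fh, indent=2)


def run_fit(cfg: RunConfig) -> FitResults:
    net = _load_network(cfg)
    strategy = efio.read_tracer_yaml(cfg.tracer)
    prob = _make_problem(cfg, net, strategy)
    solver = solve if cfg.mode == "ss" else solve_inst
    fit = solver(prob, n_starts=cfg.n_starts, seed=cfg.seed, tol=cfg.tol,
                 max_iter=cfg.max_iter)
    out = _prepare(cfg)
    _write_fit_artifacts(fit, out, local_confidence_intervals(fit, cfg.alpha))
    _log_run(cfg, out, {"phi": fit.phi})
    return fit


def run_fit_mc(cfg: RunConfig):
    net = _load_network(cfg)
    strategy = efio.read_tracer_yaml(cfg.tracer)
    prob = _make_problem(cfg, net, strategy)
    mc = solve_with_confidence_intervals(prob, n_runs=cfg.n_runs,
                                         n_jobs=cfg.n_jobs, seed=cfg.seed,
                                         alpha=cfg.alpha,
                                         n_starts=cfg.n_starts, tol=cfg.tol,
                                         max_iter=cfg.max_iter)
    out = _prepare(cfg)
    _write_fit_artifacts(mc.base, out, mc.ci())
    mc.ci().to_csv(out / "ci.tsv", sep="\t")
    _log_run(cfg, out, {"n_failed": mc.n_failed})
    return mc


def run_stats(fit: FitResults, out_dir, alpha: float = 0.05) -> dict:
    """Write chi2.json, ci.tsv, sensitivity.tsv, contribution.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stats = chi2_test(fit, alpha)
    with open(out / "chi2.json", "w") as fh:
        json.dump({"chi2": stats.chi2, "dof": stats.dof,
                   "chi2_lo": stats.chi2_lo, "chi2_hi": stats.chi2_hi,
                   "accepted": stats.accepted,
                   "normality_p": stats.normality_p}, fh, indent=2)
    local_confidence_intervals(fit, alpha).to_csv(out / "ci.tsv", sep="\t")
    sensitivity_matrix(fit).stack().rename_axis(
        ["estimate", "measurement"]).rename("sensitivity").reset_index(
    ).to_csv(out / "sensitivity.tsv", sep="\t", index=False)
    contribution_matrix(fit).stack().rename_axis(
        ["estimate", "measurement"]).rename("contribution").reset_index(
    ).to_csv(out / "contribution.tsv", sep="\t", index=False)
    return {"chi2": stats.chi2, "dof": stats.dof, "accepted": stats.accepted}


def report(fit_dir) -> dict:
    """Consolidated report from fit artifacts: simulated-vs-measured table
    with residual z-scores, flux table (CIs when present), chi2 verdict.

    Returns the report dict and writes ``report.json`` / ``report.md``
    alongside the artifacts; missing optional artifacts are skipped with a
    warning field rather than an error.
    """
    d = Path(fit_dir)
    missing = [f for f in ("fluxes.tsv", "residuals.tsv", "fit_report.json")
               if not (d / f).exists()]
    if missing:
        raise FileNotFoundError(f"fit artifacts missing from {d}: {missing}")
    fluxes = pd.read_csv(d / "fluxes.tsv", sep="\t")
    residuals = pd.read_csv(d / "residuals.tsv", sep="\t")
    fit_report = json.loads((d / "fit_report.json").read_text())
    warnings: List[str] = []
    if "ci_lo" not in fluxes.columns:
        warnings.append("no confidence intervals in fluxes.tsv")
    rep = {
        "phi": fit_report["phi"],
        "dof": fit_report["dof"],
        "chi2_accepted": fit_report["chi2_accepted"],
        "fluxes": fluxes.to_dict(orient="records"),
        "measurements": residuals.to_dict(orient="records"),
        "max_abs_z": float(residuals["weighted_residual"].abs().max()),
        "warnings": warnings,
    }
    (d / "report.json").write_text(json.dumps(rep, indent=2, default=str))
    lines = ["# Fit report", "",
             f"Phi = {rep['phi']:.4g}, dof = {rep['dof']}, chi2 "
             f"{'accepted' if rep['chi2_accepted'] else 'rejected'}", "",
             "## Fluxes", fluxes.to_markdown(index=False), "",
             "## Simulated vs measured",
             residuals.to_markdown(index=False)]
    if warnings:
        lines += ["", "## Warnings"] + [f"- {w}" for w in warnings]
    (d / "report.md").write_text("\n".join(lines) + "\n")
    return rep
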