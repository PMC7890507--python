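"""Sweep orchestration: simulate -> reconstruct -> evaluate -> aggregate.

A sweep runs the full pipeline over a grid of directional-trend settings
(total bias ``|mu|`` for migration scenarios, sector angle ``alpha`` for
expansion scenarios), several replicates per setting and one or more
reconstruction models, and collects per-run evaluation rows.  Runs whose
extant-language count falls outside [40, 200] are kept in the table but
flagged as outliers and excluded from aggregates.  Per-run seeds derive
deterministically from the master seed, so an identical grid + seed
reproduces the identical table; results are written incrementally and a
re-run skips rows already present in the output file.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evalmetrics, migsim, expsim, treestats
from .core import TimedTree, LocationTable
from .phylogeo import ModelSpec, mcmc_sample

logger = logging.getLogger("phylospread")

#: Default total-bias sweep for migration runs (km): 0..6000 in steps of 500.
MU_GRID_KM = [500.0 * k for k in range(13)]
#: Default sector-angle sweep for expansion runs: 2*pi down to 0.2*pi.
ALPHA_GRID = [2 * math.pi * k / 10 for k in range(10, 0, -1)]

RESULT_COLUMNS = [
    "scenario", "trend_param", "replicate", "model", "seed",
    "observed_trend", "n_extant", "outlier", "failed",
    "rmse", "bias", "hpd80", "hpd95",
    "clade_overlap", "diversity_space_dependence", "tree_imbalance",
]


@dataclass
class SweepGrid:
    scenario: str = "mig"                     # "mig" | "exp"
    trend_values: list[float] = field(default_factory=list)
    replicates: int = 20
    models: list[str] = field(default_factory=lambda: ["rrw"])
    fossil_regime: str = "none"               # none | recent | whole
    fossil_count: int = 20
    master_seed: int = 0
    chain: ModelSpec | None = None            # template; kind is overridden
    outlier_min: int = 40
    outlier_max: int = 200

    def __post_init__(self):
        if self.scenario not in ("mig", "exp"):
            raise ValueError("scenario must be 'mig' or 'exp'")
        if not self.trend_values:
            self.trend_values = (list(MU_GRID_KM) if self.scenario == "mig"
                                 else list(ALPHA_GRID))
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if self.fossil_regime not in ("none", "recent", "whole"):
            raise ValueError("fossil regime must be none/recent/whole")
        if self.fossil_regime != "none" and self.scenario != "mig":
            raise ValueError("fossils only apply to migration scenarios")


def _simulate(grid: SweepGrid, trend_value: float, seed: int):
    """One simulation; returns (tree-for-inference, tips, truth, result)."""
    if grid.scenario == "mig":
        params = migsim.MigSimParams(mu=(trend_value, 0.0))
        res = migsim.simulate_migration(
            params, seed=seed,
            keep_trajectories=grid.fossil_regime != "none")
        if res.tree is None:
            return None
        tree = res.tree if grid.fossil_regime != "none" \
            else res.tree.prune_to_extant()
        return tree, res.tip_locations, res.root_location, res
    params = expsim.ExpSimParams(alpha=trend_value)
    res = expsim.simulate_expansion(params, seed=seed)
    if res.n_extant == 0:
        return None
    return res.tree, res.tip_locations, res.root_location, res


def _fossils_for(grid: SweepGrid, res, rng: np.random.Generator):
    if grid.fossil_regime == "none":
        return None
    max_age = 500.0 if grid.fossil_regime == "recent" else res.params.T
    return migsim.sample_fossils(res, grid.fossil_count, max_age, rng)


def run_sweep(grid: SweepGrid, out_csv: str | None = None) -> pd.DataFrame:
    """Run the full grid; returns (and optionally writes) one row per
    (setting, replicate, model).  Reconstruction failures are flagged rows,
    not exceptions, so a sweep always completes."""
    done: set[tuple] = set()
    rows: list[dict] = []
    if out_csv and os.path.exists(out_csv):
        prev = pd.read_csv(out_csv)
        rows = prev.to_dict("records")
        done = {(r["scenario"], round(r["trend_param"], 9), r["replicate"],
                 r["model"]) for r in rows}
        logger.info("resuming sweep: %d rows present", len(rows))

    spawn = {}
    for vi, tv in enumerate(grid.trend_values):
        for rep in range(grid.replicates):
            spawn[(vi, rep)] = np.random.SeedSequence(
                entropy=grid.master_seed,
                spawn_key=(vi, rep)).generate_state(1)[0] % (2 ** 31)

    template = grid.chain or ModelSpec()
    for vi, tv in enumerate(grid.trend_values):
        for rep in range(grid.replicates):
            seed = int(spawn[(vi, rep)])
            key_base = (grid.scenario, round(tv, 9), rep)
            if all(key_base + (m,) in done for m in grid.models):
                continue
            sim = _simulate(grid, tv, seed)
            for model in grid.models:
                key = key_base + (model,)
                if key in done:
                    continue
                row = {"scenario": grid.scenario, "trend_param": tv,
                       "replicate": rep, "model": model, "seed": seed,
                       "failed": False}
                if sim is None:
                    row.update(observed_trend=np.nan, n_extant=0,
                               outlier=True, failed=True, rmse=np.nan,
                               bias=np.nan, hpd80=False, hpd95=False,
                               clade_overlap=np.nan,
                               diversity_space_dependence=np.nan,
                               tree_imbalance=np.nan)
                    rows.append(row)
                    continue
                tree, tips, truth, res = sim
                n_extant = len(tips)
                row["n_extant"] = n_extant
                row["outlier"] = bool(n_extant < grid.outlier_min
                                      or n_extant > grid.outlier_max)
                try:
                    spec = ModelSpec(
                        kind=model, iterations=template.iterations,
                        burn_in=template.burn_in,
                        thinning=template.thinning,
                        rate_hyper_scale=template.rate_hyper_scale,
                        rate_step=template.rate_step)
                    rng = np.random.default_rng(seed + 1)
                    fossils = _fossils_for(grid, res, rng)
                    samples = mcmc_sample(tree, tips, spec,
                                          fossils=fossils, seed=seed)
                    report = evalmetrics.evaluate_run(
                        samples.root, truth, tips, n_extant=n_extant)
                    stat_tree = (tree.prune_to_extant()
                                 if grid.scenario == "mig"
                                 and grid.fossil_regime != "none" else tree)
                    stats = treestats.compute_stats(stat_tree, tips)
                    row.update(observed_trend=report.observed_trend,
                               rmse=report.rmse, bias=report.bias,
                               hpd80=report.covered_80,
                               hpd95=report.covered_95,
                               clade_overlap=stats.clade_overlap,
                               diversity_space_dependence=(
                                   stats.diversity_space_dependence),
                               tree_imbalance=stats.tree_imbalance)
                except Exception as exc:  # keep the sweep alive
                    logger.warning("run %s failed: %s", key, exc)
                    row.update(observed_trend=np.nan, failed=True,
                               rmse=np.nan, bias=np.nan, hpd80=False,
                               hpd95=False, clade_overlap=np.nan,
                               diversity_space_dependence=np.nan,
                               tree_imbalance=np.nan)
                rows.append(row)
                if out_csv:
                    pd.DataFrame(rows)[RESULT_COLUMNS].to_csv(out_csv,
                                                              index=False)
    return pd.DataFrame(rows)[RESULT_COLUMNS]


def aggregate(results: pd.DataFrame, bin_by: str = "parameter",
              n_bins: int = 10) -> pd.DataFrame:
    """Per-setting (or per-observed-trend-bin) means of the metrics.

    Outlier and failed rows are excluded.  RMSE is pooled quadratically
    (mean of squares, then root), matching a pooled-draw evaluation;
    coverage columns become empirical rates.
    """
    ok = results[(~results["outlier"]) & (~results["failed"])].copy()
    if ok.empty:
        raise ValueError("no non-outlier rows to aggregate")
    if bin_by == "parameter":
        key = ["scenario", "model", "trend_param"]
    elif bin_by == "observed-trend":
        edges = np.linspace(0, float(ok["observed_trend"].max()) + 1e-9,
                            n_bins + 1)
        ok["trend_bin"] = pd.cut(ok["observed_trend"], edges)
        key = ["scenario", "model", "trend_bin"]
    else:
        raise ValueError("bin_by must be 'parameter' or 'observed-trend'")
    def _agg(g):
        return pd.Series({
            "n_runs": len(g),
            "mean_observed_trend": g["observed_trend"].mean(),
            "mean_bias": g["bias"].mean(),
            "pooled_rmse": float(np.sqrt(np.mean(g["rmse"] ** 2))),
            "coverage_80": g["hpd80"].mean(),
            "coverage_95": g["hpd95"].mean(),
            "mean_imbalance": g["tree_imbalance"].mean(),
            "mean_overlap": g["clade_overlap"].mean(),
            "mean_dependence": g["diversity_space_dependence"].mean(),
        })
    out = ok.groupby(key, observed=True).apply(_agg, include_groups=False)
    return out.reset_index()
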