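"""End-to-end benchmark harness: simulate, select penalties by each method,
refit, score edge recovery, and aggregate means and standard errors.

The harness reproduces the model-selection comparison on simulated
scale-free mixed networks.  AIC, BIC, CV and the oracle score candidates on
a shared grid (cubic by default) and share one cache of full-data fits per
dataset; single-penalty StARS and StEPS share one subsample ensemble; the
cubic stability search fits its own triple-grid ensemble.  Everything is
deterministic given the master seed.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import FitConfig, adjacency_from_parameters
from .evaluate import edge_confusion, recovery_metrics
from .selection import (LambdaGrid, DEFAULT_GRID, cross_validate, fit_path,
                        oracle_select, select_information_criterion)
from .simulate import SimulationConfig, simulate_benchmark
from . import stability as st

__all__ = ["BenchmarkConfig", "BenchmarkReport", "run_benchmark"]

ALL_METHODS = ("aic", "bic", "cv", "oracle", "stars1", "steps3", "cubic")
METRICS = ("precision", "recall", "f1", "mcc", "accuracy")


@dataclass
class BenchmarkConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    methods: tuple = ("aic", "bic", "cv", "oracle", "stars1", "steps3")
    grid_values: tuple = DEFAULT_GRID
    linear: Optional[bool] = False   # None keeps both variants of each network
    gamma: float = 0.05
    subsamples: int = 20
    subsample_size: Optional[int] = None
    cv_folds: int = 5
    cubic_rule: str = "per_type_max"
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


@dataclass
class BenchmarkReport:
    per_dataset: pd.DataFrame   # one row per (dataset, method)
    summary: pd.DataFrame       # mean and standard error per method/metric
    selections: pd.DataFrame    # chosen penalties per (dataset, method)
    config: BenchmarkConfig = None
    failures: list = field(default_factory=list)


def _score(params, truth, p, q) -> dict:
    A = adjacency_from_parameters(params)
    out = {}
    conf = edge_confusion(A, truth, p, q)
    met = recovery_metrics(conf)
    for m in METRICS:
        out[m] = met[m]
    for et in ("cc", "cd", "dd"):
        out[f"mcc_{et}"] = recovery_metrics(edge_confusion(A, truth, p, q, et))["mcc"]
    return out


def run_benchmark(config: BenchmarkConfig) -> BenchmarkReport:
    """Run every configured selection method on every simulated dataset.

    Failures in one (dataset, method) pair are recorded and excluded from
    aggregation rather than aborting the run.
    """
    sim = config.simulation
    entries = simulate_benchmark(sim)
    if config.linear is not None:
        entries = [e for e in entries if e["linear"] == config.linear]
    fit_cfg = FitConfig()
    single = LambdaGrid(config.grid_values, mode="single")
    triple = LambdaGrid(config.grid_values, mode="triple")
    seed_seq = np.random.SeedSequence(config.seed)
    ds_seeds = seed_seq.spawn(len(entries))

    rows, sel_rows, failures = [], [], []
    for d, entry in enumerate(entries):
        data, truth = entry["data"], entry["adjacency"]
        p, q = data.p, data.q
        label = f"net{entry['network']}_{'lin' if entry['linear'] else 'nonlin'}"
        sub_seed, cubic_seed, cv_seed = ds_seeds[d].spawn(3)

        cache = {}
        if {"aic", "bic", "oracle"} & set(config.methods):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                cache["grid_fits"] = fit_path(data, triple.candidates(), fit_cfg)
        if {"stars1", "steps3"} & set(config.methods):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                cache["profile"] = st.instability_profile(
                    data, single, N=config.subsamples, b=config.subsample_size,
                    config=fit_cfg, seed=sub_seed)

        for method in config.methods:
            t0 = time.time()
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    if method in ("aic", "bic"):
                        res = select_information_criterion(
                            data, triple, method, fit_cfg, fits=cache["grid_fits"])
                    elif method == "cv":
                        res = cross_validate(data, triple, K=config.cv_folds,
                                             config=fit_cfg,
                                             seed=int(cv_seed.generate_state(1)[0] % 2**31))
                    elif method == "oracle":
                        res = oracle_select(data, triple, truth, fit_cfg,
                                            fits=cache["grid_fits"])
                    elif method == "stars1":
                        res = st.stars_select(data, single, gamma=config.gamma,
                                              config=fit_cfg,
                                              profile=cache["profile"])
                    elif method == "steps3":
                        res = st.steps_select(data, single, gamma=config.gamma,
                                              config=fit_cfg,
                                              profile=cache["profile"])
                    elif method == "cubic":
                        res = st.cubic_stability_select(
                            data, single, N=config.subsamples,
                            b=config.subsample_size, gamma=config.gamma,
                            rule=config.cubic_rule, config=fit_cfg,
                            seed=cubic_seed)
            except Exception as exc:  # noqa: BLE001 - record and continue
                warnings.warn(f"{label}/{method} failed: {exc}", RuntimeWarning)
                failures.append({"dataset": label, "method": method,
                                 "error": repr(exc)})
                continue
            row = {"dataset": label, "method": method,
                   "seconds": time.time() - t0}
            row.update(_score(res.params, truth, p, q))
            rows.append(row)
            sel_rows.append({
                "dataset": label, "method": method,
                "lambda_cc": res.chosen.lambda_cc,
                "lambda_cd": res.chosen.lambda_cd,
                "lambda_dd": res.chosen.lambda_dd,
            })

    per_dataset = pd.DataFrame(rows)
    summary_rows = []
    for method in config.methods:
        sub = per_dataset[per_dataset["method"] == method]
        if sub.empty:
            continue
        row = {"method": method, "n_datasets": len(sub)}
        for m in METRICS:
            row[f"{m}_mean"] = float(sub[m].mean())
            row[f"{m}_se"] = (float(sub[m].std(ddof=1) / np.sqrt(len(sub)))
                              if len(sub) > 1 else np.nan)
        summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)
    return BenchmarkReport(per_dataset, summary, pd.DataFrame(sel_rows),
                           config, failures)
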