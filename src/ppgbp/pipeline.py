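"""Benchmark orchestration: cohorts -> splits -> (weighted) training ->
evaluation over a (train-site x scenario x architecture) matrix.

Each matrix cell trains one model on one site group under one scenario
(optionally with importance weights derived from a target test set's
label distribution) and evaluates it on every declared test set, both
in-distribution (the cell's own held-out test indices) and
out-of-distribution (other sites).  Cell failures are isolated: the
remaining cells run and the partial results table stays valid.
"""

from __future__ import annotations

import traceback
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .adaptation import default_bin_edges, make_weight_vector
from .cohort import CohortConfig, generate_cohort
from .evaluation import PredictionSet, evaluate, tabulate
from .models import ModelSpec, build_model
from .splits import (DatasetSplit, TailQuotas, make_aami_split,
                     make_calib_split, make_calibfree_split)
from .store import SegmentStore
from .training import TrainConfig, train

__all__ = ["BenchmarkMatrixSpec", "RunManifest", "run_benchmark",
           "compare_weighted_unweighted", "make_split"]

RESULT_COLUMNS = ["train_site", "scenario", "arch", "weighted", "test_set",
                  "seed", "mae_sbp", "mae_dbp", "bias_sbp", "bias_dbp",
                  "loa_sbp", "loa_dbp", "n"]


@dataclass
class BenchmarkMatrixSpec:
    """Declarative description of one benchmark run."""

    cohort: CohortConfig
    cells: list[tuple[str, str]]            # (train_site, scenario)
    architectures: list[str]
    test_sites: list[str]                   # OOD test sets (whole sites)
    weighted: tuple[bool, ...] = (False, True)
    weight_target: str | None = None        # OOD site driving the weights
    train_config: TrainConfig = field(default_factory=TrainConfig)
    model_scale: float = 1.0
    seeds: tuple[int, ...] = (0,)
    tau: float = 1.0

    def validate(self) -> None:
        sites = {s.name for s in self.cohort.sites}
        for site, scenario in self.cells:
            if site not in sites:
                raise ValueError(f"cell references unknown site {site!r}")
            if scenario not in ("calib", "calibfree", "aami"):
                raise ValueError(f"unknown scenario {scenario!r}")
        for t in self.test_sites:
            if t not in sites:
                raise ValueError(f"test set references unknown site {t!r}")
        if self.weight_target is not None and self.weight_target not in sites:
            raise ValueError(f"unknown weight target {self.weight_target!r}")


@dataclass
class RunManifest:
    spec: dict
    seeds: list[int]
    cells: list[dict]
    failures: list[dict] = field(default_factory=list)

    def save(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump({"spec": self.spec, "seeds": self.seeds,
                            "cells": self.cells, "failures": self.failures}, f)


def make_split(store: SegmentStore, scenario: str, seed: int,
               quotas: TailQuotas | None = None) -> DatasetSplit:
    if scenario == "calib":
        return make_calib_split(store, seed=seed)
    if scenario == "calibfree":
        return make_calibfree_split(store, seed=seed)
    if scenario == "aami":
        return make_aami_split(store, quotas=quotas or TailQuotas(), seed=seed)
    raise ValueError(f"unknown scenario {scenario!r}")


def _predict_set(model, store, indices, name) -> PredictionSet:
    from .models import predict
    sub = store.select(indices)
    ps = predict(model, sub)
    ps.test_set_id = name
    return ps


def run_benchmark(spec: BenchmarkMatrixSpec) -> tuple[pd.DataFrame, RunManifest]:
    spec.validate()
    store = generate_cohort(spec.cohort)
    site_idx = {s.name: np.flatnonzero(store.site_id == s.name)
                for s in spec.cohort.sites}
    edges = default_bin_edges()
    reports, manifest_cells, failures = [], [], []
    for seed in spec.seeds:
        for train_site, scenario in spec.cells:
            local = store.select(site_idx[train_site])
            split = make_split(local, scenario, seed)
            for arch in spec.architectures:
                for weighted in spec.weighted:
                    cell = {"train_site": train_site, "scenario": scenario,
                            "arch": arch, "weighted": bool(weighted),
                            "seed": int(seed)}
                    try:
                        weights = None
                        if weighted:
                            target = spec.weight_target or (
                                spec.test_sites[0] if spec.test_sites else None)
                            if target is None:
                                raise ValueError(
                                    "weighted cell without a weight target")
                            tgt = store.select(site_idx[target])
                            weights = make_weight_vector(
                                local.sbp[split.train], local.dbp[split.train],
                                tgt.sbp, tgt.dbp, bin_edges=edges, tau=spec.tau)
                        model = build_model(
                            ModelSpec(architecture=arch, scale=spec.model_scale),
                            seed=seed)
                        result = train(model, local, split,
                                       spec.train_config, weights=weights)
                        test_sets = {f"{train_site}:{scenario}:test": (
                            local, split.test)}
                        for t in spec.test_sites:
                            if t != train_site:
                                test_sets[t] = (store, site_idx[t])
                        for name, (src, idx) in test_sets.items():
                            ps = _predict_set(result.model, src, idx, name)
                            reports.append((dict(cell, test_set=name),
                                            evaluate(ps)))
                        manifest_cells.append(
                            dict(cell, best_epoch=result.best_epoch))
                    except Exception as exc:  # isolate per-cell failures
                        failures.append(dict(cell, error=repr(exc),
                                             trace=traceback.format_exc()))
    table = tabulate(reports) if reports else pd.DataFrame(columns=RESULT_COLUMNS)
    manifest = RunManifest(
        spec={"cells": [list(c) for c in spec.cells],
              "architectures": spec.architectures,
              "test_sites": spec.test_sites,
              "weighted": list(spec.weighted),
              "weight_target": spec.weight_target,
              "model_scale": spec.model_scale,
              "tau": spec.tau,
              "train_config": asdict(spec.train_config),
              "cohort_seed": spec.cohort.seed},
        seeds=[int(s) for s in spec.seeds],
        cells=manifest_cells, failures=failures)
    return table, manifest


def compare_weighted_unweighted(table: pd.DataFrame) -> pd.DataFrame:
    """Delta table: MAE(weighted) - MAE(unweighted) per cell, plus a
    summary row (mean improvement and fraction of cells improved)."""
    keys = ["train_site", "scenario", "arch", "test_set", "seed"]
    w = table[table["weighted"]].set_index(keys)
    u = table[~table["weighted"]].set_index(keys)
    unmatched = sorted(set(w.index.tolist()) ^ set(u.index.tolist()))
    if unmatched:
        raise ValueError(f"unmatched weighted/unweighted cells: {unmatched}")
    if len(w) == 0:
        raise ValueError("table contains no weighted/unweighted pairs")
    delta = pd.DataFrame({
        "delta_mae_sbp": w["mae_sbp"] - u["mae_sbp"],
        "delta_mae_dbp": w["mae_dbp"] - u["mae_dbp"]}).reset_index()
    all_deltas = np.concatenate([delta["delta_mae_sbp"], delta["delta_mae_dbp"]])
    summary = pd.DataFrame([{**{k: "ALL" for k in keys},
                             "delta_mae_sbp": delta["delta_mae_sbp"].mean(),
                             "delta_mae_dbp": delta["delta_mae_dbp"].mean(),
                             "fraction_improved": float((all_deltas < 0).mean())}])
    delta["fraction_improved"] = np.nan
    return pd.concat([delta, summary], ignore_index=True)
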