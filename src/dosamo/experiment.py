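"""Experiment driver: configured runs with CV or external validation.

A run configuration names the dataset files, the objectives (metric +
inner model per objective), the optimizer budgets, and the adjuster
kinds to compare.  In ``cv`` mode the optimizer is assessed by an
outer evaluation k-fold (the dual-stage wrapper's own internal k-fold
sits nested inside each training part); in ``external`` mode it runs on
the full training set and is validated on a held-out cohort.  Each
(adjuster, fold) cell reports the set-level estimation-error metrics
(MOPE, Pareto delta) and the attained cross hypervolume.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .core import Dataset, ObjectiveSpec, create_folds
from .hypervolume import cross_hypervolume, hypervolume, mope, pareto_delta
from .io import load_dataset, write_solution_set
from .objectives import (
    ClassificationObjective,
    ParsimonyObjective,
    SurvivalObjective,
)
from .optimizer import DosaConfig, OptimizerConfig, dosa_optimize, evaluate_on_holdout

logger = logging.getLogger("dosamo")

__all__ = [
    "build_objectives",
    "front_metrics",
    "cv_front_metrics",
    "external_front_metrics",
    "run_experiment",
]

_SEED_MOD = 2**31


def build_objectives(entries: Sequence[dict]) -> List[ObjectiveSpec]:
    """Objective specs from config entries.

    Each entry has ``metric`` in {balanced_accuracy, c_index,
    root_leanness} plus metric-specific options (``model`` nb/svm,
    ``k_inner``, ``n_bootstrap``, ``cap``).
    """
    objectives: List[ObjectiveSpec] = []
    for e in entries:
        metric = e.get("metric")
        if metric == "balanced_accuracy":
            objectives.append(
                ClassificationObjective(
                    model=e.get("model", "nb"),
                    k_inner=int(e.get("k_inner", 5)),
                    n_bootstrap=int(e.get("n_bootstrap", 100)),
                )
            )
        elif metric == "c_index":
            objectives.append(
                SurvivalObjective(
                    k_inner=int(e.get("k_inner", 5)),
                    n_bootstrap=int(e.get("n_bootstrap", 100)),
                )
            )
        elif metric == "root_leanness":
            objectives.append(ParsimonyObjective(cap=int(e.get("cap", 100))))
        else:
            raise ValueError(f"unknown objective metric {metric!r}")
    return objectives


def front_metrics(X: np.ndarray, X_test: np.ndarray) -> dict:
    """Set-level metrics of one front: train HV, test HV, CHV, MOPE, PD."""
    return {
        "hv_train": hypervolume(X),
        "hv_test": hypervolume(X_test),
        "chv": cross_hypervolume(X, X_test),
        "mope": mope(X, X_test),
        "pareto_delta": pareto_delta(X, X_test),
        "front_size": X.shape[0],
    }


def _dosa_config(
    adjuster_kind: str, base: OptimizerConfig, k_outer: int,
    tuning: Optional[OptimizerConfig], seed: int,
) -> DosaConfig:
    return DosaConfig(
        k_outer=k_outer,
        main=replace(base, seed=seed % _SEED_MOD),
        tuning=None if tuning is None else replace(tuning, seed=seed % _SEED_MOD),
        adjuster_kinds=adjuster_kind,
    )


def cv_front_metrics(
    data: Dataset,
    objectives: Sequence[ObjectiveSpec],
    adjuster_kind: str,
    base_config: OptimizerConfig,
    k_outer: int = 3,
    k_eval: int = 3,
    seed: int = 0,
    tuning_config: Optional[OptimizerConfig] = None,
    out_dir: Optional[Path] = None,
    label: str = "",
) -> pd.DataFrame:
    """Outer evaluation CV of one adjuster kind: one metrics row per fold.

    The reported X is the front's expected (adjusted) fitness; X' is the
    fitness of the refit panels on the evaluation fold's left-out part.
    """
    eval_folds = create_folds(data, k_eval, seed % _SEED_MOD)
    rows = []
    for f, (train_idx, test_idx) in enumerate(eval_folds):
        fold_train = data.subset(train_idx)
        fold_test = data.subset(test_idx)
        cfg = _dosa_config(
            adjuster_kind, base_config, k_outer, tuning_config,
            seed + 17 * (f + 1),
        )
        front = dosa_optimize(cfg, objectives, fold_train)
        X = front.fitness_matrix()
        X_test = evaluate_on_holdout(front, fold_train, fold_test, objectives)
        row = {"adjuster": adjuster_kind, "fold": f, **front_metrics(X, X_test)}
        rows.append(row)
        if out_dir is not None:
            write_solution_set(
                front,
                Path(out_dir) / f"solutions_{label or adjuster_kind}_fold{f}.json",
                holdout_matrix=X_test,
                feature_names=data.feature_names,
            )
        logger.info(
            "eval fold %d (%s): MOPE=%.4f PD=%.4f CHV=%.4f",
            f, adjuster_kind, row["mope"], row["pareto_delta"], row["chv"],
        )
    return pd.DataFrame(rows)


def external_front_metrics(
    train: Dataset,
    holdout: Dataset,
    objectives: Sequence[ObjectiveSpec],
    adjuster_kind: str,
    base_config: OptimizerConfig,
    k_outer: int = 3,
    seed: int = 0,
    tuning_config: Optional[OptimizerConfig] = None,
    out_dir: Optional[Path] = None,
) -> pd.DataFrame:
    """External validation of one adjuster kind on a held-out cohort."""
    cfg = _dosa_config(adjuster_kind, base_config, k_outer, tuning_config, seed)
    front = dosa_optimize(cfg, objectives, train)
    X = front.fitness_matrix()
    X_test = evaluate_on_holdout(front, train, holdout, objectives)
    if out_dir is not None:
        write_solution_set(
            front,
            Path(out_dir) / f"solutions_{adjuster_kind}_external.json",
            holdout_matrix=X_test,
            feature_names=train.feature_names,
        )
    return pd.DataFrame(
        [{"adjuster": adjuster_kind, "fold": -1, **front_metrics(X, X_test)}]
    )


def run_experiment(config: dict) -> pd.DataFrame:
    """Run a configured comparison and write its report files.

    Returns the long-format metrics table (adjuster x fold x metric) and
    writes ``metrics.csv``, per-fold solution sets, the summary
    ``metrics_summary.csv`` (mean and SD between folds) and
    ``run_log.json`` with the resolved configuration and its hash.
    """
    out_dir = Path(config.get("output_dir", "results"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    mode = config.get("evaluation", {}).get("mode", "cv")
    data = load_dataset(config["dataset"]["matrix"], config["dataset"]["outcome"])
    objectives = build_objectives(config["objectives"])
    opt = config.get("optimizer", {})
    base_config = OptimizerConfig(
        population_size=int(opt.get("population_size", 20)),
        generations=int(opt.get("generations", 10)),
        crossover_rate=float(opt.get("crossover_rate", 0.9)),
        mutation_strength=float(opt.get("mutation_strength", 1.0)),
        init_max_features=int(opt.get("init_max_features", 10)),
        clone_retry_budget=int(opt.get("clone_retry_budget", 3)),
        seed=seed,
    )
    adjusters = config.get("adjusters", ["zero"])
    k_outer = int(config.get("k_outer", 3))
    tables = []
    if mode == "cv":
        k_eval = int(config.get("evaluation", {}).get("k", 5))
        for kind in adjusters:
            tables.append(
                cv_front_metrics(
                    data, objectives, kind, base_config,
                    k_outer=k_outer, k_eval=k_eval, seed=seed, out_dir=out_dir,
                )
            )
    elif mode == "external":
        holdout_cfg = config.get("evaluation", {}).get("holdout")
        if not holdout_cfg:
            raise ValueError("external mode requires evaluation.holdout paths")
        holdout = load_dataset(holdout_cfg["matrix"], holdout_cfg["outcome"])
        for kind in adjusters:
            tables.append(
                external_front_metrics(
                    data, holdout, objectives, kind, base_config,
                    k_outer=k_outer, seed=seed, out_dir=out_dir,
                )
            )
    else:
        raise ValueError(f"unknown evaluation mode {mode!r}")
    metrics = pd.concat(tables, ignore_index=True)
    metrics.to_csv(out_dir / "metrics.csv", index=False)
    value_cols = [c for c in metrics.columns if c not in ("adjuster", "fold")]
    summary = metrics.groupby("adjuster")[value_cols].agg(["mean", "std"])
    summary.to_csv(out_dir / "metrics_summary.csv")
    resolved = json.dumps(config, sort_keys=True, default=str)
    (out_dir / "run_log.json").write_text(
        json.dumps(
            {
                "config": config,
                "config_sha256": hashlib.sha256(resolved.encode()).hexdigest(),
                "seed": seed,
                "n_samples": data.n_samples,
                "n_features": data.n_features,
            },
            indent=1,
            default=str,
        )
    )
    return metrics
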