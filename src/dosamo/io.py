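"""Dataset readers/writers and solution-set serialization.

The on-disk layout is plain TSV/CSV: an expression-like matrix with
samples as rows (first column sample IDs, header row of feature names)
plus an outcome table keyed by sample ID with columns among
``class`` and ``time``/``event``.  Solution sets are written as JSON
with a flat CSV twin.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import Dataset, SolutionSet

logger = logging.getLogger("dosamo")

__all__ = ["load_dataset", "write_dataset", "write_solution_set", "read_solution_set"]


def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def load_dataset(matrix_path, outcome_path) -> Dataset:
    """Load a samples x features matrix and its outcome table.

    The two tables are inner-joined on sample ID; dropped IDs are
    reported.  Non-numeric matrix cells and duplicate feature names are
    rejected with the offending locations named.
    """
    # pandas silently renames duplicate columns, so check the raw header
    sep = "\t" if str(matrix_path).endswith((".tsv", ".txt")) else ","
    with open(matrix_path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dup = sorted({name for name in header if header.count(name) > 1})
    if dup:
        raise ValueError(f"duplicate feature names: {dup}")
    M = _read_table(matrix_path)
    O = _read_table(outcome_path)
    bad = M.columns[~M.dtypes.map(lambda d: np.issubdtype(d, np.number))]
    if len(bad) or M.isna().any().any():
        cells = [
            (str(r), str(c))
            for r, c in zip(*np.where(M.isna() | M.map(lambda v: isinstance(v, str))))
        ]
        where = cells[:5] if cells else list(bad[:5])
        raise ValueError(f"non-numeric matrix cells (row, column): {where}")
    o_ids = set(O.index)
    common = [i for i in M.index if i in o_ids]
    if len(common) == 0:
        raise ValueError("no overlapping sample IDs between matrix and outcomes")
    dropped = sorted(set(M.index.symmetric_difference(O.index)))
    if dropped:
        logger.warning("dropped %d unmatched sample IDs: %s", len(dropped), dropped[:10])
    M = M.loc[common]
    O = O.loc[common]
    y = O["class"].to_numpy() if "class" in O.columns else None
    time = O["time"].to_numpy(dtype=float) if "time" in O.columns else None
    event = O["event"].to_numpy() if "event" in O.columns else None
    return Dataset(
        X=M.to_numpy(dtype=float),
        y=y,
        time=time,
        event=event,
        feature_names=list(M.columns),
        sample_ids=list(M.index.astype(str)),
    )


def write_dataset(data: Dataset, matrix_path, outcome_path) -> None:
    """Write a dataset in the TSV layout that :func:`load_dataset` reads."""
    ids = data.sample_ids or [f"s{i}" for i in range(data.n_samples)]
    M = pd.DataFrame(data.X, index=pd.Index(ids, name="sample_id"),
                     columns=data.feature_names)
    out = {}
    if data.y is not None:
        out["class"] = data.y
    if data.time is not None:
        out["time"] = data.time
        out["event"] = data.event
    O = pd.DataFrame(out, index=pd.Index(ids, name="sample_id"))
    sep = "\t" if str(matrix_path).endswith((".tsv", ".txt")) else ","
    M.to_csv(matrix_path, sep=sep)
    O.to_csv(outcome_path, sep="\t" if str(outcome_path).endswith((".tsv", ".txt")) else ",")


def solution_set_records(
    solution_set: SolutionSet,
    holdout_matrix: Optional[np.ndarray] = None,
    feature_names=None,
) -> list:
    """JSON-ready records, ordered by descending first-objective fitness."""
    obj_names = [getattr(o, "name", f"obj{j}") for j, o in
                 enumerate(solution_set.objectives)]
    order = np.argsort(
        [-s.original_fitness[0] for s in solution_set.solutions], kind="stable"
    )
    records = []
    for rank, i in enumerate(order):
        sol = solution_set.solutions[i]
        names = (
            [feature_names[k] for k in sol.feature_set.indices]
            if feature_names is not None
            else [f"f{k}" for k in sol.feature_set.indices]
        )
        entry = {
            "features": names,
            "feature_indices": list(sol.feature_set.indices),
            "n_features": sol.feature_set.size,
            "objectives": [],
        }
        for j, name in enumerate(obj_names):
            o = {
                "name": name,
                "fitness": float(sol.original_fitness[j]),
                "sd": float(sol.fitness_sd[j]),
            }
            if holdout_matrix is not None:
                o["holdout_fitness"] = float(holdout_matrix[i, j])
            elif sol.test_fitness is not None:
                o["holdout_fitness"] = float(sol.test_fitness[j])
            entry["objectives"].append(o)
        records.append(entry)
    return records


def write_solution_set(
    solution_set: SolutionSet,
    path,
    holdout_matrix: Optional[np.ndarray] = None,
    feature_names=None,
) -> None:
    """Write a solution set as JSON plus a flat CSV twin (same stem)."""
    path = Path(path)
    records = solution_set_records(solution_set, holdout_matrix, feature_names)
    path.write_text(json.dumps(records, indent=1))
    rows = []
    for r_i, rec in enumerate(records):
        row = {
            "solution": r_i,
            "n_features": rec["n_features"],
            "features": ";".join(rec["features"]),
        }
        for o in rec["objectives"]:
            row[f"{o['name']}_fitness"] = o["fitness"]
            row[f"{o['name']}_sd"] = o["sd"]
            if "holdout_fitness" in o:
                row[f"{o['name']}_holdout"] = o["holdout_fitness"]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path.with_suffix(".csv"), index=False)


def read_solution_set(path) -> list:
    """Read back the JSON records written by :func:`write_solution_set`."""
    return json.loads(Path(path).read_text())
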