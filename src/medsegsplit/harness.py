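"""Three-mode experiment harness and results-table arithmetic.

The harness trains every architecture on every dataset under three
paradigms — Centralized on pooled data (C), Locally centralized per client
(L), and SplitFed (S) — evaluates average IoU on a held-out test shard,
and assembles the results into a long-form table.  The summary arithmetic
(per-column averages over models, column differences in percentage points,
and top-k model rankings) operates on any such table, including the
transcribed reference benchmark shipped with the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .models import build_model
from .splitfed import (
    FederationConfig,
    evaluate_model,
    num_classes_for,
    run_centralized,
    run_local_only,
    run_splitfed,
)

MODES = ("C", "L", "S")


@dataclass
class ResultsTable:
    """Long-form (model, dataset, mode, avg_iou) results."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"model", "dataset", "mode", "avg_iou"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"results table needs columns {sorted(required)}")
        bad = self.data[(self.data.avg_iou < 0) | (self.data.avg_iou > 1)]
        if len(bad):
            raise ValueError("avg_iou values must lie in [0, 1]")

    @property
    def models(self) -> list[str]:
        return list(dict.fromkeys(self.data["model"]))

    def pivot(self) -> pd.DataFrame:
        return self.data.pivot_table(
            index="model", columns=["dataset", "mode"], values="avg_iou", sort=False
        )

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ResultsTable":
        return cls(pd.read_csv(path))


def load_reference_results() -> ResultsTable:
    """Transcribed reference benchmark: average IoU of ten segmentation
    architectures under the three training modes on three datasets."""
    with resources.files("medsegsplit.data").joinpath(
        "published_benchmark_iou.csv"
    ).open() as fh:
        return ResultsTable(pd.read_csv(fh))


def compute_average_row(table: ResultsTable) -> pd.Series:
    """Arithmetic mean of each (dataset, mode) column, rounded to 4
    decimals — the 'average over models' summary row."""
    if table.data.empty:
        raise ValueError("empty results table")
    means = table.data.groupby(["dataset", "mode"], sort=False)["avg_iou"].mean()
    return means.round(4)


def compute_column_diffs(table: ResultsTable, dataset: str) -> tuple[float, float]:
    """(C-L, C-S) differences of the average row for one dataset, in
    percentage points rounded to 2 decimals."""
    avg = compute_average_row(table)
    try:
        c, l, s = (avg[(dataset, m)] for m in MODES)
    except KeyError as err:
        raise ValueError(f"dataset {dataset!r} lacks a {err} column") from None
    return round((c - l) * 100, 2), round((c - s) * 100, 2)


def rank_top_models(table: ResultsTable, k: int = 3) -> dict[tuple[str, str], list[str]]:
    """Top-k models per (dataset, mode), descending IoU, lexicographic
    tie-break."""
    piv = table.pivot()
    if k > piv.shape[0]:
        raise ValueError(f"k={k} exceeds the {piv.shape[0]} available models")
    out: dict[tuple[str, str], list[str]] = {}
    for col in piv.columns:
        ordered = sorted(
            piv[col].items(), key=lambda kv: (-kv[1], kv[0])
        )
        out[col] = [name for name, _ in ordered[:k]]
    return out


def run_experiment_matrix(
    config: FederationConfig,
    datasets: dict[str, dict],
    architectures,
    base_width: int = 8,
) -> ResultsTable:
    """Train C/L/S for every (architecture, dataset) pair and evaluate
    average IoU on each dataset's held-out test shard.

    ``datasets`` maps a name to ``{"task_kind": ..., "client_shards":
    [(train, val), ...], "test": [...]}``.
    """
    rows = []
    for ds_name, ds in datasets.items():
        task = ds["task_kind"]
        shards = ds["client_shards"]
        test = ds["test"]
        nc = num_classes_for(task)
        pooled = [s for tr, _ in (map(_train_val, shards)) for s in tr]
        for arch in architectures:
            factory = lambda seed: build_model(  # noqa: E731
                arch, num_classes=nc, base_width=base_width, seed=seed
            )
            central = factory(config.seed)
            run_centralized(central, pooled, config)
            rows.append((arch, ds_name, "C", evaluate_model(central, test, task)))
            _, _, local_mean = run_local_only(factory, shards, test, config, task)
            rows.append((arch, ds_name, "L", local_mean))
            sf_model, _hist = run_splitfed(factory, shards, config, task_kind=task)
            rows.append((arch, ds_name, "S", evaluate_model(sf_model, test, task)))
    return ResultsTable(
        pd.DataFrame(rows, columns=["model", "dataset", "mode", "avg_iou"])
    )


def _train_val(shard):
    if isinstance(shard, tuple):
        return shard
    return shard, []


def summarize(table: ResultsTable, k: int = 3) -> dict:
    """JSON-friendly summary: average row, per-dataset diffs, top-k."""
    avg = compute_average_row(table)
    datasets = list(dict.fromkeys(table.data["dataset"]))
    diffs = {}
    for ds in datasets:
        try:
            c_l, c_s = compute_column_diffs(table, ds)
            diffs[ds] = {"C_minus_L_pp": c_l, "C_minus_S_pp": c_s}
        except ValueError:
            continue
    k_eff = min(k, len(table.models))
    rankings = {
        f"{ds}/{mode}": names
        for (ds, mode), names in rank_top_models(table, k_eff).items()
    }
    return {
        "average_over_models": {f"{ds}/{mode}": float(v) for (ds, mode), v in avg.items()},
        "column_diffs": diffs,
        "top_models": rankings,
    }


def mean_round_trend(history) -> list[float]:
    """Per-round mean validation IoU across clients (NaN-safe)."""
    return [float(np.nanmean(r.client_val_iou)) for r in history]
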