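"""Benchmark harness: accuracy/runtime experiments over synthetic scenarios.

Each experiment grid is a list of cells (scenario factors + fit factors);
every cell is repeated R times with fresh, independently seeded train and
held-out test draws.  Accuracy is the fraction of exact label matches on the
test set; wall-clock fit/predict times are recorded for information only —
they depend on hardware and are never asserted.

Held-out protocol: each replicate draws an independent test set of
``n_test = max(2000, n // 5)`` observations from the same scenario as its
training set.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score

from .classifier import PAVGaussianNB
from .synthdata import OVERLAP_PRESETS, ScenarioSpec

#: Columns of the long-format results table.
RESULT_COLUMNS = ["preset", "level", "n", "p", "K", "n_iter", "feature_fraction",
                  "cores", "replicate", "seed", "accuracy", "fit_seconds",
                  "predict_seconds"]


def accuracy(predicted, truth) -> float:
    """Fraction of exact matches between predicted and true labels."""
    predicted, truth = np.asarray(predicted), np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    if predicted.size == 0:
        raise ValueError("need at least one prediction")
    return float(accuracy_score(truth, predicted))


def scalability_efficiency(t1: float, tc: float, c: int) -> float:
    """Fraction of ideal linear speedup realized with c workers: t1 / (c * tc)."""
    if t1 <= 0 or tc <= 0:
        raise ValueError("runtimes must be positive")
    if c < 1:
        raise ValueError("c must be >= 1")
    return t1 / (c * tc)


def held_out_size(n: int) -> int:
    return max(2000, n // 5)


@dataclass(frozen=True)
class Cell:
    """One experiment condition: a scenario plus fit configuration."""

    level: str
    n: int
    p: int
    K: int
    n_iter: int = 100
    feature_fraction: float = 0.25
    cores: int = 1
    label: str = ""

    def scenario(self, seed: int) -> ScenarioSpec:
        d, rho = OVERLAP_PRESETS[self.level]
        return ScenarioSpec(n=self.n, p=self.p, K=self.K, spacing=d, rho=rho,
                            seed=seed)


@dataclass(frozen=True)
class ExperimentGrid:
    """A named list of cells, replicate count and base seed."""

    name: str
    cells: tuple[Cell, ...]
    replicates: int = 10
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _replicate_seeds(base_seed: int, cell_index: int, replicate: int):
    """(train_seed, test_seed, model_seed), each < 2^31, keyed by position."""
    state = np.random.SeedSequence(
        base_seed, spawn_key=(cell_index, replicate)).generate_state(3)
    return tuple(int(s) % 2 ** 31 for s in state)


def run_replicate(cell: Cell, train_seed: int, test_seed: int,
                  model_seed: int) -> dict:
    """Fresh train/test draws, one fit, one held-out accuracy measurement."""
    from .synthdata import generate_dataset  # local import keeps module load light

    train = generate_dataset(cell.scenario(train_seed))
    test_spec = replace(cell.scenario(test_seed), n=held_out_size(cell.n))
    test = generate_dataset(test_spec)
    model = PAVGaussianNB(n_iter=cell.n_iter,
                          feature_fraction=cell.feature_fraction,
                          n_jobs=cell.cores, random_state=model_seed)
    t0 = time.perf_counter()
    model.fit(train.X, train.y)
    t1 = time.perf_counter()
    predicted = model.predict(test.X)
    t2 = time.perf_counter()
    return {"accuracy": accuracy(predicted, test.y),
            "fit_seconds": t1 - t0, "predict_seconds": t2 - t1}


def run_experiment(grid: ExperimentGrid, progress=None) -> pd.DataFrame:
    """Run every cell x replicate; returns the long-format results table.

    Results are invariant to execution order: all randomness is keyed by
    (base_seed, cell index, replicate index).
    """
    rows = []
    for ci, cell in enumerate(grid.cells):
        for r in range(grid.replicates):
            train_seed, test_seed, model_seed = _replicate_seeds(
                grid.base_seed, ci, r)
            try:
                result = run_replicate(cell, train_seed, test_seed, model_seed)
            except Exception as exc:
                raise RuntimeError(
                    f"cell {ci} ({cell.label or cell.level}), replicate {r}: {exc}"
                ) from exc
            rows.append({"preset": grid.name, "level": cell.level,
                         "n": cell.n, "p": cell.p, "K": cell.K,
                         "n_iter": cell.n_iter,
                         "feature_fraction": cell.feature_fraction,
                         "cores": cell.cores, "replicate": r,
                         "seed": model_seed, **result,
                         "label": cell.label or cell.level})
            if progress is not None:
                progress(ci, r, rows[-1])
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Per-cell mean and standard deviation of accuracy (and runtime, FYI)."""
    grouped = results.groupby(
        ["preset", "label", "level", "n", "p", "K", "n_iter", "feature_fraction",
         "cores"], sort=False)
    out = grouped.agg(
        accuracy_mean=("accuracy", "mean"),
        accuracy_sd=("accuracy", "std"),
        runtime_mean=("fit_seconds", lambda s: float(np.mean(
            s + results.loc[s.index, "predict_seconds"]))),
        replicates=("accuracy", "size"),
    ).reset_index()
    out["accuracy_sd"] = out["accuracy_sd"].fillna(0.0)
    return out


def _scaled(value: int, scale: float, floor: int) -> int:
    return max(int(value * scale), floor)


def experiment_presets(scale: float = 1.0, base_seed: int = 0,
                       replicates: int = 10) -> dict[str, ExperimentGrid]:
    """The six named experiment families, optionally shrunk for desk runs.

    ``scale`` multiplies n, p and T (floored, with minimum sizes that keep
    every cell well posed); replicate counts are preserved.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")

    def N(n):  # sample sizes
        return _scaled(n, scale, 60)

    def P(p):  # feature counts
        return _scaled(p, scale, 4)

    def T(t):  # ensemble sizes
        return _scaled(t, scale, 2)

    levels = ("none", "low", "moderate", "high")
    grids = {}
    grids["baseline"] = ExperimentGrid(
        "baseline",
        tuple(Cell(level=lv, n=N(1000), p=P(50), K=3, n_iter=T(100),
                   feature_fraction=0.25, cores=1, label=lv) for lv in levels),
        replicates, base_seed)
    grids["scalability"] = ExperimentGrid(
        "scalability",
        tuple(Cell(level="moderate", n=N(5000), p=P(100), K=3, n_iter=T(100),
                   feature_fraction=0.25, cores=c, label=f"cores={c}")
              for c in (1, 2, 4, 8, 16)),
        replicates, base_seed)
    grids["dimensionality"] = ExperimentGrid(
        "dimensionality",
        tuple(Cell(level="moderate", n=N(5000), p=P(p), K=3, n_iter=T(100),
                   feature_fraction=0.25, label=f"p={p}")
              for p in (10, 50, 100, 500, 1000, 2000)),
        replicates, base_seed)
    grids["sample-size"] = ExperimentGrid(
        "sample-size",
        tuple(Cell(level="moderate", n=N(n), p=P(100), K=3, n_iter=T(100),
                   feature_fraction=0.25, label=f"n={n}")
              for n in (500, 1000, 5000, 10000, 20000, 50000, 100000, 200000)),
        replicates, base_seed)
    p_ff = P(100)
    fractions = [("sqrt(p)", np.sqrt(p_ff) / p_ff), ("p/10", 1 / 10),
                 ("p/5", 1 / 5), ("p/4", 1 / 4), ("p/3", 1 / 3),
                 ("p/2", 1 / 2), ("p", 1.0)]
    grids["feature-fraction"] = ExperimentGrid(
        "feature-fraction",
        tuple(Cell(level="moderate", n=N(5000), p=p_ff, K=3, n_iter=T(100),
                   feature_fraction=f, label=lab) for lab, f in fractions),
        replicates, base_seed)
    grids["complexity"] = ExperimentGrid(
        "complexity",
        tuple(Cell(level=lv, n=N(100000), p=P(1000), K=k, n_iter=T(100),
                   feature_fraction=0.25, cores=8, label=f"K={k},{lv}")
              for k in (2, 3, 5, 10) for lv in ("moderate", "high")),
        replicates, base_seed)
    grids["iterations"] = ExperimentGrid(
        "iterations",
        tuple(Cell(level="moderate", n=N(10000), p=P(100), K=3, n_iter=T(t),
                   feature_fraction=0.25, label=f"T={t}")
              for t in (10, 50, 100, 300, 500)),
        replicates, base_seed)
    return grids


def pima_workflow(frame: pd.DataFrame, response: str = "diabetes",
                  n_iter: int = 100, feature_fraction: float = 0.5,
                  train_fraction: float = 0.7, seed: int = 123) -> dict:
    """70/30 split workflow on a real tabular dataset (e.g. Pima diabetes).

    Shuffles rows with the given seed, trains on the first
    ``train_fraction`` share and reports held-out accuracy plus the fitted
    model.  Accuracy on real data is split- and seed-sensitive.
    """
    rng = np.random.default_rng(seed)
    n = len(frame)
    idx = rng.permutation(n)
    n_train = int(train_fraction * n)
    X = frame.drop(columns=[response]).to_numpy(dtype=float)
    y = frame[response].to_numpy()
    tr, te = idx[:n_train], idx[n_train:]
    model = PAVGaussianNB(n_iter=n_iter, feature_fraction=feature_fraction,
                          random_state=seed).fit(X[tr], y[tr])
    acc = accuracy(model.predict(X[te]), y[te])
    return {"model": model, "accuracy": acc, "n_train": len(tr), "n_test": len(te)}
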