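"""Replicate construction and fitting.

The modeling protocol: presence cells are split 70/30 into calibration and
test partitions, pseudoabsence cells are drawn 1:1 from cells with no record,
and the split is repeated independently for each of the five algorithms and
each repetition. Every (algorithm, repetition) pair yields one fitted
replicate carrying its prediction raster and test-partition AUC/TSS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import evaluation
from .grid import Raster, RasterStack
from .models import ALGORITHMS, make_model, predict_raster
from .occurrences import PresenceCells


class SamplingError(RuntimeError):
    pass


@dataclass
class ReplicateSpec:
    """One algorithm x repetition dataset: partitioned presence and background cells."""

    algorithm: str
    rep_index: int
    train_presence_cells: np.ndarray
    test_presence_cells: np.ndarray
    train_background_cells: np.ndarray
    test_background_cells: np.ndarray
    seed: int


@dataclass
class FittedReplicate:
    """A fitted replicate: model, prediction raster, and test metrics."""

    spec: ReplicateSpec
    model: object
    prediction: Raster
    auc: float
    tss: float
    threshold: float
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    source_model_label: str = "observed"


def _child_seed(master: int, algo_index: int, rep: int) -> int:
    ss = np.random.SeedSequence([master, algo_index, rep])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def make_replicates(presence_cells: PresenceCells, background_pool: np.ndarray,
                    n_reps: int = 100, train_frac: float = 0.7,
                    algorithms: tuple[str, ...] = ALGORITHMS,
                    seed: int = 0) -> list[ReplicateSpec]:
    """Build len(algorithms) * n_reps replicate datasets.

    Per replicate: round(train_frac * n) presence cells go to calibration and
    the rest to test (uniform, without replacement); background cells are
    drawn uniformly without replacement from ``background_pool`` (cells with
    no record of the species), one per presence cell in each partition.
    Partitions are redrawn independently for every (algorithm, repetition),
    each from a child seed of ``seed``.
    """
    cells = np.asarray(presence_cells.cells, dtype=np.int64)
    n = cells.size
    if n < 5:
        raise SamplingError(f"need at least 5 presence cells, got {n}")
    pool = np.setdiff1d(np.asarray(background_pool, dtype=np.int64), cells)
    if pool.size < n:
        raise SamplingError(
            f"background pool ({pool.size} cells) smaller than presence count ({n})")
    n_train = int(round(train_frac * n))
    n_train = min(max(n_train, 1), n - 1)  # both partitions non-empty

    specs: list[ReplicateSpec] = []
    for ai, alg in enumerate(algorithms):
        for rep in range(1, n_reps + 1):
            child = _child_seed(seed, ai, rep)
            rng = np.random.default_rng(child)
            perm = rng.permutation(cells)
            bg = rng.choice(pool, size=n, replace=False)
            specs.append(ReplicateSpec(
                algorithm=alg,
                rep_index=rep,
                train_presence_cells=np.sort(perm[:n_train]),
                test_presence_cells=np.sort(perm[n_train:]),
                train_background_cells=np.sort(bg[:n_train]),
                test_background_cells=np.sort(bg[n_train:]),
                seed=child,
            ))
    return specs


def fit_replicate(spec: ReplicateSpec, stack: RasterStack, var_names: list[str],
                  rf_trees: int = 500) -> FittedReplicate:
    """Fit one replicate on the calibration partition and score it on test cells.

    The model is projected over the full stack; test scores are read off the
    prediction raster so that rasters and metrics always agree.
    """
    X_train = np.vstack([
        stack.values_at_cells(spec.train_presence_cells, var_names),
        stack.values_at_cells(spec.train_background_cells, var_names),
    ])
    y_train = np.concatenate([
        np.ones(spec.train_presence_cells.size, dtype=int),
        np.zeros(spec.train_background_cells.size, dtype=int),
    ])
    model = make_model(spec.algorithm, seed=spec.seed, rf_trees=rf_trees)
    model.fit(X_train, y_train)
    pred = predict_raster(model, stack, var_names)

    s_pres = pred.at_cells(spec.test_presence_cells)
    s_back = pred.at_cells(spec.test_background_cells)
    auc = evaluation.auc(s_pres, s_back)
    threshold, tss, sens, spc = evaluation.select_threshold_tss(s_pres, s_back)
    return FittedReplicate(spec=spec, model=model, prediction=pred, auc=auc,
                           tss=tss, threshold=threshold, sensitivity=sens,
                           specificity=spc, source_model_label=stack.source_model_label)


def fit_replicates(specs: list[ReplicateSpec], stack: RasterStack,
                   var_names: list[str], rf_trees: int = 500) -> list[FittedReplicate]:
    """Fit all replicates; a replicate whose fit raises is dropped with a warning."""
    fitted: list[FittedReplicate] = []
    for spec in specs:
        try:
            fitted.append(fit_replicate(spec, stack, var_names, rf_trees=rf_trees))
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(
                f"replicate {spec.algorithm}#{spec.rep_index} dropped: {exc}",
                stacklevel=2)
    return fitted
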