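"""Permutation variable importance and response curves for the ensemble."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._rng import substream
from .ensemble_eval import EnsembleModel, to_scores
from .fitcore import WeightedDataset


@dataclass(frozen=True)
class ImportanceRecord:
    layer_name: str
    importance: float  # 1 - mean correlation, in [0, 2]
    n_permutations: int
    seed: int


@dataclass(frozen=True)
class ResponseCurve:
    layer_name: str
    grid: np.ndarray
    predicted: np.ndarray  # suitability 0..1000 per grid point
    others_at: dict        # layer -> median held fixed


def permutation_importance(
    model: EnsembleModel,
    dataset: WeightedDataset,
    n_perm: int = 10,
    seed: int = 0,
) -> list[ImportanceRecord]:
    """Importance = 1 - mean correlation(intact, permuted) over n_perm shuffles.

    Zero-variance intact predictions (or permuted ones) give importance 0 by
    convention, with a warning, so NaN never propagates.
    """
    if list(dataset.layer_names) != list(model.layer_names):
        raise ValueError("dataset columns do not match model layers")
    X = dataset.X
    intact = model.predict_rows(X)
    records = []
    for j, name in enumerate(model.layer_names):
        if np.std(intact) == 0:
            warnings.warn("constant ensemble predictions; importance set to 0")
            records.append(ImportanceRecord(name, 0.0, n_perm, seed))
            continue
        blocks = []
        for k in range(1, n_perm + 1):
            rng = substream(seed, "perm_importance", name, k)
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
            blocks.append(Xp)
        # one batched predict per layer keeps slow learners affordable
        permuted_all = model.predict_rows(np.vstack(blocks))
        corrs = []
        for k in range(n_perm):
            permuted = permuted_all[k * len(X):(k + 1) * len(X)]
            if np.std(permuted) == 0:
                corrs.append(0.0)
            else:
                corrs.append(float(np.corrcoef(intact, permuted)[0, 1]))
        records.append(ImportanceRecord(name, 1.0 - float(np.mean(corrs)), n_perm, seed))
    return records


def evaluation_strip(
    model: EnsembleModel,
    dataset: WeightedDataset,
    layer_name: str,
    n_points: int = 100,
) -> ResponseCurve:
    """Sweep one predictor over its observed range, others held at median."""
    if layer_name not in model.layer_names:
        raise KeyError(f"layer {layer_name!r} not in model")
    j = list(model.layer_names).index(layer_name)
    col = dataset.X[:, j]
    lo, hi = float(col.min()), float(col.max())
    medians = np.median(dataset.X, axis=0)
    if lo == hi:  # degenerate constant column: flat single-value curve
        grid = np.array([lo])
    else:
        grid = np.linspace(lo, hi, n_points)
    X = np.tile(medians, (len(grid), 1))
    X[:, j] = grid
    predicted = to_scores(model.predict_rows(X)).astype(float)
    others = {n: float(m) for n, m in zip(model.layer_names, medians) if n != layer_name}
    return ResponseCurve(layer_name, grid, predicted, others)
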