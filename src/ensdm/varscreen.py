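"""Predictor screening: pairwise-correlation filter and stepwise VIF.

Two fixed steps: (1) greedy removal over pairs with |r| >= cutoff in
descending |r|, dropping the lower-priority member; (2) repeated removal of
the largest VIF while it exceeds the threshold. Priority defaults to
univariate discrimination of presence vs background (|AUC - 0.5|).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import substream
from .grid_io import PredictorStack
from .occprep import OccurrenceTable, presence_cells


@dataclass
class ScreeningSample:
    """Pooled presence + background rows for the candidate layers."""

    matrix: np.ndarray            # rows = cells, cols = layers
    layer_names: list[str]
    priority: dict                # layer -> tie-breaking score (higher = keep)
    labels: np.ndarray | None = None  # 1 presence / 0 background

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.layer_names):
            raise ValueError("column count does not match layer_names")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("screening sample contains non-finite values")
        if not all(np.isfinite(self.priority[n]) for n in self.layer_names):
            raise ValueError("priorities must be finite")

    def columns(self, names: list[str]) -> np.ndarray:
        idx = [self.layer_names.index(n) for n in names]
        return self.matrix[:, idx]


def _univariate_auc(x: np.ndarray, labels: np.ndarray) -> float:
    from .ensemble_eval import roc_auc

    return roc_auc(x, labels)


def build_screening_sample(
    stack: PredictorStack,
    presences: OccurrenceTable,
    n_background: int,
    seed: int = 0,
    priority: dict | None = None,
) -> ScreeningSample:
    """Presence cells plus uniform background cells from the valid grid."""
    spec = stack.spec
    pres = presence_cells(presences, spec)
    mask = stack.union_mask()
    rows, cols = np.where(~mask)
    if n_background > len(rows):
        raise ValueError(f"n_background={n_background} exceeds {len(rows)} valid cells")
    rng = substream(seed, "screening_background")
    pick = rng.choice(len(rows), size=n_background, replace=False, shuffle=False)
    brow, bcol = rows[pick], cols[pick]

    all_rows = np.concatenate([pres[:, 0], brow])
    all_cols = np.concatenate([pres[:, 1], bcol])
    matrix = stack.design_at(all_rows, all_cols)
    labels = np.concatenate([np.ones(len(pres), int), np.zeros(n_background, int)])

    if priority is None:
        priority = {}
        for j, name in enumerate(stack.names):
            auc = _univariate_auc(matrix[:, j], labels) if n_background else 0.5
            priority[name] = abs(auc - 0.5)
    return ScreeningSample(matrix, list(stack.names), priority, labels)


def correlation_filter(sample: ScreeningSample, cutoff: float = 0.80) -> list[str]:
    """Retained layer names after greedy |r| >= cutoff removal."""
    names = sample.layer_names
    if len(names) < 2:
        return list(names)
    corr = np.corrcoef(sample.matrix, rowvar=False)
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = abs(corr[i, j])
            if r >= cutoff:
                pairs.append((r, names[i], names[j]))
    # descending |r|; name order breaks exact |r| ties deterministically
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    alive = set(names)
    for _, a, b in pairs:
        if a in alive and b in alive:
            pa, pb = sample.priority[a], sample.priority[b]
            if pa > pb:
                alive.discard(b)
            elif pb > pa:
                alive.discard(a)
            else:
                alive.discard(max(a, b))
    return [n for n in names if n in alive]


def vif(sample: ScreeningSample, names: list[str] | None = None) -> dict:
    """Variance inflation factors, VIF_j = 1/(1 - R^2_j); +inf if collinear."""
    names = names or sample.layer_names
    if len(names) < 2:
        raise ValueError("VIF needs at least two layers")
    X = sample.columns(names)
    n, k = X.shape
    if n < k + 1:
        raise ValueError("fewer rows than columns + intercept")
    out = {}
    for j, name in enumerate(names):
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0:
            out[name] = float("inf")
            continue
        r2 = 1.0 - resid @ resid / ss_tot
        out[name] = float("inf") if 1.0 - r2 < 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_stepwise(
    sample: ScreeningSample,
    threshold: float = 10.0,
    names: list[str] | None = None,
) -> tuple[list[str], list[tuple[str, float]]]:
    """Drop the largest-VIF layer while it exceeds the threshold.

    Returns (retained names, removal trace of (name, vif-at-removal)).
    """
    alive = list(names or sample.layer_names)
    trace: list[tuple[str, float]] = []
    while len(alive) >= 2:
        scores = vif(sample, alive)
        worst = max(scores.values())
        if worst <= threshold:
            break
        candidates = [n for n in alive if scores[n] == worst]
        # ties: lower priority goes first, then name order
        victim = min(candidates, key=lambda n: (sample.priority[n], n))
        alive.remove(victim)
        trace.append((victim, worst))
    return alive, trace


def screen(
    sample: ScreeningSample,
    corr_cutoff: float = 0.80,
    vif_threshold: float = 10.0,
) -> dict:
    """Full two-step screening; returns a JSON-ready report."""
    after_corr = correlation_filter(sample, corr_cutoff)
    retained, trace = vif_stepwise(sample, vif_threshold, after_corr)
    corr = np.corrcoef(sample.matrix, rowvar=False)
    return {
        "layer_names": sample.layer_names,
        "correlation_matrix": np.atleast_2d(corr).tolist(),
        "priorities": {n: float(sample.priority[n]) for n in sample.layer_names},
        "corr_cutoff": corr_cutoff,
        "vif_threshold": vif_threshold,
        "removed_by_correlation": [n for n in sample.layer_names if n not in after_corr],
        "vif_removal_trace": [[n, v] for n, v in trace],
        "retained": retained,
    }
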