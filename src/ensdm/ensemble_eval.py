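"""Held-out evaluation, TSS-gated proportional-weight ensembles and
scenario projection.

Scores live on the integer 0..1000 suitability scale; the classification
rule everywhere is "score > threshold". The TSS-maximizing threshold is an
exhaustive scan returning the smallest argmax, so cutoffs are bit-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .fitcore import ReplicateModel, WeightedDataset
from .grid_io import GridError, PredictorStack, RasterLayer


@dataclass
class EvalRecord:
    replicate_id: str
    learner_name: str
    auc: float
    tss: float
    best_threshold: int
    sensitivity: float
    specificity: float

    def __post_init__(self):
        if abs(self.tss - (self.sensitivity + self.specificity - 1.0)) > 1e-9:
            raise ValueError("tss must equal sensitivity + specificity - 1")


@dataclass
class EnsembleModel:
    replicates: list[ReplicateModel]
    weights: np.ndarray
    gate: float
    cutoff: int | None = None
    layer_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("ensemble weights must sum to 1")

    def predict_rows(self, X: np.ndarray) -> np.ndarray:
        """Weighted-mean probability prediction on raw design rows."""
        acc = np.zeros(len(X))
        for w, rep in zip(self.weights, self.replicates):
            acc += w * rep.predict_rows(X)
        return acc


@dataclass
class SuitabilityMap:
    layer: RasterLayer  # integer values 0..1000
    scenario_id: str

    def __post_init__(self):
        vals = self.layer.valid_values()
        if len(vals) and (vals.min() < 0 or vals.max() > 1000):
            raise ValueError("suitability values must lie in 0..1000")


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def to_scores(p: np.ndarray) -> np.ndarray:
    """Probabilities [0,1] -> integer suitability 0..1000."""
    return _round_half_away(1000.0 * np.asarray(p, float)).astype(int)


def confusion_at_threshold(scores, labels, t: int) -> tuple[float, float]:
    """(sensitivity, specificity) with positives defined as score > t."""
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    if not (np.any(labels == 1) and np.any(labels == 0)):
        raise ValueError("both labels must be present")
    pos = scores > t
    tp = np.sum(pos & (labels == 1))
    fn = np.sum(~pos & (labels == 1))
    tn = np.sum(~pos & (labels == 0))
    fp = np.sum(pos & (labels == 0))
    return tp / (tp + fn), tn / (tn + fp)


def roc_auc(scores, labels) -> float:
    """Rank-statistic AUC with ties counted one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("both labels must be present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def max_tss(scores, labels) -> tuple[int, float, float, float]:
    """Exhaustive threshold scan over 0..1000; smallest argmax wins.

    Returns (t*, tss*, sensitivity, specificity).
    """
    scores = np.asarray(scores).astype(int)
    labels = np.asarray(labels)
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("both labels must be present")
    # counts of each score value per class; positives are scores > t
    pos_hist = np.bincount(scores[labels == 1], minlength=1001)
    neg_hist = np.bincount(scores[labels == 0], minlength=1001)
    tp = n1 - np.cumsum(pos_hist)     # tp[t] = # presences with score > t
    fp = n0 - np.cumsum(neg_hist)
    sens = tp / n1
    spec = (n0 - fp) / n0
    tss = sens + spec - 1.0
    t_star = int(np.argmax(tss))      # argmax returns the first (smallest) index
    return t_star, float(tss[t_star]), float(sens[t_star]), float(spec[t_star])


def evaluate_replicates(
    replicates: list[ReplicateModel],
    datasets: dict[int, WeightedDataset],
) -> list[EvalRecord]:
    """Held-out AUC and max-TSS per replicate; fills rep.eval_record."""
    out = []
    for rep in replicates:
        if rep.failed:
            continue
        ds = datasets[rep.set_id]
        ev = rep.split.evaluation
        scores = to_scores(rep.predict_rows(ds.X[ev]))
        labels = ds.y[ev]
        auc = roc_auc(scores, labels)
        t, tss, sens, spec = max_tss(scores, labels)
        rec = EvalRecord(rep.replicate_id, rep.learner_name, auc, tss, t, sens, spec)
        rep.eval_record = rec
        out.append(rec)
    return out


def summarize_performance(evals: list[EvalRecord]) -> pd.DataFrame:
    """Per-learner mean +/- sample SD table, sorted by mean TSS descending."""
    if not evals:
        raise ValueError("no evaluation records")
    df = pd.DataFrame(
        [{"learner": e.learner_name, "roc": e.auc, "tss": e.tss} for e in evals]
    )
    summ = df.groupby("learner").agg(
        roc_mean=("roc", "mean"), roc_sd=("roc", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
        tss_mean=("tss", "mean"), tss_sd=("tss", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
        n=("tss", "size"),
    )
    return summ.sort_values("tss_mean", ascending=False).reset_index()


def build_ensemble(
    replicates: list[ReplicateModel],
    gate: float = 0.70,
) -> EnsembleModel:
    """TSS-gated ensemble with weights proportional to replicate TSS."""
    scored = [r for r in replicates if not r.failed and r.eval_record is not None]
    passing = [r for r in scored if r.eval_record.tss >= gate]
    if not passing:
        best = max((r.eval_record.tss for r in scored), default=float("nan"))
        raise ValueError(
            f"no replicate passes the TSS gate {gate} (best TSS {best:.3f}); "
            "lower the gate or improve the inputs"
        )
    tss = np.array([r.eval_record.tss for r in passing])
    weights = tss / tss.sum()
    return EnsembleModel(passing, weights, gate, layer_names=list(passing[0].layer_names))


def ensemble_apparent_eval(model: EnsembleModel, datasets: dict[int, WeightedDataset]):
    """Evaluate the ensemble on the full presence + pooled pseudo-absence set.

    Sets model.cutoff to the TSS-maximizing threshold and returns an
    EvalRecord. Apparent (in-sample) evaluation, matching common
    ensemble-modelling practice; the caveat is recorded in the manifest.
    """
    Xs, ys = [], []
    for sid in sorted(datasets):
        ds = datasets[sid]
        if not Xs:
            pres = ds.y == 1
            Xs.append(ds.X[pres])
            ys.append(ds.y[pres])
        Xs.append(ds.X[ds.y == 0])
        ys.append(ds.y[ds.y == 0])
    X = np.vstack(Xs)
    y = np.concatenate(ys)
    scores = to_scores(model.predict_rows(X))
    auc = roc_auc(scores, y)
    t, tss, sens, spec = max_tss(scores, y)
    model.cutoff = t
    return EvalRecord("ensemble", "EMwmean", auc, tss, t, sens, spec)


def ensemble_predict(model: EnsembleModel, stack: PredictorStack) -> SuitabilityMap:
    """Project the ensemble onto a stack: integer 0..1000 suitability map."""
    missing = set(model.layer_names) - set(stack.names)
    if missing:
        raise GridError(f"stack {stack.scenario_id!r} lacks layers {sorted(missing)}")
    mask = stack.union_mask()
    rows, cols = np.where(~mask)
    X = stack.design_at(rows, cols, model.layer_names)
    p = model.predict_rows(X)
    vals = np.zeros(stack.spec.shape, dtype=np.int16)
    vals[rows, cols] = to_scores(p)
    layer = RasterLayer(stack.spec, vals, mask.copy(), name=f"suitability_{stack.scenario_id}")
    return SuitabilityMap(layer, stack.scenario_id)


def gcm_mean(stacks: list[PredictorStack], scenario_id: str | None = None) -> PredictorStack:
    """Cellwise multi-model mean per layer; union of nodata masks."""
    first = stacks[0]
    for st in stacks[1:]:
        if not first.spec.compatible(st.spec) or st.names != first.names:
            raise GridError("grid mismatch: stacks differ in grid or layer set")
    mask = np.zeros(first.spec.shape, bool)
    for st in stacks:
        mask |= st.union_mask()
    layers = []
    for name in first.names:
        mean = np.mean([st.get(name).values for st in stacks], axis=0)
        mean[mask] = 0.0
        layers.append(RasterLayer(first.spec, mean, mask.copy(), name))
    return PredictorStack(layers, scenario_id or first.scenario_id)


def project_all(model: EnsembleModel, stacks: list[PredictorStack]) -> list[SuitabilityMap]:
    """One suitability map per scenario with identical weights and cutoff."""
    return [ensemble_predict(model, st) for st in stacks]
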