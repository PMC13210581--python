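"""Pseudo-absence design, prevalence weighting, replicate splits and base
learners.

Each replicate is one (learner, pseudo-absence set, repeat) triple fitted on
a label-stratified 75/25 calibration split with equal summed class weights
(presence weight 1, pseudo-absence weight n_presence/n_pa). Base learners
satisfy a small contract (fit with sample weights, predict probabilities,
deterministic given a seed) so any algorithm can be plugged in.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from ._rng import substream
from .centroid import geodesic_distance_km
from .grid_io import PredictorStack
from .occprep import OccurrenceTable, presence_cells


@dataclass(frozen=True)
class PseudoAbsenceSet:
    set_id: int
    cells: np.ndarray  # (n, 2) row/col
    seed: int


@dataclass
class WeightedDataset:
    """Presence + pseudo-absence design rows with balanced class weights."""

    X: np.ndarray
    y: np.ndarray
    weights: np.ndarray
    layer_names: list[str]
    cells: np.ndarray  # (n, 2) row/col per row
    set_id: int

    def __post_init__(self):
        pres = self.weights[self.y == 1].sum()
        absn = self.weights[self.y == 0].sum()
        if abs(pres - absn) > 1e-9 * max(pres, 1.0):
            raise ValueError("summed presence and pseudo-absence weights differ")


@dataclass(frozen=True)
class SplitPlan:
    replicate_id: str
    set_id: int
    repeat_index: int
    calibration: np.ndarray
    evaluation: np.ndarray
    seed: int


@dataclass
class ReplicateModel:
    """One fitted base learner with its split; scores filled by evaluation."""

    learner_name: str
    replicate_id: str
    set_id: int
    repeat_index: int
    fitted: object
    means: np.ndarray
    sds: np.ndarray
    layer_names: list[str]
    split: SplitPlan
    failed: bool = False
    eval_record: object = None

    def predict_rows(self, X: np.ndarray) -> np.ndarray:
        z = (np.asarray(X, float) - self.means) / self.sds
        return self.fitted.predict(z)


# ---------------------------------------------------------------------------
# base-learner contract and default implementations


class BaseLearner(ABC):
    """Contract: weighted probabilistic fit, deterministic under a seed."""

    name: str = "base"

    @abstractmethod
    def fit(self, X: np.ndarray, y: np.ndarray, sample_weight: np.ndarray, seed: int):
        """Return a fitted state exposing predict(X) -> probabilities."""


class _SkFitted:
    def __init__(self, est):
        self.est = est

    def predict(self, X):
        p = self.est.predict_proba(X)[:, list(self.est.classes_).index(1)]
        return np.clip(p, 0.0, 1.0)


def _quad_expand(X):
    return np.column_stack([X, X**2])


class _QuadFitted:
    def __init__(self, est):
        self.est = est

    def predict(self, X):
        p = self.est.predict_proba(_quad_expand(X))[:, list(self.est.classes_).index(1)]
        return np.clip(p, 0.0, 1.0)


class LogisticQuadLearner(BaseLearner):
    """Weighted logistic regression with per-variable quadratic terms."""

    name = "glm_quad"

    def __init__(self, C: float = 1e4):
        self.C = C

    def fit(self, X, y, sample_weight, seed):
        est = LogisticRegression(C=self.C, max_iter=2000, solver="lbfgs")
        est.fit(_quad_expand(X), y, sample_weight=sample_weight)
        return _QuadFitted(est)


class RidgeLogisticLearner(LogisticQuadLearner):
    """Regularized logistic fit (MaxEnt-style stand-in)."""

    name = "ridge_quad"

    def __init__(self):
        super().__init__(C=1.0)


class RandomForestLearner(BaseLearner):
    name = "rf"

    def __init__(self, n_estimators: int = 100):
        self.n_estimators = n_estimators

    def fit(self, X, y, sample_weight, seed):
        est = RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=seed, n_jobs=1,
            min_samples_leaf=2,
        )
        est.fit(X, y, sample_weight=sample_weight)
        return _SkFitted(est)


class GradientBoostingLearner(BaseLearner):
    name = "gbm"

    def fit(self, X, y, sample_weight, seed):
        est = HistGradientBoostingClassifier(random_state=seed, max_iter=120)
        est.fit(X, y, sample_weight=sample_weight)
        return _SkFitted(est)


class _EnvelopeFitted:
    def __init__(self, lo, hi):
        self.lo = lo
        self.hi = hi

    def predict(self, X):
        inside = np.all((X >= self.lo) & (X <= self.hi), axis=1)
        return inside.astype(float)


class EnvelopeLearner(BaseLearner):
    """Rectangular envelope scorer (surface-range-envelope stand-in).

    Predicts 1 inside the central 95% per-variable presence quantile box.
    """

    name = "sre"

    def __init__(self, quantile: float = 0.025):
        self.q = quantile

    def fit(self, X, y, sample_weight, seed):
        pres = X[y == 1]
        return _EnvelopeFitted(np.quantile(pres, self.q, axis=0),
                               np.quantile(pres, 1 - self.q, axis=0))


class _ConstantFitted:
    def __init__(self, p):
        self.p = p

    def predict(self, X):
        return np.full(len(X), self.p)


class ConstantLearner(BaseLearner):
    """Test double: predicts a constant probability everywhere."""

    name = "const"

    def __init__(self, p: float = 0.5):
        self.p = p

    def fit(self, X, y, sample_weight, seed):
        return _ConstantFitted(self.p)


DEFAULT_LEARNERS = [
    LogisticQuadLearner(),
    RidgeLogisticLearner(),
    RandomForestLearner(),
    GradientBoostingLearner(),
    EnvelopeLearner(),
]

LEARNER_REGISTRY = {lrn.name: type(lrn) for lrn in DEFAULT_LEARNERS}


def make_learners(names: list[str]) -> list[BaseLearner]:
    unknown = [n for n in names if n not in LEARNER_REGISTRY]
    if unknown:
        raise KeyError(f"unknown learners {unknown}; available: {sorted(LEARNER_REGISTRY)}")
    return [LEARNER_REGISTRY[n]() for n in names]


# ---------------------------------------------------------------------------
# sampling, weighting, splitting


def draw_pseudo_absences(
    stack: PredictorStack,
    presences: OccurrenceTable,
    n_per_set: int = 10000,
    n_sets: int = 3,
    buffer_km: float = 5.0,
    seed: int = 0,
) -> list[PseudoAbsenceSet]:
    """Uniform draws from valid cells >= buffer_km from every presence center."""
    spec = stack.spec
    pres = presence_cells(presences, spec)
    mask = stack.union_mask()
    rows, cols = np.where(~mask)
    eligible = np.ones(len(rows), dtype=bool)

    pres_set = {tuple(rc) for rc in pres}
    is_presence = np.fromiter(
        ((r, c) in pres_set for r, c in zip(rows, cols)), bool, count=len(rows)
    )
    eligible &= ~is_presence

    if buffer_km > 0:
        lat_mid = spec.lat_center(spec.n_rows / 2)
        deg_pad = buffer_km / 111.0 / max(np.cos(np.deg2rad(lat_mid)), 0.1) + spec.cell_size
        lon = spec.lon_center(cols)
        lat = spec.lat_center(rows)
        plon = spec.lon_center(pres[:, 1])
        plat = spec.lat_center(pres[:, 0])
        for pl, pb in zip(plon, plat):
            near = eligible & (np.abs(lon - pl) <= deg_pad) & (np.abs(lat - pb) <= deg_pad)
            idx = np.where(near)[0]
            for i in idx:
                d, _ = geodesic_distance_km((pl, pb), (lon[i], lat[i]))
                if d < buffer_km:
                    eligible[i] = False

    pool = np.where(eligible)[0]
    if len(pool) < n_per_set:
        raise ValueError(
            f"only {len(pool)} eligible cells for {n_per_set} pseudo-absences"
        )
    sets = []
    for s in range(1, n_sets + 1):
        rng = substream(seed, "pseudo_absences", s)
        pick = rng.choice(pool, size=n_per_set, replace=False, shuffle=False)
        cells = np.column_stack([rows[pick], cols[pick]])
        sets.append(PseudoAbsenceSet(set_id=s, cells=cells, seed=seed))
    return sets


def prevalence_weights(n_presence: int, n_pa: int) -> tuple[float, float]:
    """Unit presence weight; pseudo-absence weight n_presence/n_pa."""
    if n_presence < 1 or n_pa < 1:
        raise ValueError("counts must be >= 1")
    return 1.0, n_presence / n_pa


def assemble_dataset(
    stack: PredictorStack,
    presences: OccurrenceTable,
    pa_set: PseudoAbsenceSet,
    layer_names: list[str],
) -> WeightedDataset:
    pres = presence_cells(presences, stack.spec)
    cells = np.vstack([pres, pa_set.cells])
    X = stack.design_at(cells[:, 0], cells[:, 1], layer_names)
    y = np.concatenate([np.ones(len(pres), int), np.zeros(len(pa_set.cells), int)])
    w_pres, w_pa = prevalence_weights(len(pres), len(pa_set.cells))
    w = np.where(y == 1, w_pres, w_pa)
    return WeightedDataset(X, y, w, list(layer_names), cells, pa_set.set_id)


def make_splits(
    labels: np.ndarray,
    frac: float = 0.75,
    n_repeats: int = 5,
    seed: int = 0,
    set_id: int = 0,
) -> list[SplitPlan]:
    """Label-stratified random calibration/evaluation splits."""
    labels = np.asarray(labels)
    n = len(labels)
    if n < 8:
        raise ValueError("need at least 8 rows to split")
    if not 0 < frac < 1:
        raise ValueError("frac must be strictly between 0 and 1 (empty partition otherwise)")
    plans = []
    for rep in range(1, n_repeats + 1):
        rng = substream(seed, "split", set_id, rep)
        cal_parts = []
        for lab in (0, 1):
            idx = np.where(labels == lab)[0]
            if len(idx) < 2:
                raise ValueError(f"stratum {lab} has fewer than 2 rows")
            k = int(round(frac * len(idx)))
            k = min(max(k, 1), len(idx) - 1)
            cal_parts.append(rng.permutation(idx)[:k])
        cal = np.sort(np.concatenate(cal_parts))
        ev = np.setdiff1d(np.arange(n), cal)
        plans.append(SplitPlan(
            replicate_id=f"set{set_id}_rep{rep}", set_id=set_id,
            repeat_index=rep, calibration=cal, evaluation=ev, seed=seed,
        ))
    return plans


def fit_replicates(
    learners: list[BaseLearner],
    datasets: list[WeightedDataset],
    splits_by_set: dict[int, list[SplitPlan]],
    seed: int = 0,
) -> list[ReplicateModel]:
    """Fit every learner x pseudo-absence set x repeat on calibration rows.

    Predictors are standardized by the calibration mean/SD, stored with the
    model. Learner failures flag the replicate instead of aborting the run.
    """
    replicates = []
    for ds in datasets:
        for plan in splits_by_set[ds.set_id]:
            cal = plan.calibration
            Xc = ds.X[cal]
            means = Xc.mean(axis=0)
            sds = Xc.std(axis=0)
            sds[sds == 0] = 1.0
            Zc = (Xc - means) / sds
            for lrn in learners:
                rid = f"{lrn.name}_{plan.replicate_id}"
                sub_seed = int(substream(seed, "fit", rid).integers(0, 2**31 - 1))
                rep = ReplicateModel(
                    learner_name=lrn.name, replicate_id=rid,
                    set_id=ds.set_id, repeat_index=plan.repeat_index,
                    fitted=None, means=means, sds=sds,
                    layer_names=ds.layer_names, split=plan,
                )
                try:
                    rep.fitted = lrn.fit(Zc, ds.y[cal], ds.weights[cal], sub_seed)
                except Exception:  # noqa: BLE001 - mirror ensembles dropping failed runs
                    rep.failed = True
                replicates.append(rep)
    return replicates
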