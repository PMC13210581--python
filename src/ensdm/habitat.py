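"""Threshold binarization, cutoff-anchored Jenks classes, equal-area class
areas and cross-scenario change statistics.

Class intervals are right-closed on the integer 0..1000 scale: unsuitable
<= cutoff, low ends at b1, moderate at b2, high at 1000. Breaks are fitted
once on the baseline map (Jenks on suitable-cell values only) and reused
for every scenario.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .ensemble_eval import SuitabilityMap
from .grid_io import GridError, RasterLayer

CLASS_NAMES = ["unsuitable", "low", "moderate", "high"]


@dataclass(frozen=True)
class ClassBreaks:
    cutoff: int
    b1: int
    b2: int
    provenance: str = "jenks-on-baseline"  # or "explicit"

    def __post_init__(self):
        if not self.cutoff < self.b1 < self.b2 < 1000:
            raise ValueError(f"need cutoff < b1 < b2 < 1000, got {self}")


@dataclass
class ClassifiedMap:
    layer: RasterLayer  # values 0..3
    scenario_id: str
    breaks: ClassBreaks


@dataclass
class AreaTable:
    """Per-class areas (1e4 km²) and proportions (%) for one scenario."""

    scenario_id: str
    areas: dict          # class name -> area in 1e4 km2
    proportions: dict    # class name -> % of total valid area
    total_suitable: float

    @classmethod
    def from_class_areas(cls, scenario_id: str, unsuitable: float, low: float,
                         moderate: float, high: float) -> "AreaTable":
        """Aggregate explicit class areas (1e4 km²) into a table."""
        areas = {"unsuitable": unsuitable, "low": low, "moderate": moderate, "high": high}
        total = sum(areas.values())
        props = {k: 100.0 * v / total for k, v in areas.items()}
        return cls(scenario_id, areas, props, low + moderate + high)

    def __post_init__(self):
        if abs(sum(self.proportions.values()) - 100.0) > 0.01:
            raise ValueError("class proportions must sum to 100")
        expect = self.areas["low"] + self.areas["moderate"] + self.areas["high"]
        if abs(self.total_suitable - expect) > 1e-6:
            raise ValueError("total suitable must equal low + moderate + high")


@dataclass(frozen=True)
class ChangeRecord:
    scenario_id: str
    area_change: dict    # class name -> future - current (1e4 km2)
    rate: dict           # class name -> 100*(future-current)/current (%)
    total_rate: float    # % change of total suitable habitat
    core_rate: float     # % change of the high class

    @property
    def core_contraction(self) -> float:
        """Contraction magnitude, 100*(current - future)/current."""
        return -self.core_rate


def binarize(smap: SuitabilityMap, cutoff: int) -> RasterLayer:
    """Suitable (1) iff value > cutoff; nodata preserved."""
    if not 0 <= cutoff <= 999:
        raise ValueError("cutoff must be in 0..999")
    vals = (smap.layer.values > cutoff).astype(np.uint8)
    vals[smap.layer.nodata_mask] = 0
    return RasterLayer(smap.layer.spec, vals, smap.layer.nodata_mask.copy(),
                       name=f"suitable_{smap.scenario_id}")


def jenks_breaks(values, k: int) -> list[float]:
    """Exact Fisher-Jenks natural breaks minimizing within-class SSE.

    Returns the maximum value of each class except the last (k-1 breaks).
    Runs the dynamic program on (value, count) pairs, so integer suitability
    multisets with up to 1001 distinct values stay cheap.
    """
    values = np.asarray(values, dtype=float).ravel()
    if k < 2 or len(values) < k:
        raise ValueError("need |values| >= k >= 2")
    v, cnt = np.unique(values, return_counts=True)
    m = len(v)
    if m < k:
        warnings.warn(f"only {m} distinct values for k={k}: degenerate breaks")
        return list(v[: k - 1])
    cw = np.concatenate([[0.0], np.cumsum(cnt)])
    cs = np.concatenate([[0.0], np.cumsum(cnt * v)])
    cq = np.concatenate([[0.0], np.cumsum(cnt * v * v)])

    def sse(i: int, j: int) -> float:
        # within-class SSE of distinct values i..j inclusive
        w = cw[j + 1] - cw[i]
        s = cs[j + 1] - cs[i]
        q = cq[j + 1] - cq[i]
        return q - s * s / w

    INF = float("inf")
    cost = np.full((k + 1, m), INF)
    cut = np.zeros((k + 1, m), dtype=int)
    for j in range(m):
        cost[1, j] = sse(0, j)
    for c in range(2, k + 1):
        for j in range(c - 1, m):
            best, arg = INF, c - 2
            for i in range(c - 2, j):
                cand = cost[c - 1, i] + sse(i + 1, j)
                if cand < best:
                    best, arg = cand, i
            cost[c, j] = best
            cut[c, j] = arg
    breaks = []
    j = m - 1
    for c in range(k, 1, -1):
        i = cut[c, j]
        breaks.append(float(v[i]))
        j = i
    return breaks[::-1]


def jenks_sse(values, breaks) -> float:
    """Total within-class SSE of a multiset under given right-closed breaks."""
    values = np.asarray(values, dtype=float).ravel()
    edges = [-np.inf, *breaks, np.inf]
    total = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        grp = values[(values > lo) & (values <= hi)]
        if len(grp):
            total += float(np.sum((grp - grp.mean()) ** 2))
    return total


def anchored_classification(
    baseline: SuitabilityMap,
    cutoff: int,
    k_suitable: int = 3,
    explicit: tuple[int, int] | None = None,
) -> ClassBreaks:
    """Breaks anchored at the cutoff; Jenks on baseline suitable-cell values."""
    if explicit is not None:
        return ClassBreaks(cutoff, explicit[0], explicit[1], provenance="explicit")
    vals = baseline.layer.valid_values()
    suitable = vals[vals > cutoff]
    if len(suitable) < k_suitable:
        raise ValueError("baseline has fewer suitable cells than classes")
    bks = jenks_breaks(suitable, k_suitable)
    if len(bks) < 2:
        raise ValueError("degenerate baseline: could not derive two interior breaks")
    return ClassBreaks(cutoff, int(bks[0]), int(bks[1]))


def classify(smap: SuitabilityMap, breaks: ClassBreaks) -> ClassifiedMap:
    """0 iff <= cutoff; 1 iff (cutoff, b1]; 2 iff (b1, b2]; 3 iff > b2."""
    v = smap.layer.values
    cls = np.zeros(v.shape, dtype=np.uint8)
    cls[v > breaks.cutoff] = 1
    cls[v > breaks.b1] = 2
    cls[v > breaks.b2] = 3
    cls[smap.layer.nodata_mask] = 0
    layer = RasterLayer(smap.layer.spec, cls, smap.layer.nodata_mask.copy(),
                        name=f"classes_{smap.scenario_id}")
    return ClassifiedMap(layer, smap.scenario_id, breaks)


def area_table(classified: ClassifiedMap, areas: RasterLayer) -> AreaTable:
    """Class areas summed over cells, reported in 1e4 km² and % of valid area."""
    if not classified.layer.spec.compatible(areas.spec):
        raise GridError("grid mismatch between classified map and cell areas")
    valid = ~classified.layer.nodata_mask
    cls = classified.layer.values
    by_class = {}
    for code, name in enumerate(CLASS_NAMES):
        by_class[name] = float(areas.values[valid & (cls == code)].sum()) / 1e4
    return AreaTable.from_class_areas(classified.scenario_id, **by_class)


def change_stats(current: AreaTable, future: AreaTable) -> ChangeRecord:
    """Signed change rates of each class, total suitable and core habitat."""
    if current.total_suitable <= 0:
        raise ValueError("current total suitable area must be positive")
    change, rate = {}, {}
    for name in CLASS_NAMES:
        c, f = current.areas[name], future.areas[name]
        change[name] = f - c
        rate[name] = 100.0 * (f - c) / c if c > 0 else float("nan")
    total_rate = 100.0 * (future.total_suitable - current.total_suitable) / current.total_suitable
    core_rate = rate["high"]
    return ChangeRecord(future.scenario_id, change, rate, total_rate, core_rate)
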