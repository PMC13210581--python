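"""Synthetic predictor stacks, known-truth suitability and contaminated
occurrence tables.

Layers are smoothed Gaussian random fields (white noise convolved with an
isotropic Gaussian kernel, standardized over valid cells), cross-correlated
by mixing independent fields with a Cholesky factor of the target
correlation matrix. A quadratic-logistic TrueModel defines ground-truth
suitability; sampled presences get contaminated with records that violate
named cleaning rules, each tagged so the cleaning stage can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, linalg

from ._rng import substream
from .grid_io import GridSpec, PredictorStack, RasterLayer
from . import occprep
from .occprep import OccurrenceTable

TERRAIN_LAYER = "elev"


@dataclass(frozen=True)
class TrueModel:
    """Ground-truth logistic-quadratic suitability on standardized layers.

    p(x) = logistic(intercept + sum b_v z_v + sum g_v z_v^2), g_v <= 0 so
    responses are unimodal.
    """

    intercept: float
    linear_coefs: tuple[float, ...]
    quad_coefs: tuple[float, ...]
    layer_names: tuple[str, ...]

    def __post_init__(self):
        if not len(self.linear_coefs) == len(self.quad_coefs) == len(self.layer_names):
            raise ValueError("coefficient/name lengths differ")
        if any(g > 0 for g in self.quad_coefs):
            raise ValueError("quad_coefs must be <= 0 (unimodal responses)")


@dataclass(frozen=True)
class ScenarioDelta:
    """Per-layer mean shift and scale factor for one future scenario."""

    scenario_id: str
    shift: dict = field(default_factory=dict)   # layer -> additive shift
    scale: dict = field(default_factory=dict)   # layer -> multiplicative scale on anomalies

    def __post_init__(self):
        if self.shift.get(TERRAIN_LAYER, 0.0) != 0.0 or self.scale.get(TERRAIN_LAYER, 1.0) != 1.0:
            raise ValueError("the terrain layer must stay constant across scenarios")


def _smooth_field(rng: np.random.Generator, shape, corr_length: float) -> np.ndarray:
    noise = rng.standard_normal(shape)
    return ndimage.gaussian_filter(noise, sigma=corr_length, mode="reflect")


def generate_stack(
    spec: GridSpec,
    n_layers: int,
    corr_length: float,
    cross_corr: np.ndarray | None = None,
    seed: int = 0,
    layer_names: list[str] | None = None,
    mask: np.ndarray | None = None,
    scenario_id: str = "current",
) -> PredictorStack:
    """Spatially autocorrelated, cross-correlated standardized layers."""
    if cross_corr is None:
        cross_corr = np.eye(n_layers)
    cross_corr = np.asarray(cross_corr, dtype=float)
    if cross_corr.shape != (n_layers, n_layers) or not np.allclose(cross_corr, cross_corr.T):
        raise ValueError("cross_corr must be a symmetric n_layers x n_layers matrix")
    try:
        chol = linalg.cholesky(cross_corr, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError("cross_corr is not positive-definite") from exc
    if layer_names is None:
        layer_names = [f"var{i + 1}" for i in range(n_layers)]
    if mask is None:
        mask = np.zeros(spec.shape, dtype=bool)

    rng = substream(seed, "generate_stack", scenario_id)
    fields = np.empty((n_layers,) + spec.shape)
    for i in range(n_layers):
        f = _smooth_field(rng, spec.shape, corr_length)
        valid = f[~mask]
        fields[i] = (f - valid.mean()) / valid.std()
    mixed = np.einsum("ij,jrc->irc", chol, fields)
    layers = []
    for i, name in enumerate(layer_names):
        f = mixed[i]
        valid = f[~mask]
        std = (f - valid.mean()) / valid.std()  # restandardize after mixing
        std = std.copy()
        std[mask] = 0.0
        layers.append(RasterLayer(spec, std, mask.copy(), name))
    return PredictorStack(layers, scenario_id)


def true_suitability(
    model: TrueModel,
    stack: PredictorStack,
    reference: PredictorStack | None = None,
) -> RasterLayer:
    """Per-cell logistic evaluation of the TrueModel on standardized layers.

    Standardization constants come from ``reference`` (default: the stack
    itself); pass the baseline stack when evaluating truth on a scenario so
    climate shifts translate into suitability change.
    """
    reference = reference or stack
    mask = stack.union_mask()
    ref_mask = reference.union_mask()
    eta = np.full(stack.spec.shape, model.intercept, dtype=float)
    for name, b, g in zip(model.layer_names, model.linear_coefs, model.quad_coefs):
        vals = stack.get(name).values.astype(float)
        ref_vals = reference.get(name).values[~ref_mask]
        z = (vals - ref_vals.mean()) / (ref_vals.std() or 1.0)
        eta += b * z + g * z * z
    p = 1.0 / (1.0 + np.exp(-eta))
    p[mask] = 0.0
    return RasterLayer(stack.spec, p, mask, name="true_suitability")


@dataclass(frozen=True)
class Contamination:
    """Counts of planted records violating named cleaning rules."""

    missing_coords: int = 0
    coarse_precision: int = 0
    flagged: int = 0
    equal_coords: int = 0
    outside_domain: int = 0
    bad_elevation: int = 0
    old_year: int = 0
    duplicate_cell: int = 0

    def total(self) -> int:
        return sum(vars(self).values())


def sample_occurrences(
    truth: RasterLayer,
    n: int,
    seed: int = 0,
    contamination: Contamination | None = None,
    jitter_frac: float = 0.25,
) -> OccurrenceTable:
    """Presence cells drawn without replacement with probability ~ truth.

    Points sit at cell centers with jitter < cell_size/2. Contaminated
    records are appended and tagged in a ``truth_tag`` column that cleaning
    ignores but tests read.
    """
    rng = substream(seed, "sample_occurrences")
    spec = truth.spec
    rows, cols = np.where(~truth.nodata_mask)
    if n > len(rows):
        raise ValueError(f"n={n} exceeds {len(rows)} valid cells")
    p = truth.values[rows, cols].astype(float)
    p = p / p.sum()
    pick = rng.choice(len(rows), size=n, replace=False, p=p, shuffle=False)

    cell = spec.cell_size
    recs = []

    def _point(r, c):
        jit = rng.uniform(-jitter_frac, jitter_frac, size=2) * cell
        return spec.lon_center(c) + jit[0], spec.lat_center(r) + jit[1]

    def _base(i, r, c, tag=""):
        lon, lat = _point(r, c)
        return {
            "id": f"occ{i:05d}", "lon": lon, "lat": lat,
            "precision_deg": 0.001, "year": int(rng.integers(1980, 2023)),
            "elevation_m": float(rng.uniform(300, 2000)),
            "sea_flag": False, "centroid_flag": False, "institution_flag": False,
            "status": "raw", "drop_reason": pd.NA, "truth_tag": tag,
        }

    for i, k in enumerate(pick):
        recs.append(_base(i, rows[k], cols[k]))

    if contamination is not None:
        j = n
        pool = rng.choice(len(rows), size=max(1, contamination.total()) * 2, replace=True)
        pool_i = iter(pool.tolist())

        def bad(tag, **overrides):
            nonlocal j
            k = next(pool_i)
            rec = _base(j, rows[k], cols[k], tag=tag)
            rec["id"] = f"bad{j:05d}"
            rec.update(overrides)
            recs.append(rec)
            j += 1

        for _ in range(contamination.missing_coords):
            bad(occprep.RULE_MISSING_COORDS, lat=np.nan)
        for _ in range(contamination.coarse_precision):
            bad(occprep.RULE_PRECISION, precision_deg=0.05)
        for _ in range(contamination.flagged):
            bad(occprep.RULE_FLAGGED, sea_flag=True)
        for _ in range(contamination.equal_coords):
            bad(occprep.RULE_EQUAL_COORDS, lon=25.0, lat=25.0)
        for _ in range(contamination.outside_domain):
            bad(occprep.RULE_OUTSIDE_DOMAIN,
                lon=spec.lon_min - 5.0, lat=spec.lat_max + 5.0)
        for _ in range(contamination.bad_elevation):
            bad(occprep.RULE_ELEVATION, elevation_m=5000.0)
        for _ in range(contamination.old_year):
            bad(occprep.RULE_YEAR, year=1960)
        for _ in range(contamination.duplicate_cell):
            # same cell as an existing clean presence -> thinning must fire
            k = pick[int(rng.integers(0, n))]
            r, c = rows[k], cols[k]
            rec = _base(j, r, c, tag=occprep.RULE_THINNED)
            rec["id"] = f"zzz{j:05d}"  # sorts after occ* so the original wins
            rec["lon"], rec["lat"] = spec.lon_center(c), spec.lat_center(r)
            recs.append(rec)
            j += 1

    return OccurrenceTable(pd.DataFrame(recs))


def apply_scenario(stack: PredictorStack, delta: ScenarioDelta) -> PredictorStack:
    """value' = (value - mean)*scale + mean + shift, per layer over valid cells."""
    unknown = (set(delta.shift) | set(delta.scale)) - set(stack.names)
    if unknown:
        raise KeyError(f"delta refers to layers not in stack: {sorted(unknown)}")
    layers = []
    for lay in stack.layers:
        sh = delta.shift.get(lay.name, 0.0)
        sc = delta.scale.get(lay.name, 1.0)
        if lay.name == TERRAIN_LAYER or (sh == 0.0 and sc == 1.0):
            layers.append(lay.copy_with())
            continue
        vals = lay.values.astype(float).copy()
        mean = vals[~lay.nodata_mask].mean()
        vals[~lay.nodata_mask] = (vals[~lay.nodata_mask] - mean) * sc + mean + sh
        layers.append(RasterLayer(lay.spec, vals, lay.nodata_mask.copy(), lay.name))
    return PredictorStack(layers, delta.scenario_id)


def shift_stack_rows(
    stack: PredictorStack,
    d_rows: int,
    scenario_id: str,
    include_terrain: bool = False,
) -> PredictorStack:
    """Translate layers (and their masks) by whole rows; positive = south.

    A constructed translation-validation scenario: with ``include_terrain``
    the whole environment moves, so a cellwise model's suitability surface
    translates exactly and the expected centroid-shift direction is known.
    Without it the terrain stays fixed, as in real scenario stacks.
    """
    layers = []
    for lay in stack.layers:
        if lay.name == TERRAIN_LAYER and not include_terrain:
            layers.append(lay.copy_with())
        else:
            vals = np.roll(lay.values, d_rows, axis=0)
            mask = np.roll(lay.nodata_mask, d_rows, axis=0)
            layers.append(RasterLayer(lay.spec, vals, mask, lay.name))
    return PredictorStack(layers, scenario_id)


# ---------------------------------------------------------------------------
# default synthetic study system used by the demo pipeline and recovery tests

DEFAULT_LAYER_NAMES = ["bio7", TERRAIN_LAYER, "bio18", "bio19", "decoy1", "decoy2"]
DEFAULT_SIGNAL_BETAS = (1.5, -1.0, 0.8, 0.4)
# strong unimodal curvature, graded with |beta|: concentrates the niche in a
# small pocket (~7% of the domain) so presences are separable from background
DEFAULT_SIGNAL_GAMMAS = (-16.0, -10.0, -6.0, -4.0)


def default_spec(n_rows: int = 150, n_cols: int = 150) -> GridSpec:
    return GridSpec(n_rows=n_rows, n_cols=n_cols, lon_min=100.0, lat_max=35.0, cell_size=0.1)


def default_true_model() -> TrueModel:
    return TrueModel(
        intercept=6.0,
        linear_coefs=DEFAULT_SIGNAL_BETAS,
        quad_coefs=DEFAULT_SIGNAL_GAMMAS,
        layer_names=tuple(DEFAULT_LAYER_NAMES[:4]),
    )


def default_cross_corr(n_layers: int = 6) -> np.ndarray:
    corr = np.eye(n_layers)
    corr[0, 2] = corr[2, 0] = 0.3   # mild, realistic cross-correlation
    corr[3, 4] = corr[4, 3] = 0.3
    return corr


def default_mask(spec: GridSpec, seed: int) -> np.ndarray:
    """A smooth ~2% nodata blob, shared by all layers and scenarios."""
    rng = substream(seed, "default_mask")
    f = _smooth_field(rng, spec.shape, 8.0)
    return f > np.quantile(f, 0.98)


def default_stack(seed: int = 123, spec: GridSpec | None = None,
                  corr_length: float = 10.0) -> PredictorStack:
    spec = spec or default_spec()
    return generate_stack(
        spec, n_layers=len(DEFAULT_LAYER_NAMES), corr_length=corr_length,
        cross_corr=default_cross_corr(), seed=seed,
        layer_names=DEFAULT_LAYER_NAMES, mask=default_mask(spec, seed),
    )
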