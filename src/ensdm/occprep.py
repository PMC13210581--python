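"""Occurrence-record cleaning and per-cell spatial thinning.

Cleaning applies a fixed sequence of rules; only the first failing rule is
recorded, so the audit is deterministic. Thinning keeps one record per grid
cell (lexicographically smallest id wins), which makes it idempotent and
independent of input row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid_io import GridSpec, PredictorStack

# rule names in the fixed order of application
RULE_MISSING_COORDS = "missing-coords"
RULE_PRECISION = "precision"
RULE_FLAGGED = "flagged"
RULE_EQUAL_COORDS = "equal-coords"
RULE_OUTSIDE_DOMAIN = "outside-domain"
RULE_ELEVATION = "elevation"
RULE_YEAR = "year"
RULE_MISSING_FIELD = "missing-field"
RULE_THINNED = "thinned"
RULE_NODATA = "no-data-cell"


class OccurrenceTable:
    """Presence records with cleaning metadata and an audit trail.

    Thin wrapper around a pandas frame with columns id, lon, lat,
    precision_deg, year, elevation_m, the three provenance flags, status
    (raw/retained/dropped) and drop_reason. Extra columns (e.g. synthetic
    truth tags) are carried through untouched and ignored by cleaning.
    """

    def __init__(self, df: pd.DataFrame):
        if "id" not in df.columns:
            raise ValueError("occurrence table needs an 'id' column")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def retained(self) -> pd.DataFrame:
        return self.df[self.df["status"] == "retained"]

    def copy(self) -> "OccurrenceTable":
        return OccurrenceTable(self.df.copy())

    def audit(self) -> dict:
        """Dropped-record counts per rule plus the retained count."""
        dropped = self.df[self.df["status"] == "dropped"]
        counts = dropped["drop_reason"].value_counts().to_dict()
        counts["retained"] = int((self.df["status"] == "retained").sum())
        return counts


@dataclass(frozen=True)
class CleaningRules:
    max_precision_deg: float = 0.01
    elev_range: tuple[float, float] = (200.0, 2200.0)
    min_year: int = 1970
    domain: tuple[float, float, float, float] | None = None  # lon_min, lon_max, lat_min, lat_max
    flag_rules: bool = True
    strict: bool = True  # drop records missing precision/year/elevation

    def __post_init__(self):
        if self.max_precision_deg <= 0:
            raise ValueError("max_precision_deg must be positive")
        if self.elev_range[0] >= self.elev_range[1]:
            raise ValueError("elev_range min must be below max")


def _first_failure(rec: pd.Series, rules: CleaningRules) -> str | None:
    lon, lat = rec.get("lon"), rec.get("lat")
    if pd.isna(lon) or pd.isna(lat):
        return RULE_MISSING_COORDS
    prec = rec.get("precision_deg")
    if pd.isna(prec):
        if rules.strict:
            return RULE_MISSING_FIELD
    elif prec > rules.max_precision_deg:
        return RULE_PRECISION
    if rules.flag_rules and (
        bool(rec.get("sea_flag", False))
        or bool(rec.get("centroid_flag", False))
        or bool(rec.get("institution_flag", False))
    ):
        return RULE_FLAGGED
    if lon == lat or lon == 0 or lat == 0:
        return RULE_EQUAL_COORDS
    if rules.domain is not None:
        lo, hi, la, ha = rules.domain
        if not (lo <= lon <= hi and la <= lat <= ha):
            return RULE_OUTSIDE_DOMAIN
    elev = rec.get("elevation_m")
    if pd.isna(elev):
        if rules.strict:
            return RULE_MISSING_FIELD
    elif not (rules.elev_range[0] <= elev <= rules.elev_range[1]):
        return RULE_ELEVATION
    year = rec.get("year")
    if pd.isna(year):
        if rules.strict:
            return RULE_MISSING_FIELD
    elif year < rules.min_year:
        return RULE_YEAR
    return None


def clean_records(raw: OccurrenceTable, rules: CleaningRules | None = None):
    """Apply the cleaning rules in fixed order; return (table, audit dict)."""
    rules = rules or CleaningRules()
    df = raw.df.copy()
    if not (df["status"] == "raw").all():
        raise ValueError("clean_records expects all records in status 'raw'")
    statuses, reasons = [], []
    for _, rec in df.iterrows():
        reason = _first_failure(rec, rules)
        statuses.append("dropped" if reason else "retained")
        reasons.append(reason if reason else pd.NA)
    df["status"] = statuses
    df["drop_reason"] = reasons
    out = OccurrenceTable(df)
    return out, out.audit()


def thin_records(cleaned: OccurrenceTable, spec: GridSpec) -> OccurrenceTable:
    """At most one record per grid cell; smallest id wins within a cell."""
    df = cleaned.df.copy()
    kept = df["status"] == "retained"
    sub = df[kept]
    row, col, inside = spec.cell_of(sub["lon"].to_numpy(), sub["lat"].to_numpy())
    cells = pd.DataFrame({"row": row, "col": col, "id": sub["id"].to_numpy()}, index=sub.index)
    winners = set()
    for (_, _), grp in cells.groupby(["row", "col"], sort=True):
        winners.add(grp["id"].min())
    losers = ~df["id"].isin(winners) & kept
    df.loc[losers, "status"] = "dropped"
    df.loc[losers, "drop_reason"] = RULE_THINNED
    return OccurrenceTable(df)


def validate_on_stack(thinned: OccurrenceTable, stack: PredictorStack) -> OccurrenceTable:
    """Drop retained records landing outside the grid or on masked cells."""
    df = thinned.df.copy()
    kept = df["status"] == "retained"
    sub = df[kept]
    row, col, inside = stack.spec.cell_of(sub["lon"].to_numpy(), sub["lat"].to_numpy())
    mask = stack.union_mask()
    r = np.where(inside, row, 0)
    c = np.where(inside, col, 0)
    bad = ~inside | mask[r, c]
    idx = sub.index[bad]
    df.loc[idx, "status"] = "dropped"
    df.loc[idx, "drop_reason"] = RULE_NODATA
    return OccurrenceTable(df)


def presence_cells(table: OccurrenceTable, spec: GridSpec) -> np.ndarray:
    """Distinct (row, col) cells of the retained records, sorted."""
    sub = table.retained
    row, col, inside = spec.cell_of(sub["lon"].to_numpy(), sub["lat"].to_numpy())
    if not inside.all():
        raise ValueError("retained records outside the grid; run validate_on_stack first")
    cells = np.unique(np.column_stack([row, col]), axis=0)
    return cells
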