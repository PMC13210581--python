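"""Area-weighted habitat centroids, geodesic shifts and compass sectors.

Centroids are averaged in an Albers equal-area conic projection (spherical
equations on the authalic radius) and reported back in WGS84. Shift
distances use the ellipsoidal (Vincenty) geodesic; bearings are initial
bearings at the origin point, binned into eight 45-degree sectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grid_io import AUTHALIC_RADIUS_KM, RasterLayer

WGS84_A_KM = 6378.137
WGS84_F = 1.0 / 298.257223563

SECTORS = ["N", "NE", "E", "SE", "S", "SW", "W", "NW"]


@dataclass(frozen=True)
class AlbersParams:
    """Albers equal-area conic parameters (defaults suit mainland China)."""

    lon0: float = 105.0
    lat0: float = 0.0
    lat1: float = 25.0
    lat2: float = 47.0
    radius_km: float = AUTHALIC_RADIUS_KM


@dataclass(frozen=True)
class CentroidRecord:
    scenario_id: str
    scope: str  # "overall" | "core"
    lon: float
    lat: float
    area_1e4km2: float


@dataclass(frozen=True)
class ShiftRecord:
    from_scenario: str
    to_scenario: str
    scope: str
    distance_km: float
    bearing_deg: float
    sector: str
    area_1e4km2: float
    small_area_caveat: bool
    status: str = "ok"  # "ok" | "original" | "no habitat"


def _cone_constants(p: AlbersParams):
    phi0, phi1, phi2 = map(np.deg2rad, (p.lat0, p.lat1, p.lat2))
    n = (np.sin(phi1) + np.sin(phi2)) / 2.0
    C = np.cos(phi1) ** 2 + 2.0 * n * np.sin(phi1)
    rho0 = p.radius_km * np.sqrt(C - 2.0 * n * np.sin(phi0)) / n
    return n, C, rho0


def albers_forward(lon, lat, params: AlbersParams = AlbersParams()):
    """Spherical Albers equal-area conic, lon/lat degrees -> x/y km."""
    n, C, rho0 = _cone_constants(params)
    lam = np.deg2rad(np.asarray(lon, float) - params.lon0)
    phi = np.deg2rad(np.asarray(lat, float))
    if np.any(np.abs(np.asarray(lat, float)) > 90.0):
        raise ValueError("latitude beyond the valid cone range")
    under = np.maximum(C - 2.0 * n * np.sin(phi), 0.0)
    rho = params.radius_km * np.sqrt(under) / n
    theta = n * lam
    return rho * np.sin(theta), rho0 - rho * np.cos(theta)


def albers_inverse(x, y, params: AlbersParams = AlbersParams()):
    """Inverse of :func:`albers_forward`; x/y km -> lon/lat degrees."""
    n, C, rho0 = _cone_constants(params)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    rho = np.sqrt(x**2 + (rho0 - y) ** 2)
    theta = np.arctan2(np.sign(n) * x, np.sign(n) * (rho0 - y))
    sin_phi = (C - (rho * n / params.radius_km) ** 2) / (2.0 * n)
    phi = np.arcsin(np.clip(sin_phi, -1.0, 1.0))
    lam = theta / n
    return params.lon0 + np.rad2deg(lam), np.rad2deg(phi)


def weighted_centroid(
    mask: RasterLayer,
    areas: RasterLayer,
    params: AlbersParams = AlbersParams(),
    scenario_id: str = "",
    scope: str = "overall",
) -> CentroidRecord:
    """Area-weighted mean of true-cell centers in projected space."""
    sel = (mask.values.astype(bool)) & (~mask.nodata_mask)
    if not sel.any():
        raise ValueError("no habitat: empty mask")
    rows, cols = np.where(sel)
    lon = mask.spec.lon_center(cols)
    lat = mask.spec.lat_center(rows)
    w = areas.values[rows, cols]
    x, y = albers_forward(lon, lat, params)
    xm = np.average(x, weights=w)
    ym = np.average(y, weights=w)
    clon, clat = albers_inverse(xm, ym, params)
    return CentroidRecord(scenario_id, scope, float(clon), float(clat), float(w.sum() / 1e4))


# ---------------------------------------------------------------------------
# geodesics


def _vincenty_inverse(lon1, lat1, lon2, lat2, tol=1e-12, max_iter=200):
    """Returns (distance_km, initial_bearing_deg) or None on non-convergence."""
    a = WGS84_A_KM
    f = WGS84_F
    b = a * (1.0 - f)
    phi1, phi2 = np.deg2rad(lat1), np.deg2rad(lat2)
    L = np.deg2rad(lon2 - lon1)
    U1 = np.arctan((1 - f) * np.tan(phi1))
    U2 = np.arctan((1 - f) * np.tan(phi2))
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    sinU2, cosU2 = np.sin(U2), np.cos(U2)

    lam = L
    for _ in range(max_iter):
        sin_lam, cos_lam = np.sin(lam), np.cos(lam)
        sin_sigma = np.sqrt(
            (cosU2 * sin_lam) ** 2 + (cosU1 * sinU2 - sinU1 * cosU2 * cos_lam) ** 2
        )
        if sin_sigma == 0:
            return 0.0, 0.0  # coincident points
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = np.arctan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos2_alpha = 1.0 - sin_alpha**2
        cos_2sm = cos_sigma - 2.0 * sinU1 * sinU2 / cos2_alpha if cos2_alpha != 0 else 0.0
        Cc = f / 16.0 * cos2_alpha * (4.0 + f * (4.0 - 3.0 * cos2_alpha))
        lam_prev = lam
        lam = L + (1.0 - Cc) * f * sin_alpha * (
            sigma + Cc * sin_sigma * (cos_2sm + Cc * cos_sigma * (-1.0 + 2.0 * cos_2sm**2))
        )
        if abs(lam - lam_prev) < tol:
            break
    else:
        return None

    u2 = cos2_alpha * (a**2 - b**2) / b**2
    A = 1.0 + u2 / 16384.0 * (4096.0 + u2 * (-768.0 + u2 * (320.0 - 175.0 * u2)))
    B = u2 / 1024.0 * (256.0 + u2 * (-128.0 + u2 * (74.0 - 47.0 * u2)))
    d_sigma = B * sin_sigma * (
        cos_2sm
        + B / 4.0 * (
            cos_sigma * (-1.0 + 2.0 * cos_2sm**2)
            - B / 6.0 * cos_2sm * (-3.0 + 4.0 * sin_sigma**2) * (-3.0 + 4.0 * cos_2sm**2)
        )
    )
    s = b * A * (sigma - d_sigma)
    alpha1 = np.arctan2(cosU2 * sin_lam, cosU1 * sinU2 - sinU1 * cosU2 * cos_lam)
    return float(s), float(np.rad2deg(alpha1) % 360.0)


def _spherical(lon1, lat1, lon2, lat2):
    phi1, phi2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dlam = np.deg2rad(lon2 - lon1)
    d = AUTHALIC_RADIUS_KM * np.arccos(
        np.clip(np.sin(phi1) * np.sin(phi2) + np.cos(phi1) * np.cos(phi2) * np.cos(dlam), -1, 1)
    )
    yb = np.sin(dlam) * np.cos(phi2)
    xb = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlam)
    return float(d), float(np.rad2deg(np.arctan2(yb, xb)) % 360.0)


def geodesic_distance_km(p1, p2) -> tuple[float, float]:
    """Ellipsoidal geodesic (distance km, initial bearing deg) p1 -> p2.

    Falls back to the spherical great circle with a warning if the Vincenty
    iteration fails to converge (near-antipodal points).
    """
    lon1, lat1 = p1
    lon2, lat2 = p2
    if lon1 == lon2 and lat1 == lat2:
        return 0.0, 0.0
    res = _vincenty_inverse(lon1, lat1, lon2, lat2)
    if res is None:
        warnings.warn("Vincenty failed to converge; using spherical great circle")
        return _spherical(lon1, lat1, lon2, lat2)
    return res


def initial_bearing_deg(p1, p2) -> float:
    return geodesic_distance_km(p1, p2)[1]


def bearing_sector(bearing_deg: float) -> str:
    """45-degree sectors centered on the eight compass directions."""
    if not 0 <= bearing_deg < 360:
        raise ValueError("bearing must be in [0, 360)")
    return SECTORS[int(((bearing_deg + 22.5) % 360.0) // 45.0)]


def shift_table(
    classified_maps: dict,
    areas: RasterLayer,
    baseline_id: str = "current",
    params: AlbersParams = AlbersParams(),
    area_floor_1e4km2: float = 5.0,
) -> list[ShiftRecord]:
    """Centroid-shift records per scenario for overall and core habitat.

    ``classified_maps`` maps scenario_id -> ClassifiedMap (habitat module).
    Overall = classes 1-3, core = class 3 only. The small-area caveat flag
    marks centroids supported by less area than the configured floor.
    """
    if baseline_id not in classified_maps:
        raise KeyError(f"baseline scenario {baseline_id!r} missing")

    def _mask(cmap, scope):
        sel = cmap.layer.values >= 1 if scope == "overall" else cmap.layer.values == 3
        vals = sel & ~cmap.layer.nodata_mask
        return RasterLayer(cmap.layer.spec, vals.astype(np.uint8), cmap.layer.nodata_mask, scope)

    records = []
    base = {}
    for scope in ("overall", "core"):
        base[scope] = weighted_centroid(
            _mask(classified_maps[baseline_id], scope), areas, params,
            scenario_id=baseline_id, scope=scope,
        )
    for sid, cmap in classified_maps.items():
        for scope in ("overall", "core"):
            b = base[scope]
            try:
                cen = weighted_centroid(_mask(cmap, scope), areas, params, sid, scope)
            except ValueError:
                records.append(ShiftRecord(
                    baseline_id, sid, scope, float("nan"), float("nan"), "",
                    0.0, True, status="no habitat",
                ))
                continue
            if sid == baseline_id or (cen.lon == b.lon and cen.lat == b.lat):
                records.append(ShiftRecord(
                    baseline_id, sid, scope, 0.0, 0.0, "Original",
                    cen.area_1e4km2, cen.area_1e4km2 < area_floor_1e4km2,
                    status="original",
                ))
                continue
            dist, bearing = geodesic_distance_km((b.lon, b.lat), (cen.lon, cen.lat))
            records.append(ShiftRecord(
                baseline_id, sid, scope, dist, bearing, bearing_sector(bearing),
                cen.area_1e4km2, cen.area_1e4km2 < area_floor_1e4km2,
            ))
    return records
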