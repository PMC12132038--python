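"""Lagged infestation-pressure ("Spatial") predictor.

For target hexagon i in year t, pressure is a force-of-invasion sum over
every hexagon k infested in year t-1 or t-2 within 300 km:

    Spatial_i(t) = sum_k f(d_ik)

where d_ik is the centroid great-circle distance standardized to [0, 1] by
the cutoff, and the kernel is either exp(-d^a) (``power`` form, default) or
exp(-d/a) (``scale`` form). Low a concentrates colonisation potential near
sources; high a (power form) flattens the kernel so distant infestations
weigh relatively more. A hexagon infested in both lag years contributes one
term per lag year; the target's own lagged infestation enters at d = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .grid import EARTH_RADIUS_M, HexGrid, OutOfNeighborhoodError


class InsufficientHistoryError(ValueError):
    """Raised when a requested year lacks occurrence data for its lag years."""


@dataclass(frozen=True)
class PressureConfig:
    """Kernel settings: shape a, distance cutoff, lag set, functional form."""

    a: float = 1.0
    cutoff_m: float = 300_000.0
    lags: tuple[int, ...] = (1, 2)
    form: str = "power"

    #: candidate shape values screened by AIC
    CANDIDATE_A = (1.0, 3.0, 5.0, 10.0)

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("kernel shape a must be positive")
        if self.cutoff_m <= 0:
            raise ValueError("cutoff must be positive")
        if not self.lags or any(l <= 0 for l in self.lags):
            raise ValueError("lags must be a non-empty set of positive integers")
        if self.form not in ("power", "scale"):
            raise ValueError("form must be 'power' or 'scale'")


def standardize_distance(d, cutoff_m: float):
    """Scale a distance in metres into [0, 1] by the neighbourhood cutoff."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if np.any(d > cutoff_m):
        raise OutOfNeighborhoodError(
            f"distance exceeds the {cutoff_m/1000:.0f}-km cutoff; callers must pre-filter"
        )
    return d / cutoff_m


def kernel_value(d_std, cfg: PressureConfig):
    """Per-source kernel contribution for standardized distance(s)."""
    d_std = np.asarray(d_std, dtype=float)
    if cfg.form == "power":
        return np.exp(-(d_std**cfg.a))
    return np.exp(-d_std / cfg.a)


def _unit_sphere(lon, lat):
    lam, phi = np.radians(lon), np.radians(lat)
    return np.column_stack(
        [np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)]
    )


def _chord_for(cutoff_m: float) -> float:
    # great-circle distance d  <->  unit-sphere chord 2 sin(d / 2R)
    return 2.0 * np.sin(cutoff_m / (2.0 * EARTH_RADIUS_M))


def _check_history(occ: pd.DataFrame, years, lags) -> None:
    if len(occ) == 0:
        raise InsufficientHistoryError("occurrence table is empty; no lag years available")
    first = int(occ["year"].min())
    need = min(int(y) for y in np.atleast_1d(years)) - max(lags)
    if need < first:
        raise InsufficientHistoryError(
            f"lag years reach back to {need} but occurrence data start in {first}"
        )


def infestation_pressure(
    target: int, year: int, occ: pd.DataFrame, grid: HexGrid, cfg: PressureConfig
) -> float:
    """Pressure on one hexagon in one year (see module docstring)."""
    surf = pressure_surface(occ, grid, cfg, [year], targets=[target])
    return float(surf["spatial"].iloc[0])


def pressure_surface(
    occ: pd.DataFrame,
    grid: HexGrid,
    cfg: PressureConfig,
    years,
    targets=None,
) -> pd.DataFrame:
    """Pressure for every requested (hexagon, year).

    Uses a KD-tree over infested-source centroids on the unit sphere, so the
    cost is O(targets x sources-within-cutoff) rather than all-pairs.
    Returns a DataFrame hex_id, year, spatial.
    """
    years = [int(y) for y in np.atleast_1d(years)]
    _check_history(occ, years, cfg.lags)

    if targets is None:
        t_ids = grid.hex_id
        t_pos = np.arange(len(grid))
    else:
        t_ids = np.asarray(targets, dtype=int)
        pos_of = {int(h): i for i, h in enumerate(grid.hex_id)}
        missing = [h for h in t_ids if int(h) not in pos_of]
        if missing:
            raise KeyError(f"target hexagons not in grid: {missing[:5]}")
        t_pos = np.array([pos_of[int(h)] for h in t_ids])

    xyz_all = _unit_sphere(grid.centroid_lon, grid.centroid_lat)
    t_xyz = xyz_all[t_pos]
    t_lon = grid.centroid_lon[t_pos]
    t_lat = grid.centroid_lat[t_pos]
    chord = _chord_for(cfg.cutoff_m)

    pos_of_hex = {int(h): i for i, h in enumerate(grid.hex_id)}
    infested_by_year = {
        int(y): g["hex_id"].to_numpy()
        for y, g in occ[occ["presence"] == 1].groupby("year")
    }

    out = []
    for year in years:
        total = np.zeros(len(t_pos))
        for lag in cfg.lags:
            src = infested_by_year.get(year - lag)
            if src is None or len(src) == 0:
                continue
            s_pos = np.array([pos_of_hex[int(h)] for h in src])
            tree = cKDTree(xyz_all[s_pos])
            hits = tree.query_ball_point(t_xyz, chord * (1 + 1e-12))
            for i, hit in enumerate(hits):
                if not hit:
                    continue
                sp = s_pos[np.asarray(hit)]
                from .grid import geodetic_distance

                d = geodetic_distance(
                    (t_lon[i], t_lat[i]),
                    (grid.centroid_lon[sp], grid.centroid_lat[sp]),
                )
                d = np.minimum(d, cfg.cutoff_m)  # clamp KD-tree boundary overshoot
                total[i] += kernel_value(d / cfg.cutoff_m, cfg).sum()
        out.append(pd.DataFrame({"hex_id": t_ids, "year": year, "spatial": total}))
    return pd.concat(out, ignore_index=True)


def pressure_surface_bruteforce(
    occ: pd.DataFrame, grid: HexGrid, cfg: PressureConfig, years
) -> pd.DataFrame:
    """Naive all-pairs double loop; oracle for the indexed implementation."""
    from .grid import geodetic_distance

    years = [int(y) for y in np.atleast_1d(years)]
    _check_history(occ, years, cfg.lags)
    pos_of_hex = {int(h): i for i, h in enumerate(grid.hex_id)}
    rows = []
    for year in years:
        for i, h in enumerate(grid.hex_id):
            s = 0.0
            for lag in cfg.lags:
                sub = occ[(occ["year"] == year - lag) & (occ["presence"] == 1)]
                for k in sub["hex_id"]:
                    j = pos_of_hex[int(k)]
                    d = float(
                        geodetic_distance(
                            (grid.centroid_lon[i], grid.centroid_lat[i]),
                            (grid.centroid_lon[j], grid.centroid_lat[j]),
                        )
                    )
                    if d <= cfg.cutoff_m * (1 + 1e-12):
                        s += float(kernel_value(min(d, cfg.cutoff_m) / cfg.cutoff_m, cfg))
            rows.append((int(h), year, s))
    return pd.DataFrame(rows, columns=["hex_id", "year", "spatial"])
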