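"""Synthetic landscapes and stratified-dispersal invasions.

The study's occurrence data are private, so every downstream stage is
exercised on simulations with known truth. The generator emulates the
statistical structure of the real data:

* per-hexagon predictor surfaces (topography, transport/human-activity,
  host, and climate variables) as spatially autocorrelated fields with the
  units and supports of the real covariates;
* an invasion that spreads by short-distance pressure from lagged infested
  neighbourhoods (the same kernel the analysis estimates) plus rare
  long-distance human-assisted jumps to uniformly random hexagons;
* imperfect detection and partial survey coverage, producing the strongly
  imbalanced presence/absence hexagon-year response of detection surveys.

Colonisation probability for an uninfested hexagon in year t is

    p = inv_logit(b0 + b_spatial * Spatial_t + sum_j b_j z_j)

with Spatial_t computed from years t-1 and t-2 using the true kernel shape,
and z_j the standardized (landcover: raw 0/1) predictor values. Colonised
hexagons stay infested. All randomness flows from one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .grid import HexGrid, LocalEqualArea
from .pressure import PressureConfig, kernel_value, _unit_sphere, _chord_for

#: predictor name -> (low, high, autocorrelation range km, kind)
DEFAULT_PREDICTOR_SPECS: dict[str, tuple] = {
    "elev": (0.0, 500.0, 10.0, "continuous"),
    "slope": (0.0, 15.0, 5.0, "continuous"),
    "aspect": (-1.0, 1.0, 3.0, "continuous"),
    "roads_log10": (0.0, 4.5, 5.0, "continuous"),
    "rail_log10": (0.0, 3.5, 8.0, "continuous"),
    "stations": (0.0, 2.0, 5.0, "count"),
    "campgrounds": (0.0, 2.0, 5.0, "count"),
    "parks": (0.0, 100.0, 10.0, "continuous"),
    "popdensity_log10": (0.0, 4.0, 8.0, "continuous"),
    "crown": (0.0, 100.0, 8.0, "continuous"),
    "treed": (0.0, 100.0, 8.0, "continuous"),
    "broadleaf": (0.0, 100.0, 8.0, "continuous"),
    "deg_days": (150.0, 900.0, 15.0, "continuous"),
    "cqmt": (-20.0, 0.0, 15.0, "continuous"),
}

#: generating coefficients (standardized scale; landcover raw 0/1; spatial raw)
DEFAULT_TRUE_BETAS: dict[str, float] = {
    "spatial": 0.5,
    "elev": -0.8,
    "slope": 0.15,
    "campgrounds": -0.3,
    "popdensity_log10": 0.6,
    "crown": 0.3,
    "landcover": 0.9,
    "deg_days": 0.6,
}


@dataclass
class LandscapeConfig:
    """Scenario parameters for the landscape and the invasion process."""

    grid_rows: int = 40
    grid_cols: int = 40
    seed: int = 0
    predictor_specs: dict = field(default_factory=lambda: dict(DEFAULT_PREDICTOR_SPECS))
    true_betas: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_BETAS))
    intercept: float = -7.25
    true_a: float = 1.0
    kernel_form: str = "power"
    # neighbourhood cutoff scaled to the toy landscape (~1/13 of the extent,
    # the same order as the full-scale study's cutoff-to-extent ratio), so the
    # standardized distance spans (0, 1] as in the full-scale analysis
    cutoff_m: float = 3_000.0
    lags: tuple[int, ...] = (1, 2)
    detection_prob: float = 0.9
    survey_fraction: float = 0.12
    # detection surveys move on once a hexagon is confirmed positive: by
    # default a hexagon contributes presence rows only up to its first
    # detection (re-surveying confirmed hexagons is available as an option)
    resurvey_detected: bool = False
    jump_rate: float = 0.5
    years: int = 12
    start_year: int = 2002
    n_epicenters: int = 2
    # epicenters are seeded as a cell plus its ring(s); a lone infested cell
    # rarely ignites under a sharp colonisation threshold
    epicenter_radius: int = 1
    landcover_urban_quantile: float = 0.85
    center_lon: float = -75.7
    center_lat: float = 45.4
    cell_area_km2: float = 1.0

    def __post_init__(self):
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if not (0.0 < self.detection_prob <= 1.0):
            raise ValueError("detection_prob must be in (0, 1]")
        if not (0.0 < self.survey_fraction <= 1.0):
            raise ValueError("survey_fraction must be in (0, 1]")
        if self.years < max(self.lags) + 1:
            raise ValueError("horizon must exceed the maximum lag")

    def pressure_config(self) -> PressureConfig:
        return PressureConfig(
            a=self.true_a, cutoff_m=self.cutoff_m, lags=tuple(self.lags), form=self.kernel_form
        )


@dataclass
class SimulatedStudy:
    """A generated landscape plus (optionally) its simulated invasion."""

    grid: HexGrid
    predictors: pd.DataFrame
    occurrences: pd.DataFrame
    latent: pd.DataFrame
    truth: LandscapeConfig

    def standardized_predictors(self) -> pd.DataFrame:
        """Predictors z-scored over hexagons (landcover left as 0/1)."""
        out = self.predictors.copy()
        for c in out.columns:
            if c in ("hex_id", "landcover"):
                continue
            v = out[c].to_numpy(dtype=float)
            sd = v.std()
            out[c] = (v - v.mean()) / (sd if sd > 0 else 1.0)
        return out


def _lattice_grid(cfg: LandscapeConfig) -> HexGrid:
    """A rows x cols flat-top hexagon lattice centred on the scenario origin."""
    proj = LocalEqualArea(cfg.center_lon, cfg.center_lat)
    area_m2 = cfg.cell_area_km2 * 1e6
    r = np.sqrt(2.0 * area_m2 / (3.0 * np.sqrt(3.0)))
    dx, dy = 1.5 * r, np.sqrt(3.0) * r
    rows, cols = np.meshgrid(
        np.arange(cfg.grid_rows), np.arange(cfg.grid_cols), indexing="ij"
    )
    rows, cols = rows.ravel(), cols.ravel()
    cx = (cols - cfg.grid_cols / 2) * dx
    cy = (rows - cfg.grid_rows / 2) * dy + (np.mod(cols, 2)) * dy / 2.0
    lon, lat = proj.inverse(cx, cy)
    lon_min, lon_max = float(np.min(lon)), float(np.max(lon))
    lat_min, lat_max = float(np.min(lat)), float(np.max(lat))
    return HexGrid(
        hex_id=np.arange(len(rows)),
        centroid_lon=np.asarray(lon),
        centroid_lat=np.asarray(lat),
        cell_area_km2=cfg.cell_area_km2,
        circumradius_m=r,
        proj=proj,
        row=rows - cfg.grid_rows // 2,
        col=cols - cfg.grid_cols // 2,
        x=cx,
        y=cy,
        bbox=(lon_min, lat_min, lon_max, lat_max),
    )


def _autocorrelated_field(rng, shape, range_km: float) -> np.ndarray:
    """Seeded white noise smoothed to the requested autocorrelation range.

    The smoother is a Gaussian moving average over the row/column index grid
    (cell pitch ~1 km), then rank-preserving; range 0 returns pure noise.
    """
    z = rng.standard_normal(shape)
    if range_km > 0:
        z = gaussian_filter(z, sigma=range_km / 2.0, mode="reflect")
    return z


def generate_landscape(cfg: LandscapeConfig) -> SimulatedStudy:
    """Build the grid and predictor surfaces (no invasion yet)."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    grid = _lattice_grid(cfg)
    shape = (cfg.grid_rows, cfg.grid_cols)
    # hexes were generated row-major over (row, col), so fields flatten in order
    data = {"hex_id": grid.hex_id}
    pop_field = None
    for name, (lo, hi, rng_km, kind) in cfg.predictor_specs.items():
        f = _autocorrelated_field(rng, shape, rng_km).ravel()
        span = f.max() - f.min()
        scaled = (f - f.min()) / (span if span > 0 else 1.0)
        if kind == "count":
            # sparse small counts: mostly zero, clustered where the field is high
            q1, q2 = np.quantile(scaled, [0.85, 0.97])
            vals = (scaled > q1).astype(float) + (scaled > q2).astype(float)
            vals = np.minimum(vals, hi)
        else:
            vals = lo + scaled * (hi - lo)
        data[name] = vals
        if name == "popdensity_log10":
            pop_field = scaled
    if pop_field is None:
        pop_field = rng.random(cfg.grid_rows * cfg.grid_cols)
    # urban cells cluster where population density is high
    thr = np.quantile(pop_field, cfg.landcover_urban_quantile)
    data["landcover"] = (pop_field > thr).astype(int)
    predictors = pd.DataFrame(data)
    empty = pd.DataFrame(columns=["hex_id", "year", "presence"]).astype(
        {"hex_id": int, "year": int, "presence": int}
    )
    empty_latent = pd.DataFrame(columns=["hex_id", "year", "infested"]).astype(
        {"hex_id": int, "year": int, "infested": int}
    )
    return SimulatedStudy(
        grid=grid, predictors=predictors, occurrences=empty, latent=empty_latent, truth=cfg
    )


def _spatial_from_latent(
    grid: HexGrid, infested_by_year: dict[int, np.ndarray], year: int, cfg: LandscapeConfig
) -> np.ndarray:
    """True-kernel pressure on every hexagon; missing lag years contribute 0."""
    pcfg = cfg.pressure_config()
    xyz = _unit_sphere(grid.centroid_lon, grid.centroid_lat)
    chord = _chord_for(cfg.cutoff_m)
    total = np.zeros(len(grid))
    from .grid import geodetic_distance

    for lag in cfg.lags:
        src = infested_by_year.get(year - lag)
        if src is None or len(src) == 0:
            continue
        tree = cKDTree(xyz[src])
        hits = tree.query_ball_point(xyz, chord * (1 + 1e-12))
        for i, hit in enumerate(hits):
            if not hit:
                continue
            sp = src[np.asarray(hit)]
            d = geodetic_distance(
                (grid.centroid_lon[i], grid.centroid_lat[i]),
                (grid.centroid_lon[sp], grid.centroid_lat[sp]),
            )
            d = np.minimum(d, cfg.cutoff_m)
            total[i] += kernel_value(d / cfg.cutoff_m, pcfg).sum()
    return total


def simulate_invasion(study: SimulatedStudy, cfg: LandscapeConfig | None = None) -> SimulatedStudy:
    """Run the stratified-dispersal invasion and the detection surveys.

    Returns a new :class:`SimulatedStudy` whose ``occurrences`` holds the
    observed hexagon-year response and ``latent`` the true infestation state.
    """
    cfg = cfg or study.truth
    grid = study.grid
    n = len(grid)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))

    z = study.standardized_predictors()
    beta_env = np.zeros(n)
    for name, b in cfg.true_betas.items():
        if name == "spatial":
            continue
        if name not in z.columns:
            raise KeyError(f"true_betas references unknown predictor {name!r}")
        beta_env += b * z[name].to_numpy(dtype=float)
    b_spatial = cfg.true_betas.get("spatial", 0.0)

    infested = np.zeros(n, dtype=bool)
    # seeded epicenters in the first year: a cell plus its neighbour ring(s)
    epicenters = rng.choice(n, size=min(cfg.n_epicenters, n), replace=False)
    infested[epicenters] = True
    if cfg.epicenter_radius > 0:
        tree = cKDTree(np.column_stack([grid.x, grid.y]))
        _, dy = grid.spacing
        for e in epicenters:
            near = tree.query_ball_point(
                [grid.x[e], grid.y[e]], dy * (cfg.epicenter_radius + 0.1)
            )
            infested[np.asarray(near)] = True

    years = [cfg.start_year + i for i in range(cfg.years)]
    infested_by_year: dict[int, np.ndarray] = {}
    ever_detected = np.zeros(n, dtype=bool)
    occ_rows = []
    latent_rows = []
    for t_idx, year in enumerate(years):
        if t_idx > 0:
            spatial = _spatial_from_latent(grid, infested_by_year, year, cfg)
            lp = cfg.intercept + b_spatial * spatial + beta_env
            p = 1.0 / (1.0 + np.exp(-lp))
            new = (~infested) & (rng.random(n) < p)
            infested = infested | new
            # long-distance human-assisted jumps, uniform over the grid
            n_jump = rng.poisson(cfg.jump_rate)
            if n_jump > 0:
                infested[rng.choice(n, size=n_jump, replace=True)] = True
        infested_by_year[year] = np.nonzero(infested)[0]

        inf_ids = np.nonzero(infested)[0]
        latent_rows.append(pd.DataFrame({"hex_id": inf_ids, "year": year, "infested": 1}))
        # detection surveys: infested hexagons (all of them, or only those not
        # yet confirmed) are surveyed and detected w.p. detection_prob; a
        # survey_fraction sample of uninfested ones is recorded absent
        if cfg.resurvey_detected:
            surveyed_inf = inf_ids
        else:
            surveyed_inf = inf_ids[~ever_detected[inf_ids]]
        detected = rng.random(len(surveyed_inf)) < cfg.detection_prob
        ever_detected[surveyed_inf[detected]] = True
        occ_rows.append(
            pd.DataFrame(
                {"hex_id": surveyed_inf, "year": year, "presence": detected.astype(int)}
            )
        )
        unin = np.nonzero(~infested)[0]
        if cfg.survey_fraction >= 1.0:
            surveyed = unin
        else:
            k = int(round(cfg.survey_fraction * len(unin)))
            surveyed = rng.choice(unin, size=k, replace=False) if k > 0 else unin[:0]
        occ_rows.append(pd.DataFrame({"hex_id": surveyed, "year": year, "presence": 0}))

    occ = pd.concat(occ_rows, ignore_index=True).astype(
        {"hex_id": int, "year": int, "presence": int}
    )
    occ = occ.sort_values(["year", "hex_id"], kind="stable").reset_index(drop=True)
    latent = pd.concat(latent_rows, ignore_index=True).astype(
        {"hex_id": int, "year": int, "infested": int}
    )
    return SimulatedStudy(
        grid=grid, predictors=study.predictors, occurrences=occ, latent=latent, truth=cfg
    )


def simulate_study(cfg: LandscapeConfig) -> SimulatedStudy:
    """Landscape + invasion in one call."""
    return simulate_invasion(generate_landscape(cfg))


def simulate_colonization_trial(
    cfg: LandscapeConfig | None = None,
    seed: int = 0,
    n_sources: int = 25,
    n_years: int = 8,
    rows_per_year: int = 250,
    spatial_beta: float = 4.0,
    intercept: float = -8.5,
) -> tuple[pd.DataFrame, pd.DataFrame, "HexGrid"]:
    """Scattered-foci dispersal trial for kernel-shape inference.

    A contiguous invasion front yields candidate pressure surfaces that are
    nearly collinear across kernel shapes (pressure is dominated by the mass
    of the adjacent cluster), so the shape is weakly identified there. This
    design emulates the situation that *does* identify it: each year an
    independent cohort of scattered nascent foci acts as sources for the two
    following years, and surveyed cells colonise with the hazard
    ``inv_logit(intercept + spatial_beta * Spatial)`` computed with the true
    kernel, so colonisation events sample the kernel profile over the full
    standardized-distance range.

    Returns ``(response_occ, source_occ, grid)``: the colonisation
    response rows (all events plus filler absences, ~``rows_per_year`` per
    year) and the source occurrence table to compute pressure from.
    """
    cfg = cfg or LandscapeConfig(seed=seed)
    study = generate_landscape(cfg)
    grid = study.grid
    n = len(grid)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    pcfg = cfg.pressure_config()
    y0 = cfg.start_year
    sources = {
        y0 + t: np.sort(rng.choice(n, size=min(n_sources, n), replace=False))
        for t in range(n_years + max(cfg.lags))
    }
    src_rows = [
        pd.DataFrame({"hex_id": s, "year": y, "presence": 1})
        for y, s in sources.items()
    ]
    source_occ = pd.concat(src_rows, ignore_index=True)

    resp_rows = []
    for t in range(max(cfg.lags), max(cfg.lags) + n_years):
        year = y0 + t
        by_year = {y: s for y, s in sources.items() if y < year}
        spatial = _spatial_from_latent(grid, by_year, year, cfg)
        p = 1.0 / (1.0 + np.exp(-(intercept + spatial_beta * spatial)))
        colonised = rng.random(n) < p
        pres = np.nonzero(colonised)[0]
        absn = np.nonzero(~colonised)[0]
        k = max(0, rows_per_year - len(pres))
        filler = rng.choice(absn, size=min(k, len(absn)), replace=False)
        resp_rows.append(pd.DataFrame({"hex_id": pres, "year": year, "presence": 1}))
        resp_rows.append(pd.DataFrame({"hex_id": filler, "year": year, "presence": 0}))
    response_occ = pd.concat(resp_rows, ignore_index=True).astype(
        {"hex_id": int, "year": int, "presence": int}
    )
    return response_occ, source_occ, grid


def accumulate_degree_days(daily_mean_temps, base: float = 10.0) -> float:
    """Accumulated degree-days above a base temperature: sum max(0, T - base)."""
    t = np.asarray(daily_mean_temps, dtype=float)
    if t.size == 0:
        raise ValueError("temperature series is empty")
    return float(np.maximum(0.0, t - base).sum())


def truth_as_dict(cfg: LandscapeConfig) -> dict:
    d = asdict(cfg)
    d["lags"] = list(cfg.lags)
    return d
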