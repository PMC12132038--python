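"""End-to-end orchestration: simulate/ingest -> pressure -> logistic model
selection -> multi-model zoo -> ensemble -> (optional) projection.

Every stage writes plain CSV/GeoJSON/JSON artifacts into the run directory so
any stage can be re-entered independently; a manifest records the seeds,
record counts and SHA-256 checksums of every artifact. All randomness flows
from the single master seed, so re-running a config reproduces byte-identical
outputs. No binary model objects are persisted; model handles are re-fit from
the logged seeds when needed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import glmselect, zoo
from .grid import HexGrid, aggregate_detections, read_detections_csv, read_occurrence_csv
from .pressure import PressureConfig, pressure_surface
from .simdata import LandscapeConfig, SimulatedStudy, generate_landscape, simulate_invasion, truth_as_dict

logger = logging.getLogger(__name__)

#: driver groups used for the per-group candidate models
DRIVER_GROUPS: dict[str, tuple[str, ...]] = {
    "topography": ("elev", "slope", "aspect"),
    "transport": ("roads_log10", "rail_log10", "stations", "campgrounds", "parks", "popdensity_log10"),
    "host": ("crown", "treed", "broadleaf", "landcover"),
    "weather": ("deg_days", "cqmt"),
}


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {exc}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """One config for the whole pipeline; see the YAML loader below."""

    outdir: str = "run"
    seed: int = 0
    # either a simulation scenario ...
    scenario: dict | None = field(default_factory=dict)
    # ... or paths to real inputs
    detections_csv: str | None = None
    occurrences_csv: str | None = None
    grid_geojson: str | None = None
    predictors_csv: str | None = None
    # pressure; cutoff None = the scenario's cutoff (simulated runs) or the
    # standard 300-km neighbourhood (real inputs)
    a_candidates: tuple[float, ...] = (1.0, 3.0, 5.0, 10.0)
    cutoff_m: float | None = None
    lags: tuple[int, ...] = (1, 2)
    kernel_form: str = "power"
    # screening / selection
    r_max: float = 0.75
    vif_max: float = 5.0
    # zoo
    n_absence_sets: int = 10
    n_cv: int = 3
    cv_calibration_fraction: float = 0.70
    families: tuple[str, ...] = zoo.FAMILIES
    member_tss_min: float = 0.6
    vi_runs_per_family: int = 6
    # optional projection
    project_predictors_csv: str | None = None
    project_zero_spatial: bool = True

    def validate(self) -> None:
        sim = self.scenario is not None
        real = self.occurrences_csv or self.detections_csv
        if not sim and not real:
            raise ValueError(
                "config must provide a simulation scenario or occurrence inputs"
            )
        if real and not (self.grid_geojson and self.predictors_csv):
            raise ValueError("real inputs require grid_geojson and predictors_csv")
        for p in (
            self.detections_csv, self.occurrences_csv, self.grid_geojson,
            self.predictors_csv, self.project_predictors_csv,
        ):
            if p is not None and not Path(p).exists():
                raise ValueError(f"referenced input does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("a_candidates", "lags", "families"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=float))


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute all stages, writing artifacts + manifest to cfg.outdir."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "files": {}}
    timings: dict[str, float] = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                counts = fn() or {}
            except Exception as exc:
                logger.error("stage %s failed: %s", name, exc)
                raise StageError(name, exc) from exc
            timings[name] = time.perf_counter() - t0
            manifest["stages"][name] = {"status": "completed", **counts}
            return None
        return deco

    state: dict = {}

    @stage("data")
    def _data():
        if cfg.occurrences_csv or cfg.detections_csv:
            grid = HexGrid.from_geojson(cfg.grid_geojson)
            predictors = pd.read_csv(cfg.predictors_csv)
            if cfg.occurrences_csv:
                occ = read_occurrence_csv(cfg.occurrences_csv)
            else:
                occ = aggregate_detections(read_detections_csv(cfg.detections_csv), grid)
            study = SimulatedStudy(
                grid=grid, predictors=predictors, occurrences=occ,
                latent=pd.DataFrame(), truth=LandscapeConfig(seed=cfg.seed),
            )
            state["simulated"] = False
        else:
            state["simulated"] = True
            scen = dict(cfg.scenario or {})
            scen.setdefault("seed", cfg.seed)
            if "lags" in scen:
                scen["lags"] = tuple(scen["lags"])
            lcfg = LandscapeConfig(**scen)
            study = simulate_invasion(generate_landscape(lcfg))
            _dump_json(truth_as_dict(lcfg), out / "truth.json")
        study.grid.to_geojson(out / "grid.geojson")
        study.occurrences.to_csv(out / "occ.csv", index=False)
        study.predictors.to_csv(out / "predictors.csv", index=False)
        state["study"] = study
        return {"hexagons": len(study.grid), "occurrence_rows": len(study.occurrences)}

    @stage("pressure")
    def _pressure():
        study = state["study"]
        if cfg.cutoff_m is not None:
            cutoff = cfg.cutoff_m
        elif state.get("simulated"):
            cutoff = study.truth.cutoff_m
        else:
            cutoff = 300_000.0
        base = PressureConfig(
            a=cfg.a_candidates[0], cutoff_m=cutoff, lags=tuple(cfg.lags),
            form=cfg.kernel_form,
        )
        best_a, fits = glmselect.select_kernel_shape(
            study.occurrences, study.grid, cfg.a_candidates, base
        )
        pcfg = PressureConfig(
            a=best_a, cutoff_m=cutoff, lags=tuple(cfg.lags), form=cfg.kernel_form
        )
        first = int(study.occurrences["year"].min())
        years = sorted(
            y for y in study.occurrences["year"].unique()
            if y - max(pcfg.lags) >= first
        )
        surf = pressure_surface(study.occurrences, study.grid, pcfg, years)
        surf.to_csv(out / "spatial.csv", index=False)
        state["pcfg"] = pcfg
        state["spatial"] = surf
        state["kernel_fits"] = {a: f.aic for a, f in fits.items()}
        return {"selected_a": best_a, "years": len(years)}

    @stage("design")
    def _design():
        study = state["study"]
        occ = study.occurrences
        surf = state["spatial"]
        design = glmselect.build_design(
            occ[occ["year"].isin(surf["year"].unique())], surf, study.predictors
        )
        design.to_csv(out / "design.csv", index=False)
        state["design"] = design
        return {"rows": len(design), "presences": int(design["presence"].sum())}

    @stage("glmselect")
    def _glm():
        design = state["design"]
        balanced = glmselect.balanced_design(design, seed=cfg.seed)
        all_cols = glmselect.predictor_columns(design)
        retained, screen_report = glmselect.screen_predictors(
            balanced, columns=all_cols, r_max=cfg.r_max, vif_max=cfg.vif_max,
            keep=("spatial",),
        )
        final = glmselect.backward_eliminate(balanced, columns=retained, keep=("spatial",))
        fits = {"all_combined": final}
        for group, cols in DRIVER_GROUPS.items():
            cols = [c for c in cols if c in retained]
            if not cols:
                continue
            fits[f"combined_{group}"] = glmselect.backward_eliminate(
                balanced, columns=["spatial"] + cols, keep=("spatial",)
            )
        fits["spatial_only"] = glmselect.fit_logistic(balanced, columns=["spatial"])
        fits["intercept_only"] = glmselect.fit_logistic(balanced, columns=[])
        comparison = glmselect.compare_models(fits)
        report = {
            "kernel_aics": state["kernel_fits"],
            "screening": screen_report,
            "final_terms": list(final.feature_names),
            "final_coefficients": final.coefficient_table().to_dict(orient="records"),
            "comparison": comparison.to_dict(orient="records"),
        }
        _dump_json(report, out / "report.json")
        state["final_fit"] = final
        state["zoo_columns"] = list(final.feature_names)
        return {"final_terms": len(final.feature_names)}

    @stage("zoo")
    def _zoo():
        design = state["design"]
        cols = ["hex_id", "year", "presence"] + state["zoo_columns"]
        zdesign = design[cols].reset_index(drop=True)
        plan = zoo.make_split_plan(
            zdesign, seed=cfg.seed, n_absence_sets=cfg.n_absence_sets,
            n_cv=cfg.n_cv, cv_calibration_fraction=cfg.cv_calibration_fraction,
        )
        runs = zoo.run_zoo(plan, zdesign, families=cfg.families)
        state["plan"], state["zdesign"], state["runs"] = plan, zdesign, runs
        zoo.runs_table(runs).to_csv(out / "runs.csv", index=False)
        # permutation VI and marginal response curves, averaged per family
        vi_rows, curve_rows = [], []
        feats = state["zoo_columns"]
        for fam in cfg.families:
            fam_runs = [r for r in runs if r.family == fam and r.status == "ok"]
            fam_runs = fam_runs[: cfg.vi_runs_per_family]
            if not fam_runs:
                continue
            vis = []
            for i, r in enumerate(fam_runs):
                train = zdesign.loc[np.concatenate([r.calibration_ids, r.validation_ids])]
                vis.append(zoo.permutation_importance(r, train, n_rep=1, seed=cfg.seed + i))
            mean_vi = pd.concat(vis, axis=1).mean(axis=1)
            for f, v in mean_vi.items():
                vi_rows.append({"family": fam, "predictor": f, "vi": float(v)})
            top = mean_vi.sort_values(ascending=False).index[:5]
            for f in top:
                curve = zoo.marginal_response(fam_runs, f, zdesign)
                curve["family"] = fam
                curve_rows.append(curve)
        pd.DataFrame(vi_rows).to_csv(out / "vi.csv", index=False)
        if curve_rows:
            pd.concat(curve_rows, ignore_index=True).to_csv(out / "curves.csv", index=False)
        n_ok = sum(r.status == "ok" for r in runs)
        return {"model_runs": len(runs), "ok": n_ok}

    @stage("ensemble")
    def _ensemble():
        runs, plan, zdesign = state["runs"], state["plan"], state["zdesign"]
        ens = zoo.ensemble_runs(runs, zdesign, plan, member_tss_min=cfg.member_tss_min)
        all_runs = runs + ens
        state["all_runs"] = all_runs
        zoo.runs_table(all_runs).to_csv(out / "runs.csv", index=False)
        comparison = {}
        for which in ("validation", "evaluation"):
            try:
                c = zoo.compare_tss(all_runs, which)
                comparison[which] = {
                    "anova": c["anova"],
                    "means": c["means"],
                    "pairwise": c["pairwise"].to_dict(orient="records"),
                }
            except ValueError as exc:
                comparison[which] = {"error": str(exc)}
        _dump_json(comparison, out / "tss_comparison.json")
        n_members = sum(
            1 for r in runs
            if r.status == "ok" and r.tss_validation > cfg.member_tss_min
        )
        return {"qualifying_members": n_members, "ensembles": len(ens)}

    if cfg.project_predictors_csv:
        @stage("project")
        def _project():
            preds = pd.read_csv(cfg.project_predictors_csv)
            riskmap = project_region(
                state["all_runs"], preds, zero_spatial=cfg.project_zero_spatial,
                member_tss_min=cfg.member_tss_min,
            )
            riskmap.to_csv(out / "riskmap.csv", index=False)
            return {"region_hexagons": len(riskmap)}

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][f.name] = _sha256(f)
    _dump_json(manifest, out / "manifest.json")
    (out / "pipeline.log").write_text(
        "".join(f"{k}: {v:.2f}s\n" for k, v in timings.items())
    )
    return out


def project_region(
    runs: list[zoo.ModelRun],
    predictors: pd.DataFrame,
    zero_spatial: bool = True,
    member_tss_min: float = 0.6,
) -> pd.DataFrame:
    """Forecast a (possibly uninvaded) region from fitted runs.

    With ``zero_spatial`` the infestation-pressure column is forced to zero —
    the treatment for regions with no confirmed detection within the kernel
    cutoff. Returns one row per hexagon: committee consensus, vote fraction,
    the count of members flagging it, and per-family mean probability.
    """
    preds = predictors.copy()
    family_runs = [r for r in runs if r.status == "ok" and r.family != "ENSEMBLE"]
    if not family_runs:
        raise ValueError("no successful model runs supplied")
    feats = list(family_runs[0].feature_names)
    if zero_spatial:
        preds["spatial"] = 0.0
    missing = [c for c in feats if c not in preds.columns]
    if missing:
        raise KeyError(f"region predictor table missing columns: {missing}")
    spec = zoo.make_ensemble(family_runs, member_tss_min=member_tss_min)
    consensus, frac = zoo.committee_predict(spec, preds[feats].to_numpy(dtype=float))
    votes = np.stack(
        [(r.predict_prob(preds) >= r.threshold).astype(int) for r in spec.members]
    )
    out = pd.DataFrame(
        {
            "hex_id": preds["hex_id"] if "hex_id" in preds.columns else np.arange(len(preds)),
            "consensus": consensus,
            "vote_fraction": frac,
            "members_flagging": votes.sum(axis=0),
        }
    )
    for fam in sorted({r.family for r in family_runs}):
        fr = [r for r in family_runs if r.family == fam]
        out[f"prob_{fam}"] = np.stack([r.predict_prob(preds) for r in fr]).mean(axis=0)
    return out
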