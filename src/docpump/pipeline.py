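"""End-to-end orchestration of the diagnostic analysis with manifests.

Stages: generate the synthetic world, gap-fill sparse DOC observations with
the network ensemble, invert for net production and nitrate uptake at three
surface definitions, solve the absorbing-layer export, propagate
uncertainty by Monte Carlo, and build the regional tables and the
export-efficiency regression.  Every run archives its configuration
verbatim and writes a manifest of outputs with SHA-256 hashes, seeds, and
timings so results regenerate from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ann_mapping as am
from . import export_flux as ef
from . import io as dio
from . import regional_analysis as ra
from . import surface_diagnostics as sd
from . import synthetic_ocean as so
from . import uncertainty_mc as mc

__all__ = ["RunConfig", "RunManifest", "PipelineError", "run_all", "synth_stage"]


class PipelineError(RuntimeError):
    """A stage failed; the manifest records the stages that completed."""


@dataclass
class RunConfig:
    """Fully serializable configuration of an end-to-end run."""

    seed: int = 0
    out_dir: str = "docpump_run"
    # scenario
    n_lat: int = 36
    n_lon: int = 3
    overturning_sv: float = 20.0
    obs_fraction: float = 0.05
    obs_noise_sd: float = 2.0
    # mapping
    ann_members: int = 20
    ann_hidden: int = 15
    # diagnostics
    tau: float = sd.DEFAULT_TAU_YEARS
    surface_definitions: tuple[str, ...] = ("36m", "74m", "euphotic")
    export_depth: float = 74.0
    # Monte Carlo
    mc_runs: int = 200
    mc_tau_range: tuple[float, float] = (0.25, 0.75)
    n_circulations: int = 10
    # regionalization
    oligotrophic_threshold: float = 0.5
    antarctic_threshold: float = 20.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = dio.read_config(path)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        if "surface_definitions" in raw:
            raw["surface_definitions"] = tuple(raw["surface_definitions"])
        if "mc_tau_range" in raw:
            raw["mc_tau_range"] = tuple(raw["mc_tau_range"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["surface_definitions"] = list(self.surface_definitions)
        d["mc_tau_range"] = list(self.mc_tau_range)
        return d


@dataclass
class RunManifest:
    """Record of a run: per-stage outputs, hashes, seeds, and wall-clock."""

    config: dict
    stages: list[dict] = field(default_factory=list)

    def add_stage(self, name: str, outputs: dict[str, Path], seconds: float,
                  info: dict | None = None) -> None:
        self.stages.append({
            "stage": name,
            "outputs": {k: str(p) for k, p in outputs.items()},
            "sha256": {k: _sha256(p) for k, p in outputs.items()},
            "seconds": round(seconds, 3),
            "info": info or {},
        })

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        seen = [p for s in self.stages for p in s["outputs"].values()]
        if len(seen) != len(set(seen)):
            raise PipelineError("manifest lists an output file more than once")
        path.write_text(json.dumps({"config": self.config, "stages": self.stages}, indent=2))
        return path


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def synth_stage(config: RunConfig, out: Path) -> tuple[so.Scenario, so.ObservationSet, dict]:
    """Generate and write the synthetic world and its sparse observations."""
    scenario = so.make_scenario(
        seed=config.seed, n_lat=config.n_lat, n_lon=config.n_lon,
        overturning_sv=config.overturning_sv,
    )
    rng = np.random.default_rng(config.seed + 1)
    obs = so.sample_observations(
        scenario.doc, scenario.grid, fraction=config.obs_fraction,
        noise_sd=config.obs_noise_sd, seed=int(rng.integers(0, 2**31 - 1)),
    )
    paths = dio.save_scenario(scenario, out / "scenario")
    paths["observations"] = dio.write_observations(obs, scenario.grid,
                                                   out / "scenario" / "observations.csv")
    return scenario, obs, paths


def run_all(config: RunConfig) -> RunManifest:
    """Run every stage; stage failure halts with a manifest of completed stages."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dio.write_config(config.to_dict(), out / "config.yml")
    manifest = RunManifest(config=config.to_dict())
    manifest_path = out / "manifest.json"

    def guard(stage: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            manifest.write(manifest_path)
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        return result, time.perf_counter() - t0

    # ---- synth ------------------------------------------------------------
    (scenario, obs, paths), dt = guard("synth", lambda: synth_stage(config, out))
    manifest.add_stage("synth", paths, dt, {"seed": config.seed, "n_obs": len(obs)})
    grid = scenario.grid

    # ---- map-doc ----------------------------------------------------------
    def _map():
        predictors = am.assemble_predictors(grid, scenario.predictor_fields())
        cfg = am.ANNConfig(n_hidden=config.ann_hidden, n_members=config.ann_members,
                           seed=config.seed + 2)
        ensemble = am.train_ensemble(obs, predictors, cfg)
        mapped = am.predict_field(ensemble, predictors)
        stats = am.holdout_stats(mapped.values[obs.box_index], obs.values)
        p1 = out / "mapped" / "ensemble.json"
        p1.parent.mkdir(parents=True, exist_ok=True)
        p1.write_text(json.dumps(am.ensemble_to_dict(ensemble)))
        ds = dio.grid_to_dataset(grid, {"doc_mapped": mapped.values,
                                        "doc_spread": mapped.spread})
        p2 = dio.write_netcdf(ds, out / "mapped" / "doc.nc")
        return ensemble, mapped, stats, {"ensemble": p1, "doc": p2}

    (ensemble, mapped, map_stats, paths), dt = guard("map-doc", _map)
    manifest.add_stage("map-doc", paths, dt, {
        "n_members": ensemble.n_members,
        "fit_vs_obs": {"slope": map_stats.slope, "r2": map_stats.r2, "rmse": map_stats.rmse},
    })

    # ---- diagnose ---------------------------------------------------------
    def _diagnose():
        prof = sd.diagnose_profile(scenario.transport, mapped.values, scenario.no3,
                                   tau=config.tau, definitions=config.surface_definitions)
        fields, rows = {}, []
        for d in prof.solutions:
            ndp = sd.to_areal_flux(prof.ndp(d), element="C")
            upt = sd.to_areal_flux(prof.uptake(d), element="N")
            key = d.replace("euphotic", "zeu")
            fields[f"ndp_{key}"] = ndp.areal
            fields[f"uptake_{key}"] = upt.areal
            rows.append({"definition": d, "tau": config.tau,
                         "ndp_global_pgc": ndp.global_pg,
                         "uptake_global_pgn": upt.global_pg})
        p1 = dio.write_netcdf(dio.grid_to_dataset(grid, fields), out / "diagnostics" / "fluxes.nc")
        p2 = out / "diagnostics" / "global_integrals.csv"
        pd.DataFrame(rows).to_csv(p2, index=False)
        return prof, {"fluxes": p1, "globals": p2}

    (prof, paths), dt = guard("diagnose", _diagnose)
    manifest.add_stage("diagnose", paths, dt, {"tau": config.tau})

    # ---- export -----------------------------------------------------------
    def _export():
        sol = prof.ndp("74m")
        export = ef.solve_export(scenario.transport, sol.j_full, config.export_depth)
        ds = dio.grid_to_dataset(grid, {"ndx_areal": export.areal})
        ds.attrs.update({"export_depth": export.export_depth, "k": export.k})
        p1 = dio.write_netcdf(ds, out / "export" / "ndx.nc")
        return export, {"ndx": p1}

    (export, paths), dt = guard("export", _export)
    manifest.add_stage("export", paths, dt, {"global_ndx_pgc": export.global_pg})

    # ---- mc ---------------------------------------------------------------
    def _mc():
        pool = so.transport_ensemble(grid, n_members=config.n_circulations,
                                     seed=config.seed + 3,
                                     overturning_sv=config.overturning_sv)
        no3_mean = ra.depth_mean_no3(scenario.no3, grid)
        regions = ra.regionalize(no3_mean, grid,
                                 oligotrophic_threshold=config.oligotrophic_threshold,
                                 antarctic_threshold=config.antarctic_threshold)
        bands = {r: regions.mask(r) for r in regions.names}
        inputs = mc.MCInputs(transport_pool=pool, doc_pool=mapped.member_fields,
                             no3_field=scenario.no3, band_masks=bands,
                             c_export=scenario.ancillary.c_export)
        summary = mc.run_mc(
            mc.MCConfig(n_runs=config.mc_runs, tau_range=config.mc_tau_range,
                        export_depth=config.export_depth, seed=config.seed + 4),
            inputs,
        )
        p1 = out / "mc" / "run_log.csv"
        p1.parent.mkdir(parents=True, exist_ok=True)
        summary.run_log.to_csv(p1, index=False)
        ds = dio.grid_to_dataset(grid, {
            "ndp_mean": summary.ndp_mean, "ndp_sd": summary.ndp_sd,
            "uptake_mean": summary.uptake_mean, "uptake_sd": summary.uptake_sd,
            "ndx_mean": summary.ndx_mean, "ndx_sd": summary.ndx_sd,
        })
        p2 = dio.write_netcdf(ds, out / "mc" / "summary.nc")
        return summary, regions, {"run_log": p1, "summary": p2}

    (mc_summary, regions, paths), dt = guard("mc", _mc)
    log = mc_summary.run_log
    manifest.add_stage("mc", paths, dt, {
        "n_runs": int(mc_summary.n_runs),
        "ndp_global_pgc": [float(log.ndp_global_pgc.mean()), float(log.ndp_global_pgc.std())],
        "ndx_global_pgc": [float(log.ndx_global_pgc.mean()), float(log.ndx_global_pgc.std())],
    })

    # ---- regions + MLR ----------------------------------------------------
    def _regions():
        anc = scenario.ancillary
        ndp74 = sd.to_areal_flux(prof.ndp("74m"), element="C")
        ratios = ra.efficiency_ratios(
            {"ndp": ndp74.areal, "ndx": export.areal,
             "cexport": anc.c_export, "npp": anc.npp},
            regions, grid,
        )
        weights = np.clip(export.areal, 0.0, None)
        predictors = ra.regional_means({
            "f_pico": anc.f_pico,
            "log10_no3": np.log10(np.maximum(regions.no3_mean, ra.NO3_LOG_FLOOR)),
            "sst": anc.sst,
        }, weights, regions)
        response = ratios.loc[list(regions.names), "ndp:cexport"]
        fit = ra.fit_mlr(response, predictors[["f_pico", "log10_no3"]])
        p1 = out / "regions" / "ratios.csv"
        p1.parent.mkdir(parents=True, exist_ok=True)
        ratios.to_csv(p1)
        p2 = out / "regions" / "mlr.json"
        p2.write_text(json.dumps({
            "equation": fit.equation(),
            "coefficients": fit.params.to_dict(),
            "standard_errors": fit.bse.to_dict(),
            "standardized": fit.standardized.to_dict(),
            "standardized_ratio": fit.standardized_ratio,
            "r2": fit.r2, "n": fit.n,
        }, indent=2))
        return ratios, fit, {"ratios": p1, "mlr": p2}

    (ratios, fit, paths), dt = guard("regions", _regions)
    manifest.add_stage("regions", paths, dt, {"mlr_r2": fit.r2})

    manifest.write(manifest_path)
    return manifest
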