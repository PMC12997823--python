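"""End-to-end orchestration: simulate -> sample -> fit -> compare ->
cross-validate -> diel -> functional response.

A :class:`RunConfig` (YAML round-trippable) pins every stage seed, so a
re-run with the same config reproduces identical outputs. Stage outputs
and a manifest (seeds, row counts, best models, set-support ratios,
cross-validation summaries) are written under the output directory.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import pandas as pd
import yaml
from shapely.geometry import box

from . import crossval, funcresp, model_selection, sampling, synthetic, temporal
from .covariates import synthetic_moon_series
from .glmm import ModelSpec, build_model_matrix, fit_glmm

__all__ = ["RunConfig", "run_pipeline"]


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full synthetic-world analysis run."""

    extent: tuple[float, float, float, float] = (0.0, 0.0, 12_000.0, 12_000.0)
    cell_size: float = 60.0
    truth: synthetic.TruthConfig = dataclasses.field(
        default_factory=lambda: synthetic.TruthConfig(
            n_individuals=8, fixes_per_individual=1000, home_range_scale=1500.0
        )
    )
    seeds: dict[str, int] = dataclasses.field(
        default_factory=lambda: {"landscape": 1, "sampling": 2, "crossval": 3}
    )
    levels: tuple[str, ...] = ("landscape", "homerange")
    hourly_spec: str = "Sfr"
    run_hourly: bool = True
    cv_folds: int = 5
    n_bins: int = 10

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["extent"] = list(self.extent)
        d["levels"] = list(self.levels)
        d["truth"] = dataclasses.asdict(self.truth)
        d["truth"]["start_window"] = list(self.truth.start_window)
        d["truth"]["diel_amplitude"] = {
            k: [a, t] for k, (a, t) in self.truth.diel_amplitude.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "truth" in d:
            t = d["truth"]
            if "diel_amplitude" in t:
                t["diel_amplitude"] = {k: (v[0], v[1]) for k, v in t["diel_amplitude"].items()}
            if "start_window" in t:
                t["start_window"] = tuple(t["start_window"])
            d["truth"] = synthetic.TruthConfig(**t)
        if "extent" in d:
            d["extent"] = tuple(d["extent"])
        if "levels" in d:
            d["levels"] = tuple(d["levels"])
        return cls(**d)


def run_pipeline(config: RunConfig, outdir, stages: tuple[str, ...] | None = None) -> dict:
    """Execute the pipeline and return the run manifest.

    ``stages`` restricts execution to a prefix of the stage order
    (simulate, sample, fit, crossval, diel, funcresp); a failed stage
    halts the run, and the partial manifest written so far names it.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"config_seeds": dict(config.seeds)}
    order = ("simulate", "sample", "fit", "crossval", "diel", "funcresp")
    wanted = set(stages or order)
    stage = "simulate"
    try:
        # -- simulate --------------------------------------------------
        land = synthetic.generate_landscape(
            config.extent, cell_size=config.cell_size, seed=config.seeds["landscape"]
        )
        t_lo = pd.Timestamp(config.truth.start_window[0])
        t_hi = pd.Timestamp(config.truth.start_window[1]) + pd.Timedelta(
            hours=config.truth.fix_interval_hours * config.truth.fixes_per_individual
        )
        moon = synthetic_moon_series(
            t_lo - pd.Timedelta(days=2), t_hi + pd.Timedelta(days=2), new_moon_epoch=t_lo
        )
        tracks = synthetic.simulate_tracks(land, config.truth, moon)
        synthetic.tracks_to_csv(tracks, out / "tracks.csv")
        synthetic.mcps_to_geojson(tracks, out / "mcps.geojson")
        config.truth.to_yaml(out / "truth.yaml")
        manifest["n_individuals"] = len(tracks)
        manifest["n_relocations"] = int(sum(t.n_fixes for t in tracks))
        manifest["median_mcp_km2"] = float(
            pd.Series([t.mcp_area_km2 for t in tracks]).median()
        )
        if "sample" not in wanted:
            return _write_manifest(manifest, out)

        # -- sample ----------------------------------------------------
        stage = "sample"
        n_reloc = manifest["n_relocations"]
        n_avail = sampling.availability_count(n_reloc)
        seed = config.seeds["sampling"]
        region = box(*config.extent)
        counts = {t.individual_id: t.n_fixes for t in tracks}
        region_pts = sampling.draw_available(region, n_avail, seed)
        mcp_pts = sampling.draw_available(
            {t.individual_id: t.mcp for t in tracks}, n_avail, seed + 1, counts
        )
        tables: dict[str, pd.DataFrame] = {}
        infos = {}
        if "landscape" in config.levels:
            tables["landscape"], infos["landscape"] = sampling.build_landscape_table(
                region_pts, mcp_pts, land, seed + 2, relocation_counts=counts
            )
        if "homerange" in config.levels:
            tables["homerange"], infos["homerange"] = sampling.build_homerange_table(
                mcp_pts, tracks, land, moon, seed + 3
            )
        hourly = None
        if config.run_hourly:
            hourly = sampling.build_hourly_tables(mcp_pts, tracks, land, moon, seed + 4)
        for lvl, tab in tables.items():
            tab.to_csv(out / f"table_{lvl}.csv", index=False)
        manifest["sampling"] = {"n_available_points": n_avail, **{
            lvl: info for lvl, info in infos.items()}}
        if "fit" not in wanted:
            return _write_manifest(manifest, out)

        # -- fit & compare ----------------------------------------------
        stage = "fit"
        comparisons = {}
        best_fits = {}
        all_fits: dict[str, dict[str, Any]] = {}
        for lvl in config.levels:
            fits = []
            for spec in model_selection.model_set(lvl):
                fits.append(fit_glmm(build_model_matrix(tables[lvl], spec)))
            comp = model_selection.compare(fits, level=lvl)
            comp.to_csv(out / f"comparison_{lvl}.csv")
            comp.to_json(out / f"comparison_{lvl}.json")
            comparisons[lvl] = comp
            all_fits[lvl] = {f.spec.name: f for f in fits}
            best_fits[lvl] = all_fits[lvl][comp.best]
            best_fits[lvl].to_json(out / f"fit_{lvl}_{comp.best}.json")
            manifest.setdefault("model_selection", {})[lvl] = {
                "best": comp.best,
                "delta_aic_ratios": {k: round(v, 2) for k, v in comp.ratios.items()},
            }
        if "crossval" not in wanted:
            return _write_manifest(manifest, out)

        # -- cross-validation -------------------------------------------
        stage = "crossval"
        cv_seed = config.seeds["crossval"]
        for lvl, fit in best_fits.items():
            cv = crossval.kfold_crossvalidate(
                tables[lvl], fit.spec, k=config.cv_folds, n_bins=config.n_bins,
                seed=cv_seed,
            )
            cv.to_json(out / f"cv_{lvl}.json")
            manifest.setdefault("crossval", {})[lvl] = {
                "mean_rho": cv.mean_rho, "rho_range": list(cv.rho_range),
                "combined_p": cv.combined_p,
            }
        if "diel" not in wanted or hourly is None:
            return _write_manifest(manifest, out)

        # -- diel / lunar -----------------------------------------------
        stage = "diel"
        spec = ModelSpec.from_name(config.hourly_spec, "homerange")
        hour_fits = temporal.fit_hourly_models(hourly, spec)
        diel = temporal.diel_analysis(hour_fits)
        diel.to_csv(out / "diel_tests.csv")
        pd.concat(
            [df.assign(covariate=c, side=s) for (c, s), df in diel.series.items()]
        ).to_csv(out / "diel_series.csv", index=False)
        manifest["diel"] = {
            "hourly_aic_mean": float(diel.hourly_aic.mean()),
            "hourly_aic_sd": float(diel.hourly_aic.std()),
        }
        if "homerange" in all_fits and "STfr" in all_fits["homerange"]:
            lun = temporal.lunar_interaction(all_fits["homerange"]["STfr"], "WC")
            manifest["lunar_WC"] = {"estimate": lun.estimate, "se": lun.se,
                                    "z": lun.z, "p": lun.p}
        if "funcresp" not in wanted or "landscape" not in tables:
            return _write_manifest(manifest, out)

        # -- functional response ----------------------------------------
        stage = "funcresp"
        ratios = funcresp.selection_ratios(tables["landscape"], tables["homerange"])
        ratios.to_csv(out / "selection_ratios.csv", index=False)
        fr = funcresp.functional_response_table(ratios)
        fr.to_csv(out / "functional_response.csv", index=False)
        manifest["functional_response_rows"] = int(len(fr))
    except Exception as exc:  # noqa: BLE001 - halt with stage context
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_manifest(manifest, out)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return _write_manifest(manifest, out)


def _write_manifest(manifest: dict, out: Path) -> dict:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
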