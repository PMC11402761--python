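"""End-to-end orchestration: index -> regression -> inversion -> map.

One call runs every stage on a well table (read from CSV or freshly
simulated), writes all artifacts (fit and boundary model files, ASCII
rasters, CSV reports) into an output directory together with a
machine-readable run manifest, and is deterministic under fixed seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .assoc_stats import (
    SplitSpec,
    correlation_matrix,
    split_train_validation,
    stepwise_select,
    validate_fit,
    vif,
)
from .boundary import boundary_for_wells, invert_model
from .geospatial import (
    boundary_raster,
    classify_equal_interval,
    grid_from_bounds,
    project_wells,
    raster_summary,
    rasterize_field,
    write_ascii_grid,
)
from .gwqi import batch_gwqi
from .synthetic import VARIABLES, SyntheticConfig, simulate_structural_mode
from .well_data import GuidelineTable, WellTable, load_fixture, read_wells, write_wells

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """All pipeline settings; every field lands in the run manifest."""

    wells_csv: str | None = None          # None -> simulate instead
    guidelines_csv: str | None = None     # None -> packaged guideline table
    simulate_n: int = 112
    seed: int | None = None
    split_fraction: float = 0.8
    p_enter: float = 0.05
    p_remove: float = 0.10
    nominal_gwqi: float = 25.0
    idw_power: float = 2.0
    idw_neighbors: int = 12
    cell_size_m: float = 50.0
    crs: str = "local"
    n_classes: int = 5
    outdir: str = "sanibound_out"


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-tagged with stage
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns a summary dict (also written
    as ``manifest.json`` next to the artifacts)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    @_stage("load")
    def load():
        if config.guidelines_csv:
            guide = GuidelineTable.from_csv(config.guidelines_csv)
        else:
            guide = load_fixture("guidelines")
        if config.wells_csv:
            wells = read_wells(config.wells_csv)
        else:
            wells = simulate_structural_mode(
                SyntheticConfig(mode="structural", n=config.simulate_n,
                                seed=config.seed)
            )
        return guide, wells

    guide, wells = load()

    @_stage("gwqi")
    def index():
        t = batch_gwqi(wells, guide)
        write_wells(t, out / "wells_indexed.csv")
        return t

    wells = index()

    @_stage("correlate")
    def correlate():
        cm = correlation_matrix(wells, list(VARIABLES))
        cm.to_csv(out / "correlations.csv")
        return cm

    corr = correlate()

    @_stage("fit")
    def fit_stage():
        spec = SplitSpec(fraction=config.split_fraction, seed=config.seed)
        train, valid = split_train_validation(wells, spec)
        fit = stepwise_select(train, "gwqi_actual", list(VARIABLES[1:]),
                              config.p_enter, config.p_remove)
        fit.to_csv(out / "fit.csv")
        vifs = vif(train, list(VARIABLES[1:])) if len(VARIABLES) > 2 else {}
        report = validate_fit(fit, valid) if len(valid) >= 3 else None
        if report is not None:
            report.frame.to_csv(out / "validation.csv", index=False)
        return spec, fit, vifs, report

    spec, fit, vifs, report = fit_stage()

    @_stage("invert")
    def invert():
        # the boundary equation admits only the three hydro terms; when
        # selection retained anything else (a false positive), refit the
        # forward model on the admissible subset before inverting
        admissible = ("transmissivity_m2day", "depth_m", "dist_latrine_m")
        inv_fit = fit
        extra = [t for t in fit.predictors if t not in admissible]
        if extra:
            log.warning("invert: dropping non-boundary term(s) %s and "
                        "refitting", extra)
            from .assoc_stats import ols_fit

            keep = [t for t in fit.predictors if t in admissible]
            train = WellTable(wells.frame.iloc[list(spec.train_indices)]
                              .reset_index(drop=True), wells.provenance)
            inv_fit = ols_fit(train, "gwqi_actual", keep)
        model = invert_model(inv_fit, nominal_gwqi=config.nominal_gwqi)
        model.to_json(out / "boundary_model.json")
        wb = boundary_for_wells(model, wells)
        write_wells(wb, out / "wells_boundary.csv")
        return model

    model = invert()

    @_stage("map")
    def map_stage():
        pw = project_wells(wells, config.crs)
        x, y = pw.frame["x_m"], pw.frame["y_m"]
        pad = config.cell_size_m
        grid = grid_from_bounds(x.min() - pad, y.min() - pad,
                                x.max() + pad, y.max() + pad,
                                config.cell_size_m, config.crs)
        tr = rasterize_field(pw, "transmissivity_m2day", grid,
                             config.idw_power, config.idw_neighbors)
        dp = rasterize_field(pw, "depth_m", grid,
                             config.idw_power, config.idw_neighbors)
        br = boundary_raster(model, tr, dp)
        classified = classify_equal_interval(br, config.n_classes)
        write_ascii_grid(tr, out / "transmissivity.asc")
        write_ascii_grid(dp, out / "depth.asc")
        write_ascii_grid(br, out / "boundary.asc")
        write_ascii_grid(classified.grid, out / "boundary_classes.asc",
                         fmt="%g")
        return br, classified

    br, classified = map_stage()

    summary = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "n_wells": len(wells),
        "split": {"train": len(spec.train_indices),
                  "validation": len(spec.validation_indices)},
        "selected_predictors": list(fit.predictors),
        "fit_r_squared": fit.r_squared,
        "vif": vifs,
        "validation_r_squared":
            None if report is None else report.r_squared,
        "boundary_equation": model.rounded_equation(),
        "boundary_raster": raster_summary(br),
        "class_ranges_m": [list(r) for r in classified.display_ranges],
        "class_histogram": classified.histogram(),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, default=float)
        fh.write("\n")
    log.info("pipeline complete: artifacts in %s", out)
    return summary
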