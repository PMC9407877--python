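"""End-to-end orchestration: simulate -> ES -> metrics -> constraint ->
dynamics -> drivers, with per-stage outputs, a manifest and determinism
under a fixed global seed."""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import constraint as cst
from . import drivers as drv
from . import dynamics as dyn
from . import esmodels as esm
from . import landmetrics as lm
from . import synthgen as sg
from .config import config_hash, validate_config
from .errors import InsufficientDataError
from .grids import GridSpec, write_raster

logger = logging.getLogger(__name__)

__all__ = ["RunState", "run_all", "write_fixtures"]


@dataclass
class RunState:
    """In-memory products of the pipeline stages."""

    config: dict
    grid: GridSpec
    years: list[int]
    landuse: dict[int, sg.LandUseMap] = field(default_factory=dict)
    forcings: dict[int, sg.ForcingStack] = field(default_factory=dict)
    zones: np.ndarray | None = None
    zone_yields: pd.DataFrame | None = None
    es_layers: dict[int, dict[str, esm.ESLayer]] = field(default_factory=dict)
    es_means: pd.DataFrame | None = None
    metrics_rows: list[dict] = field(default_factory=list)
    curves: pd.DataFrame | None = None
    feature_trends: pd.DataFrame | None = None
    feature_boxstats: pd.DataFrame | None = None
    attribution: pd.DataFrame | None = None


def _interp_proportions(start: dict, end: dict, frac: float) -> dict:
    props = {k: (1 - frac) * start[k] + frac * end.get(k, start[k]) for k in start}
    total = sum(props.values())
    return {k: v / total for k, v in props.items()}


def stage_simulate(state: RunState) -> None:
    cfg = state.config
    seed = int(cfg["seed"])
    years = state.years
    land_cfg = cfg["landscape"]
    n_span = max(len(years) - 1, 1)
    for i, year in enumerate(years):
        props = _interp_proportions(
            land_cfg["proportions_start"], land_cfg["proportions_end"], i / n_span
        )
        lu_seed = int(np.random.SeedSequence((seed, 101, i)).generate_state(1)[0])
        state.landuse[year] = sg.generate_landscape(
            state.grid, props, clumping=float(land_cfg["clumping"]), seed=lu_seed
        )
    f_cfg = cfg["forcing"]
    stacks = sg.generate_forcing(
        state.grid,
        years,
        ppt_params=f_cfg["ppt"],
        tem_params=f_cfg["tem"],
        sol_params=f_cfg["sol"],
        ndvi_coupling=float(f_cfg["ndvi_coupling"]),
        seed=int(np.random.SeedSequence((seed, 102)).generate_state(1)[0]),
    )
    state.forcings = {s.year: s for s in stacks}

    z_cfg = cfg["zones"]
    state.zones = sg.generate_zones(state.grid, int(z_cfg["rows"]), int(z_cfg["cols"]))
    rows = []
    for i, year in enumerate(years):
        lu = state.landuse[year]
        for zid in np.unique(state.zones):
            crop_ha = (
                np.count_nonzero(lu.mask("cropland") & (state.zones == zid))
                * state.grid.cell_area_ha
            )
            gsum = crop_ha * (
                float(z_cfg["base_yield_t_ha"]) + float(z_cfg["yield_trend_t_ha"]) * i
            )
            rows.append({"zone_id": int(zid), "year": year, "gsum_t": gsum})
    state.zone_yields = pd.DataFrame(rows)


def _zone_map(state: RunState, year: int) -> sg.ZoneMap:
    yt = state.zone_yields
    table = {
        int(r.zone_id): float(r.gsum_t)
        for r in yt[yt["year"] == year].itertuples()
    }
    return sg.ZoneMap(grid=state.grid, zones=state.zones, yield_table=table)


def stage_es(state: RunState) -> None:
    wy_params = esm.WaterYieldParams(z=float(state.config["es"]["z"]))
    mean_rows = []
    for year in state.years:
        layers = esm.compute_all_services(
            state.forcings[year],
            state.landuse[year],
            _zone_map(state, year),
            wy_params=wy_params,
        )
        state.es_layers[year] = layers
        mean_rows.append(
            {
                "year": year,
                **{f"{s.lower()}_mean": float(l.values.mean()) for s, l in layers.items()},
            }
        )
    state.es_means = pd.DataFrame(mean_rows)


def stage_metrics(state: RunState) -> None:
    connectivity = int(state.config["metrics"]["connectivity"])
    state.metrics_rows = [
        lm.metrics_to_row(lm.metrics_for_year(state.landuse[y], year=y, connectivity=connectivity))
        for y in state.years
    ]


def stage_constraint(state: RunState) -> None:
    c = state.config["constraint"]
    pair_cfg = cst.PairConfig(
        n_bins=int(c["n_bins"]),
        quantile=float(c["quantile"]),
        min_points=int(c["min_points"]),
        sample_n=int(c["sample_n"]),
        form_map=dict(c["forms"]),
        default_form=str(c["default_form"]),
    )
    state.curves = cst.run_pairs(
        state.es_layers,
        pairs=cst.DEFAULT_PAIRS,
        landuse_by_year=state.landuse,
        config=pair_cfg,
        seed=int(state.config["seed"]),
    )
    state.curves["config_hash"] = config_hash(state.config)


def stage_trends(state: RunState) -> None:
    if len(state.years) < 3:
        raise InsufficientDataError(
            f"trend stage needs >= 3 years, got {len(state.years)}"
        )
    trend_rows, box_rows = [], []
    for series in dyn.feature_series_from_curves(state.curves):
        try:
            t = dyn.trend_test(series)
        except InsufficientDataError as exc:
            logger.warning("trend skipped for %s/%s: %s", series.pair_label, series.feature, exc)
            continue
        trend_rows.append(
            {
                "pair": series.pair_label,
                "feature": series.feature,
                "slope": t.slope,
                "p_value": t.p_value,
                "flag": t.flag,
                "n_years": t.n,
            }
        )
        _, vals = series.arrays()
        if vals.size >= 4:
            b = dyn.box_stats(vals)
            box_rows.append(
                {
                    "pair": series.pair_label,
                    "feature": series.feature,
                    "min": b.minimum,
                    "q1": b.q1,
                    "median": b.median,
                    "q3": b.q3,
                    "max": b.maximum,
                    "iqr": b.iqr,
                    "lower_fence": b.lower_fence,
                    "upper_fence": b.upper_fence,
                    "n_outliers": len(b.outliers),
                }
            )
    state.feature_trends = pd.DataFrame(trend_rows)
    state.feature_boxstats = pd.DataFrame(box_rows)


def stage_attribute(state: RunState) -> None:
    d = state.config["drivers"]
    sel = drv.SelectionConfig(
        max_terms=int(d["max_terms"]),
        vif_cap=float(d["vif_cap"]),
        min_aicc_drop=float(d["min_aicc_drop"]),
    )
    matrix = drv.build_driver_matrix(list(state.forcings.values()), state.metrics_rows)
    rows: list[dict] = []
    for series in dyn.feature_series_from_curves(state.curves):
        if len(series.values) < 8:
            continue
        for fitter in (drv.fit_model0, drv.fit_model1):
            result = fitter(series, matrix, sel)
            rows.extend(drv.attribution_to_rows(result))
    state.attribution = pd.DataFrame(rows)


STAGES = (
    ("simulate", stage_simulate),
    ("es", stage_es),
    ("metrics", stage_metrics),
    ("constraint", stage_constraint),
    ("trends", stage_trends),
    ("attribute", stage_attribute),
)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_outputs(state: RunState, outdir: Path) -> dict[str, str]:
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    def put(df: pd.DataFrame | None, name: str) -> None:
        if df is None:
            return
        path = outdir / name
        df.to_csv(path, index=False)
        written[name] = _checksum(path)

    put(state.zone_yields, "zone_yields.csv")
    put(state.es_means, "es_means.csv")
    if state.metrics_rows:
        put(pd.DataFrame(state.metrics_rows), "landscape_metrics.csv")
    put(state.curves, "constraint_curves.csv")
    put(state.feature_trends, "feature_trends.csv")
    put(state.feature_boxstats, "feature_boxstats.csv")
    put(state.attribution, "attribution.csv")
    if state.es_means is not None and len(state.es_means) >= 3:
        put(dyn.es_annual_report(state.es_means), "es_annual_report.csv")

    if state.config["output"]["write_rasters"]:
        raster_dir = outdir / "rasters"
        nodata = state.grid.nodata_value
        for year in state.years:
            write_raster(
                raster_dir / f"landuse_{year}.tif",
                state.landuse[year].classes.astype(float),
                nodata=nodata,
            )
            for service, layer in state.es_layers.get(year, {}).items():
                write_raster(
                    raster_dir / f"{service.lower()}_{year}.tif", layer.values, nodata=nodata
                )
    return written


def run_all(
    config: dict | None = None,
    outdir: str | Path | None = None,
    seed: int | None = None,
    stop_after: str | None = None,
) -> RunState:
    """Run the full pipeline; any stage failure aborts naming the stage.

    Partial outputs written before the failure are retained.
    """
    cfg = validate_config(config or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    g = cfg["grid"]
    state = RunState(
        config=cfg,
        grid=GridSpec(
            n_rows=int(g["n_rows"]),
            n_cols=int(g["n_cols"]),
            cell_size=float(g["cell_size"]),
            nodata_value=float(g["nodata_value"]),
        ),
        years=list(cfg["years"]),
    )
    timings: dict[str, float] = {}
    for stage_name, fn in STAGES:
        t0 = time.perf_counter()
        try:
            fn(state)
        except Exception:
            logger.error("stage %r failed", stage_name)
            if outdir is not None:
                _write_outputs(state, Path(outdir))
            raise
        timings[stage_name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.2fs", stage_name, timings[stage_name])
        if stop_after == stage_name:
            break

    if outdir is not None:
        outdir = Path(outdir)
        checksums = _write_outputs(state, outdir)
        manifest = {
            "config": cfg,
            "config_hash": config_hash(cfg),
            "seed": cfg["seed"],
            "stage_seconds": timings,
            "output_checksums": checksums,
        }
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
    return state


def write_fixtures(name: str, outdir: str | Path) -> list[Path]:
    """Write packaged fixtures: the reference feature table or toy clouds."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if name == "table4":
        path = outdir / "table4_features.csv"
        dyn.load_table4().to_csv(path, index=False)
        return [path]
    if name == "toy_clouds":
        paths = []
        specs = [
            ("hump", {"x_star": 5.0, "y_star": 10.0, "width": 1.0}, (2.0, 8.0)),
            ("exponential", {"k": 0.9995, "b": 8.0}, (0.0, 3000.0)),
        ]
        for form, params, x_range in specs:
            cloud = sg.generate_constrained_cloud(
                10_000, form, params, noise_exponent=3.0, x_range=x_range, seed=42
            )
            path = outdir / f"toy_cloud_{form}.csv"
            pd.DataFrame({"x": cloud.x, "y": cloud.y}).to_csv(path, index=False)
            with open(outdir / f"toy_cloud_{form}_truth.yaml", "w") as fh:
                yaml.safe_dump(
                    {k: (list(v) if isinstance(v, tuple) else v) for k, v in cloud.truth.items()},
                    fh,
                )
            paths.append(path)
        return paths
    raise ValueError(f"unknown fixture name {name!r}")
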