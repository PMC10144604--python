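"""End-to-end analysis driver: inputs -> tables, metrics and maps.

A :class:`RunConfig` names the inputs (a district CSV, gridded surfaces
plus polygons, or a synthetic spec), the reference and comparator
indicators, and the classification parameters. :func:`run_pipeline`
executes aggregation, classification, overlap summaries, the AUC panel
and map rendering, writing every figure's plotted values as CSV alongside
it and a provenance sidecar (config echo + package version). Any stage
failure removes the partial outputs of this run and re-raises with the
stage name.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .aggregate import aggregate_to_districts, compute_pixel_fractions, prevalence_to_counts
from .classify import (
    ClassificationSpec,
    assign_population_weighted_bins,
    assignments_to_frame,
)
from .overlap import (
    auc_panel,
    build_targeting_curve,
    count_high_indicators,
    cross_tabulate,
    pct_high_overlap,
    proportion_high_for_any,
)
from .plots import (
    render_bivariate_map,
    render_high_quartile_map,
    render_multi_indicator_map,
)
from .raster import DistrictPolygons, IndicatorRaster
from .synthetic import SyntheticSpec, generate_district_table, rasterize_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; message names the stage."""


@dataclass
class RunConfig:
    """Inputs, indicator roles and classification parameters for one run."""

    outdir: str | Path = "zdoverlap_out"
    reference: str = "no_dtp"
    comparators: list[str] = field(default_factory=lambda: ["comparator"])
    n_bins: int = 4
    scope: str = "within_country"
    basis: str = "prevalence"
    seed: int = 0
    # input A: pre-aggregated district table
    district_table: str | Path | None = None
    # input B: gridded surfaces (indicator name -> prevalence GeoTIFF)
    indicator_rasters: dict[str, str] = field(default_factory=dict)
    population_raster: str | Path | None = None
    polygons: str | Path | None = None
    district_field: str = "ADM2_CODE"
    country_field: str = "ADM0_NAME"
    # input C: synthetic data (also renders maps via rasterized polygons)
    synthetic: SyntheticSpec | None = None
    make_maps: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "synthetic" in doc and doc["synthetic"] is not None:
            syn = dict(doc["synthetic"])
            if "prevalence_range" in syn:
                syn["prevalence_range"] = tuple(syn["prevalence_range"])
            if "raster_shape" in syn and syn["raster_shape"] is not None:
                syn["raster_shape"] = tuple(syn["raster_shape"])
            doc["synthetic"] = SyntheticSpec(**syn)
        return cls(**doc)

    def to_jsonable(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["outdir"] = str(doc["outdir"])
        for key in ("district_table", "population_raster", "polygons"):
            if doc[key] is not None:
                doc[key] = str(doc[key])
        return doc


def _load_inputs(config: RunConfig):
    """Stage 1: obtain the district table and, when possible, polygons."""
    polygons: DistrictPolygons | None = None
    if config.synthetic is not None:
        spec = config.synthetic
        if config.seed and spec.seed != config.seed:
            spec = dataclasses.replace(spec, seed=config.seed)
        table = generate_district_table(spec)
        if spec.raster_shape is not None:
            _, _, polygons = rasterize_table(table, spec)
        return table, polygons
    if config.district_table is not None:
        table = pd.read_csv(config.district_table, dtype={"district_id": str})
        table["district_id"] = table["district_id"].astype(str)
        table["country_id"] = table["country_id"].astype(str)
        if config.polygons is not None:
            polygons = DistrictPolygons.from_geojson(
                config.polygons, config.district_field, config.country_field
            )
        return table, polygons
    if config.indicator_rasters:
        if config.population_raster is None or config.polygons is None:
            raise ValueError(
                "raster input needs population_raster and polygons as well"
            )
        polygons = DistrictPolygons.from_geojson(
            config.polygons, config.district_field, config.country_field
        )
        population = IndicatorRaster.from_geotiff(config.population_raster)
        table = None
        fractions = None
        for name, path in config.indicator_rasters.items():
            raster = IndicatorRaster.from_geotiff(path)
            if fractions is None:
                fractions = compute_pixel_fractions(raster, polygons)
            part = aggregate_to_districts(
                raster, population, polygons, indicator_name=name, fractions=fractions
            )
            if table is None:
                table = part
            else:
                table = table.merge(
                    part.drop(columns=["country_id", "target_population"]),
                    on="district_id",
                )
        return table, polygons
    raise ValueError("config names no input: set synthetic, district_table or rasters")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full analysis; returns a name -> path map of outputs."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    outputs: dict[str, Path] = {}

    def emit(name: str, path: Path) -> Path:
        created.append(path)
        outputs[name] = path
        return path

    stage = "load-inputs"
    try:
        table, polygons = _load_inputs(config)

        stage = "derive-counts"
        indicators = [config.reference, *config.comparators]
        for ind in indicators:
            if f"{ind}_count" not in table.columns and f"{ind}_prev" in table.columns:
                table = prevalence_to_counts(table, ind)
        table.to_csv(emit("district_table", outdir / "district_table.csv"), index=False)

        stage = "classify"
        spec = ClassificationSpec(
            indicator=config.reference,
            n_bins=config.n_bins,
            scope=config.scope,
            basis=config.basis,
        )
        assignments = {}
        for ind in indicators:
            s = dataclasses.replace(spec, indicator=ind)
            if s.value_column not in table.columns:
                logger.warning("indicator %s missing from table; skipped", ind)
                continue
            assignments[ind] = assign_population_weighted_bins(table, s)
        if config.reference not in assignments:
            raise ValueError(f"reference indicator {config.reference!r} unavailable")
        assignments_to_frame(assignments.values()).to_csv(
            emit("assignments", outdir / "assignments.csv"), index=False
        )

        stage = "overlap-metrics"
        ref_asg = assignments[config.reference]
        rows = []
        for comp in config.comparators:
            if comp not in assignments:
                rows.append((comp, "status", "missing"))
                continue
            summary = cross_tabulate(ref_asg, assignments[comp])
            rows += [
                (comp, "exact_match_proportion", summary.exact_match_proportion),
                (comp, "high_high_count", summary.high_high_count),
                (comp, "high_either_count", summary.high_either_count),
                (comp, "pct_ref_high", pct_high_overlap(ref_asg, assignments[comp])),
                (
                    comp,
                    "pct_either_high",
                    pct_high_overlap(ref_asg, assignments[comp], "either_high"),
                ),
            ]
        counts_frame = count_high_indicators(
            list(assignments.values()), config.reference
        )
        rows.append(("all", "pct_high_for_any", proportion_high_for_any(counts_frame)))
        summary_frame = pd.DataFrame(rows, columns=["indicator", "metric", "value"])
        summary_frame.insert(0, "basis", config.basis)
        summary_frame.insert(0, "scope", config.scope)
        summary_frame.to_csv(
            emit("overlap_summary", outdir / "overlap_summary.csv"), index=False
        )

        stage = "targeting-auc"
        available = [c for c in config.comparators if c in assignments]
        panel = auc_panel(table, config.reference, available)
        panel.to_csv(emit("auc_panel", outdir / "auc_panel.csv"), index=False)
        gi = table.set_index("district_id")
        for comp in available:
            curve = build_targeting_curve(
                gi[f"{config.reference}_count"], gi[f"{comp}_count"]
            )
            pd.DataFrame({"x": curve.x, "y": curve.y}).to_csv(
                emit(
                    f"targeting_curve_{comp}",
                    outdir / f"targeting_curve_{comp}.csv",
                ),
                index=False,
            )

        if config.make_maps and polygons is not None:
            stage = "render-maps"
            for comp in available:
                fig, data = render_bivariate_map(
                    ref_asg, assignments[comp], polygons,
                    title=f"{config.reference} vs {comp} ({config.basis}, {config.scope})",
                )
                fig.savefig(emit(f"bivariate_map_{comp}", outdir / f"bivariate_{comp}.png"), dpi=150)
                data.to_csv(
                    emit(f"bivariate_data_{comp}", outdir / f"bivariate_{comp}.csv"),
                    index=False,
                )
                fig2, data2 = render_high_quartile_map(
                    ref_asg, assignments[comp], polygons
                )
                fig2.savefig(
                    emit(f"high_bin_map_{comp}", outdir / f"high_bin_{comp}.png"),
                    dpi=150,
                )
                data2.to_csv(
                    emit(f"high_bin_data_{comp}", outdir / f"high_bin_{comp}.csv"),
                    index=False,
                )
            fig3, data3 = render_multi_indicator_map(counts_frame, polygons)
            fig3.savefig(emit("multi_indicator_map", outdir / "multi_indicator.png"), dpi=150)
            data3.to_csv(
                emit("multi_indicator_data", outdir / "multi_indicator.csv"),
                index=False,
            )

        stage = "provenance"
        sidecar = {
            "package": "zdoverlap",
            "version": __version__,
            "config": config.to_jsonable(),
            "outputs": {k: str(v) for k, v in outputs.items()},
        }
        prov = emit("provenance", outdir / "provenance.json")
        prov.write_text(json.dumps(sidecar, indent=2, default=str))
    except Exception as exc:
        for path in created:
            path.unlink(missing_ok=True)
        raise PipelineError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return outputs
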