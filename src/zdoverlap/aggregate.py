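"""Fractional aggregation of gridded surfaces to district polygons.

Boundary pixels are split between districts in proportion to the exact
polygon–pixel intersection area (not assigned whole by centroid), so that
totals are conserved when districts tile the grid. District prevalence is
the population-weighted mean of pixel prevalences,

    prev_d = sum_p (prev_p * pop_p * w_pd) / sum_p (pop_p * w_pd),

where w_pd is the fraction of pixel p's area inside district d, and the
district target population is the denominator sum. Counts follow as
prevalence times target population. Nodata pixels are excluded from both
numerator and denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .raster import DistrictPolygons, IndicatorRaster

logger = logging.getLogger(__name__)

__all__ = [
    "PixelFractions",
    "compute_pixel_fractions",
    "aggregate_to_districts",
    "complement_prevalence",
    "prevalence_to_counts",
]


@dataclass
class PixelFractions:
    """Sparse pixel-to-district area fractions.

    ``entries[district_id]`` is a ``(rows, cols, fractions)`` triple of
    equal-length arrays giving, for every pixel that intersects the
    district, the fraction of that pixel's area falling inside it.
    """

    shape: tuple[int, int]
    entries: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    @property
    def district_ids(self) -> list[str]:
        return list(self.entries)

    def coverage_grid(self) -> np.ndarray:
        """Total fraction of each pixel claimed by any district (<= 1 when
        districts do not overlap)."""
        grid = np.zeros(self.shape)
        for rows, cols, frac in self.entries.values():
            np.add.at(grid, (rows, cols), frac)
        return grid


def _check_crs(a_label: str | None, b_label: str | None, what: str) -> None:
    if a_label != b_label:
        raise ValueError(
            f"coordinate system mismatch between raster and {what}: "
            f"{a_label!r} != {b_label!r}; reproject inputs explicitly"
        )


def compute_pixel_fractions(
    raster: IndicatorRaster, districts: DistrictPolygons
) -> PixelFractions:
    """Exact area fraction of each raster pixel inside each district.

    For every district polygon, pixels in its bounding window are
    intersected with the polygon (shapely, exact polygon clipping) and the
    intersection area is divided by the pixel area. Fractions are in
    [0, 1]; for non-overlapping districts the per-pixel fractions sum to
    at most 1, with equality where the districts tile the pixel.

    A district lying entirely outside the raster extent is recorded with
    zero coverage and a warning is logged.
    """
    _check_crs(raster.crs_id, districts.crs_id, "district polygons")
    n_rows, n_cols = raster.shape
    a, _, c, _, e, f = raster.transform
    px_area = raster.pixel_area
    result = PixelFractions(shape=raster.shape)
    empty = (np.array([], dtype=int), np.array([], dtype=int), np.array([]))

    n_outside = 0
    for did, _, geom in districts:
        gxmin, gymin, gxmax, gymax = geom.bounds
        # pixel-index window covering the polygon bounds, clipped to grid
        col0 = max(int(np.floor((gxmin - c) / a)), 0)
        col1 = min(int(np.ceil((gxmax - c) / a)), n_cols)
        row0 = max(int(np.floor((gymax - f) / e)), 0)
        row1 = min(int(np.ceil((gymin - f) / e)), n_rows)
        if col0 >= col1 or row0 >= row1:
            result.entries[did] = empty
            n_outside += 1
            logger.warning("district %s lies outside the raster extent", did)
            continue
        rows, cols = np.mgrid[row0:row1, col0:col1]
        rows, cols = rows.ravel(), cols.ravel()
        xmin, ymin, xmax, ymax = raster.pixel_bounds(rows, cols)
        boxes = shapely.box(xmin, ymin, xmax, ymax)
        frac = shapely.area(shapely.intersection(boxes, geom)) / px_area
        keep = frac > 0.0
        if not keep.any():
            n_outside += 1
            logger.warning("district %s has zero overlap with the raster", did)
        result.entries[did] = (rows[keep], cols[keep], np.minimum(frac[keep], 1.0))
    if n_outside:
        logger.warning("%d district(s) had no raster coverage", n_outside)
    return result


def aggregate_to_districts(
    indicator: IndicatorRaster,
    population: IndicatorRaster,
    districts: DistrictPolygons,
    indicator_name: str = "indicator",
    fractions: PixelFractions | None = None,
) -> pd.DataFrame:
    """Aggregate a prevalence surface to districts, weighting by population.

    Returns a district table with columns ``district_id``, ``country_id``,
    ``target_population``, ``<indicator_name>_prev`` and
    ``<indicator_name>_count``. Districts with zero aggregated population
    (or all-nodata pixels) get NaN prevalence and counts; a warning is
    logged with the number of such districts.

    Parameters
    ----------
    fractions : PixelFractions, optional
        Precomputed pixel fractions (e.g. reused across indicator layers on
        the same grid); computed from ``indicator`` and ``districts`` when
        omitted.
    """
    if indicator.shape != population.shape:
        raise ValueError(
            f"indicator grid {indicator.shape} and population grid "
            f"{population.shape} differ"
        )
    if indicator.transform != population.transform:
        raise ValueError("indicator and population grids have different transforms")
    _check_crs(indicator.crs_id, population.crs_id, "population raster")
    indicator.validate_prevalence()
    population.validate_population()
    if fractions is None:
        fractions = compute_pixel_fractions(indicator, districts)

    valid = indicator.mask() & population.mask()
    prev = indicator.values
    pop = population.values

    records = []
    n_empty = 0
    for did, cid, _ in districts:
        rows, cols, frac = fractions.entries[did]
        if rows.size:
            ok = valid[rows, cols]
            rows, cols, frac = rows[ok], cols[ok], frac[ok]
        weight = pop[rows, cols] * frac if rows.size else np.array([])
        denom = float(weight.sum()) if rows.size else 0.0
        if denom > 0.0:
            p = float((prev[rows, cols] * weight).sum()) / denom
            records.append((did, cid, denom, p, p * denom))
        else:
            n_empty += 1
            records.append((did, cid, denom, np.nan, np.nan))
    if n_empty:
        logger.warning(
            "%d district(s) have zero aggregated population; prevalence recorded "
            "as missing",
            n_empty,
        )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "district_id",
            "country_id",
            "target_population",
            f"{indicator_name}_prev",
            f"{indicator_name}_count",
        ],
    )


def complement_prevalence(coverage):
    """Burden prevalence as the complement of coverage, ``1 - coverage``.

    The reference indicator (no-DTP, children with no dose of a
    DTP-containing vaccine) is defined as 1 minus DTP1 coverage. Accepts a
    scalar, array, pandas Series, or :class:`IndicatorRaster` (nodata
    pixels pass through untouched); values must lie in [0, 1].
    """
    if isinstance(coverage, IndicatorRaster):
        coverage.validate_prevalence()
        out = coverage.values.copy()
        m = coverage.mask()
        out[m] = 1.0 - out[m]
        return IndicatorRaster(
            values=out,
            transform=coverage.transform,
            nodata=coverage.nodata,
            crs_id=coverage.crs_id,
        )
    arr = np.asarray(coverage, dtype=float)
    finite = np.isfinite(arr)
    if np.any((arr[finite] < 0.0) | (arr[finite] > 1.0)):
        raise ValueError("coverage values must lie in [0, 1]")
    result = 1.0 - arr
    if isinstance(coverage, pd.Series):
        return pd.Series(result, index=coverage.index, name=coverage.name)
    if np.isscalar(coverage):
        return float(result)
    return result


def prevalence_to_counts(table: pd.DataFrame, indicator: str) -> pd.DataFrame:
    """Add a ``<indicator>_count`` column: prevalence times target population.

    Districts with missing prevalence get missing counts, which downstream
    classification and overlap metrics treat as excluded.
    """
    prev_col = f"{indicator}_prev"
    if prev_col not in table.columns:
        raise KeyError(f"table has no column {prev_col!r}")
    if "target_population" not in table.columns:
        raise KeyError("table has no column 'target_population'")
    prev = table[prev_col].astype(float)
    if ((prev < 0) | (prev > 1)).any():
        raise ValueError(f"{prev_col} has values outside [0, 1]")
    out = table.copy()
    out[f"{indicator}_count"] = prev * out["target_population"].astype(float)
    return out
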