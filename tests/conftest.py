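import numpy as np
import pandas as pd
import pytest
import shapely

from zdoverlap.raster import DistrictPolygons, IndicatorRaster

NORTH_UP = (1.0, 0.0, 0.0, 0.0, -1.0, None)  # filled per-grid


def make_raster(values, nodata=None, crs_id="EPSG:3857", pixel=1.0, origin=(0.0, None)):
    """Unit-pixel north-up raster; origin y defaults to n_rows (grid top)."""
    values = np.asarray(values, dtype=float)
    x0, y0 = origin
    if y0 is None:
        y0 = float(values.shape[0]) * pixel
    transform = (pixel, 0.0, x0, 0.0, -pixel, y0)
    return IndicatorRaster(values=values, transform=transform, nodata=nodata, crs_id=crs_id)


def rect_districts(rects, crs_id="EPSG:3857", countries=None):
    """Districts from (xmin, ymin, xmax, ymax) rectangles, ids D1, D2, ..."""
    ids = [f"D{i + 1}" for i in range(len(rects))]
    if countries is None:
        countries = ["C1"] * len(rects)
    geoms = [shapely.box(*r) for r in rects]
    return DistrictPolygons(ids, countries, geoms, crs_id=crs_id)


def simple_table(values, populations, countries=None, indicator="no_dtp"):
    """District table from parallel value/population lists."""
    n = len(values)
    if countries is None:
        countries = ["C1"] * n
    df = pd.DataFrame(
        {
            "district_id": [f"D{i + 1}" for i in range(n)],
            "country_id": countries,
            "target_population": np.asarray(populations, dtype=float),
            f"{indicator}_prev": np.asarray(values, dtype=float),
        }
    )
    df[f"{indicator}_count"] = df[f"{indicator}_prev"] * df["target_population"]
    return df


@pytest.fixture
def two_by_two_uniform():
    """2x2 prevalence grid with uniform population, one covering district."""
    prev = make_raster([[0.2, 0.4], [0.6, 0.8]])
    pop = make_raster(np.ones((2, 2)))
    districts = rect_districts([(0, 0, 2, 2)])
    return prev, pop, districts
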