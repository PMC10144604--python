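"""Georeferenced raster and district-polygon containers with file I/O.

Gridded indicator surfaces (prevalence in [0, 1]) and target-population
surfaces (persons per pixel) are carried as :class:`IndicatorRaster`: a 2-D
array plus a north-up affine transform, an optional nodata sentinel, and a
coordinate-reference-system label. District boundaries (admin-2 units) are
carried as :class:`DistrictPolygons` backed by shapely geometries.

GeoTIFF I/O is implemented directly on top of :mod:`tifffile` using the
standard GeoTIFF tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory) and
the GDAL nodata convention; polygon I/O uses GeoJSON via :mod:`json` and
:func:`shapely.geometry.shape`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
import tifffile
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry import shape as shapely_shape

logger = logging.getLogger(__name__)

# GeoTIFF / GDAL tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey ids
_KEY_MODEL_TYPE = 1024
_KEY_GEOGRAPHIC_TYPE = 2048
_KEY_PROJECTED_CS_TYPE = 3072


@dataclass
class IndicatorRaster:
    """A single-band gridded surface with georeferencing.

    Parameters
    ----------
    values : ndarray of shape (n_rows, n_cols)
        Pixel values. Prevalence layers must lie in [0, 1] outside nodata;
        population layers must be non-negative.
    transform : tuple of 6 floats ``(a, b, c, d, e, f)``
        Affine map from pixel indices to world coordinates,
        ``x = a*col + b*row + c`` and ``y = d*col + e*row + f``
        (same ordering as rasterio's ``Affine``). Only north-up,
        axis-aligned transforms are supported (``b == d == 0``,
        ``a > 0``, ``e < 0``).
    nodata : float or None
        Sentinel marking missing pixels.
    crs_id : str or None
        Coordinate reference system label, e.g. ``"EPSG:4326"``. Aggregation
        refuses to mix rasters and polygons with different labels.
    """

    values: np.ndarray
    transform: tuple[float, float, float, float, float, float]
    nodata: float | None = None
    crs_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"raster values must be 2-D, got shape {self.values.shape}")
        a, b, c, d, e, f = (float(v) for v in self.transform)
        if b != 0.0 or d != 0.0:
            raise ValueError("only axis-aligned (north-up) transforms are supported")
        if a <= 0 or e >= 0:
            raise ValueError("expected pixel width > 0 and pixel height < 0 (north-up)")
        self.transform = (a, b, c, d, e, f)

    # -- geometry helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def pixel_width(self) -> float:
        return self.transform[0]

    @property
    def pixel_height(self) -> float:
        """Absolute pixel height in world units."""
        return -self.transform[4]

    @property
    def pixel_area(self) -> float:
        return self.pixel_width * self.pixel_height

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid."""
        a, _, c, _, e, f = self.transform
        n_rows, n_cols = self.shape
        xmin, xmax = c, c + a * n_cols
        ytop, ybot = f, f + e * n_rows
        return (xmin, ybot, xmax, ytop)

    def pixel_bounds(self, rows: np.ndarray, cols: np.ndarray):
        """Vectorized (xmin, ymin, xmax, ymax) for pixel (row, col) pairs."""
        a, _, c, _, e, f = self.transform
        xmin = c + a * cols
        xmax = xmin + a
        ymax = f + e * rows
        ymin = ymax + e
        return xmin, ymin, xmax, ymax

    def mask(self) -> np.ndarray:
        """Boolean array, True where the pixel holds a valid value."""
        valid = np.isfinite(self.values)
        if self.nodata is not None:
            valid &= self.values != self.nodata
        return valid

    # -- validation -------------------------------------------------------

    def validate_prevalence(self) -> None:
        vals = self.values[self.mask()]
        if vals.size and (vals.min() < 0.0 or vals.max() > 1.0):
            raise ValueError(
                f"prevalence layer has values outside [0, 1]: "
                f"range [{vals.min():g}, {vals.max():g}]"
            )

    def validate_population(self) -> None:
        vals = self.values[self.mask()]
        if vals.size and vals.min() < 0.0:
            raise ValueError(f"population layer has negative values (min {vals.min():g})")

    # -- I/O ---------------------------------------------------------------

    def to_geotiff(self, path: str | Path) -> None:
        """Write a single-band GeoTIFF with standard georeferencing tags."""
        a, _, c, _, e, f = self.transform
        extratags = [
            (_TAG_MODEL_PIXEL_SCALE, "d", 3, (a, -e, 0.0)),
            (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, c, f, 0.0)),
        ]
        geokeys = _crs_to_geokeys(self.crs_id)
        if geokeys is not None:
            extratags.append((_TAG_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys))
        if self.nodata is not None:
            nd = f"{self.nodata:.17g}\x00"
            extratags.append((_TAG_GDAL_NODATA, "s", len(nd), nd))
        tifffile.imwrite(str(path), self.values.astype(np.float64), extratags=extratags)

    @classmethod
    def from_geotiff(cls, path: str | Path) -> "IndicatorRaster":
        """Read a single-band GeoTIFF written by this package or GDAL-style tools."""
        with tifffile.TiffFile(str(path)) as tif:
            page = tif.pages[0]
            values = page.asarray()
            if values.ndim == 3:  # single band stored with a channel axis
                values = values[..., 0] if values.shape[-1] == 1 else values[0]
            tags = {tag.code: tag.value for tag in page.tags.values()}
        scale = tags.get(_TAG_MODEL_PIXEL_SCALE)
        tie = tags.get(_TAG_MODEL_TIEPOINT)
        if scale is None or tie is None:
            raise ValueError(f"{path}: missing GeoTIFF georeferencing tags")
        sx, sy = float(scale[0]), float(scale[1])
        i, j, _, x, y, _ = (float(v) for v in tie[:6])
        transform = (sx, 0.0, x - sx * i, 0.0, -sy, y + sy * j)
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            txt = tags[_TAG_GDAL_NODATA]
            if isinstance(txt, bytes):
                txt = txt.decode("ascii", "ignore")
            txt = txt.strip("\x00 ")
            if txt and txt.lower() not in {"nan"}:
                nodata = float(txt)
            elif txt.lower() == "nan":
                nodata = float("nan")
        crs_id = _geokeys_to_crs(tags.get(_TAG_GEO_KEY_DIRECTORY))
        return cls(values=values, transform=transform, nodata=nodata, crs_id=crs_id)


def _crs_to_geokeys(crs_id: str | None) -> tuple[int, ...] | None:
    """Encode an ``EPSG:xxxx`` label as a minimal GeoKeyDirectory."""
    if crs_id is None:
        return None
    label = crs_id.upper()
    if not label.startswith("EPSG:"):
        return None
    code = int(label.split(":", 1)[1])
    geographic = 4000 <= code < 5000
    if geographic:
        keys = [(_KEY_MODEL_TYPE, 0, 1, 2), (_KEY_GEOGRAPHIC_TYPE, 0, 1, code)]
    else:
        keys = [(_KEY_MODEL_TYPE, 0, 1, 1), (_KEY_PROJECTED_CS_TYPE, 0, 1, code)]
    flat: list[int] = [1, 1, 0, len(keys)]
    for entry in keys:
        flat.extend(entry)
    return tuple(flat)


def _geokeys_to_crs(directory) -> str | None:
    if directory is None:
        return None
    vals = [int(v) for v in directory]
    for k in range(4, len(vals) - 3, 4):
        key, _, _, value = vals[k : k + 4]
        if key in (_KEY_GEOGRAPHIC_TYPE, _KEY_PROJECTED_CS_TYPE):
            return f"EPSG:{value}"
    return None


@dataclass
class DistrictPolygons:
    """District (admin-2) boundaries keyed by district and country id."""

    district_id: list[str]
    country_id: list[str]
    geometry: list  # shapely geometries
    crs_id: str | None = None

    def __post_init__(self) -> None:
        self.district_id = [str(d) for d in self.district_id]
        self.country_id = [str(cn) for cn in self.country_id]
        if not (len(self.district_id) == len(self.country_id) == len(self.geometry)):
            raise ValueError("district_id, country_id and geometry lengths differ")
        if len(set(self.district_id)) != len(self.district_id):
            dupes = sorted(
                d for d in set(self.district_id) if self.district_id.count(d) > 1
            )
            raise ValueError(f"duplicate district ids: {dupes[:5]}")
        for did, cid, geom in zip(self.district_id, self.country_id, self.geometry):
            if geom is None or geom.is_empty:
                raise ValueError(f"district {did!r} has empty geometry")
            if not cid:
                raise ValueError(f"district {did!r} has empty country_id")

    def __len__(self) -> int:
        return len(self.district_id)

    def __iter__(self):
        return iter(zip(self.district_id, self.country_id, self.geometry))

    @classmethod
    def from_geojson(
        cls,
        path: str | Path,
        district_field: str = "ADM2_CODE",
        country_field: str = "ADM0_NAME",
        crs_id: str | None = None,
    ) -> "DistrictPolygons":
        """Load a GeoJSON FeatureCollection of district polygons.

        ``crs_id`` overrides any CRS recorded in the file (GeoJSON is
        nominally always EPSG:4326, but the surfaces this package consumes
        are often in equal-area projections).
        """
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("type") != "FeatureCollection":
            raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
        if crs_id is None:
            name = doc.get("crs", {}).get("properties", {}).get("name")
            crs_id = _normalize_crs_name(name)
        dids, cids, geoms = [], [], []
        for feat in doc["features"]:
            props = feat.get("properties", {})
            if district_field not in props:
                raise KeyError(
                    f"feature lacks district attribute {district_field!r}; "
                    f"available: {sorted(props)}"
                )
            dids.append(str(props[district_field]))
            cids.append(str(props.get(country_field, "")))
            geoms.append(shapely_shape(feat["geometry"]))
        return cls(district_id=dids, country_id=cids, geometry=geoms, crs_id=crs_id)

    def to_geojson(
        self,
        path: str | Path,
        district_field: str = "ADM2_CODE",
        country_field: str = "ADM0_NAME",
    ) -> None:
        features = [
            {
                "type": "Feature",
                "properties": {district_field: did, country_field: cid},
                "geometry": shapely_mapping(geom),
            }
            for did, cid, geom in self
        ]
        doc: dict = {"type": "FeatureCollection", "features": features}
        if self.crs_id is not None:
            doc["crs"] = {"type": "name", "properties": {"name": self.crs_id}}
        with open(path, "w") as fh:
            json.dump(doc, fh)


def _normalize_crs_name(name: str | None) -> str | None:
    if not name:
        return None
    # e.g. "urn:ogc:def:crs:EPSG::4326" or "EPSG:4326"
    if "EPSG" in name.upper():
        code = name.replace("::", ":").rstrip(":").split(":")[-1]
        if code.isdigit():
            return f"EPSG:{code}"
    return name
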