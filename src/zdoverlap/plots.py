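"""Choropleth rendering of quantile overlap.

Three map styles mirror the standard presentation of bivariate district
overlap:

* a full bivariate map colouring each district by its joint (reference
  bin, comparator bin) cell, with an n_bins x n_bins legend whose diagonal
  marks matching assignments;
* a simplified highest-bin map with three classes — top bin for the
  reference only, the comparator only, or both — plus a neutral class;
* a multi-indicator map shading each district by the number of indicators
  in their top bin, outlining districts where the reference is among them.

Every renderer also returns the exact per-district values plotted, so a
machine-readable CSV can sit next to each figure. Matplotlib only; the
shapely polygons are drawn directly as path patches (holes respected).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from matplotlib.collections import PatchCollection
from matplotlib.figure import Figure
from matplotlib.patches import PathPatch, Rectangle
from matplotlib.path import Path as MplPath

from .classify import QuantileAssignment
from .raster import DistrictPolygons

logger = logging.getLogger(__name__)

__all__ = [
    "bivariate_palette",
    "render_bivariate_map",
    "render_high_quartile_map",
    "render_multi_indicator_map",
]

_MISSING_FACE = "#f0f0f0"


def bivariate_palette(n_bins: int = 4) -> np.ndarray:
    """An (n_bins, n_bins, 3) RGB grid for joint-bin colouring.

    Reference bins deepen a blue channel along rows, comparator bins a red
    channel along columns; the diagonal (matching assignments) runs from
    pale grey to dark purple.
    """
    t = np.linspace(0.15, 0.95, n_bins)
    ref = t[:, None]  # rows
    comp = t[None, :]  # columns
    rgb = np.empty((n_bins, n_bins, 3))
    rgb[..., 0] = 1.0 - 0.85 * ref  # red falls with reference bin
    rgb[..., 2] = 1.0 - 0.85 * comp  # blue falls with comparator bin
    rgb[..., 1] = 1.0 - 0.75 * np.maximum(ref, comp)
    return rgb


def _geom_to_patch(geom, **kwargs) -> PathPatch:
    """Shapely (Multi)Polygon to a single matplotlib PathPatch."""
    polys = geom.geoms if geom.geom_type == "MultiPolygon" else [geom]
    vertices: list[np.ndarray] = []
    codes: list[np.ndarray] = []
    for poly in polys:
        for ring in [poly.exterior, *poly.interiors]:
            pts = np.asarray(ring.coords)
            vertices.append(pts)
            code = np.full(len(pts), MplPath.LINETO)
            code[0] = MplPath.MOVETO
            code[-1] = MplPath.CLOSEPOLY
            codes.append(code)
    path = MplPath(np.concatenate(vertices), np.concatenate(codes))
    return PathPatch(path, **kwargs)


def _geometry_lookup(polygons: DistrictPolygons) -> dict[str, object]:
    return {did: geom for did, _, geom in polygons}


def render_bivariate_map(
    ref: QuantileAssignment,
    comp: QuantileAssignment,
    polygons: DistrictPolygons,
    palette: np.ndarray | None = None,
    title: str | None = None,
) -> tuple[Figure, pd.DataFrame]:
    """Bivariate choropleth of joint bin membership.

    Districts classified for only one (or neither) indicator are drawn in
    a hatched neutral fill. Returns the figure and the per-district frame
    of plotted values (``district_id``, ``ref_bin``, ``comp_bin``).
    """
    if not ref.compatible_with(comp):
        raise ValueError("assignments were produced under different specs")
    n_bins = ref.spec.n_bins
    if palette is None:
        palette = bivariate_palette(n_bins)
    joined = ref.frame.merge(
        comp.frame[["district_id", "bin"]],
        on="district_id",
        how="outer",
        suffixes=("_ref", "_comp"),
    ).rename(columns={"bin_ref": "ref_bin", "bin_comp": "comp_bin"})
    lookup = _geometry_lookup(polygons)

    fig = Figure(figsize=(8, 6))
    ax = fig.add_subplot(1, 1, 1)
    plotted = []
    for rec in joined.itertuples(index=False):
        geom = lookup.get(rec.district_id)
        if geom is None:
            logger.warning("no geometry for district %s; omitted", rec.district_id)
            continue
        if pd.isna(rec.ref_bin) or pd.isna(rec.comp_bin):
            patch = _geom_to_patch(
                geom, facecolor=_MISSING_FACE, edgecolor="0.6", hatch="///", lw=0.3
            )
        else:
            color = palette[int(rec.ref_bin) - 1, int(rec.comp_bin) - 1]
            patch = _geom_to_patch(geom, facecolor=color, edgecolor="white", lw=0.3)
        ax.add_patch(patch)
        plotted.append(rec)
    ax.autoscale_view()
    ax.set_aspect("equal")
    ax.set_axis_off()
    if title:
        ax.set_title(title)

    # inset legend: reference bins upward, comparator bins rightward
    leg = fig.add_axes([0.78, 0.08, 0.18, 0.24])
    for i in range(n_bins):
        for j in range(n_bins):
            leg.add_patch(
                Rectangle((j, i), 1, 1, facecolor=palette[i, j], edgecolor="white")
            )
    leg.set_xlim(0, n_bins)
    leg.set_ylim(0, n_bins)
    leg.set_xticks([])
    leg.set_yticks([])
    leg.set_xlabel(f"{comp.spec.indicator} bin →", fontsize=7)
    leg.set_ylabel(f"{ref.spec.indicator} bin →", fontsize=7)

    data = pd.DataFrame(plotted, columns=joined.columns)[
        ["district_id", "ref_bin", "comp_bin"]
    ]
    return fig, data


def render_high_quartile_map(
    ref: QuantileAssignment,
    comp: QuantileAssignment,
    polygons: DistrictPolygons,
    title: str | None = None,
) -> tuple[Figure, pd.DataFrame]:
    """Three-class map of highest-bin membership.

    Red: top bin for the reference only; blue: comparator only; purple:
    both; light grey: neither. Returns the figure and the per-district
    class frame (``category`` in {"ref_only", "comp_only", "both",
    "neither"}).
    """
    if not ref.compatible_with(comp):
        raise ValueError("assignments were produced under different specs")
    ref_top = ref.top_bin_ids()
    comp_top = comp.top_bin_ids()
    colors = {
        "ref_only": "#d7301f",
        "comp_only": "#0570b0",
        "both": "#7b3294",
        "neither": _MISSING_FACE,
    }
    fig = Figure(figsize=(8, 6))
    ax = fig.add_subplot(1, 1, 1)
    rows = []
    for did, cid, geom in polygons:
        in_ref, in_comp = did in ref_top, did in comp_top
        cat = (
            "both"
            if in_ref and in_comp
            else "ref_only" if in_ref else "comp_only" if in_comp else "neither"
        )
        ax.add_patch(
            _geom_to_patch(geom, facecolor=colors[cat], edgecolor="white", lw=0.3)
        )
        rows.append((did, cid, cat))
    ax.autoscale_view()
    ax.set_aspect("equal")
    ax.set_axis_off()
    if title:
        ax.set_title(title)
    handles = [
        Rectangle((0, 0), 1, 1, facecolor=c, label=lbl) for lbl, c in colors.items()
    ]
    ax.legend(handles=handles, loc="lower right", fontsize=7, frameon=False)
    data = pd.DataFrame(rows, columns=["district_id", "country_id", "category"])
    return fig, data


def render_multi_indicator_map(
    counts: pd.DataFrame,
    polygons: DistrictPolygons,
    title: str | None = None,
) -> tuple[Figure, pd.DataFrame]:
    """Sequential map of the number of indicators in the top bin.

    ``counts`` is the frame from
    :func:`zdoverlap.overlap.count_high_indicators` (``district_id``,
    ``n_high``, ``ref_in_high``). Districts where the reference indicator
    is among the top-bin indicators are outlined in white, heavier than
    the base stroke.
    """
    from matplotlib import colormaps

    n_max = int(counts["n_high"].max()) if len(counts) else 0
    cmap = colormaps["YlOrRd"]
    lut = counts.set_index("district_id")
    fig = Figure(figsize=(8, 6))
    ax = fig.add_subplot(1, 1, 1)
    rows = []
    for did, cid, geom in polygons:
        if did not in lut.index:
            ax.add_patch(
                _geom_to_patch(
                    geom, facecolor=_MISSING_FACE, edgecolor="0.6", hatch="///", lw=0.3
                )
            )
            continue
        n_high = int(lut.at[did, "n_high"])
        ref_in = bool(lut.at[did, "ref_in_high"])
        face = cmap(n_high / n_max) if n_max else cmap(0.0)
        edge, lw = ("white", 1.6) if ref_in else ("0.4", 0.3)
        ax.add_patch(_geom_to_patch(geom, facecolor=face, edgecolor=edge, lw=lw))
        rows.append((did, cid, n_high, ref_in))
    ax.autoscale_view()
    ax.set_aspect("equal")
    ax.set_axis_off()
    if title:
        ax.set_title(title)
    data = pd.DataFrame(
        rows, columns=["district_id", "country_id", "n_high", "ref_in_high"]
    )
    return fig, data
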