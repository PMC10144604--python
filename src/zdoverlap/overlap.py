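"""Bivariate overlap metrics between a reference and comparator indicator.

Two families of summaries quantify how far the geographic burden of the
reference indicator (no-DTP children) coincides with a comparator (e.g.
stunting):

* quartile-based: joint bin cross-tabulations, the proportion of districts
  assigned to the same bin for both indicators, and highest-bin overlap
  percentages under either denominator (districts high for the reference,
  or high for at least one of the two);

* the serial-targeting curve: districts are targeted in descending order
  of reference counts — first the district with the most no-DTP children,
  then the top two, and so on — and at each step the cumulative proportion
  of reference and comparator individuals reached is recorded. The area
  under this curve (trapezoidal, anchored at the origin) summarises
  overlap: AUC = 0.5 means targeting by the reference reaches comparator
  individuals in exactly proportional measure; below 0.5, a smaller
  proportion; above, a greater one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classify import QuantileAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapSummary",
    "TargetingCurve",
    "cross_tabulate",
    "pct_high_overlap",
    "count_high_indicators",
    "proportion_high_for_any",
    "build_targeting_curve",
    "compute_auc",
    "auc_panel",
]


@dataclass
class OverlapSummary:
    """Joint-bin summary of two quantile assignments.

    ``cross_tab`` is an n_bins x n_bins integer matrix of district counts,
    rows = reference bin, columns = comparator bin.
    """

    cross_tab: pd.DataFrame
    exact_match_proportion: float
    high_high_count: int
    high_either_count: int
    pct_of_ref_high_also_comp_high: float
    n_districts: int


@dataclass
class TargetingCurve:
    """Cumulative-proportion curve for serial district targeting.

    ``x[k]`` / ``y[k]`` are the cumulative proportions of reference and
    comparator counts after targeting the k districts with the highest
    reference counts; both start at 0 and end at 1. ``order`` lists the
    district ids in targeting order.
    """

    x: np.ndarray
    y: np.ndarray
    order: list[str]
    auc: float = float("nan")


def _check_pair(ref: QuantileAssignment, comp: QuantileAssignment) -> pd.DataFrame:
    if not ref.compatible_with(comp):
        raise ValueError(
            "assignments were produced under different specs: "
            f"{ref.spec} vs {comp.spec}"
        )
    joined = ref.frame.merge(
        comp.frame[["district_id", "bin"]],
        on="district_id",
        suffixes=("_ref", "_comp"),
    )
    if joined.empty:
        raise ValueError("assignments share no districts")
    return joined


def cross_tabulate(ref: QuantileAssignment, comp: QuantileAssignment) -> OverlapSummary:
    """Cross-tabulate joint bin membership of two assignments.

    Districts missing from either assignment are excluded. The exact-match
    proportion is the fraction of jointly classified districts placed in
    the same bin for both indicators (the trace over the table total).
    """
    joined = _check_pair(ref, comp)
    n_bins = ref.spec.n_bins
    bins = list(range(1, n_bins + 1))
    tab = (
        pd.crosstab(joined["bin_ref"], joined["bin_comp"])
        .reindex(index=bins, columns=bins, fill_value=0)
        .astype(int)
    )
    tab.index.name = "ref_bin"
    tab.columns.name = "comp_bin"
    n = int(tab.to_numpy().sum())
    ref_high = joined["bin_ref"] == n_bins
    comp_high = joined["bin_comp"] == n_bins
    hh = int((ref_high & comp_high).sum())
    he = int((ref_high | comp_high).sum())
    pct = 100.0 * hh / int(ref_high.sum()) if ref_high.any() else float("nan")
    return OverlapSummary(
        cross_tab=tab,
        exact_match_proportion=float(np.trace(tab.to_numpy())) / n,
        high_high_count=hh,
        high_either_count=he,
        pct_of_ref_high_also_comp_high=pct,
        n_districts=n,
    )


def pct_high_overlap(
    ref: QuantileAssignment,
    comp: QuantileAssignment,
    denominator: str = "ref_high",
) -> float:
    """Percent of highest-bin districts shared by both indicators.

    ``denominator="ref_high"`` divides by the districts in the reference's
    top bin; ``"either_high"`` divides by districts in the top bin of at
    least one indicator. Returns NaN (with a warning) when the denominator
    is empty.
    """
    if denominator not in ("ref_high", "either_high"):
        raise ValueError("denominator must be 'ref_high' or 'either_high'")
    joined = _check_pair(ref, comp)
    n_bins = ref.spec.n_bins
    ref_high = joined["bin_ref"] == n_bins
    comp_high = joined["bin_comp"] == n_bins
    hh = int((ref_high & comp_high).sum())
    denom = int(ref_high.sum()) if denominator == "ref_high" else int(
        (ref_high | comp_high).sum()
    )
    if denom == 0:
        logger.warning("pct_high_overlap: empty denominator (%s)", denominator)
        return float("nan")
    return 100.0 * hh / denom


def count_high_indicators(
    assignments: Sequence[QuantileAssignment], ref: str
) -> pd.DataFrame:
    """Per district, how many indicators fall in their highest bin.

    Returns a frame with ``district_id``, ``country_id``, ``n_high`` (count
    of indicators whose assignment put the district in the top bin) and
    ``ref_in_high`` (whether the reference indicator is among them). A
    district missing from an indicator's assignment simply contributes no
    count for that indicator.
    """
    if not assignments:
        raise ValueError("no assignments given")
    first = assignments[0]
    for other in assignments[1:]:
        if not first.compatible_with(other):
            raise ValueError("assignments mix different n_bins/scope/basis")
    names = [a.spec.indicator for a in assignments]
    if ref not in names:
        raise ValueError(f"reference indicator {ref!r} not among {names}")
    base = pd.concat(
        [a.frame[["district_id", "country_id"]] for a in assignments]
    ).drop_duplicates("district_id")
    n_high = pd.Series(0, index=base["district_id"], dtype=int)
    ref_high = pd.Series(False, index=base["district_id"])
    for asg in assignments:
        top = asg.top_bin_ids()
        hit = n_high.index.isin(top)
        n_high[hit] += 1
        if asg.spec.indicator == ref:
            ref_high[hit] = True
    out = base.copy()
    out["n_high"] = n_high.to_numpy()
    out["ref_in_high"] = ref_high.to_numpy()
    return out.reset_index(drop=True)


def proportion_high_for_any(counts: pd.DataFrame) -> float:
    """Percent of districts in the top bin for at least one indicator."""
    if counts.empty:
        raise ValueError("empty multi-indicator count table")
    return 100.0 * float((counts["n_high"] >= 1).mean())


def build_targeting_curve(
    ref_counts: pd.Series, comp_counts: pd.Series
) -> TargetingCurve:
    """Serial-targeting curve: comparator reach under reference targeting.

    Both series are indexed by district id. Districts missing a count in
    either series are dropped (complete-case alignment, logged). Districts
    are then sorted by descending reference count (ties by ascending
    district id) and the cumulative proportions accumulated; the curve is
    anchored at (0, 0) and ends at (1, 1). The AUC is filled in via
    :func:`compute_auc`.
    """
    df = pd.DataFrame({"ref": ref_counts, "comp": comp_counts})
    n_before = len(df)
    df = df.dropna()
    if len(df) < n_before:
        logger.warning(
            "targeting curve: dropped %d district(s) with missing counts",
            n_before - len(df),
        )
    if df.empty:
        raise ValueError("no jointly observed districts")
    if (df["ref"] < 0).any() or (df["comp"] < 0).any():
        raise ValueError("counts must be non-negative")
    ref_total = float(df["ref"].sum())
    comp_total = float(df["comp"].sum())
    if ref_total <= 0 or comp_total <= 0:
        raise ValueError("both indicators need a positive total count")
    df = (
        df.rename_axis("district_id")
        .reset_index()
        .sort_values(["ref", "district_id"], ascending=[False, True])
    )
    x = np.concatenate([[0.0], np.cumsum(df["ref"].to_numpy()) / ref_total])
    y = np.concatenate([[0.0], np.cumsum(df["comp"].to_numpy()) / comp_total])
    curve = TargetingCurve(x=x, y=y, order=df["district_id"].astype(str).tolist())
    curve.auc = compute_auc(curve)
    return curve


def compute_auc(curve: TargetingCurve) -> float:
    """Trapezoidal area under a targeting curve; in [0, 1].

    Equals exactly 0.5 when comparator counts are district-wise
    proportional to reference counts (the curve is the diagonal).
    """
    x, y = np.asarray(curve.x, dtype=float), np.asarray(curve.y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("curve must hold matching 1-D x and y with >= 2 points")
    if np.any(np.diff(x) < 0):
        raise ValueError("curve x values must be non-decreasing")
    return float(np.trapezoid(y, x))


def auc_panel(
    table: pd.DataFrame,
    ref: str,
    comparators: Sequence[str],
    years: Sequence | None = None,
) -> pd.DataFrame:
    """Within-country AUC for every comparator (and year, if present).

    ``table`` is a district table with ``<name>_count`` columns and
    optionally a ``year`` column. Country-indicator(-year) cells whose
    counts are absent or entirely missing are skipped with a log entry.
    Returns a tidy frame: ``country_id``, ``indicator``, ``year``, ``auc``.
    """
    has_year = "year" in table.columns
    if years is None:
        years = sorted(table["year"].unique()) if has_year else [None]
    rows = []
    for year in years:
        sub = table[table["year"] == year] if has_year and year is not None else table
        for country, grp in sub.groupby("country_id", sort=True):
            gi = grp.set_index("district_id")
            ref_col = f"{ref}_count"
            if ref_col not in gi or gi[ref_col].dropna().empty:
                logger.info("auc_panel: no %s counts for %s / %s", ref, country, year)
                continue
            for comp in comparators:
                comp_col = f"{comp}_count"
                if comp_col not in gi or gi[comp_col].dropna().empty:
                    logger.info(
                        "auc_panel: skipping %s for %s / %s (missing counts)",
                        comp,
                        country,
                        year,
                    )
                    continue
                curve = build_targeting_curve(gi[ref_col], gi[comp_col])
                rows.append((country, comp, year, curve.auc))
    return pd.DataFrame(rows, columns=["country_id", "indicator", "year", "auc"])
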