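"""Population-weighted quantile classification of district burden.

Districts are binned so that each bin holds approximately equal *target
population* rather than an equal number of districts: with quartiles
(``n_bins=4``) each bin covers about one quarter of the children at risk.
The rule is deterministic: districts are sorted ascending by burden value
(ties broken by district id), the cumulative population is accumulated in
that order, and a district belongs to the bin whose population interval
``((k-1) T / n_bins, k T / n_bins]`` contains the midpoint of the
district's cumulative-population span, ``T`` being the scope unit's total
target population. Bin 1 is lowest burden, bin ``n_bins`` highest.

Classification can be scoped ``within_country`` (each country ranked
separately, so every country has top-bin districts) or ``multinational``
(all districts pooled into one ranked list), and based on either
``prevalence`` or ``counts``.

The core rule is exposed as :class:`PopulationWeightedDiscretizer`, an
sklearn-compatible transformer; :func:`assign_population_weighted_bins` and
:func:`classify_all` drive it over district tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "ClassificationSpec",
    "QuantileAssignment",
    "PopulationWeightedDiscretizer",
    "assign_population_weighted_bins",
    "classify_all",
]

_SCOPES = ("within_country", "multinational")
_BASES = ("prevalence", "counts")


@dataclass(frozen=True)
class ClassificationSpec:
    """How districts are binned: bin count, scope, and value basis."""

    indicator: str = "no_dtp"
    n_bins: int = 4
    scope: str = "within_country"
    basis: str = "prevalence"

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")
        if self.scope not in _SCOPES:
            raise ValueError(f"scope must be one of {_SCOPES}, got {self.scope!r}")
        if self.basis not in _BASES:
            raise ValueError(f"basis must be one of {_BASES}, got {self.basis!r}")

    @property
    def value_column(self) -> str:
        suffix = "prev" if self.basis == "prevalence" else "count"
        return f"{self.indicator}_{suffix}"


@dataclass
class QuantileAssignment:
    """Per-district bin labels under a given :class:`ClassificationSpec`.

    ``frame`` has columns ``district_id``, ``country_id``, ``bin``
    (integers in 1..n_bins, 1 = lowest burden). Districts with missing
    values are absent.
    """

    frame: pd.DataFrame
    spec: ClassificationSpec

    def __post_init__(self) -> None:
        required = {"district_id", "country_id", "bin"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"assignment frame lacks columns {sorted(missing)}")

    def compatible_with(self, other: "QuantileAssignment") -> bool:
        a, b = self.spec, other.spec
        return (a.n_bins, a.scope, a.basis) == (b.n_bins, b.scope, b.basis)

    def top_bin_ids(self) -> set[str]:
        f = self.frame
        return set(f.loc[f["bin"] == self.spec.n_bins, "district_id"])


class PopulationWeightedDiscretizer(TransformerMixin, BaseEstimator):
    """Bin samples into quantiles of approximately equal total weight.

    Like :class:`~sklearn.preprocessing.KBinsDiscretizer` with a quantile
    strategy, but the quantiles are weighted: each bin's summed
    ``sample_weight`` (target population) deviates from ``total/n_bins``
    by at most the largest single sample's weight. A sample straddling a
    bin boundary goes to the bin containing the midpoint of its
    cumulative-weight span; a boundary landing exactly on ``k*T/n_bins``
    resolves to the lower bin. Ties in value are ordered by the optional
    ``ids`` passed to :meth:`fit` (stable and deterministic), else by
    position.

    Parameters
    ----------
    n_bins : int, default=4
        Number of bins; 4 gives population-weighted quartiles.

    Attributes
    ----------
    bins_ : ndarray of shape (n_samples,)
        Bin label (1..n_bins) of each training sample, 1 = lowest value.
    thresholds_ : ndarray of shape (n_bins - 1,)
        Upper value bound of each bin except the last, used by
        :meth:`transform` for unseen values.
    total_weight_ : float
        Summed sample weight of the fitted data.
    """

    def __init__(self, n_bins: int = 4):
        self.n_bins = n_bins

    def fit(self, X, y=None, sample_weight=None, ids=None):
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")
        X = check_array(X, ensure_2d=False, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("expected a single feature column")
            X = X[:, 0]
        n = X.shape[0]
        if n < self.n_bins:
            raise ValueError(f"need at least n_bins={self.n_bins} samples, got {n}")
        if sample_weight is None:
            w = np.ones(n)
        else:
            w = np.asarray(sample_weight, dtype=float)
            if w.shape != (n,):
                raise ValueError("sample_weight length mismatch")
            if (w < 0).any():
                raise ValueError("sample_weight must be non-negative")
        if ids is None:
            tie = np.arange(n)
        else:
            tie = np.asarray(ids)
            if tie.shape != (n,):
                raise ValueError("ids length mismatch")
        order = np.lexsort((tie, X))
        total = float(w.sum())
        if total <= 0:
            raise ValueError("total sample weight must be positive")
        csum = np.cumsum(w[order])
        mid = csum - w[order] / 2.0
        # bin k iff midpoint in ((k-1)T/n, kT/n]; tiny slack absorbs
        # floating-point drift at exact boundaries
        ratio = mid * self.n_bins / total
        bins_sorted = np.ceil(ratio - 1e-12).astype(int)
        np.clip(bins_sorted, 1, self.n_bins, out=bins_sorted)
        bins = np.empty(n, dtype=int)
        bins[order] = bins_sorted
        self.bins_ = bins
        self.total_weight_ = total
        xs = X[order]
        thr = np.full(self.n_bins - 1, np.inf)
        for k in range(1, self.n_bins):
            in_k = bins_sorted <= k
            thr[k - 1] = xs[in_k][-1] if in_k.any() else -np.inf
        self.thresholds_ = thr
        self.n_features_in_ = 1
        return self

    def transform(self, X):
        """Bin new values against the fitted thresholds (1..n_bins)."""
        check_is_fitted(self, "thresholds_")
        X = check_array(X, ensure_2d=False, dtype=float)
        flat = X[:, 0] if X.ndim == 2 else X
        labels = np.searchsorted(self.thresholds_, flat, side="left") + 1
        return labels.reshape(-1, 1)

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).bins_.reshape(-1, 1)


def assign_population_weighted_bins(
    table: pd.DataFrame, spec: ClassificationSpec
) -> QuantileAssignment:
    """Assign each district to a population-weighted quantile bin.

    Districts with a missing indicator value are excluded from the
    classification (and logged); the scope unit's total population is
    recomputed over the remaining districts. A scope unit with fewer
    districts than bins raises an error naming the unit.
    """
    col = spec.value_column
    if col not in table.columns:
        raise KeyError(f"table has no column {col!r} for indicator {spec.indicator!r}")
    work = table[["district_id", "country_id", "target_population", col]].copy()
    n_missing = int(work[col].isna().sum())
    if n_missing:
        logger.warning(
            "%s: excluding %d district(s) with missing %s", spec.indicator, n_missing, col
        )
        work = work.dropna(subset=[col])

    if spec.scope == "within_country":
        groups = list(work.groupby("country_id", sort=True))
    else:
        groups = [("all", work)]

    pieces = []
    disc = PopulationWeightedDiscretizer(n_bins=spec.n_bins)
    for unit, grp in groups:
        if len(grp) < spec.n_bins:
            raise ValueError(
                f"scope unit {unit!r} has {len(grp)} classifiable districts, "
                f"fewer than n_bins={spec.n_bins}"
            )
        disc.fit(
            grp[col].to_numpy(),
            sample_weight=grp["target_population"].to_numpy(),
            ids=grp["district_id"].to_numpy(),
        )
        pieces.append(
            pd.DataFrame(
                {
                    "district_id": grp["district_id"].to_numpy(),
                    "country_id": grp["country_id"].to_numpy(),
                    "bin": disc.bins_,
                }
            )
        )
    frame = pd.concat(pieces, ignore_index=True)
    return QuantileAssignment(frame=frame, spec=spec)


def classify_all(
    table: pd.DataFrame,
    indicators: Sequence[str],
    specs: Iterable[ClassificationSpec],
) -> list[QuantileAssignment]:
    """One :class:`QuantileAssignment` per indicator x spec combination."""
    out = []
    for spec in specs:
        for ind in indicators:
            s = replace(spec, indicator=ind)
            if s.value_column not in table.columns:
                raise KeyError(
                    f"unknown indicator {ind!r}: no column {s.value_column!r}"
                )
            out.append(assign_population_weighted_bins(table, s))
    return out


def assignments_to_frame(assignments: Iterable[QuantileAssignment]) -> pd.DataFrame:
    """Tidy CSV-ready view: district, country, indicator, scope, basis, bin."""
    rows = []
    for asg in assignments:
        f = asg.frame.copy()
        f["indicator"] = asg.spec.indicator
        f["scope"] = asg.spec.scope
        f["basis"] = asg.spec.basis
        rows.append(f)
    return pd.concat(rows, ignore_index=True)[
        ["district_id", "country_id", "indicator", "scope", "basis", "bin"]
    ]
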