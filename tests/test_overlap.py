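"""Bivariate overlap summaries and the serial-targeting AUC."""

import numpy as np
import pandas as pd
import pytest

from zdoverlap.classify import ClassificationSpec, QuantileAssignment
from zdoverlap.overlap import (
    TargetingCurve,
    auc_panel,
    build_targeting_curve,
    compute_auc,
    count_high_indicators,
    cross_tabulate,
    pct_high_overlap,
    proportion_high_for_any,
)


def make_assignment(bins, indicator="no_dtp", countries=None, n_bins=4, **spec_kw):
    n = len(bins)
    frame = pd.DataFrame(
        {
            "district_id": [f"D{i + 1}" for i in range(n)],
            "country_id": countries if countries is not None else ["C1"] * n,
            "bin": bins,
        }
    )
    return QuantileAssignment(
        frame=frame, spec=ClassificationSpec(indicator=indicator, n_bins=n_bins, **spec_kw)
    )


def brute_force_auc(ref, comp, ids):
    """Explicit sort, cumulative sums, trapezoid-by-trapezoid area."""
    order = sorted(range(len(ref)), key=lambda i: (-ref[i], ids[i]))
    xs, ys = [0.0], [0.0]
    rt, ct = sum(ref), sum(comp)
    cr = cc = 0.0
    for i in order:
        cr += ref[i]
        cc += comp[i]
        xs.append(cr / rt)
        ys.append(cc / ct)
    area = 0.0
    for k in range(len(xs) - 1):
        area += (xs[k + 1] - xs[k]) * (ys[k] + ys[k + 1]) / 2.0
    return area


class TestCrossTabulate:
    def test_identical_assignments_are_all_diagonal(self):
        a = make_assignment([1, 2, 3, 4, 2, 3])
        b = make_assignment([1, 2, 3, 4, 2, 3], indicator="stunting")
        s = cross_tabulate(a, b)
        assert s.exact_match_proportion == 1.0
        off_diag = s.cross_tab.to_numpy() - np.diag(np.diag(s.cross_tab.to_numpy()))
        assert off_diag.sum() == 0

    def test_reversed_bins_have_zero_exact_match(self):
        a = make_assignment([1, 2, 3, 4])
        b = make_assignment([4, 3, 2, 1], indicator="stunting")
        assert cross_tabulate(a, b).exact_match_proportion == 0.0

    def test_hand_tally_of_eight_bin_pairs(self):
        pairs = [(1, 1), (1, 2), (2, 2), (2, 2), (3, 4), (3, 3), (4, 4), (4, 1)]
        a = make_assignment([p[0] for p in pairs])
        b = make_assignment([p[1] for p in pairs], indicator="stunting")
        s = cross_tabulate(a, b)
        assert s.exact_match_proportion == pytest.approx(5 / 8)
        assert s.high_high_count == 1
        assert s.high_either_count == 3

    def test_margins_match_per_indicator_bin_counts(self):
        rng = np.random.default_rng(4)
        a = make_assignment(rng.integers(1, 5, 40))
        b = make_assignment(rng.integers(1, 5, 40), indicator="stunting")
        s = cross_tabulate(a, b)
        row_sums = s.cross_tab.sum(axis=1)
        col_sums = s.cross_tab.sum(axis=0)
        for k in range(1, 5):
            assert row_sums[k] == (a.frame["bin"] == k).sum()
            assert col_sums[k] == (b.frame["bin"] == k).sum()

    def test_mismatched_specs_rejected(self):
        a = make_assignment([1, 2, 3, 4], scope="within_country")
        b = make_assignment([1, 2, 3, 4], scope="multinational")
        with pytest.raises(ValueError, match="specs"):
            cross_tabulate(a, b)

    def test_districts_missing_from_one_side_are_excluded(self):
        a = make_assignment([1, 2, 3, 4, 4])
        b = make_assignment([1, 2, 3, 4], indicator="stunting")
        assert cross_tabulate(a, b).n_districts == 4


class TestPctHighOverlap:
    def test_identity_and_disjoint_extremes(self):
        a = make_assignment([1, 2, 3, 4])
        assert pct_high_overlap(a, make_assignment([1, 2, 3, 4], "s")) == 100.0
        assert pct_high_overlap(a, make_assignment([4, 3, 2, 1], "s")) == 0.0

    def test_both_denominators_on_constructed_fixture(self):
        # 10 districts: 3 ref-high, 2 of them comp-high, 4 high for either
        ref = make_assignment([4, 4, 4, 1, 1, 1, 2, 2, 3, 3])
        comp = make_assignment([4, 4, 1, 4, 1, 1, 2, 2, 3, 3], "s")
        assert pct_high_overlap(ref, comp, "ref_high") == pytest.approx(200 / 3)
        assert pct_high_overlap(ref, comp, "either_high") == pytest.approx(50.0)

    def test_empty_denominator_returns_nan(self, caplog):
        ref = make_assignment([1, 1, 2, 3])  # nobody in bin 4
        comp = make_assignment([1, 2, 3, 4], "s")
        with caplog.at_level("WARNING"):
            assert np.isnan(pct_high_overlap(ref, comp, "ref_high"))


class TestMultiIndicatorCounts:
    def _assignments(self):
        bins = {
            "no_dtp": [4, 1, 1, 2],
            "stunting": [4, 4, 1, 3],
            "lf": [4, 4, 1, 1],
        }
        return [make_assignment(b, indicator=k) for k, b in bins.items()]

    def test_counts_and_reference_flag(self):
        out = count_high_indicators(self._assignments(), ref="no_dtp")
        lut = out.set_index("district_id")
        assert lut.at["D1", "n_high"] == 3 and lut.at["D1", "ref_in_high"]
        assert lut.at["D2", "n_high"] == 2 and not lut.at["D2", "ref_in_high"]
        assert lut.at["D3", "n_high"] == 0 and not lut.at["D3", "ref_in_high"]

    def test_proportion_high_for_any(self):
        out = count_high_indicators(self._assignments(), ref="no_dtp")
        # D1 and D2 have n_high >= 1 out of 4 districts
        assert proportion_high_for_any(out) == pytest.approx(50.0)

    def test_all_or_none_extremes(self):
        none = pd.DataFrame(
            {"district_id": ["a", "b"], "country_id": "C", "n_high": [0, 0]}
        )
        assert proportion_high_for_any(none) == 0.0
        allh = none.assign(n_high=[2, 1])
        assert proportion_high_for_any(allh) == 100.0
        with pytest.raises(ValueError):
            proportion_high_for_any(none.iloc[:0])

    def test_five_of_eight_fraction(self):
        df = pd.DataFrame(
            {
                "district_id": list("abcdefgh"),
                "country_id": "C",
                "n_high": [1, 2, 3, 0, 0, 1, 0, 4],
            }
        )
        assert proportion_high_for_any(df) == pytest.approx(62.5)


class TestTargetingCurve:
    def test_proportional_counts_lie_on_diagonal(self):
        ref = pd.Series([50.0, 30, 20], index=["a", "b", "c"])
        curve = build_targeting_curve(ref, 3.7 * ref)
        np.testing.assert_allclose(curve.x, curve.y, atol=1e-15)
        assert curve.auc == pytest.approx(0.5, abs=1e-12)

    def test_hand_cumulative_sums_after_descending_sort(self):
        ref = pd.Series([50.0, 30, 20], index=["a", "b", "c"])
        comp = pd.Series([20.0, 30, 50], index=["a", "b", "c"])
        curve = build_targeting_curve(ref, comp)
        np.testing.assert_allclose(curve.x, [0, 0.5, 0.8, 1.0], atol=1e-12)
        np.testing.assert_allclose(curve.y, [0, 0.2, 0.5, 1.0], atol=1e-12)
        assert curve.auc == pytest.approx(0.305, abs=1e-12)

    def test_concentrated_comparator_reaches_one_immediately(self):
        ref = pd.Series([50.0, 30, 20], index=["a", "b", "c"])
        comp = pd.Series([99.0, 0, 0], index=["a", "b", "c"])
        curve = build_targeting_curve(ref, comp)
        assert curve.y[1] == pytest.approx(1.0)

    def test_comparator_in_last_district_auc_tenth(self):
        # x spacing [0.5, 0.3, 0.2], y zero until the final segment
        curve = TargetingCurve(
            x=np.array([0, 0.5, 0.8, 1.0]), y=np.array([0, 0.0, 0.0, 1.0]), order=[]
        )
        assert compute_auc(curve) == pytest.approx(0.1, abs=1e-12)

    def test_rescaling_either_vector_leaves_auc_unchanged(self):
        rng = np.random.default_rng(8)
        ref = pd.Series(rng.uniform(0, 100, 20))
        comp = pd.Series(rng.uniform(0, 100, 20))
        base = build_targeting_curve(ref, comp).auc
        assert build_targeting_curve(7.3 * ref, comp).auc == pytest.approx(base, abs=1e-12)
        assert build_targeting_curve(ref, 0.002 * comp).auc == pytest.approx(base, abs=1e-12)

    def test_errors_on_invalid_counts(self):
        ref = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="non-negative"):
            build_targeting_curve(ref, pd.Series([-1.0, 2.0], index=["a", "b"]))
        with pytest.raises(ValueError, match="positive total"):
            build_targeting_curve(ref, pd.Series([0.0, 0.0], index=["a", "b"]))
        with pytest.raises(ValueError, match="non-decreasing"):
            compute_auc(
                TargetingCurve(x=np.array([0, 0.6, 0.5]), y=np.array([0, 0.5, 1]), order=[])
            )

    def test_missing_counts_dropped_complete_case(self, caplog):
        ref = pd.Series([5.0, 3, 2], index=["a", "b", "c"])
        comp = pd.Series([1.0, np.nan, 2], index=["a", "b", "c"])
        with caplog.at_level("WARNING"):
            curve = build_targeting_curve(ref, comp)
        assert len(curve.order) == 2

    @pytest.mark.parametrize("n", range(1, 7))
    def test_matches_brute_force_oracle(self, n):
        """Library AUC equals explicit sort + cumsum + trapezoid arithmetic."""
        rng = np.random.default_rng(100 + n)
        for _ in range(100):
            ref = rng.uniform(0, 50, n) + 0.01
            comp = rng.uniform(0, 50, n) + 0.01
            ids = [f"D{i}" for i in range(n)]
            got = build_targeting_curve(
                pd.Series(ref, index=ids), pd.Series(comp, index=ids)
            ).auc
            assert got == pytest.approx(brute_force_auc(ref, comp, ids), abs=1e-12)


class TestAucPanel:
    def _table(self):
        rng = np.random.default_rng(5)
        rows = []
        for country in ("A", "B"):
            for year in (2000, 2019):
                for d in range(6):
                    pop = rng.uniform(10, 100)
                    rows.append(
                        {
                            "district_id": f"{country}{d}",
                            "country_id": country,
                            "year": year,
                            "target_population": pop,
                            "no_dtp_count": rng.uniform(1, 50),
                            "stunting_count": rng.uniform(1, 50),
                        }
                    )
        return pd.DataFrame(rows)

    def test_identity_panel_is_all_half(self):
        table = self._table()
        table["stunting_count"] = 3 * table["no_dtp_count"]
        panel = auc_panel(table, "no_dtp", ["stunting"])
        assert len(panel) == 4  # 2 countries x 2 years
        np.testing.assert_allclose(panel["auc"], 0.5, atol=1e-12)

    def test_aligned_vs_reversed_countries_order_correctly(self):
        ref = np.array([50.0, 30, 20, 10, 5, 2])
        rows = []
        for country, comp in (("A", ref.copy()), ("B", ref[::-1].copy())):
            for d in range(6):
                rows.append(
                    {
                        "district_id": f"{country}{d}",
                        "country_id": country,
                        "no_dtp_count": ref[d],
                        "stunting_count": comp[d],
                    }
                )
        panel = auc_panel(pd.DataFrame(rows), "no_dtp", ["stunting"]).set_index(
            "country_id"
        )
        assert panel.at["A", "auc"] > panel.at["B", "auc"]

    def test_missing_indicator_cells_are_skipped(self):
        table = self._table()
        table.loc[table["country_id"] == "B", "stunting_count"] = np.nan
        panel = auc_panel(table, "no_dtp", ["stunting", "lf"])
        assert set(panel["country_id"]) == {"A"}
        assert set(panel["indicator"]) == {"stunting"}

    def test_year2_proportional_gives_half_year1_matches_single(self):
        table = self._table()
        y2 = table["year"] == 2019
        table.loc[y2, "stunting_count"] = 2 * table.loc[y2, "no_dtp_count"]
        panel = auc_panel(table, "no_dtp", ["stunting"])
        p = panel.set_index(["country_id", "year"])
        assert p.at[("A", 2019), "auc"] == pytest.approx(0.5, abs=1e-12)
        single = auc_panel(
            table[(table["country_id"] == "A") & (table["year"] == 2000)],
            "no_dtp",
            ["stunting"],
        )
        assert p.at[("A", 2000), "auc"] == pytest.approx(single["auc"].iloc[0])
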