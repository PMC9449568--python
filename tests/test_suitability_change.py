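"""Suitability binning, area accounting, change categories and change rates."""

import numpy as np
import pandas as pd
import pytest

from ensdm.geodata_io import GridTransform, RasterGrid
from ensdm.suitability_change import (
    CHANGE_CODES,
    DEFAULT_SCHEME,
    AreaSummary,
    ClassificationScheme,
    area_summary,
    change_map,
    change_rate,
    change_rate_result,
    classify,
    scenario_report,
    total_suitable,
)

T = GridTransform(west=0.0, north=0.0, dx=0.5, dy=-0.5)


def grid(vals, mask=None):
    vals = np.asarray(vals, dtype=float)
    if mask is None:
        mask = np.zeros(vals.shape, bool)
    return RasterGrid(vals, T, nodata_mask=np.asarray(mask, bool))


class TestClassify:
    @pytest.mark.parametrize(
        "value,expected_class",
        [(0.0, 0), (0.1, 0), (0.25, 1), (0.3, 1), (0.5, 2), (0.74, 2), (0.75, 3), (1.0, 3)],
    )
    def test_bin_assignment(self, value, expected_class):
        out = classify(grid([[value]]))
        assert out.values[0, 0] == expected_class

    def test_nodata_propagates(self):
        out = classify(grid([[0.5, 0.5]], mask=[[True, False]]))
        assert out.nodata_mask[0, 0] and not out.nodata_mask[0, 1]

    def test_marginal_values_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            out = classify(grid([[-0.005, 1.005]]))
        assert out.values[0, 0] == 0 and out.values[0, 1] == 3

    def test_far_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            classify(grid([[1.5]]))

    def test_bad_scheme_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            ClassificationScheme(bins=(("a", 0.0, 0.5),))


class TestAreaSummary:
    def test_four_cell_counts(self):
        cls = grid([[0, 0], [1, 3]])
        summ = area_summary(cls)
        assert summ.percentages == {"not": 50.0, "low": 25.0, "moderate": 0.0, "high": 25.0}

    def test_single_class(self):
        summ = area_summary(grid([[2, 2], [2, 2]]))
        assert summ.percentages["moderate"] == 100.0

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(0)
        cls = grid(rng.integers(0, 4, size=(10, 10)).astype(float))
        summ = area_summary(cls)
        assert sum(summ.percentages.values()) == pytest.approx(100.0, abs=1e-9)

    def test_all_nodata_rejected(self):
        with pytest.raises(ValueError, match="no valid"):
            area_summary(grid([[0.0]], mask=[[True]]))

    def test_latitude_weighting_changes_weights(self):
        # two rows at different latitudes with different classes
        t = GridTransform(west=0.0, north=60.0, dx=1.0, dy=-30.0)
        cls = RasterGrid(np.array([[0.0], [1.0]]), t)
        plain = area_summary(cls)
        weighted = area_summary(cls, latitude_weighted=True)
        assert plain.percentages["not"] == 50.0
        # northern (higher-latitude) row has smaller cosine weight
        assert weighted.percentages["not"] < 50.0 < weighted.percentages["low"]


class TestTotalSuitable:
    def test_low_to_high_sum(self):
        summ = AreaSummary({"not": 80.97, "low": 15.46, "moderate": 3.32, "high": 0.25})
        assert total_suitable(summ) == pytest.approx(19.03)

    def test_complement_identity(self):
        rng = np.random.default_rng(1)
        cls = grid(rng.integers(0, 4, size=(8, 8)).astype(float))
        summ = area_summary(cls)
        assert total_suitable(summ) == pytest.approx(
            100.0 - summ.percentages["not"], abs=1e-9
        )

    def test_all_unsuitable_zero(self):
        summ = area_summary(grid(np.zeros((3, 3))))
        assert total_suitable(summ) == 0.0


class TestChangeMap:
    def test_identical_inputs_only_stable(self):
        rng = np.random.default_rng(2)
        cls = grid(rng.integers(0, 4, size=(6, 6)).astype(float))
        cm = change_map(cls, cls)
        assert cm.counts["gain"] == 0 and cm.counts["loss"] == 0
        assert cm.counts["stable_suitable"] + cm.counts["stable_unsuitable"] == 36

    def test_total_loss(self):
        cur = grid(np.full((3, 3), 2.0))
        fut = grid(np.zeros((3, 3)))
        cm = change_map(cur, fut)
        assert cm.counts["loss"] == 9

    def test_category_counts_match_percell_oracle(self):
        rng = np.random.default_rng(3)
        cur = grid(rng.integers(0, 4, size=(12, 12)).astype(float))
        fut = grid(rng.integers(0, 4, size=(12, 12)).astype(float))
        cm = change_map(cur, fut, suitable_floor="low")
        # exhaustive truth table per cell
        expect = {k: 0 for k in CHANGE_CODES}
        for i in range(12):
            for j in range(12):
                c = cur.values[i, j] >= 1
                f = fut.values[i, j] >= 1
                key = {(False, False): "stable_unsuitable", (False, True): "gain",
                       (True, True): "stable_suitable", (True, False): "loss"}[(c, f)]
                expect[key] += 1
        assert cm.counts == expect

    def test_overlay_identities(self):
        rng = np.random.default_rng(4)
        cur = grid(rng.integers(0, 4, size=(15, 15)).astype(float))
        fut = grid(rng.integers(0, 4, size=(15, 15)).astype(float))
        cm = change_map(cur, fut)
        fut_suit = int((fut.values >= 1).sum())
        cur_suit = int((cur.values >= 1).sum())
        assert cm.counts["gain"] + cm.counts["stable_suitable"] == fut_suit
        assert cm.counts["loss"] + cm.counts["stable_suitable"] == cur_suit
        assert sum(cm.counts.values()) == 225

    def test_mask_union(self):
        cur = grid(np.ones((2, 2)), mask=[[True, False], [False, False]])
        fut = grid(np.ones((2, 2)), mask=[[False, False], [False, True]])
        cm = change_map(cur, fut)
        assert cm.raster.nodata_mask.sum() == 2

    def test_registration_mismatch_rejected(self):
        cur = grid(np.ones((2, 2)))
        other_t = GridTransform(west=1.0, north=0.0, dx=0.5, dy=-0.5)
        fut = RasterGrid(np.ones((2, 2)), other_t)
        with pytest.raises(ValueError, match="co-registered"):
            change_map(cur, fut)


class TestChangeRate:
    def test_equal_areas_zero(self):
        assert change_rate(40.0, 40.0) == 0.0

    def test_sign_conventions(self):
        assert change_rate(10.0, 15.0) == pytest.approx(50.0)
        assert change_rate(20.0, 10.0) == pytest.approx(-50.0)

    def test_zero_current_area_undefined(self):
        with pytest.raises(ZeroDivisionError):
            change_rate(0.0, 5.0)

    def test_antisymmetry_scaling(self):
        # AC(a->b) and AC(b->a) relate through the a/b ratio
        a, b = 30.0, 45.0
        assert change_rate(a, b) == pytest.approx(-change_rate(b, a) * b / a)

    def test_result_includes_overlap(self):
        cur = classify(grid([[0.1, 0.6], [0.6, 0.6]]))
        fut = classify(grid([[0.6, 0.6], [0.1, 0.6]]))
        cm = change_map(cur, fut)
        res = change_rate_result(area_summary(cur), area_summary(fut), cm)
        assert res.Ac == 75.0 and res.Af == 75.0 and res.AC == 0.0
        assert res.Acf == 50.0  # two cells suitable in both periods


class TestScenarioReport:
    def test_future_equal_current_all_zero(self):
        cls = classify(grid(np.random.default_rng(5).random((6, 6))))
        cur = area_summary(cls)
        fut = area_summary(cls, ("2050", "x"))
        areas, rates = scenario_report(cur, {("2050", "x"): fut})
        assert np.allclose(rates.to_numpy(), 0.0)

    def test_shapes(self):
        rng = np.random.default_rng(6)
        cur = area_summary(classify(grid(rng.random((6, 6)))))
        futs = {
            ("2050", "a"): area_summary(classify(grid(rng.random((6, 6)))), ("2050", "a")),
            ("2070", "b"): area_summary(classify(grid(rng.random((6, 6)))), ("2070", "b")),
        }
        areas, rates = scenario_report(cur, futs)
        assert areas.shape == (3, 4) and rates.shape == (2, 4)
        assert list(areas.columns) == DEFAULT_SCHEME.labels

    def test_rates_consistent_with_change_rate(self):
        rng = np.random.default_rng(7)
        cur = area_summary(classify(grid(rng.random((8, 8)))))
        fut = area_summary(classify(grid(rng.random((8, 8)))), ("2050", "a"))
        _, rates = scenario_report(cur, {("2050", "a"): fut})
        for label in DEFAULT_SCHEME.labels:
            ac = cur.percentages[label]
            if ac:
                assert rates.loc[("2050", "a"), label] == pytest.approx(
                    change_rate(ac, fut.percentages[label])
                )
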