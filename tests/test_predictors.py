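"""Feature extraction and the two-stage collinearity screen."""

import numpy as np
import pandas as pd
import pytest

from ensdm.geodata_io import OccurrenceSet
from ensdm.predictors import (
    FeatureTable,
    extract_features,
    pearson_screen,
    screen_predictors,
    vif,
    vifstep,
)


def brute_force_vif(X: pd.DataFrame) -> pd.Series:
    """Independent oracle: normal-equations least squares per column."""
    out = {}
    A = X.to_numpy(float)
    n = A.shape[0]
    for j, name in enumerate(X.columns):
        y = A[:, j]
        D = np.column_stack([np.ones(n), np.delete(A, j, axis=1)])
        beta = np.linalg.solve(D.T @ D, D.T @ y)
        resid = y - D @ beta
        r2 = 1.0 - (resid @ resid) / ((y - y.mean()) @ (y - y.mean()))
        out[name] = 1.0 / (1.0 - r2)
    return pd.Series(out)


class TestExtractFeatures:
    def test_constant_layer(self, small_stack, points_on):
        table = extract_features(small_stack, points_on([(0, 0), (3, 4)]))
        assert (table.features["b"] == 1.0).all()

    def test_counting_grid_lookup(self, small_stack, points_on):
        # layer "a" holds value 5*row + col
        table = extract_features(small_stack, points_on([(2, 3), (4, 0)]))
        assert table.features["a"].tolist() == [13.0, 20.0]

    def test_point_outside_extent(self, small_stack):
        occ = OccurrenceSet.from_arrays([100.0], [50.0])
        with pytest.raises(ValueError, match="point 0"):
            extract_features(small_stack, occ)

    def test_row_order_preserved(self, small_stack, points_on):
        table = extract_features(small_stack, points_on([(4, 4), (0, 0)]))
        assert table.features["a"].tolist() == [24.0, 0.0]


class TestPearsonScreen:
    def test_identical_columns_one_dropped(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        X = pd.DataFrame({"c1": x, "c2": x.copy()})
        retained, dropped = pearson_screen(X)
        assert len(retained) == 1
        assert len(dropped) == 1
        assert dropped[0][2] == pytest.approx(1.0)

    def test_independent_noise_none_dropped(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(500, 5)), columns=list("abcde"))
        assert np.abs(np.triu(X.corr().to_numpy(), 1)).max() < 0.7  # sanity
        retained, dropped = pearson_screen(X)
        assert retained == list("abcde") and dropped == []

    def test_near_duplicate_pair_breaks_correctly(self):
        rng = np.random.default_rng(2)
        c1 = rng.normal(size=300)
        c2 = rng.normal(size=300)
        c3 = c1 + rng.normal(scale=1e-3, size=300)
        X = pd.DataFrame({"c1": c1, "c2": c2, "c3": c3})
        retained, dropped = pearson_screen(X)
        assert "c2" in retained
        assert sorted(retained + [d[0] for d in dropped]) == ["c1", "c2", "c3"]
        assert len(dropped) == 1 and dropped[0][0] in ("c1", "c3")

    def test_retained_pairs_below_threshold(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(400, 3))
        X = pd.DataFrame(
            {
                "a": base[:, 0],
                "b": 0.9 * base[:, 0] + 0.1 * base[:, 1],
                "c": base[:, 1],
                "d": 0.95 * base[:, 1] + 0.05 * base[:, 2],
            }
        )
        retained, _ = pearson_screen(X, threshold=0.7)
        corr = X[retained].corr().abs().to_numpy()
        assert np.triu(corr, 1).max() <= 0.7

    def test_zero_variance_column_retained(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"a": rng.normal(size=50), "k": np.ones(50)})
        retained, dropped = pearson_screen(X)
        assert "k" in retained and dropped == []


class TestVIF:
    def test_orthogonal_columns_unit_vif(self):
        # centre before orthogonalising: the auxiliary regressions include an
        # intercept, so VIF = 1 exactly only for mutually orthogonal
        # *centred* columns
        raw = np.random.default_rng(5).normal(size=(50, 3))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        X = pd.DataFrame(q, columns=["a", "b", "c"])
        v = vif(X)
        assert np.allclose(v.to_numpy(), 1.0, atol=1e-9)

    def test_duplicate_column_capped(self):
        x = np.random.default_rng(6).normal(size=40)
        v = vif(pd.DataFrame({"a": x, "b": x.copy()}))
        assert (v > 1e10).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(120, 3))
        X = pd.DataFrame(
            {
                "a": base[:, 0],
                "b": base[:, 1] + 0.5 * base[:, 0],
                "c": base[:, 2] + 0.3 * base[:, 1],
            }
        )
        v = vif(X)
        expected = brute_force_vif(X)
        pd.testing.assert_series_equal(v, expected, rtol=1e-8)


class TestVifstep:
    def test_identity_below_threshold(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        report = vifstep(X)
        assert report.retained == list("abcd")
        assert report.dropped_by_vif == []

    def test_duplicate_dependency_broken(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=200)
        X = pd.DataFrame({"a": x, "b": rng.normal(size=200), "a2": x + rng.normal(scale=1e-6, size=200)})
        report = vifstep(X)
        assert len(report.dropped_by_vif) == 1
        assert report.dropped_by_vif[0][0] in ("a", "a2")
        assert vif(X[report.retained]).max() <= 10.0

    def test_chained_collinearity_resolved(self):
        rng = np.random.default_rng(9)
        z = rng.normal(size=(300, 2))
        X = pd.DataFrame(
            {
                "a": z[:, 0],
                "b": z[:, 0] + 0.05 * rng.normal(size=300),
                "c": z[:, 0] + z[:, 1],
                "d": z[:, 1] + 0.05 * rng.normal(size=300),
                "e": rng.normal(size=300),
            }
        )
        report = vifstep(X, vif_threshold=10.0)
        assert (vif(X[report.retained]) <= 10.0).all()  # oracle recheck

    def test_single_column_identity(self):
        X = pd.DataFrame({"a": np.arange(10.0)})
        report = vifstep(X)
        assert report.retained == ["a"] and report.dropped_by_vif == []


class TestFullScreen:
    def test_post_screen_guarantees(self):
        """After both stages no retained pair or VIF violates its threshold."""
        rng = np.random.default_rng(10)
        base = rng.normal(size=(400, 4))
        X = pd.DataFrame(
            {
                "s1": base[:, 0],
                "s2": base[:, 1],
                "dup": base[:, 0] + 0.1 * rng.normal(size=400),
                "mix": base[:, 1] + base[:, 2],
                "n1": base[:, 2],
                "n2": base[:, 3],
            }
        )
        table = FeatureTable(X, rng.integers(0, 2, size=400))
        report = screen_predictors(table)
        kept = X[report.retained]
        assert np.triu(kept.corr().abs().to_numpy(), 1).max() <= 0.7
        assert (vif(kept) <= 10.0).all()
        assert sorted(report.retained + report.dropped) == sorted(X.columns)

    def test_deterministic_given_column_order(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(size=(300, 5)), columns=list("abcde"))
        X["f"] = X["a"] * 0.95 + 0.05 * rng.normal(size=300)
        t = FeatureTable(X, rng.integers(0, 2, size=300))
        r1 = screen_predictors(t)
        r2 = screen_predictors(t)
        assert r1.retained == r2.retained
        assert r1.dropped_by_correlation == r2.dropped_by_correlation
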