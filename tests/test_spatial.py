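"""Variogram estimation, ordinary kriging, regional aggregation, mapping."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

import cdbiorisk as cb
from cdbiorisk.spatial import empirical_variogram


@pytest.fixture(scope="module")
def scattered_field():
    rng = np.random.default_rng(3)
    pts = rng.uniform(0, 10, (25, 2))
    vals = np.sin(pts[:, 0] / 2.5) + np.cos(pts[:, 1] / 3.0) \
        + 0.05 * rng.normal(size=25)
    return pts, vals


def dense_ok_solve(points, values, vario, targets):
    """Brute-force oracle: assemble and solve the full OK system directly."""
    n = len(points)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = vario(cdist(points, points))
    A[n, :n] = A[:n, n] = 1.0
    out = np.empty(len(targets))
    for t, tg in enumerate(targets):
        b = np.append(vario(cdist(points, tg[None, :])).ravel(), 1.0)
        lam = np.linalg.solve(A, b)
        out[t] = lam[:n] @ values
    return out


class TestVariogram:
    def test_constant_values_give_zero_semivariance(self):
        pts = np.random.default_rng(0).uniform(0, 5, (15, 2))
        emp = empirical_variogram(pts, np.full(15, 3.0))
        assert (emp["gamma"] == 0.0).all()
        with pytest.warns(UserWarning, match="constant"):
            v = cb.fit_variogram(pts, np.full(15, 3.0))
        assert v.nugget == 0.0 and v.partial_sill == 0.0

    def test_two_point_semivariance(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0]])
        emp = empirical_variogram(pts, np.array([0.0, 2.0]), n_lags=1)
        assert emp["gamma"].iloc[0] == pytest.approx(2.0)  # (0-2)^2 / 2

    def test_sill_approximates_field_variance(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 50, (400, 2))
        vals = rng.normal(0, 2.0, 400)  # stationary, uncorrelated
        v = cb.fit_variogram(pts, vals, n_lags=15)
        assert v.sill == pytest.approx(np.var(vals), rel=0.2)

    def test_monotone_nondecreasing_families(self):
        h = np.linspace(1e-9, 30, 200)
        for fam in ("spherical", "exponential", "gaussian"):
            v = cb.Variogram(fam, nugget=0.1, partial_sill=1.0, range_=10.0)
            g = v(h)
            assert np.all(np.diff(g) >= -1e-12)
            assert g[0] == pytest.approx(0.1, abs=1e-3)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            cb.Variogram("spherical", nugget=-1.0)
        with pytest.raises(ValueError):
            cb.Variogram("cubic")


class TestOrdinaryKriging:
    def test_exact_at_data_with_zero_nugget(self, scattered_field):
        pts, vals = scattered_field
        v = cb.Variogram("spherical", 0.0, 1.0, 8.0)
        pred = cb.ordinary_kriging(pts, vals, v, pts)
        np.testing.assert_allclose(pred, vals, atol=1e-10)

    def test_constant_data_predicts_constant(self):
        pts = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1], [0.5, 0.5]])
        v = cb.Variogram("exponential", 0.1, 1.0, 2.0)
        pred = cb.ordinary_kriging(pts, np.full(5, 4.2), v,
                                   np.array([[0.3, 0.7], [2.0, 2.0]]))
        np.testing.assert_allclose(pred, 4.2, atol=1e-10)

    def test_matches_dense_direct_solve(self, scattered_field):
        pts, vals = scattered_field
        pts, vals = pts[:20], vals[:20]
        v = cb.fit_variogram(pts, vals, n_lags=8)
        targets = np.random.default_rng(1).uniform(0, 10, (30, 2))
        pred = cb.ordinary_kriging(pts, vals, v, targets)
        oracle = dense_ok_solve(pts, vals, v, targets)
        np.testing.assert_allclose(pred, oracle, atol=1e-8)

    def test_weights_sum_to_one(self, scattered_field):
        from cdbiorisk.spatial import _solve_ok

        pts, vals = scattered_field
        v = cb.Variogram("spherical", 0.05, 1.0, 6.0)
        n = len(pts)
        A = np.zeros((n + 1, n + 1))
        A[:n, :n] = v(cdist(pts, pts))
        A[n, :n] = A[:n, n] = 1.0
        targets = np.random.default_rng(2).uniform(0, 10, (40, 2))
        B = np.vstack([v(cdist(pts, targets)), np.ones(40)])
        lam = np.linalg.solve(A, B)
        np.testing.assert_allclose(lam[:n].sum(axis=0), 1.0, atol=1e-10)

    def test_duplicate_points_deduped_with_warning(self, scattered_field):
        pts, vals = scattered_field
        pts2 = np.vstack([pts, pts[0]])
        vals2 = np.append(vals, vals[0] + 1.0)
        v = cb.Variogram("spherical", 0.0, 1.0, 8.0)
        with pytest.warns(UserWarning, match="duplicate"):
            pred = cb.ordinary_kriging(pts2, vals2, v, pts[1:2])
        assert np.isfinite(pred).all()

    def test_collinear_points_rejected(self):
        pts = np.array([[0.0, 0], [1, 0], [2, 0]])
        v = cb.Variogram("spherical", 0.0, 1.0, 2.0)
        with pytest.raises(ValueError, match="collinear"):
            cb.ordinary_kriging(pts, [1.0, 2, 3], v, np.array([[0.5, 0.5]]))

    def test_max_neighbors_close_to_full_solve(self, scattered_field):
        pts, vals = scattered_field
        v = cb.Variogram("spherical", 0.0, 1.0, 8.0)
        targets = np.random.default_rng(4).uniform(2, 8, (10, 2))
        full = cb.ordinary_kriging(pts, vals, v, targets)
        near = cb.ordinary_kriging(pts, vals, v, targets, max_neighbors=15)
        assert np.corrcoef(full, near)[0, 1] > 0.98


class TestRegionalGeometricMean:
    def test_textbook_cases(self):
        out = cb.regional_geometric_mean([1.0, 100.0, 2, 4, 8],
                                         ["a", "a", "b", "b", "b"])
        gm = dict(zip(out["region"], out["geometric_mean"]))
        assert gm["a"] == pytest.approx(10.0)
        assert gm["b"] == pytest.approx(4.0)

    def test_constant_region(self):
        out = cb.regional_geometric_mean([5.0, 5.0, 5.0], ["r"] * 3)
        assert out["geometric_mean"].iloc[0] == pytest.approx(5.0)
        assert out["cv_percent"].iloc[0] == pytest.approx(0.0)

    def test_nonpositive_rejected_naming_row(self):
        with pytest.raises(ValueError, match="row 1"):
            cb.regional_geometric_mean([1.0, 0.0, 2.0], ["a", "a", "b"])


class TestNationalMap:
    def test_uniform_grid_single_region_gives_uniform_map(self, forest126):
        grid = cb.generate_property_grid(8, 8, seed=0, constant=True,
                                         n_region_bands=1)
        regional_cd = pd.DataFrame({"region": ["north"],
                                    "geometric_mean": [1.5]})
        out, summaries = cb.map_national_bioaccessibility(forest126, grid,
                                                          regional_cd)
        pct = out.properties["ba_percent"]
        assert np.ptp(pct) == pytest.approx(0.0)
        assert len(summaries) == 1

    def test_percent_bounds_and_nodata_propagation(self, forest126):
        grid = cb.generate_property_grid(10, 10, seed=2)
        grid.properties["ph"][0, 0] = np.nan
        regional_cd = pd.DataFrame({
            "region": ["north", "central", "south"],
            "geometric_mean": [2.0, 1.0, 3.0]})
        out, summaries = cb.map_national_bioaccessibility(forest126, grid,
                                                          regional_cd)
        pct = out.properties["ba_percent"]
        assert np.isnan(pct[0, 0])
        finite = pct[np.isfinite(pct)]
        assert np.all(finite > 0) and np.all(finite <= 100)
        assert set(summaries["region"]) == {"north", "central", "south"}

    def test_missing_region_cd_rejected(self, forest126):
        grid = cb.generate_property_grid(6, 6, seed=1)
        with pytest.raises(ValueError, match="region"):
            cb.map_national_bioaccessibility(
                forest126, grid,
                pd.DataFrame({"region": ["north"], "geometric_mean": [1.0]}))


class TestAsciiGridRoundtrip:
    def test_roundtrip_preserves_values_and_georeference(self, tmp_path):
        g = cb.generate_property_grid(7, 5, seed=0)
        g.properties["ph"][2, 3] = np.nan
        p = tmp_path / "ph.asc"
        cb.write_ascii_grid(p, g, "ph")
        back = cb.read_ascii_grid(p, "ph")
        assert (back.nx, back.ny) == (7, 5)
        assert back.origin == g.origin
        np.testing.assert_allclose(back.properties["ph"], g.properties["ph"],
                                   equal_nan=True)
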