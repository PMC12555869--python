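import numpy as np
import pandas as pd
import pytest

from bioscatter.gam import RandomIntercept, Smooth, Smooth2D
from bioscatter.geometry import RadarSite, build_cvp_lattice
from bioscatter.raster import Raster
from bioscatter.simulate import generate_covariate_rasters, simulate_model_table
from bioscatter.trend import (
    ModelSpec,
    annual_trend,
    assemble_model_table,
    default_candidate_ladder,
    estimate_rho,
    fit_trend_gam,
    morans_i_correlogram,
    predict_map,
    select_best_model,
)


class TestEstimateRho:
    def test_white_noise_near_zero(self, rng):
        assert abs(estimate_rho(rng.standard_normal(5000))) < 0.05

    def test_ar1_truth_recovered(self, rng):
        rho = 0.6
        eps = np.empty(5000)
        eps[0] = rng.normal()
        for t in range(1, 5000):
            eps[t] = rho * eps[t - 1] + rng.normal()
        assert 0.55 <= estimate_rho(eps) <= 0.65

    def test_scale_invariant(self, rng):
        e = rng.standard_normal(500).cumsum()
        assert estimate_rho(e) == pytest.approx(estimate_rho(10.0 * e))

    def test_pooled_across_series(self, rng):
        rho = 0.5
        chunks, labels = [], []
        for s in range(50):
            eps = np.empty(100)
            eps[0] = rng.normal()
            for t in range(1, 100):
                eps[t] = rho * eps[t - 1] + rng.normal()
            chunks.append(eps)
            labels.extend([s] * 100)
        est = estimate_rho(np.concatenate(chunks), pd.Series(labels))
        assert 0.4 <= est <= 0.6

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            estimate_rho(np.ones(100))


class TestMoransI:
    def test_iid_residuals_flat_correlogram(self, rng):
        xy = rng.uniform(0, 60, (500, 2))
        z = rng.standard_normal(500)
        res = morans_i_correlogram(z, xy, [0, 10, 20, 30], n_perm=199, seed=3)
        np.testing.assert_allclose(res.observed_i, res.expected_i, atol=0.05)
        assert (res.p_values > 0.05).all()

    def test_smooth_field_detected(self, rng):
        xy = rng.uniform(0, 60, (400, 2))
        z = np.sin(xy[:, 0] / 15) + np.cos(xy[:, 1] / 15) + 0.1 * rng.standard_normal(400)
        res = morans_i_correlogram(z, xy, [0, 10], n_perm=199, seed=3)
        assert res.observed_i[0] > 0.3
        assert res.p_values[0] <= 0.01

    def test_checkerboard_negative(self):
        g = np.arange(10)
        gx, gy = np.meshgrid(g, g)
        coords = np.column_stack([gx.ravel() * 1.0, gy.ravel() * 1.0])
        z = (((gx + gy) % 2) * 2 - 1).ravel().astype(float)
        res = morans_i_correlogram(z, coords, [0.5, 1.2], n_perm=99, seed=1)
        assert res.observed_i[0] == pytest.approx(-1.0)

    def test_empty_bin_flagged(self, rng):
        xy = rng.uniform(0, 10, (50, 2))
        res = morans_i_correlogram(rng.standard_normal(50), xy, [0, 5, 100, 200],
                                   n_perm=49, seed=0)
        assert np.isnan(res.observed_i[-1])
        assert res.n_pairs[-1] == 0

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError):
            morans_i_correlogram(np.ones(5), rng.uniform(0, 1, (5, 2)), [0, 1])


@pytest.fixture(scope="module")
def pieces():
    site = RadarSite("wsr-a")
    lattice = build_cvp_lattice(site)
    covs = generate_covariate_rasters(seed=4)
    est = []
    for day in ("2014-06-01", "2014-06-02"):
        for cell in lattice.retained()[:40]:
            est.append(
                {
                    "site_id": "wsr-a",
                    "grid_row": cell.grid_row,
                    "grid_col": cell.grid_col,
                    "date": day,
                    "window": 0,
                    "density_per_km3": 1e6 * (1 + cell.grid_row),
                }
            )
    return pd.DataFrame(est), covs, lattice


class TestAssembleModelTable:
    def test_row_bookkeeping(self, pieces):
        est, covs, lattice = pieces
        table = assemble_model_table(est, covs, lattice)
        assert len(table) == len(est)
        assert {"tmax", "alan", "urban", "x", "y", "year", "month", "cell",
                "radar", "response"} <= set(table.columns)

    def test_constant_raster_footprint_mean(self, pieces):
        est, covs, lattice = pieces
        covs = dict(covs)
        covs["tmax"] = Raster(np.full((60, 60), 17.5), -30, -30, 1.0)
        table = assemble_model_table(est, covs, lattice)
        assert (table.tmax == 17.5).all()

    def test_linear_gradient_footprint_mean_is_centre_value(self):
        site = RadarSite("wsr-b")
        lattice = build_cvp_lattice(site)
        x = np.linspace(-29.75, 29.75, 120)
        vals = np.tile(2.0 * x, (120, 1))  # linear in easting only
        cov = {"tmax": Raster(vals, -30, -30, 0.5)}
        est = pd.DataFrame(
            [{"site_id": "wsr-b", "grid_row": 5, "grid_col": 9, "date": "2014-06-01",
              "window": 0, "density_per_km3": 1.0}]
        )
        table = assemble_model_table(est, cov, lattice)
        centre = lattice.cell(5, 9).easting
        assert table.tmax.iloc[0] == pytest.approx(2.0 * centre, abs=0.02)

    def test_log_transform_recorded(self, pieces):
        est, covs, lattice = pieces
        table = assemble_model_table(est, covs, lattice, log_response=True)
        np.testing.assert_allclose(
            table.response, np.log10(table.density_per_km3 + 1.0)
        )


class TestModelSelection:
    def test_duplicate_candidates_stable_order(self, rng):
        table, _ = simulate_model_table(seed=3, n_cells=40, years=range(2014, 2018))
        spec = ModelSpec("a", [Smooth("year", k=4)])
        dup = ModelSpec("b", [Smooth("year", k=4)])
        out = select_best_model([spec, dup], table)
        assert out.aic.iloc[0] == pytest.approx(out.aic.iloc[1], rel=1e-9)
        assert list(out["index"]) == [0, 1]

    def test_true_structure_wins(self):
        # data carry a tmax effect: the candidate with s(tmax) must beat the
        # year-only model across seeded replicates
        wins = 0
        for seed in (1, 2, 3):
            table, _ = simulate_model_table(
                seed=seed, n_cells=60, years=range(2014, 2018),
                include_spatial=False, include_trend=False,
            )
            candidates = [
                ModelSpec("year_only", [Smooth("year", k=4)]),
                ModelSpec("with_tmax", [Smooth("year", k=4), Smooth("tmax"),
                                        Smooth("alan"), Smooth("urban")]),
            ]
            out = select_best_model(candidates, table)
            if out.name.iloc[0] == "with_tmax" and out.delta_aic.iloc[1] > 2:
                wins += 1
        assert wins == 3

    def test_nested_ladder_null_data_prefers_simple(self):
        # truly exchangeable noise: no effects, no cell heterogeneity, no AR(1)
        table, _ = simulate_model_table(
            seed=9, n_cells=60, years=range(2014, 2018), ar_rho=0.0, cell_re_sd=0.0,
            include_effects=False, include_spatial=False, include_trend=False,
        )
        candidates = [
            ModelSpec("simple", [Smooth("year", k=4)], select=True),
            ModelSpec("complex", [Smooth("year", k=4), Smooth("tmax"), Smooth("wind")],
                      select=True),
        ]
        out = select_best_model(candidates, table)
        simple_aic = float(out.loc[out.name == "simple", "aic"].iloc[0])
        assert simple_aic <= out.aic.min() + 2.0

    def test_failing_candidate_recorded(self):
        table, _ = simulate_model_table(seed=3, n_cells=30, years=range(2014, 2016))
        bad = ModelSpec("bad", [Smooth("nonexistent_covariate")])
        ok = ModelSpec("ok", [Smooth("year", k=4)])
        out = select_best_model([ok, bad], table)
        assert out.loc[out.name == "bad", "error"].notna().all()
        assert out.name.iloc[0] == "ok"

    def test_needs_two_candidates(self):
        table, _ = simulate_model_table(seed=3, n_cells=20, years=range(2014, 2016))
        with pytest.raises(ValueError):
            select_best_model([ModelSpec("only", [Smooth("year", k=4)])], table)

    def test_default_ladder_structure(self):
        table, _ = simulate_model_table(seed=3, n_cells=30, years=range(2014, 2018))
        ladder = default_candidate_ladder(table)
        assert len(ladder) == 7
        assert ladder[0].name == "m1_year" and len(ladder[0].terms) == 1
        # deviance explained is non-decreasing along the nested ladder
        fits = [fit_trend_gam(s, table) for s in ladder[:3]]
        devs = [f.deviance_explained_ for f in fits]
        assert devs[0] <= devs[1] + 1e-6 <= devs[2] + 2e-6


@pytest.fixture(scope="module")
def fitted():
    table, _ = simulate_model_table(seed=6, n_cells=80, years=range(2014, 2020))
    # the latitude-dependent trend needs a spatially varying year term:
    # a year smooth per radar (radars are latitude blocks)
    spec = ModelSpec(
        "m", [Smooth("year", k=4), Smooth("year", k=4, by="radar"),
              Smooth2D("x", "y", k=16), Smooth("tmax"),
              RandomIntercept("radar"), RandomIntercept("cell")],
    )
    return fit_trend_gam(spec, table), table


class TestPredictMap:
    def test_prediction_rasters_and_se(self, fitted):
        fit, table = fitted
        covs = generate_covariate_rasters(seed=8, extent_km=60, cell_size_km=5.0)
        maps = predict_map(fit, covs, years=[2014, 2019])
        assert set(maps) == {2014.0, 2019.0}
        for yr in maps:
            assert maps[yr]["prediction"].values.shape == (12, 12)
            assert np.nanmin(maps[yr]["se"].values) > 0

    def test_training_point_prediction_matches_fitted(self, fitted):
        fit, table = fitted
        np.testing.assert_allclose(fit.predict(table), fit.fitted_values_, rtol=1e-9)

    def test_annual_trend_and_change_map(self, fitted):
        fit, table = fitted
        annual, change = annual_trend(fit, table)
        assert len(annual) == table.year.nunique()
        assert {"cell", "x", "y", "change"} <= set(change.columns)
        # truth declines in the north, increases in the south
        north = change.loc[change.y > 10, "change"].mean()
        south = change.loc[change.y < -10, "change"].mean()
        assert north < 0 < south

    def test_constant_truth_flat_change_map(self):
        table, _ = simulate_model_table(
            seed=13, n_cells=60, years=range(2014, 2019),
            include_trend=False, noise_sd=0.05,
        )
        spec = ModelSpec("m", [Smooth("year", k=4), Smooth2D("x", "y", k=16),
                               Smooth("tmax"), Smooth("alan"), Smooth("urban")],
                         select=True)
        fit = fit_trend_gam(spec, table)
        _, change = annual_trend(fit, table)
        assert np.abs(change.change).max() < 0.1
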