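"""Generator determinism, contracts, and ground-truth structure tests."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point

from thermoplast.heterogeneity import (
    average_roughness,
    extract_square_buffer,
    shannon_diversity,
)
from thermoplast.synthetic_data import (
    SyntheticConfig,
    generate_landscape,
    generate_range_and_climate,
    place_populations,
    simulate_driver_table,
    simulate_trait_data,
)


def sites_frame(rng, n, rp=None, eh=None):
    return pd.DataFrame({
        "population": [f"p{i}" for i in range(n)],
        "rp": rng.standard_normal(n) if rp is None else rp,
        "eh": rng.standard_normal(n) if eh is None else eh,
    })


class TestConfigValidation:
    @pytest.mark.parametrize(
        "bad",
        [
            dict(n_replicates=0),
            dict(sigma_slope=-0.1),
            dict(slope_intercept_corr=1.5),
            dict(treatments_C=(20.0, 20.0)),
            dict(heterogeneity_knob=1.2),
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            SyntheticConfig(**bad).validate()


class TestRangeAndClimate:
    def test_shapes_and_no_missing(self):
        cfg = SyntheticConfig(n_climate_vars=5, n_range_cells_target=1000)
        rm, clim = generate_range_and_climate(cfg, np.random.default_rng(0))
        assert len(rm.cells) >= 200
        bio = clim[[f"bio{j}" for j in range(1, 6)]]
        assert bio.shape[1] == 5
        assert not bio.isna().any().any()
        assert rm.polygon.is_simple
        # every cell centre inside the boundary
        poly = rm.polygon
        assert all(poly.contains(Point(x, y))
                   for x, y in zip(rm.cells["x"], rm.cells["y"]))

    def test_zero_noise_climate_is_function_of_latitude(self):
        cfg = SyntheticConfig(climate_noise_sd=0.0)
        _, clim = generate_range_and_climate(cfg, np.random.default_rng(1))
        for j in range(1, cfg.n_climate_vars + 1):
            grouped = clim.groupby("y")[f"bio{j}"].nunique()
            assert (grouped == 1).all()

    def test_determinism(self):
        cfg = SyntheticConfig(rng_seed=9)
        a = generate_range_and_climate(cfg, np.random.default_rng(9))
        b = generate_range_and_climate(cfg, np.random.default_rng(9))
        np.testing.assert_array_equal(a[0].boundary, b[0].boundary)
        pd.testing.assert_frame_equal(a[1], b[1])


class TestPlacePopulations:
    def test_two_distinct_interior_sites(self):
        cfg = SyntheticConfig()
        rm, _ = generate_range_and_climate(cfg, np.random.default_rng(2))
        sites = place_populations(rm, 2, np.random.default_rng(2))
        assert len(sites) == 2
        assert not sites.duplicated(subset=["x", "y"]).any()

    def test_circle_spans_distance_gradient(self):
        # disc of radius 100 km: near-edge and deep-core sites must appear
        from thermoplast.synthetic_data import RangeMap
        from shapely.geometry import Polygon

        th = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        boundary = np.column_stack([100 * np.cos(th), 100 * np.sin(th)])
        xs = np.arange(-99, 100, 4.0)
        gx, gy = np.meshgrid(xs, xs)
        inside = gx**2 + gy**2 < 95.0**2
        cells = pd.DataFrame({"cell_id": np.arange(inside.sum()),
                              "x": gx[inside], "y": gy[inside]})
        rm = RangeMap(boundary=boundary, cells=cells)
        sites = place_populations(rm, 50, np.random.default_rng(3))
        d = sites["boundary_distance_km"]
        assert d.min() < 10.0
        assert d.max() > 50.0

    def test_determinism_and_gradient_guarantee(self):
        cfg = SyntheticConfig()
        rm, _ = generate_range_and_climate(cfg, np.random.default_rng(4))
        s1 = place_populations(rm, 12, np.random.default_rng(7))
        s2 = place_populations(rm, 12, np.random.default_rng(7))
        pd.testing.assert_frame_equal(s1, s2)
        # spanning guarantee relative to interior-cell distances
        from shapely.geometry import Point
        ring = rm.polygon.exterior
        dcells = np.array([ring.distance(Point(x, y))
                           for x, y in zip(rm.cells["x"], rm.cells["y"])])
        qlo, qhi = np.quantile(dcells, [0.1, 0.9])
        assert s1["boundary_distance_km"].min() <= qlo
        assert s1["boundary_distance_km"].max() >= qhi

    def test_too_many_sites_raises(self):
        from thermoplast.synthetic_data import RangeMap

        rm = RangeMap(boundary=np.array([[0, 0], [1, 0], [0, 1]], float),
                      cells=pd.DataFrame({"cell_id": [0], "x": [0.3], "y": [0.3]}))
        with pytest.raises(ValueError, match="too small"):
            place_populations(rm, 5, np.random.default_rng(0))


class TestGenerateLandscape:
    def test_zero_knob_is_flat_single_class(self):
        cfg = SyntheticConfig(heterogeneity_knob=0.0)
        lc, dem = generate_landscape((0.0, 0.0), cfg, np.random.default_rng(0))
        buf_lc = extract_square_buffer(lc, (0.0, 0.0), 500.0)
        buf_dem = extract_square_buffer(dem, (0.0, 0.0), 500.0)
        assert shannon_diversity(buf_lc) == 0.0
        assert average_roughness(buf_dem) == 0.0

    def test_raster_covers_buffer(self):
        cfg = SyntheticConfig(raster_size=40)  # 400 m at 10 m: too small
        with pytest.raises(ValueError, match="buffer"):
            generate_landscape((0.0, 0.0), cfg, np.random.default_rng(0))

    def test_knob_monotone_in_expectation(self):
        """Monte-Carlo over 200 replicate rasters per knob level."""
        reps = 200
        means = {}
        for knob in (0.1, 1.0):
            cfg = SyntheticConfig(heterogeneity_knob=knob, raster_size=110)
            shdi, are = [], []
            for seed in range(reps):
                lc, dem = generate_landscape((0.0, 0.0), cfg,
                                             np.random.default_rng(seed))
                shdi.append(shannon_diversity(
                    extract_square_buffer(lc, (0.0, 0.0), 500.0)))
                are.append(average_roughness(
                    extract_square_buffer(dem, (0.0, 0.0), 500.0)))
            means[knob] = (np.mean(shdi), np.mean(are))
        assert means[1.0][0] > means[0.1][0]  # SHDI rises with the knob
        assert means[1.0][1] > means[0.1][1]  # ARE rises with the knob

    def test_determinism(self):
        cfg = SyntheticConfig()
        a = generate_landscape((0.0, 0.0), cfg, np.random.default_rng(11))
        b = generate_landscape((0.0, 0.0), cfg, np.random.default_rng(11))
        np.testing.assert_array_equal(a[0].values, b[0].values)
        np.testing.assert_array_equal(a[1].values, b[1].values)


class TestSimulateTraitData:
    def test_degenerate_config_gives_exact_slopes(self, rng):
        cfg = SyntheticConfig(sigma_intercept=0.0, sigma_slope=0.0,
                              sigma_replicate=0.0, sigma_resid=0.0,
                              fixed_slope=-0.6, n_individuals=2)
        sites = sites_frame(rng, 6)
        table, truth = simulate_trait_data(sites, cfg, rng)
        assert np.all(np.abs(truth.populations["true_slope"]) == 0.6)
        # per-population OLS slope on centred temperature recovers it exactly
        for popname, g in table.groupby("population"):
            tc = g["treatment_C"] - g["treatment_C"].mean()
            slope = np.polyfit(tc, g["value"], 1)[0]
            true = truth.populations.set_index("population").loc[popname,
                                                                 "true_slope"]
            assert slope == pytest.approx(true, abs=1e-9)

    def test_binomial_counts_bounded(self, rng):
        cfg = SyntheticConfig()
        table, _ = simulate_trait_data(sites_frame(rng, 8), cfg, rng,
                                       family="binomial")
        assert (table["n_germinated"] >= 0).all()
        assert (table["n_germinated"] <= table["n_viable"]).all()

    def test_true_slope_magnitude_linear_in_drivers(self, rng):
        # OLS of true |slope| on EH recovers gamma_eh within 3 SE
        cfg = SyntheticConfig(gamma_eh=0.5, sigma_slope=0.05, fixed_slope=-3.0,
                              n_individuals=1)
        sites = sites_frame(rng, 40)
        _, truth = simulate_trait_data(sites, cfg, rng)
        mag = np.abs(truth.populations["true_slope"])
        X = np.column_stack([np.ones(40), truth.populations["eh"]])
        beta, res = np.linalg.lstsq(X, mag, rcond=None)[:2]
        se = np.sqrt(res[0] / 38 * np.linalg.inv(X.T @ X)[1, 1])
        assert abs(beta[1] - 0.5) < 3 * se

    def test_expected_magnitude_linear_in_all_drivers(self, rng):
        cfg = SyntheticConfig(gamma_rp=0.3, gamma_eh=0.5, gamma_int=-0.2,
                              sigma_slope=0.02, fixed_slope=-5.0,
                              n_individuals=1)
        sites = sites_frame(rng, 250)
        _, truth = simulate_trait_data(sites, cfg, rng)
        t = truth.populations
        X = np.column_stack([np.ones(len(t)), t["rp"], t["eh"], t["rp"] * t["eh"]])
        beta = np.linalg.lstsq(X, np.abs(t["true_slope"]), rcond=None)[0]
        np.testing.assert_allclose(beta, [5.0, 0.3, 0.5, -0.2], atol=0.02)

    def test_determinism(self, rng):
        cfg = SyntheticConfig()
        sites = sites_frame(np.random.default_rng(0), 6)
        a, _ = simulate_trait_data(sites, cfg, np.random.default_rng(42))
        b, _ = simulate_trait_data(sites, cfg, np.random.default_rng(42))
        pd.testing.assert_frame_equal(a, b)

    def test_negative_sigma_rejected(self, rng):
        cfg = SyntheticConfig(sigma_resid=-1.0)
        with pytest.raises(ValueError):
            simulate_trait_data(sites_frame(rng, 4), cfg, rng)


class TestSimulateDriverTable:
    def test_columns_and_floor(self, rng):
        df = simulate_driver_table(rng, n_populations=30, gamma_int=0.5)
        assert set(["DRE", "DCE", "SHDI", "PAR", "ARE",
                    "plasticity"]).issubset(df.columns)
        assert (df["plasticity"] >= 0).all()
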