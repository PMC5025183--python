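import numpy as np
import pytest
from scipy import stats

from firerisk import covariates as cov
from firerisk.raster import Grid, Layer, Stack
from firerisk.scenarios import DYNAMIC_VARIABLES
from firerisk.synthetic import (
    LandscapeConfig,
    generate_covariates,
    generate_landscape,
    make_scenario_fixture,
    sample_hotspots,
    true_probability,
)

SMALL = LandscapeConfig(n_rows=50, n_cols=50)


@pytest.fixture(scope="module")
def landscape():
    return generate_landscape(SMALL, seed=21)


class TestGeneration:
    def test_deterministic_per_seed(self, landscape):
        again = generate_landscape(SMALL, seed=21)
        for name in landscape.stack.names:
            assert np.array_equal(landscape.stack[name].values,
                                  again.stack[name].values), name
        assert np.array_equal(landscape.truth.probability.values,
                              again.truth.probability.values)

    def test_different_seed_differs(self, landscape):
        other = generate_landscape(SMALL, seed=22)
        assert not np.array_equal(landscape.stack["deforestation"].values,
                                  other.stack["deforestation"].values)

    def test_eight_covariates(self, landscape):
        assert landscape.stack.names == [
            "shrubland", "grassland", "deforestation", "roads", "settlements",
            "protected_areas", "temperature_anomaly", "mcwd_anomaly"]

    def test_fraction_layers_in_unit_interval(self, landscape):
        for name in ("shrubland", "grassland", "deforestation"):
            v = landscape.stack[name].valid_values
            assert v.min() >= 0.0 and v.max() <= 1.0

    def test_spec_shaped_wrapper(self):
        stack, climate, roads, settlements = generate_covariates(SMALL, seed=5)
        assert len(stack) == 8
        assert climate.years == SMALL.years
        assert len(roads.polylines) == SMALL.n_paved_roads + SMALL.n_unpaved_roads
        assert settlements.points.shape[0] == SMALL.n_settlements

    def test_dry_year_drier_and_warmer_than_wet(self):
        """Constructed contrast: dry-year MCWD anomaly more negative, warmer."""
        for seed in (1, 2, 3):
            ls = generate_landscape(SMALL, seed=seed)
            dry = ls.anomaly_layers["dry_year"]
            wet = ls.anomaly_layers["wet_year"]
            assert (dry["mcwd_anomaly"].values.mean()
                    < wet["mcwd_anomaly"].values.mean())
            assert (dry["temperature_anomaly"].values.mean()
                    > wet["temperature_anomaly"].values.mean())

    def test_degenerate_dims_rejected(self):
        with pytest.raises(ValueError):
            LandscapeConfig(n_rows=2, n_cols=50)


class TestFullLoopRecovery:
    """Derived stack layers must equal re-derivation via the covariate ops."""

    def test_deforestation_from_fine_map(self, landscape):
        redo = cov.aggregate_fraction(landscape.deforestation_fine,
                                      landscape.config.fine_factor)
        assert np.array_equal(redo.values,
                              landscape.stack["deforestation"].values)

    def test_landcover_fractions_from_fine_map(self, landscape):
        shrub = cov.landcover_fraction(landscape.landcover_fine, 1,
                                       landscape.config.fine_factor)
        grass = cov.landcover_fraction(landscape.landcover_fine, 2,
                                       landscape.config.fine_factor)
        assert np.array_equal(shrub.values, landscape.stack["shrubland"].values)
        assert np.array_equal(grass.values, landscape.stack["grassland"].values)

    def test_road_distance_from_roadset(self, landscape):
        redo = cov.distance_to_roads(landscape.roads, landscape.stack.grid)
        assert np.array_equal(redo.values, landscape.stack["roads"].values)

    def test_settlement_density_from_points(self, landscape):
        redo = cov.settlement_density(landscape.settlements, landscape.stack.grid,
                                      bandwidth=landscape.config.settlement_bandwidth)
        assert np.array_equal(redo.values, landscape.stack["settlements"].values)

    def test_climate_anomalies_from_series(self, landscape):
        cfg = landscape.config
        mcwd = {y: cov.compute_mcwd(landscape.climate, y)
                for y in landscape.climate.year_list}
        redo = cov.compute_anomaly(mcwd, cfg.dry_year)
        assert np.allclose(redo.values, landscape.stack["mcwd_anomaly"].values)


class TestTrueProbability:
    def make_stack(self):
        rng = np.random.default_rng(0)
        grid = Grid(10, 10)
        return Stack([Layer(grid=grid, name="x", values=rng.random((10, 10)))])

    def test_zero_weights_give_logistic_intercept(self):
        stack = self.make_stack()
        truth = true_probability(stack, {"x": 0.0}, intercept=-1.0)
        assert np.allclose(truth.probability.values, 1 / (1 + np.e))

    def test_weight_sign_flip_mirrors_correlation(self):
        stack = self.make_stack()
        x = stack["x"].values.ravel()
        pos = true_probability(stack, {"x": 1.5}, 0.0).probability.values.ravel()
        neg = true_probability(stack, {"x": -1.5}, 0.0).probability.values.ravel()
        assert np.corrcoef(x, pos)[0, 1] > 0
        assert np.corrcoef(x, neg)[0, 1] < 0

    def test_low_intercept_limit(self):
        stack = self.make_stack()
        truth = true_probability(stack, {"x": 1.0}, intercept=-30.0)
        assert truth.probability.values.max() < 1e-6

    def test_unknown_variable_rejected(self):
        stack = self.make_stack()
        with pytest.raises(KeyError):
            true_probability(stack, {"nope": 1.0}, 0.0)


class TestSampleHotspots:
    def test_concentrated_cell(self, landscape):
        vals = np.zeros(landscape.stack.grid.shape)
        vals[3, 4] = 1.0
        truth = landscape.truth.__class__(
            probability=Layer(grid=landscape.stack.grid, name="p", values=vals),
            weights={}, intercept=0.0)
        pres = sample_hotspots(truth, 50, seed=1)
        assert np.all(pres.rows == 3) and np.all(pres.cols == 4)

    def test_uniform_surface_uniform_cells(self):
        grid = Grid(10, 10)
        from firerisk.synthetic import GroundTruth
        truth = GroundTruth(
            probability=Layer(grid=grid, name="p", values=np.full((10, 10), 0.4)),
            weights={}, intercept=0.0)
        pres = sample_hotspots(truth, 100_000, seed=2)
        counts = np.bincount(pres.rows * 10 + pres.cols, minlength=100)
        chi2 = ((counts - 1000.0) ** 2 / 1000.0).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=99)

    def test_default_months_concentrate_in_aug_sep(self, landscape):
        pres = sample_hotspots(landscape.truth, 10_000, seed=3)
        frac = np.isin(pres.months, (8, 9)).mean()
        assert frac == pytest.approx(0.83, abs=0.02)

    def test_zero_surface_rejected(self):
        grid = Grid(4, 4)
        from firerisk.synthetic import GroundTruth
        truth = GroundTruth(
            probability=Layer(grid=grid, name="p", values=np.zeros((4, 4))),
            weights={}, intercept=0.0)
        with pytest.raises(ValueError):
            sample_hotspots(truth, 10, seed=0)


class TestScenarioFixtures:
    def test_deforestation_ordering_built_in(self, landscape):
        specs = {m: make_scenario_fixture(landscape, m, "wet")
                 for m in ("A_like", "B_like", "C_like")}
        a = specs["A_like"].replacements["deforestation"].values
        b = specs["B_like"].replacements["deforestation"].values
        c = specs["C_like"].replacements["deforestation"].values
        assert np.all(b >= a - 1e-12)
        assert np.all(c >= b - 1e-12)

    def test_a_like_adds_protection(self, landscape):
        spec = make_scenario_fixture(landscape, "A_like", "wet")
        base_protected = (landscape.stack["protected_areas"].values > 0).sum()
        new_protected = (spec.replacements["protected_areas"].values > 0).sum()
        assert new_protected > base_protected

    def test_climate_swap_replaces_exactly_the_anomaly_pair(self, landscape):
        dry = make_scenario_fixture(landscape, "B_like", "dry")
        wet = make_scenario_fixture(landscape, "B_like", "wet")
        climate_vars = {"temperature_anomaly", "mcwd_anomaly"}
        assert climate_vars <= set(dry.replacements)
        # only the climate pair differs between the wet and dry variants
        for var in set(dry.replacements) - climate_vars:
            assert np.array_equal(dry.replacements[var].values,
                                  wet.replacements[var].values)
        for var in climate_vars:
            assert not np.array_equal(dry.replacements[var].values,
                                      wet.replacements[var].values)
        assert set(dry.replacements) <= DYNAMIC_VARIABLES

    def test_unknown_mode_rejected(self, landscape):
        with pytest.raises(ValueError):
            make_scenario_fixture(landscape, "D_like", "wet")
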