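import numpy as np
import pytest

from firerisk.impact import (
    AGBStack,
    agb_loss,
    classify_risk,
    high_risk_area,
    hotspot_monthly_histogram,
    zonal_stats,
)
from firerisk.maxent import PresenceSample
from firerisk.raster import Grid, GridMismatchError, Layer


def risk_layer(values, cell_size=1.0):
    values = np.asarray(values, dtype=float)
    grid = Grid(values.shape[0], values.shape[1], cell_size=cell_size)
    return Layer(grid=grid, name="risk", values=values, units="probability")


class TestClassifyRisk:
    def test_uniform_high(self):
        rc = classify_risk(risk_layer(np.full((10, 10), 0.6)))
        assert rc.areas_km2["high"] == 100.0
        assert rc.areas_km2["low"] == rc.areas_km2["moderate"] == 0.0

    def test_boundary_half_is_high(self):
        rc = classify_risk(risk_layer([[0.5]]))
        assert rc.counts["high"] == 1

    def test_boundary_quarter_is_moderate_and_one_is_extreme(self):
        rc = classify_risk(risk_layer([[0.25, 1.0]]))
        assert rc.counts["moderate"] == 1
        assert rc.counts["extreme"] == 1

    def test_partition_sums_to_total(self):
        rng = np.random.default_rng(0)
        rc = classify_risk(risk_layer(rng.random((25, 25)), cell_size=2.0))
        assert sum(rc.areas_km2.values()) == pytest.approx(rc.total_area_km2)
        assert rc.total_area_km2 == 25 * 25 * 4.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_risk(risk_layer([[1.2]]))


class TestHighRiskArea:
    def test_seven_cells(self):
        vals = np.zeros((3, 3))
        vals.ravel()[:7] = 0.8
        assert high_risk_area(risk_layer(vals)) == 7.0

    def test_threshold_one_gives_zero(self):
        assert high_risk_area(risk_layer(np.full((3, 3), 0.99)), 1.0) == 0.0

    def test_strictness_at_threshold(self):
        assert high_risk_area(risk_layer([[0.5]])) == 0.0

    def test_matches_class_areas_for_generic_layer(self):
        rng = np.random.default_rng(1)
        layer = risk_layer(rng.random((30, 30)))  # exact 0.5 has measure zero
        rc = classify_risk(layer)
        assert high_risk_area(layer) == pytest.approx(
            rc.areas_km2["high"] + rc.areas_km2["extreme"])


class TestAGBLoss:
    def agb(self, values, n=1):
        values = np.asarray(values, dtype=float)
        grid = Grid(values.shape[0], values.shape[1])
        return AGBStack([Layer(grid=grid, name=f"agb{i}", values=values,
                               units="Mg/ha") for i in range(n)])

    def test_alpha_one_means_no_loss(self):
        rep = agb_loss(risk_layer([[0.9]]), self.agb([[150.0]]),
                       alpha_low=1.0, alpha_high=1.0)
        assert rep.total_loss_tg == 0.0

    def test_hand_case_0002_tg(self):
        """1 km2 at p=0.8, 100 Mg/ha, alpha=0.8: 20 Mg/ha x 100 ha = 0.002 Tg."""
        rep = agb_loss(risk_layer([[0.8]]), self.agb([[100.0]]),
                       alpha_low=0.8, alpha_high=0.8)
        assert rep.total_loss_tg == pytest.approx(0.002)

    def test_printed_envelope_constants(self):
        rep = agb_loss(risk_layer([[0.8]]), self.agb([[100.0]]))
        assert rep.central_loss_factor == pytest.approx(0.195, abs=1e-3)
        assert rep.loss_factor_half_range == pytest.approx(0.096, abs=1e-3)

    def test_envelope_ordering(self):
        rng = np.random.default_rng(2)
        rep = agb_loss(risk_layer(rng.random((10, 10))),
                       self.agb(rng.uniform(0, 300, (10, 10))))
        assert rep.total_loss_low_tg <= rep.total_loss_tg <= rep.total_loss_high_tg

    def test_loss_monotone_in_alpha(self):
        risk = risk_layer([[0.9, 0.7], [0.6, 0.2]])
        agb = self.agb([[100.0, 50.0], [80.0, 200.0]])
        losses = [agb_loss(risk, agb, alpha_low=a, alpha_high=a).total_loss_tg
                  for a in (0.6, 0.7, 0.8, 0.9, 1.0)]
        assert all(a >= b for a, b in zip(losses, losses[1:]))

    def test_additive_over_cells(self):
        """Total equals the sum of single-cell losses."""
        vals = np.array([[0.9, 0.7], [0.6, 0.2]])
        agbs = np.array([[100.0, 50.0], [80.0, 200.0]])
        whole = agb_loss(risk_layer(vals), self.agb(agbs)).total_loss_tg
        parts = sum(
            agb_loss(risk_layer([[v]]), self.agb([[b]])).total_loss_tg
            for v, b in zip(vals.ravel(), agbs.ravel()))
        assert whole == pytest.approx(parts)

    def test_multi_dataset_mean(self):
        grid_vals = [[0.8]]
        stack = AGBStack([
            Layer(grid=Grid(1, 1), name="a", values=np.array([[90.0]])),
            Layer(grid=Grid(1, 1), name="b", values=np.array([[110.0]])),
        ])
        rep = agb_loss(risk_layer(grid_vals), stack,
                       alpha_low=0.8, alpha_high=0.8)
        assert rep.total_loss_tg == pytest.approx(0.002)  # mean AGB = 100

    def test_bad_alpha_rejected(self):
        with pytest.raises(ValueError):
            agb_loss(risk_layer([[0.5]]), self.agb([[10.0]]), alpha_low=0.0)
        with pytest.raises(ValueError):
            agb_loss(risk_layer([[0.5]]), self.agb([[10.0]]),
                     alpha_low=0.9, alpha_high=0.8)


class TestZonalStats:
    def zones(self, values, codes):
        values = np.asarray(values)
        grid = Grid(values.shape[0], values.shape[1])
        return Layer(grid=grid, name="zones", values=values,
                     kind="categorical", codes=codes)

    def test_uniform_risk(self):
        risk = risk_layer(np.full((4, 4), 0.3))
        zones = self.zones(np.arange(16).reshape(4, 4) % 3, (0, 1, 2))
        table = zonal_stats(risk, zones)
        assert np.allclose(table["mean_risk"], 0.3)
        assert np.allclose(table["std_risk"], 0.0)

    def test_two_cell_mean(self):
        risk = risk_layer([[0.2, 0.4]])
        zones = self.zones([[1, 1]], (1,))
        table = zonal_stats(risk, zones)
        assert table["mean_risk"].iloc[0] == pytest.approx(0.3)

    def test_areas_partition_total(self):
        rng = np.random.default_rng(3)
        risk = risk_layer(rng.random((20, 20)))
        zones = self.zones(rng.integers(0, 4, (20, 20)), (0, 1, 2, 3))
        table = zonal_stats(risk, zones)
        assert table["area_km2"].sum() == pytest.approx(400.0)

    def test_zonal_means_recompose_global_mean(self):
        rng = np.random.default_rng(4)
        risk = risk_layer(rng.random((20, 20)))
        zones = self.zones(rng.integers(0, 4, (20, 20)), (0, 1, 2, 3))
        table = zonal_stats(risk, zones)
        weighted = (table["mean_risk"] * table["count"]).sum() / table["count"].sum()
        assert weighted == pytest.approx(risk.valid_values.mean())

    def test_empty_category_flagged(self):
        risk = risk_layer([[0.1, 0.9]])
        zones = self.zones([[1, 1]], (1, 2))
        table = zonal_stats(risk, zones).set_index("zone")
        assert bool(table.loc[2, "empty"])
        assert table.loc[2, "count"] == 0
        assert np.isnan(table.loc[2, "mean_risk"])

    def test_grid_mismatch_rejected(self):
        risk = risk_layer([[0.5]])
        zones = self.zones(np.zeros((2, 2), dtype=int), (0,))
        with pytest.raises(GridMismatchError):
            zonal_stats(risk, zones)


class TestMonthlyHistogram:
    def test_single_month(self):
        pres = PresenceSample([0] * 5, [0] * 5, [2005] * 5, [8] * 5)
        hist = hotspot_monthly_histogram(pres)
        assert hist["counts"][7] == 5
        assert hist["top2_fraction"] == 1.0
        assert 8 in hist["peak_months"]

    def test_counts_sum_to_sample_size(self):
        rng = np.random.default_rng(5)
        months = rng.integers(1, 13, 500)
        pres = PresenceSample(np.zeros(500, dtype=int), np.zeros(500, dtype=int),
                              np.full(500, 2005), months)
        hist = hotspot_monthly_histogram(pres)
        assert hist["counts"].sum() == 500

    def test_aug_sep_weighting_recovered(self):
        """Sampler months at (Aug .5, Sep .33) land ~83% in the top pair."""
        rng = np.random.default_rng(6)
        w = np.full(12, 0.17 / 10)
        w[7], w[8] = 0.50, 0.33
        months = rng.choice(np.arange(1, 13), size=10_000, p=w / w.sum())
        n = len(months)
        pres = PresenceSample(np.zeros(n, dtype=int), np.zeros(n, dtype=int),
                              np.full(n, 2005), months)
        hist = hotspot_monthly_histogram(pres)
        assert set(hist["peak_months"]) == {8, 9}
        assert hist["top2_fraction"] == pytest.approx(0.83, abs=0.03)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hotspot_monthly_histogram(PresenceSample([], [], [], []))
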