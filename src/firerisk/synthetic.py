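"""Synthetic landscape generator with known ground truth.

Emulates the statistical structure of the study inputs so every pipeline
stage is testable without external data: spatially autocorrelated
land-cover mosaics (Gaussian random fields squashed to fractions), a sparse
road network of paved and unpaved polylines, population-weighted point
settlements, a blocky categorical protection layer, seasonal monthly
rainfall with a July–November dry season (one designated dry year with a
suppressed wet season), and fire presences sampled from a known logistic
suitability surface concentrated near roads and recent deforestation.

Derived covariates (fractions, distances, densities, MCWD and temperature
anomalies) are produced through the production operators of
:mod:`firerisk.covariates` — the generator never bypasses them — so
full-loop recovery tests are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from . import covariates as cov
from .maxent import PresenceSample
from .raster import Grid, Layer, Stack
from .scenarios import ScenarioSpec

__all__ = [
    "LandscapeConfig",
    "Landscape",
    "GroundTruth",
    "gaussian_random_field",
    "generate_landscape",
    "generate_covariates",
    "true_probability",
    "default_ground_truth",
    "recovery_config",
    "sample_hotspots",
    "make_scenario_fixture",
    "DEFAULT_MONTH_WEIGHTS",
]

# August/September carry ~83% of hotspots, remaining months split the rest.
DEFAULT_MONTH_WEIGHTS = np.array(
    [0.017] * 7 + [0.50, 0.33] + [0.017] * 3
)
DEFAULT_MONTH_WEIGHTS = DEFAULT_MONTH_WEIGHTS / DEFAULT_MONTH_WEIGHTS.sum()

# Dominant drivers: road proximity, recent deforestation and settlement
# density, with a secondary climate control (warm/dry years raise risk).
DEFAULT_TRUE_WEIGHTS = {
    "deforestation": 2.0,
    "roads": -1.5,
    "settlements": 1.0,
    "shrubland": 0.5,
    "grassland": 0.5,
    "temperature_anomaly": 0.8,
    "mcwd_anomaly": -0.8,
}
DEFAULT_INTERCEPT = -1.0
DEFAULT_PROTECTION_INHIBITION = 0.5


@dataclass
class LandscapeConfig:
    """Generator parameters; defaults give a 200×200 km landscape at 1 km."""

    n_rows: int = 200
    n_cols: int = 200
    cell_size: float = 1.0  # km
    fine_factor: int = 4  # fine maps at cell_size / fine_factor (250 m)

    # land cover (fine categorical map codes: 1 shrubland, 2 grassland,
    # 3 forest, 4 other)
    landcover_length_scale: float = 15.0  # km
    shrubland_target: float = 0.25
    grassland_target: float = 0.20

    # deforestation (fine binary map; concentrated near roads)
    deforestation_rate: float = 0.08
    deforestation_road_pull: float = 2.0  # logit pull toward roads
    deforestation_length_scale: float = 8.0

    # roads / settlements
    n_paved_roads: int = 2
    n_unpaved_roads: int = 6
    road_weights: dict = field(default_factory=lambda: dict(cov.DEFAULT_ROAD_WEIGHTS))
    n_settlements: int = 25
    population_log_mean: float = 8.0  # lognormal(8, 1) ≈ 3000 median persons
    population_log_sd: float = 1.0
    settlement_bandwidth: float = 10.0  # km

    # protected areas: blocky categorical layer, 8 codes (0 = unprotected)
    n_protected_blocks: int = 6
    n_protection_codes: int = 8

    # climate (years 2000–2010; dry season July–November)
    years: tuple[int, int] = (2000, 2010)
    wet_month_rain: float = 170.0  # mm/month Dec–Jun
    dry_month_rain: float = 40.0  # mm/month Jul–Nov
    rain_sd: float = 15.0
    rain_length_scale: float = 40.0
    dry_year: int = 2010  # drought analogue year
    wet_year: int = 2009  # normal/wet validation year
    dry_year_rain_factor: float = 0.5  # dry-season rain suppression in dry year
    temperature_base: float = 299.0  # K
    temperature_sd: float = 0.6
    dry_year_warming: float = 1.2  # K added in the dry year

    # ground truth
    true_weights: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_WEIGHTS))
    intercept: float = DEFAULT_INTERCEPT
    protection_inhibition: float = DEFAULT_PROTECTION_INHIBITION

    # aboveground biomass (three emulated datasets, Mg/ha)
    agb_mean: float = 120.0
    agb_sd: float = 40.0
    agb_length_scale: float = 20.0
    agb_dataset_biases: tuple[float, ...] = (-15.0, 0.0, 15.0)
    agb_dataset_noise_sd: float = 10.0

    def __post_init__(self):
        if self.n_rows < 4 or self.n_cols < 4:
            raise ValueError("grid too small")
        if self.fine_factor < 1:
            raise ValueError("fine_factor must be >= 1")
        if self.dry_month_rain > self.wet_month_rain:
            raise ValueError("dry-season rain must not exceed wet-season rain")


def recovery_config() -> LandscapeConfig:
    """Fixture for parameter-recovery checks: one dominant, independent driver.

    Deforestation carries the dominant effect (+3 on the standardized linear
    predictor) and is generated independently of the road network; the other
    covariates keep weak effects.  The low intercept makes fires rare and
    spatially concentrated.
    """
    return LandscapeConfig(
        deforestation_road_pull=0.0,
        intercept=-2.0,
        true_weights={
            "deforestation": 3.0,
            "roads": -0.5,
            "settlements": 0.5,
            "shrubland": 0.3,
            "grassland": 0.3,
            "temperature_anomaly": 0.3,
            "mcwd_anomaly": -0.3,
        },
    )


@dataclass
class GroundTruth:
    """Known suitability surface behind a synthetic presence sample."""

    probability: Layer
    weights: dict
    intercept: float


@dataclass
class Landscape:
    """Everything the generator produced for one seed."""

    config: LandscapeConfig
    seed: int
    stack: Stack
    climate: cov.MonthlyClimateSeries
    roads: cov.RoadSet
    settlements: cov.SettlementSet
    landcover_fine: Layer
    deforestation_fine: Layer
    anomaly_layers: dict  # {"wet_year"/"dry_year": {"temperature_anomaly","mcwd_anomaly"}}
    agb_layers: list[Layer]
    truth: GroundTruth | None = None


def gaussian_random_field(shape: tuple[int, int], length_scale: float,
                          rng: np.random.Generator,
                          cell_size: float = 1.0) -> np.ndarray:
    """Standardized GRF by spectral synthesis with a Gaussian spectrum."""
    white = rng.normal(size=shape)
    ky = np.fft.fftfreq(shape[0], d=cell_size)[:, None]
    kx = np.fft.fftfreq(shape[1], d=cell_size)[None, :]
    k2 = kx**2 + ky**2
    amp = np.exp(-0.5 * k2 * (length_scale**2) * (2 * np.pi**2))
    f = np.fft.ifft2(np.fft.fft2(white) * np.sqrt(amp)).real
    sd = f.std()
    if sd == 0:
        return np.zeros(shape)
    return (f - f.mean()) / sd


def _threshold_to_fraction(g: np.ndarray, target: float) -> np.ndarray:
    """Binary map with the given areal fraction, cutting the field at a quantile."""
    cut = np.quantile(g, 1.0 - target)
    return (g > cut).astype(np.float64)


def _make_roads(config: LandscapeConfig, rng: np.random.Generator) -> cov.RoadSet:
    w = config.n_cols * config.cell_size
    h = config.n_rows * config.cell_size
    polylines = []

    def one_road():
        # roughly straight line crossing the domain, with jittered vertices
        if rng.random() < 0.5:
            x = np.linspace(0, w, 8)
            y = np.full(8, rng.uniform(0.1, 0.9) * h)
            y = -y + rng.normal(0, h * 0.03, 8).cumsum()  # negative-y world coords
        else:
            y = -np.linspace(0, h, 8)
            x = np.full(8, rng.uniform(0.1, 0.9) * w)
            x = x + rng.normal(0, w * 0.03, 8).cumsum()
        return np.column_stack([x, y])

    for _ in range(config.n_paved_roads):
        polylines.append(("paved", one_road()))
    for _ in range(config.n_unpaved_roads):
        polylines.append(("unpaved", one_road()))
    return cov.RoadSet(polylines, dict(config.road_weights))


def _make_settlements(config: LandscapeConfig, grid: Grid,
                      road_dist: Layer, rng: np.random.Generator
                      ) -> cov.SettlementSet:
    # settlements prefer cells near roads
    logit = -road_dist.values / 20_000.0
    p = np.exp(logit)
    p[grid.mask] = 0.0
    p = p.ravel() / p.sum()
    idx = rng.choice(grid.n_rows * grid.n_cols, size=config.n_settlements,
                     replace=False, p=p)
    rows, cols = np.unravel_index(idx, grid.shape)
    ox, oy = grid.origin
    x = ox + (cols + 0.5) * grid.cell_size
    y = oy - (rows + 0.5) * grid.cell_size
    pop = rng.lognormal(config.population_log_mean, config.population_log_sd,
                        config.n_settlements)
    return cov.SettlementSet(np.column_stack([x, y]), pop)


def _make_protected(config: LandscapeConfig, grid: Grid,
                    rng: np.random.Generator) -> Layer:
    vals = np.zeros(grid.shape, dtype=np.int64)
    codes = list(range(1, config.n_protection_codes))
    for i in range(config.n_protected_blocks):
        bh = rng.integers(grid.n_rows // 10, grid.n_rows // 4)
        bw = rng.integers(grid.n_cols // 10, grid.n_cols // 4)
        r0 = rng.integers(0, grid.n_rows - bh)
        c0 = rng.integers(0, grid.n_cols - bw)
        vals[r0:r0 + bh, c0:c0 + bw] = codes[i % len(codes)]
    return Layer(grid=grid, name="protected_areas", values=vals,
                 kind="categorical",
                 codes=tuple(range(config.n_protection_codes)))


def _make_climate(config: LandscapeConfig, grid: Grid,
                  rng: np.random.Generator) -> cov.MonthlyClimateSeries:
    y0, y1 = config.years
    n_years = y1 - y0 + 1
    dry_months = {7, 8, 9, 10, 11}
    spatial = gaussian_random_field(grid.shape, config.rain_length_scale, rng,
                                    grid.cell_size)
    precip = np.empty((n_years, 12) + grid.shape)
    temp = np.empty((n_years, 12) + grid.shape)
    t_spatial = gaussian_random_field(grid.shape, config.rain_length_scale, rng,
                                      grid.cell_size)
    for yi, year in enumerate(range(y0, y1 + 1)):
        # interannual variation has spatial structure, like its satellite
        # counterparts: per-year anomaly fields, not flat offsets
        rain_factor = (rng.uniform(0.9, 1.1)
                       * (1.0 + 0.15 * gaussian_random_field(
                           grid.shape, config.rain_length_scale, rng,
                           grid.cell_size)))
        warm_field = (rng.normal(0.0, 0.3)
                      + 0.5 * gaussian_random_field(
                          grid.shape, config.rain_length_scale, rng,
                          grid.cell_size))
        if year == config.dry_year:
            warm_field = warm_field + config.dry_year_warming
        for m in range(1, 13):
            base = config.dry_month_rain if m in dry_months else config.wet_month_rain
            if year == config.dry_year and m in dry_months:
                base *= config.dry_year_rain_factor
            field_ = (base * rain_factor
                      + config.rain_sd * spatial
                      + rng.normal(0, config.rain_sd * 0.3, grid.shape))
            precip[yi, m - 1] = np.maximum(field_, 0.0)
            temp[yi, m - 1] = (config.temperature_base + warm_field
                               + 0.8 * t_spatial
                               + rng.normal(0, config.temperature_sd, grid.shape))
    return cov.MonthlyClimateSeries(grid=grid, years=(y0, y1),
                                    precipitation=precip, temperature=temp)


def _climate_anomalies(config: LandscapeConfig,
                       climate: cov.MonthlyClimateSeries) -> dict:
    """Per-mode MCWD and temperature anomaly layers (2000–2010 baseline)."""
    years = [y for y in climate.year_list if y < climate.years[1] + 1]
    # the 12-month window starting January needs no spill-over year
    mcwd_per_year = {y: cov.compute_mcwd(climate, y) for y in years}
    temp_per_year = {y: cov.annual_mean_temperature(climate, y) for y in years}
    out = {}
    for mode, year in (("wet_year", config.wet_year), ("dry_year", config.dry_year)):
        mc = cov.compute_anomaly(mcwd_per_year, year, name="mcwd_anomaly")
        tm = cov.compute_anomaly(temp_per_year, year, name="temperature_anomaly")
        out[mode] = {"mcwd_anomaly": mc, "temperature_anomaly": tm}
    return out


def generate_landscape(config: LandscapeConfig | None = None,
                       seed: int = 0) -> Landscape:
    """Generate the full synthetic landscape for one seed.

    The model stack holds the eight covariates (shrubland, grassland,
    deforestation, roads, settlements, protected_areas,
    temperature_anomaly, mcwd_anomaly), with the climate pair taken from the
    dry year (the calibration analogue).  Bit-reproducible per (config, seed).
    """
    config = config or LandscapeConfig()
    rng = np.random.default_rng(seed)
    grid = Grid(config.n_rows, config.n_cols, cell_size=config.cell_size)
    fine = Grid(config.n_rows * config.fine_factor,
                config.n_cols * config.fine_factor,
                cell_size=config.cell_size / config.fine_factor)

    # --- land cover mosaic on the fine grid
    g1 = gaussian_random_field(fine.shape, config.landcover_length_scale, rng,
                               fine.cell_size)
    g2 = gaussian_random_field(fine.shape, config.landcover_length_scale, rng,
                               fine.cell_size)
    shrub = _threshold_to_fraction(g1, config.shrubland_target).astype(bool)
    grass = _threshold_to_fraction(g2, config.grassland_target).astype(bool) & ~shrub
    lc = np.full(fine.shape, 3, dtype=np.int64)  # forest
    lc[shrub] = 1
    lc[grass] = 2
    lc[(~shrub) & (~grass) & (gaussian_random_field(
        fine.shape, config.landcover_length_scale, rng, fine.cell_size) > 1.5)] = 4
    landcover_fine = Layer(grid=fine, name="landcover", values=lc,
                           kind="categorical", codes=(1, 2, 3, 4))
    shrub_frac = cov.landcover_fraction(landcover_fine, 1, config.fine_factor,
                                        name="shrubland")
    grass_frac = cov.landcover_fraction(landcover_fine, 2, config.fine_factor,
                                        name="grassland")

    # --- roads, settlements
    roads = _make_roads(config, rng)
    road_dist = cov.distance_to_roads(roads, grid)
    settlements = _make_settlements(config, grid, road_dist, rng)
    sett_dens = cov.settlement_density(settlements, grid,
                                       bandwidth=config.settlement_bandwidth)

    # --- deforestation on the fine grid, pulled toward roads
    fine_road_dist = cov.distance_to_roads(roads, fine)
    gdef = gaussian_random_field(fine.shape, config.deforestation_length_scale,
                                 rng, fine.cell_size)
    pull = config.deforestation_road_pull * np.exp(-fine_road_dist.values / 10_000.0)
    score = gdef + pull
    cut = np.quantile(score, 1.0 - config.deforestation_rate)
    defo_fine = Layer(grid=fine, name="deforestation",
                      values=(score > cut).astype(np.float64))
    defo = cov.aggregate_fraction(defo_fine, config.fine_factor)

    # --- protection, climate
    protected = _make_protected(config, grid, rng)
    climate = _make_climate(config, grid, rng)
    anomalies = _climate_anomalies(config, climate)
    dry = anomalies["dry_year"]

    # --- aboveground biomass datasets
    agb_base = (config.agb_mean
                + config.agb_sd * gaussian_random_field(
                    grid.shape, config.agb_length_scale, rng, grid.cell_size))
    agb_layers = []
    for i, bias in enumerate(config.agb_dataset_biases):
        vals = np.maximum(
            agb_base + bias + rng.normal(0, config.agb_dataset_noise_sd, grid.shape),
            0.0)
        agb_layers.append(Layer(grid=grid, name=f"agb_dataset_{i + 1}",
                                values=vals, units="Mg/ha"))

    # --- the eight-variable model stack (dry-year climate = calibration year)
    stack = Stack([
        shrub_frac.with_values(shrub_frac.values, name="shrubland"),
        grass_frac.with_values(grass_frac.values, name="grassland"),
        defo.with_values(defo.values, name="deforestation"),
        road_dist,
        sett_dens,
        protected,
        Layer(grid=grid, name="temperature_anomaly",
              values=dry["temperature_anomaly"].values, units="K"),
        Layer(grid=grid, name="mcwd_anomaly",
              values=dry["mcwd_anomaly"].values, units="mm"),
    ])

    landscape = Landscape(
        config=config, seed=seed, stack=stack, climate=climate, roads=roads,
        settlements=settlements, landcover_fine=landcover_fine,
        deforestation_fine=defo_fine, anomaly_layers=anomalies,
        agb_layers=agb_layers,
    )
    landscape.truth = default_ground_truth(landscape)
    return landscape


def generate_covariates(config: LandscapeConfig | None = None, seed: int = 0
                        ) -> tuple[Stack, cov.MonthlyClimateSeries,
                                   cov.RoadSet, cov.SettlementSet]:
    """Spec-shaped wrapper: (stack, climate series, roads, settlements)."""
    ls = generate_landscape(config, seed)
    return ls.stack, ls.climate, ls.roads, ls.settlements


def true_probability(stack: Stack, weights: dict, intercept: float) -> GroundTruth:
    """Known suitability p*(x) = logistic(intercept + Σ w·standardized cov)."""
    grid = stack.grid
    valid = ~grid.mask
    eta = np.full(grid.shape, intercept)
    for name, w in weights.items():
        if name not in stack:
            raise KeyError(f"unknown variable {name!r} in true weights")
        v = stack[name].values.astype(np.float64)
        mu, sd = v[valid].mean(), v[valid].std()
        z = (v - mu) / sd if sd > 0 else np.zeros_like(v)
        eta = eta + w * z
    p = expit(eta)
    p[grid.mask] = 0.0
    return GroundTruth(
        probability=Layer(grid=grid, name="true_probability", values=p,
                          units="probability"),
        weights=dict(weights),
        intercept=intercept,
    )


def default_ground_truth(landscape: Landscape) -> GroundTruth:
    """Config-driven truth with protected-area inhibition applied."""
    config = landscape.config
    truth = true_probability(landscape.stack, config.true_weights,
                             config.intercept)
    if config.protection_inhibition < 1.0:
        prot = landscape.stack["protected_areas"].values > 0
        vals = truth.probability.values.copy()
        vals[prot] *= config.protection_inhibition
        truth = GroundTruth(
            probability=truth.probability.with_values(vals),
            weights=truth.weights, intercept=truth.intercept)
    return truth


def sample_hotspots(truth: GroundTruth, n: int, seed: int = 0,
                    month_weights: np.ndarray | None = None,
                    years: tuple[int, int] = (2001, 2010)) -> PresenceSample:
    """Draw n presences with cell probability ∝ p*, months per month_weights."""
    if n < 1:
        raise ValueError("n must be >= 1")
    mw = DEFAULT_MONTH_WEIGHTS if month_weights is None else np.asarray(month_weights)
    if mw.shape != (12,) or not np.isclose(mw.sum(), 1.0):
        raise ValueError("month_weights must be 12 probabilities summing to 1")
    grid = truth.probability.grid
    p = truth.probability.values.copy()
    p[grid.mask] = 0.0
    flat = p.ravel()
    total = flat.sum()
    if total <= 0:
        raise ValueError("all-zero suitability surface")
    rng = np.random.default_rng(seed)
    idx = rng.choice(flat.size, size=n, replace=True, p=flat / total)
    rows, cols = np.unravel_index(idx, grid.shape)
    months = rng.choice(np.arange(1, 13), size=n, p=mw)
    yrs = rng.integers(years[0], years[1] + 1, size=n)
    return PresenceSample(rows, cols, yrs, months)


def make_scenario_fixture(landscape: Landscape, mode: str,
                          climate: str = "wet") -> ScenarioSpec:
    """Scenario replacement layers with built-in ordering A ≤ B ≤ C.

    ``A_like`` freezes deforestation and adds new protected blocks where the
    base risk drivers are strong; ``B_like`` applies moderate road and
    deforestation growth; ``C_like`` strong growth.  ``climate`` selects the
    wet-year or dry-year anomaly pair.
    """
    base = landscape.stack
    grid = base.grid
    if mode not in ("A_like", "B_like", "C_like"):
        raise ValueError(f"unknown scenario mode {mode!r}")
    if climate not in ("wet", "dry"):
        raise ValueError(f"unknown climate {climate!r}")

    defo = base["deforestation"].values
    road = base["roads"].values
    replacements: dict[str, Layer] = {}

    if mode == "A_like":
        # deforestation frozen at the base level; protection expands onto the
        # most threatened cells (highest deforestation pressure)
        replacements["deforestation"] = base["deforestation"].with_values(defo)
        prot = base["protected_areas"].values.copy()
        pressure = np.where(prot == 0, defo, -np.inf)
        k = max(1, int(0.05 * grid.n_valid))
        flat = pressure.ravel()
        top = np.argpartition(flat, -k)[-k:]
        prot_new = prot.ravel().copy()
        prot_new[top] = (landscape.config.n_protection_codes - 1)
        replacements["protected_areas"] = Layer(
            grid=grid, name="protected_areas",
            values=prot_new.reshape(grid.shape), kind="categorical",
            codes=base["protected_areas"].codes)
    elif mode == "B_like":
        replacements["deforestation"] = base["deforestation"].with_values(
            np.clip(defo * 1.3 + 0.03, 0.0, 1.0))
        replacements["roads"] = base["roads"].with_values(road * 0.7)
    else:  # C_like
        replacements["deforestation"] = base["deforestation"].with_values(
            np.clip(defo * 1.6 + 0.08, 0.0, 1.0))
        replacements["roads"] = base["roads"].with_values(road * 0.45)

    anoms = landscape.anomaly_layers["dry_year" if climate == "dry" else "wet_year"]
    for var in ("temperature_anomaly", "mcwd_anomaly"):
        replacements[var] = Layer(grid=grid, name=var,
                                  values=anoms[var].values,
                                  units=anoms[var].units)
    return ScenarioSpec(name=f"{mode}_{climate}", replacements=replacements,
                        climate_mode="dry_year" if climate == "dry" else "wet_year")
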