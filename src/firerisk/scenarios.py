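"""Scenario construction and projection of fitted models.

A scenario is a named set of replacement layers for the *dynamic* variables
(deforestation, roads, protected areas and the two climate-anomaly layers)
plus a climate tag (wet-year or dry-year anomaly pair).  Projection
evaluates the fitted replicate models on the scenario stack with clamping,
averages the replicate maps cell-wise and summarizes the high-risk area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .maxent import MaxentModel, PresenceSample, predict
from .raster import GridMismatchError, Layer, Stack

__all__ = [
    "DYNAMIC_VARIABLES",
    "ScenarioSpec",
    "ScenarioResult",
    "apply_scenario",
    "project_scenario",
    "compare_scenarios",
    "specificity_validation",
]

DYNAMIC_VARIABLES = frozenset(
    {"deforestation", "roads", "protected_areas", "temperature_anomaly",
     "mcwd_anomaly"}
)
HIGH_RISK_THRESHOLD = 0.5

_RISK_CLASS_EDGES = (0.0, 0.25, 0.5, 0.75, 1.0)
_RISK_CLASS_NAMES = ("low", "moderate", "high", "extreme")


class ScenarioPolicyError(ValueError):
    """Raised when a scenario tries to replace a non-dynamic variable."""


@dataclass
class ScenarioSpec:
    """Named scenario: replacement layers for dynamic variables + climate tag."""

    name: str
    replacements: dict[str, Layer] = field(default_factory=dict)
    climate_mode: str = "wet_year"  # "wet_year" | "dry_year"

    def __post_init__(self):
        if self.climate_mode not in ("wet_year", "dry_year"):
            raise ValueError(f"unknown climate_mode {self.climate_mode!r}")
        for var in self.replacements:
            if var not in DYNAMIC_VARIABLES:
                raise ScenarioPolicyError(
                    f"{var!r} is not a dynamic variable; replaceable: "
                    f"{sorted(DYNAMIC_VARIABLES)}")


@dataclass
class ScenarioResult:
    """Projection of one scenario: replicate maps, their mean, summaries."""

    spec_name: str
    mean_risk: Layer
    replicate_risk: list[Layer]
    clamped_fraction: float
    high_risk_area_km2: float


def apply_scenario(base: Stack, spec: ScenarioSpec) -> Stack:
    """Stack equal to ``base`` with the scenario's layers swapped in.

    Side-effect free and idempotent: the base stack is never modified and
    an empty replacement map returns a stack identical to the base.
    """
    out = base
    for var, layer in spec.replacements.items():
        if var not in base:
            raise KeyError(f"base stack has no layer {var!r}")
        if not layer.grid.compatible(base.grid):
            raise GridMismatchError(f"replacement {var!r} on a mismatched grid")
        if layer.name != var:
            layer = layer.with_values(layer.values, name=var)
        out = out.replace(layer)
    return out


def project_scenario(models: list[MaxentModel], spec: ScenarioSpec,
                     base: Stack) -> ScenarioResult:
    """Project fitted replicates onto a scenario stack (clamped logistic)."""
    if not models:
        raise ValueError("need at least one fitted model")
    stack = apply_scenario(base, spec)
    layers = [predict(m, stack, output="logistic", clamp=True) for m in models]
    mean_vals = np.mean([l.values for l in layers], axis=0)
    mean_vals[stack.grid.mask] = 0.0
    mean_layer = Layer(grid=stack.grid, name=f"risk_{spec.name}",
                       values=mean_vals, units="probability")
    valid = mean_vals[~stack.grid.mask]
    area = float((valid > HIGH_RISK_THRESHOLD).sum()) * stack.grid.cell_area_km2
    clamped = models[0].expansion.clamped_fraction(stack)
    return ScenarioResult(
        spec_name=spec.name,
        mean_risk=mean_layer,
        replicate_risk=layers,
        clamped_fraction=clamped,
        high_risk_area_km2=area,
    )


def _class_areas(layer: Layer) -> dict[str, float]:
    vals = layer.valid_values
    areas = {}
    for name, lo, hi in zip(_RISK_CLASS_NAMES, _RISK_CLASS_EDGES[:-1],
                            _RISK_CLASS_EDGES[1:]):
        if hi >= 1.0:
            n = ((vals >= lo) & (vals <= hi)).sum()
        else:
            n = ((vals >= lo) & (vals < hi)).sum()
        areas[name] = float(n) * layer.grid.cell_area_km2
    return areas


def compare_scenarios(a: ScenarioResult, b: ScenarioResult
                      ) -> tuple[pd.DataFrame, Layer]:
    """Comparison table and difference layer (a − b) of two projections."""
    if not a.mean_risk.grid.compatible(b.mean_risk.grid):
        raise GridMismatchError("scenario results on mismatched grids")
    diff_vals = a.mean_risk.values - b.mean_risk.values
    diff_vals[a.mean_risk.grid.mask] = 0.0
    diff = Layer(grid=a.mean_risk.grid, name=f"{a.spec_name}-{b.spec_name}",
                 values=diff_vals)
    rows = []
    areas_a, areas_b = _class_areas(a.mean_risk), _class_areas(b.mean_risk)
    for cls in _RISK_CLASS_NAMES:
        rows.append({"metric": f"area_{cls}_km2",
                     a.spec_name: areas_a[cls], b.spec_name: areas_b[cls]})
    ha, hb = a.high_risk_area_km2, b.high_risk_area_km2
    rows.append({"metric": "high_risk_area_km2", a.spec_name: ha, b.spec_name: hb})
    rows.append({"metric": "high_risk_ratio",
                 a.spec_name: (ha / hb if hb > 0 else np.inf), b.spec_name: 1.0})
    rows.append({"metric": "high_risk_pct_difference",
                 a.spec_name: (100.0 * (ha - hb) / hb if hb > 0 else np.inf),
                 b.spec_name: 0.0})
    return pd.DataFrame(rows), diff


def specificity_validation(risk: Layer, observed: PresenceSample,
                           bin_width: float = 0.1) -> pd.DataFrame:
    """Distribution of observed presences across probability bins.

    Counts and fractions of observed hotspots per probability bin of the
    projected risk map, plus the fraction above the high-risk threshold
    (returned as DataFrame attribute ``fraction_above_05``).
    """
    if observed.m == 0:
        raise ValueError("empty presence sample")
    observed.check_on_grid(risk.grid)
    p = risk.values[observed.rows, observed.cols]
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(p, bins=edges)
    df = pd.DataFrame({
        "bin_lo": edges[:-1],
        "bin_hi": edges[1:],
        "count": counts,
        "fraction": counts / observed.m,
    })
    df.attrs["fraction_above_05"] = float((p > HIGH_RISK_THRESHOLD).mean())
    df.attrs["n"] = observed.m
    return df
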