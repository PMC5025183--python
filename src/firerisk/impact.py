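"""Impact accounting on risk maps: classes, areas, biomass loss, zones.

Risk probabilities partition into four classes (low [0, 0.25), moderate
[0.25, 0.5), high [0.5, 0.75), extreme [0.75, 1]); "high fire risk area"
means cells strictly above 0.5.  Potential aboveground-biomass (AGB) loss
per burned cell follows

    B_l = (1 − α) · B_i

with B_i the initial AGB (Mg/ha) and α the proportion of AGB remaining
post-fire; the default α range [0.7084, 0.90] spans published 1–5 year
post-fire estimates, giving a central loss factor of ~0.1958 with an
uncertainty half-range of ~0.0958.  Totals use 1 km² = 100 ha and
1 Tg = 10⁶ Mg.  Fire recurrence is not accounted for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .maxent import PresenceSample
from .raster import GridMismatchError, Layer

__all__ = [
    "RiskClassification",
    "AGBStack",
    "ImpactReport",
    "classify_risk",
    "high_risk_area",
    "agb_loss",
    "zonal_stats",
    "hotspot_monthly_histogram",
]

RISK_CLASS_EDGES = (0.0, 0.25, 0.5, 0.75, 1.0)
RISK_CLASS_NAMES = ("low", "moderate", "high", "extreme")
DEFAULT_ALPHA_LOW = 0.7084
DEFAULT_ALPHA_HIGH = 0.90
HA_PER_KM2 = 100.0
MG_PER_TG = 1e6


@dataclass
class RiskClassification:
    """Per-class cell counts and areas; classes partition [0, 1]."""

    counts: dict[str, int]
    areas_km2: dict[str, float]
    total_area_km2: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "class": list(RISK_CLASS_NAMES),
            "count": [self.counts[c] for c in RISK_CLASS_NAMES],
            "area_km2": [self.areas_km2[c] for c in RISK_CLASS_NAMES],
        })


@dataclass
class AGBStack:
    """One or more aboveground-biomass layers (Mg/ha) plus their mean."""

    layers: list[Layer]

    def __post_init__(self):
        if not self.layers:
            raise ValueError("need at least one AGB layer")
        grid = self.layers[0].grid
        for l in self.layers[1:]:
            if not l.grid.compatible(grid):
                raise GridMismatchError("AGB layers on mismatched grids")
        for l in self.layers:
            if np.any(l.valid_values < 0):
                raise ValueError(f"negative AGB in {l.name!r}")

    @property
    def grid(self):
        return self.layers[0].grid

    @property
    def mean_layer(self) -> Layer:
        vals = np.mean([l.values for l in self.layers], axis=0)
        vals[self.grid.mask] = 0.0
        return Layer(grid=self.grid, name="agb_mean", values=vals, units="Mg/ha")


@dataclass
class ImpactReport:
    """Per-bin AGB means, loss envelope and totals for one risk map."""

    per_bin: pd.DataFrame  # bin_lo/bin_hi, per-dataset + mean AGB, losses (Tg)
    total_loss_tg: float
    total_loss_low_tg: float  # at alpha_high (least loss)
    total_loss_high_tg: float  # at alpha_low (most loss)
    high_risk_area_km2: float
    central_loss_factor: float
    loss_factor_half_range: float
    alpha_low: float
    alpha_high: float
    threshold: float


def classify_risk(risk: Layer) -> RiskClassification:
    """Partition a probability layer into the four risk classes.

    Intervals are half-open with the top class closed; p = 0.5 falls in the
    high class.  Class areas sum exactly to the total unmasked area.
    """
    vals = risk.valid_values
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise ValueError("risk values must lie in [0, 1]")
    area = risk.grid.cell_area_km2
    counts, areas = {}, {}
    for name, lo, hi in zip(RISK_CLASS_NAMES, RISK_CLASS_EDGES[:-1],
                            RISK_CLASS_EDGES[1:]):
        if hi >= 1.0:
            n = int(((vals >= lo) & (vals <= hi)).sum())
        else:
            n = int(((vals >= lo) & (vals < hi)).sum())
        counts[name] = n
        areas[name] = n * area
    return RiskClassification(counts=counts, areas_km2=areas,
                              total_area_km2=vals.size * area)


def high_risk_area(risk: Layer, threshold: float = 0.5) -> float:
    """Area (km²) of cells with risk strictly above the threshold."""
    vals = risk.valid_values
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise ValueError("risk values must lie in [0, 1]")
    return float((vals > threshold).sum()) * risk.grid.cell_area_km2


def agb_loss(risk: Layer, agb: AGBStack,
             alpha_low: float = DEFAULT_ALPHA_LOW,
             alpha_high: float = DEFAULT_ALPHA_HIGH,
             threshold: float = 0.5, bin_width: float = 0.1) -> ImpactReport:
    """Potential AGB loss over cells above the risk threshold.

    Central estimate uses the mean of the two loss factors (1 − α_low) and
    (1 − α_high); the envelope spans the endpoints.  Per-bin rows report the
    mean AGB of every probability bin (per dataset and averaged) and the
    loss of the bins above the threshold; losses in Tg.
    """
    if not (0.0 < alpha_low <= 1.0 and 0.0 < alpha_high <= 1.0):
        raise ValueError("alpha values must be in (0, 1]")
    if alpha_low > alpha_high:
        raise ValueError("alpha_low must be <= alpha_high")
    if not risk.grid.compatible(agb.grid):
        raise GridMismatchError("risk and AGB on mismatched grids")
    vals = risk.valid_values
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise ValueError("risk values must lie in [0, 1]")

    f_low = 1.0 - alpha_high  # least loss
    f_high = 1.0 - alpha_low  # most loss
    f_central = 0.5 * (f_low + f_high)
    half_range = 0.5 * (f_high - f_low)
    cell_ha = risk.grid.cell_area_km2 * HA_PER_KM2

    mean_agb = agb.mean_layer.valid_values
    per_ds = {l.name: l.valid_values for l in agb.layers}

    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(vals, edges[1:-1], right=False), 0, n_bins - 1)
    rows = []
    tot_c = tot_lo = tot_hi = 0.0
    for b in range(n_bins):
        in_bin = idx == b
        n = int(in_bin.sum())
        row = {"bin_lo": edges[b], "bin_hi": edges[b + 1], "count": n}
        row["agb_mean"] = float(mean_agb[in_bin].mean()) if n else np.nan
        for nm, v in per_ds.items():
            row[f"agb_{nm}"] = float(v[in_bin].mean()) if n else np.nan
        above = in_bin & (vals > threshold)
        biomass_mg = float(mean_agb[above].sum()) * cell_ha  # Mg at risk in bin
        row["loss_tg"] = f_central * biomass_mg / MG_PER_TG
        row["loss_low_tg"] = f_low * biomass_mg / MG_PER_TG
        row["loss_high_tg"] = f_high * biomass_mg / MG_PER_TG
        tot_c += row["loss_tg"]
        tot_lo += row["loss_low_tg"]
        tot_hi += row["loss_high_tg"]
        rows.append(row)
    return ImpactReport(
        per_bin=pd.DataFrame(rows),
        total_loss_tg=tot_c,
        total_loss_low_tg=tot_lo,
        total_loss_high_tg=tot_hi,
        high_risk_area_km2=high_risk_area(risk, threshold),
        central_loss_factor=f_central,
        loss_factor_half_range=half_range,
        alpha_low=alpha_low,
        alpha_high=alpha_high,
        threshold=threshold,
    )


def zonal_stats(risk: Layer, zones: Layer, threshold: float = 0.5) -> pd.DataFrame:
    """Per-category mean/STD of risk plus areas over a categorical zoning map.

    Declared categories absent from the map get a row with count 0 and NaN
    mean (flagged ``empty``).  Category areas sum to the total unmasked area.
    """
    if zones.kind != "categorical":
        raise ValueError("zones must be a categorical layer")
    if not risk.grid.compatible(zones.grid):
        raise GridMismatchError("risk and zones on mismatched grids")
    valid = ~risk.grid.mask
    r = risk.values[valid]
    z = zones.values[valid]
    area = risk.grid.cell_area_km2
    rows = []
    for code in zones.codes or np.unique(z):
        sel = z == code
        n = int(sel.sum())
        rows.append({
            "zone": int(code),
            "count": n,
            "area_km2": n * area,
            "mean_risk": float(r[sel].mean()) if n else np.nan,
            "std_risk": float(r[sel].std()) if n else np.nan,
            "area_above_threshold_km2": float((r[sel] > threshold).sum()) * area,
            "empty": n == 0,
        })
    return pd.DataFrame(rows)


def hotspot_monthly_histogram(presences: PresenceSample) -> dict:
    """Monthly hotspot counts, peak months and concentration fractions.

    Returns counts per calendar month (1..12), the two peak months, the
    fraction of records in those two months, and the largest fraction in any
    contiguous (circular) 3-month window.
    """
    if presences.m == 0:
        raise ValueError("empty presence sample")
    counts = np.bincount(presences.months, minlength=13)[1:]
    order = np.argsort(counts)[::-1]
    top2 = [int(order[0]) + 1, int(order[1]) + 1]
    top2_fraction = float(counts[order[:2]].sum() / presences.m)
    wrapped = np.concatenate([counts, counts[:2]])
    win3 = np.array([wrapped[i:i + 3].sum() for i in range(12)])
    best = int(win3.argmax())
    return {
        "counts": counts,
        "peak_months": top2,
        "top2_fraction": top2_fraction,
        "window3_months": [best + 1, (best + 1) % 12 + 1, (best + 2) % 12 + 1],
        "window3_fraction": float(win3[best] / presences.m),
    }
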