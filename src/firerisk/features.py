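"""Environmental feature expansion for the maximum-entropy model.

Each source variable expands into a set of features, affinely scaled so the
feature values over the *background* sample lie in [0, 1]:

* continuous variables: linear, quadratic, hinge (forward and reverse, at
  evenly spaced quantile knots), optionally pairwise products;
* categorical variables: one 0/1 indicator per declared code.

Clamping truncates a variable to its training (background) range before
feature evaluation; it is the extrapolation guard used when projecting the
fitted model onto scenario conditions outside the calibration envelope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .raster import Stack

__all__ = ["FeatureConfig", "Feature", "FeatureExpansion", "build_features"]


@dataclass(frozen=True)
class FeatureConfig:
    """Which feature classes to generate for continuous variables."""

    linear: bool = True
    quadratic: bool = True
    hinge: bool = True
    product: bool = False
    n_hinge_knots: int = 4  # knots per direction per variable


@dataclass(frozen=True)
class Feature:
    """One scalar feature: its type, source variable(s) and scaling.

    ``lo``/``hi`` are the affine scaling bounds of the *raw* feature value
    over background, mapping it onto [0, 1]; hinge features carry their knot.
    """

    name: str
    ftype: str  # linear | quadratic | product | hinge_fwd | hinge_rev | indicator
    variables: tuple[str, ...]
    lo: float = 0.0
    hi: float = 1.0
    knot: float = np.nan
    code: int = -1

    def raw(self, cols: dict[str, np.ndarray]) -> np.ndarray:
        x = cols[self.variables[0]]
        if self.ftype == "linear":
            return x
        if self.ftype == "quadratic":
            return x * x
        if self.ftype == "product":
            return x * cols[self.variables[1]]
        if self.ftype == "hinge_fwd":
            return np.maximum(0.0, x - self.knot)
        if self.ftype == "hinge_rev":
            return np.maximum(0.0, self.knot - x)
        if self.ftype == "indicator":
            return (x == self.code).astype(np.float64)
        raise ValueError(f"unknown feature type {self.ftype!r}")

    def scaled(self, cols: dict[str, np.ndarray]) -> np.ndarray:
        r = self.raw(cols)
        span = self.hi - self.lo
        if span <= 0:
            return np.zeros_like(r, dtype=np.float64)
        return (r - self.lo) / span


@dataclass
class FeatureExpansion:
    """Fitted expansion: feature list plus per-variable clamp bounds."""

    features: list[Feature]
    variable_names: list[str]
    clamp_bounds: dict[str, tuple[float, float]]  # background min/max per continuous var
    config: FeatureConfig = field(default_factory=FeatureConfig)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def variable_of(self, j: int) -> tuple[str, ...]:
        return self.features[j].variables

    def transform_columns(self, cols: dict[str, np.ndarray],
                          clamp: bool = False) -> np.ndarray:
        """Feature matrix (n_points, n_features) from raw variable columns."""
        if clamp:
            cols = dict(cols)
            for v, (lo, hi) in self.clamp_bounds.items():
                if v in cols:
                    cols[v] = np.clip(cols[v], lo, hi)
        out = np.empty((len(next(iter(cols.values()))), self.n_features))
        for j, f in enumerate(self.features):
            col = f.scaled(cols)
            if clamp and f.ftype != "indicator":
                np.clip(col, 0.0, 1.0, out=col)
            out[:, j] = col
        return out

    def stack_columns(self, stack: Stack,
                      cells: np.ndarray | None = None) -> dict[str, np.ndarray]:
        """Raw variable columns for the given cells (default: all unmasked)."""
        grid = stack.grid
        if cells is None:
            rows, cols_idx = np.nonzero(~grid.mask)
        else:
            cells = np.asarray(cells)
            rows, cols_idx = cells[:, 0], cells[:, 1]
        out = {}
        for name in self.variable_names:
            if name not in stack:
                raise KeyError(f"stack is missing model variable {name!r}")
            out[name] = stack[name].values[rows, cols_idx].astype(np.float64)
        return out

    def transform_stack(self, stack: Stack, cells: np.ndarray | None = None,
                        clamp: bool = False) -> np.ndarray:
        return self.transform_columns(self.stack_columns(stack, cells), clamp=clamp)

    def clamped_fraction(self, stack: Stack) -> float:
        """Fraction of unmasked cells where any variable exceeds training bounds."""
        cols = self.stack_columns(stack)
        n = len(next(iter(cols.values())))
        out = np.zeros(n, dtype=bool)
        for v, (lo, hi) in self.clamp_bounds.items():
            out |= (cols[v] < lo) | (cols[v] > hi)
        return float(out.mean()) if n else 0.0


def build_features(stack: Stack, config: FeatureConfig | None = None,
                   background_cells: np.ndarray | None = None) -> FeatureExpansion:
    """Build the feature expansion with scalings over the background cells.

    Continuous variables with zero range over background contribute no
    features (a warning is emitted); categorical variables expand to one
    indicator per declared code.
    """
    if len(stack) == 0:
        raise ValueError("empty stack")
    config = config or FeatureConfig()
    grid = stack.grid
    if background_cells is None:
        rows, cols_idx = np.nonzero(~grid.mask)
    else:
        bc = np.asarray(background_cells)
        rows, cols_idx = bc[:, 0], bc[:, 1]

    features: list[Feature] = []
    clamp_bounds: dict[str, tuple[float, float]] = {}
    continuous: list[tuple[str, np.ndarray]] = []

    for layer in stack:
        col = layer.values[rows, cols_idx].astype(np.float64)
        if layer.kind == "categorical":
            for code in layer.codes or ():
                features.append(Feature(
                    name=f"{layer.name}=={code}", ftype="indicator",
                    variables=(layer.name,), code=int(code), lo=0.0, hi=1.0))
            continue
        lo, hi = float(col.min()), float(col.max())
        clamp_bounds[layer.name] = (lo, hi)
        if hi <= lo:
            warnings.warn(
                f"variable {layer.name!r} is constant over background; "
                "its features are dropped")
            continue
        continuous.append((layer.name, col))
        if config.linear:
            features.append(Feature(
                name=f"{layer.name}", ftype="linear", variables=(layer.name,),
                lo=lo, hi=hi))
        if config.quadratic:
            sq = col * col
            features.append(Feature(
                name=f"{layer.name}^2", ftype="quadratic", variables=(layer.name,),
                lo=float(sq.min()), hi=float(sq.max())))
        if config.hinge and config.n_hinge_knots > 0:
            qs = np.linspace(0, 1, config.n_hinge_knots + 2)[1:-1]
            knots = np.quantile(col, qs)
            for k in knots:
                k = float(k)
                if k < hi:
                    features.append(Feature(
                        name=f"hinge({layer.name}>{k:.4g})", ftype="hinge_fwd",
                        variables=(layer.name,), knot=k, lo=0.0, hi=hi - k))
                if k > lo:
                    features.append(Feature(
                        name=f"hinge({layer.name}<{k:.4g})", ftype="hinge_rev",
                        variables=(layer.name,), knot=k, lo=0.0, hi=k - lo))

    if config.product:
        for i in range(len(continuous)):
            for j in range(i + 1, len(continuous)):
                (na, ca), (nb, cb) = continuous[i], continuous[j]
                pr = ca * cb
                lo, hi = float(pr.min()), float(pr.max())
                if hi > lo:
                    features.append(Feature(
                        name=f"{na}*{nb}", ftype="product", variables=(na, nb),
                        lo=lo, hi=hi))

    return FeatureExpansion(
        features=features,
        variable_names=stack.names,
        clamp_bounds=clamp_bounds,
        config=config,
    )
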