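"""Presence-only maximum-entropy model: fitting, prediction, evaluation.

The model estimates a probability distribution ``q`` over background cells,
``q(x) ∝ exp(Σ_j λ_j f_j(x))``, chosen to maximize the L1-regularized
log-likelihood of the presence sample

    (1/m) Σ_presence ln q(x)  −  Σ_j β_j |λ_j|,

equivalently the distribution of maximum entropy subject to the constraint
that each feature's expectation under ``q`` stays within ``β_j`` of its
empirical presence average.  At the optimum ``|E_q[f_j] − f̄_j| ≤ β_j``,
with equality whenever ``λ_j ≠ 0``.

The solver is accelerated proximal gradient (FISTA) with backtracking line
search and soft-thresholding for the L1 term; it is deterministic given its
inputs.  The per-feature penalties follow the standard presence-only
defaults: ``β_j = multiplier × β_class(m) × s_j / √m`` where ``s_j`` is the
feature's spread over the presence sample and ``β_class`` interpolates a
per-feature-class table in the presence count ``m`` (table in
``_BETA_TABLES``).

Two outputs are available: the *raw* distribution renormalized over the
prediction region, and the *logistic* transform
``p = τ e^H q / (1 − τ + τ e^H q)`` with entropy ``H`` of the fitted
training distribution and prevalence ``τ`` (default 0.5), read as relative
probability of presence in [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import rankdata

from .features import Feature, FeatureConfig, FeatureExpansion
from .raster import Grid, Layer, Stack

__all__ = [
    "PresenceSample",
    "MaxentModel",
    "sample_background",
    "solve_maxent",
    "fit",
    "predict",
    "auc",
    "split_sample",
]

DEFAULT_MAX_ITER = 500
DEFAULT_TOL = 1e-6
DEFAULT_PREVALENCE = 0.5
DEFAULT_BACKGROUND_SIZE = 10_000

# Per-feature-class L1 penalty tables: breakpoints in presence count m and
# the base penalty at each, linearly interpolated, clamped at the ends.
_BETA_TABLES = {
    "linear": ([10, 30, 100], [1.0, 0.2, 0.05]),
    "quadratic": ([10, 30, 100], [1.0, 0.2, 0.05]),
    "product": ([10, 30, 100], [1.0, 0.2, 0.05]),
    "hinge_fwd": ([1], [0.5]),
    "hinge_rev": ([1], [0.5]),
    "indicator": ([0, 10, 17], [0.65, 0.5, 0.25]),
}
_MIN_FEATURE_SPREAD = 0.05  # floor on s_j so every penalty stays positive


@dataclass
class PresenceSample:
    """Presence-only fire locations: cell indices plus observation dates."""

    rows: np.ndarray
    cols: np.ndarray
    years: np.ndarray
    months: np.ndarray

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=np.int64).reshape(-1)
        self.cols = np.asarray(self.cols, dtype=np.int64).reshape(-1)
        self.years = np.asarray(self.years, dtype=np.int64).reshape(-1)
        self.months = np.asarray(self.months, dtype=np.int64).reshape(-1)
        n = self.m
        if not (len(self.cols) == len(self.years) == len(self.months) == n):
            raise ValueError("presence record arrays must have equal length")
        if n and (self.months.min() < 1 or self.months.max() > 12):
            raise ValueError("months must be in 1..12")

    @property
    def m(self) -> int:
        return len(self.rows)

    @property
    def cells(self) -> np.ndarray:
        return np.column_stack([self.rows, self.cols])

    def subset(self, idx: np.ndarray) -> "PresenceSample":
        return PresenceSample(self.rows[idx], self.cols[idx],
                              self.years[idx], self.months[idx])

    def unique_cells(self) -> np.ndarray:
        """One record per occupied cell (duplicate collapse)."""
        return np.unique(self.cells, axis=0)

    def check_on_grid(self, grid: Grid) -> None:
        if self.m == 0:
            return
        if (self.rows.min() < 0 or self.rows.max() >= grid.n_rows
                or self.cols.min() < 0 or self.cols.max() >= grid.n_cols):
            raise ValueError("presence cell outside grid")
        if grid.mask[self.rows, self.cols].any():
            raise ValueError("presence record on a masked cell")

    @classmethod
    def from_csv(cls, path: str) -> "PresenceSample":
        df = pd.read_csv(path)
        return cls(df["row"].to_numpy(), df["col"].to_numpy(),
                   df["year"].to_numpy(), df["month"].to_numpy())

    def to_csv(self, path: str) -> None:
        pd.DataFrame({"row": self.rows, "col": self.cols,
                      "year": self.years, "month": self.months}).to_csv(path, index=False)


def sample_background(grid: Grid, max_n: int = DEFAULT_BACKGROUND_SIZE,
                      seed: int | None = None) -> np.ndarray:
    """Background cells: all unmasked cells, or a seeded uniform subsample.

    Presence cells are allowed in the background (standard presence-
    background convention).
    """
    cells = np.column_stack(np.nonzero(~grid.mask))
    if len(cells) == 0:
        raise ValueError("grid has no unmasked cells")
    if len(cells) <= max_n:
        return cells
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(cells), size=max_n, replace=False)
    return cells[np.sort(idx)]


# ---------------------------------------------------------------------------
# Solver


def compute_betas(expansion: FeatureExpansion, F_pres: np.ndarray,
                  reg_multiplier: float = 1.0) -> np.ndarray:
    """Per-feature L1 penalties from the class table and presence spread."""
    m = F_pres.shape[0]
    betas = np.empty(expansion.n_features)
    for j, feat in enumerate(expansion.features):
        breaks, vals = _BETA_TABLES[feat.ftype]
        base = float(np.interp(m, breaks, vals))
        s = float(F_pres[:, j].std(ddof=1)) if m > 1 else 1.0
        s = max(s, _MIN_FEATURE_SPREAD)
        betas[j] = reg_multiplier * base * s / np.sqrt(m)
    return betas


def _objective(lam: np.ndarray, F_bg: np.ndarray, fbar: np.ndarray,
               beta: np.ndarray) -> tuple[float, np.ndarray, float]:
    """(J, grad of smooth part, lnZ): J = lnZ − f̄·λ + Σβ|λ|."""
    eta = F_bg @ lam
    ln_z = float(logsumexp(eta))
    q = np.exp(eta - ln_z)
    smooth = ln_z - float(fbar @ lam)
    grad = F_bg.T @ q - fbar
    return smooth + float(beta @ np.abs(lam)), grad, ln_z


def solve_maxent(F_bg: np.ndarray, F_pres: np.ndarray, beta: np.ndarray,
                 max_iter: int = DEFAULT_MAX_ITER, tol: float = DEFAULT_TOL,
                 ) -> tuple[np.ndarray, dict]:
    """Minimize ``lnZ(λ) − f̄·λ + Σ β_j|λ_j|`` by FISTA with backtracking.

    Returns the weight vector and an info dict with the objective trace,
    convergence flag and per-feature gain-contribution increments (used for
    percent-contribution diagnostics).
    """
    n_bg, k = F_bg.shape
    fbar = F_pres.mean(axis=0)
    lam = np.zeros(k)
    y = lam.copy()
    t_mom = 1.0
    step = 1.0
    obj, _, _ = _objective(lam, F_bg, fbar, beta)
    trace = [obj]
    contrib = np.zeros(k)
    converged = False

    def smooth_parts(v):
        eta = F_bg @ v
        ln_z = float(logsumexp(eta))
        g = ln_z - float(fbar @ v)
        grad = F_bg.T @ np.exp(eta - ln_z) - fbar
        return g, grad

    g_y, grad_y = smooth_parts(y)
    for _ in range(max_iter):
        # backtracking on the quadratic majorization at y
        while True:
            cand = np.sign(y - step * grad_y) * np.maximum(
                np.abs(y - step * grad_y) - step * beta, 0.0)
            d = cand - y
            g_c, _ = smooth_parts(cand)
            if g_c <= g_y + grad_y @ d + (d @ d) / (2 * step) + 1e-12:
                break
            step *= 0.5
            if step < 1e-14:
                break
        new_obj = g_c + float(beta @ np.abs(cand))
        # monotone restart: fall back to plain proximal step from lam if the
        # accelerated step overshoots
        if new_obj > trace[-1] + 1e-12:
            g_l, grad_l = smooth_parts(lam)
            cand2 = np.sign(lam - step * grad_l) * np.maximum(
                np.abs(lam - step * grad_l) - step * beta, 0.0)
            g_c2, _ = smooth_parts(cand2)
            new_obj2 = g_c2 + float(beta @ np.abs(cand2))
            if new_obj2 < new_obj:
                cand, new_obj = cand2, new_obj2
            t_mom = 1.0
        gain_inc = trace[-1] - new_obj
        dlam = np.abs(cand - lam)
        if dlam.sum() > 0 and gain_inc != 0.0:
            contrib += gain_inc * dlam / dlam.sum()
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2)) / 2.0
        y = cand + ((t_mom - 1.0) / t_next) * (cand - lam)
        lam, t_mom = cand, t_next
        g_y, grad_y = smooth_parts(y)
        trace.append(new_obj)
        step *= 1.3  # allow the step to grow back
        if abs(trace[-2] - trace[-1]) < tol * max(1.0, abs(trace[-1])):
            converged = True
            break

    eta = F_bg @ lam
    ln_z = float(logsumexp(eta))
    q = np.exp(eta - ln_z)
    info = {
        "converged": converged,
        "n_iter": len(trace) - 1,
        "objective": trace[-1],
        "trace": np.asarray(trace),
        "ln_z": ln_z,
        "q": q,
        "entropy": float(-(q * np.log(np.maximum(q, 1e-300))).sum()),
        "contrib": contrib,
        "fbar": fbar,
    }
    return lam, info


@dataclass
class MaxentModel:
    """A fitted maxent model: weights, scalings, normalizer, entropy."""

    expansion: FeatureExpansion
    weights: np.ndarray
    betas: np.ndarray
    reg_multiplier: float
    prevalence: float
    ln_z: float  # over the training background
    entropy: float
    gain: float  # regularized training gain (uniform model = 0)
    n_background: int
    n_presences: int
    converged: bool
    max_iter: int
    background_cells: np.ndarray | None = None
    feature_contrib: np.ndarray | None = None

    def linear_predictor(self, F: np.ndarray) -> np.ndarray:
        return F @ self.weights

    def raw_scores(self, F: np.ndarray) -> np.ndarray:
        """exp(η − lnZ_train): training-scale raw output per point."""
        return np.exp(self.linear_predictor(F) - self.ln_z)

    def logistic_scores(self, F: np.ndarray) -> np.ndarray:
        tau = self.prevalence
        s = np.exp(self.entropy) * self.raw_scores(F)
        return tau * s / (1.0 - tau + tau * s)

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str) -> None:
        doc = {
            "weights": self.weights.tolist(),
            "betas": self.betas.tolist(),
            "reg_multiplier": self.reg_multiplier,
            "prevalence": self.prevalence,
            "ln_z": self.ln_z,
            "entropy": self.entropy,
            "gain": self.gain,
            "n_background": self.n_background,
            "n_presences": self.n_presences,
            "converged": self.converged,
            "max_iter": self.max_iter,
            "feature_contrib": (self.feature_contrib.tolist()
                                if self.feature_contrib is not None else None),
            "expansion": {
                "variable_names": self.expansion.variable_names,
                "clamp_bounds": {k: list(v) for k, v in self.expansion.clamp_bounds.items()},
                "config": asdict(self.expansion.config),
                "features": [
                    {k: (v if not isinstance(v, tuple) else list(v))
                     for k, v in asdict(f).items()}
                    for f in self.expansion.features
                ],
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "MaxentModel":
        with open(path) as fh:
            doc = json.load(fh)
        exp_doc = doc["expansion"]
        feats = [Feature(name=f["name"], ftype=f["ftype"],
                         variables=tuple(f["variables"]), lo=f["lo"], hi=f["hi"],
                         knot=f["knot"], code=f["code"])
                 for f in exp_doc["features"]]
        expansion = FeatureExpansion(
            features=feats,
            variable_names=list(exp_doc["variable_names"]),
            clamp_bounds={k: tuple(v) for k, v in exp_doc["clamp_bounds"].items()},
            config=FeatureConfig(**exp_doc["config"]),
        )
        return cls(
            expansion=expansion,
            weights=np.asarray(doc["weights"]),
            betas=np.asarray(doc["betas"]),
            reg_multiplier=doc["reg_multiplier"],
            prevalence=doc["prevalence"],
            ln_z=doc["ln_z"],
            entropy=doc["entropy"],
            gain=doc["gain"],
            n_background=doc["n_background"],
            n_presences=doc["n_presences"],
            converged=doc["converged"],
            max_iter=doc["max_iter"],
            feature_contrib=(np.asarray(doc["feature_contrib"])
                             if doc["feature_contrib"] is not None else None),
        )


def fit(presences: PresenceSample, background: np.ndarray,
        features: FeatureExpansion, stack: Stack,
        reg_multiplier: float = 1.0, max_iter: int = DEFAULT_MAX_ITER,
        prevalence: float = DEFAULT_PREVALENCE, tol: float = DEFAULT_TOL,
        collapse_duplicates: bool = True) -> MaxentModel:
    """Fit the L1-regularized maxent model on background cells.

    ``background`` is an (N, 2) array of (row, col) cells.  Duplicate
    presences within one cell are collapsed to a single record by default.
    Deterministic given its inputs.
    """
    if presences.m < 2:
        raise ValueError("need at least 2 presence records")
    background = np.asarray(background)
    if background.ndim != 2 or background.shape[1] != 2 or len(background) == 0:
        raise ValueError("background must be a non-empty (N, 2) cell array")
    if features.n_features == 0:
        raise ValueError("empty feature expansion")
    if len(background) < presences.m and not collapse_duplicates:
        raise ValueError("background smaller than presence sample")
    presences.check_on_grid(stack.grid)

    pres_cells = presences.unique_cells() if collapse_duplicates else presences.cells
    F_bg = features.transform_stack(stack, cells=background)
    F_pres = features.transform_stack(stack, cells=pres_cells)
    betas = compute_betas(features, F_pres, reg_multiplier)
    lam, info = solve_maxent(F_bg, F_pres, betas, max_iter=max_iter, tol=tol)
    m = F_pres.shape[0]
    gain = (float(info["fbar"] @ lam) - info["ln_z"] + np.log(len(F_bg))
            - float(betas @ np.abs(lam)))
    return MaxentModel(
        expansion=features,
        weights=lam,
        betas=betas,
        reg_multiplier=reg_multiplier,
        prevalence=prevalence,
        ln_z=info["ln_z"],
        entropy=info["entropy"],
        gain=gain,
        n_background=len(F_bg),
        n_presences=m,
        converged=info["converged"],
        max_iter=max_iter,
        background_cells=background,
        feature_contrib=info["contrib"],
    )


def predict(model: MaxentModel, stack: Stack, output: str = "logistic",
            clamp: bool = True) -> Layer:
    """Evaluate the fitted model on every unmasked cell of a stack.

    ``raw`` renormalizes q over the prediction region (it sums to 1 there);
    ``logistic`` applies the prevalence/entropy transform to the training-
    scale raw output.  With ``clamp`` on, variables are truncated to their
    training range first.
    """
    if output not in ("raw", "logistic"):
        raise ValueError("output must be 'raw' or 'logistic'")
    grid = stack.grid
    F = model.expansion.transform_stack(stack, clamp=clamp)
    if output == "raw":
        eta = model.linear_predictor(F)
        vals = np.exp(eta - logsumexp(eta))
        units = None
    else:
        vals = model.logistic_scores(F)
        units = "probability"
    out = np.zeros(grid.shape)
    out[~grid.mask] = vals
    return Layer(grid=grid, name=f"risk_{output}", values=out, units=units)


def auc(scores_presence: np.ndarray, scores_background: np.ndarray) -> float:
    """Probability a random presence outscores a random background point.

    Rank-sum (Mann-Whitney) form; ties count one half.
    """
    sp = np.asarray(scores_presence, dtype=float).ravel()
    sb = np.asarray(scores_background, dtype=float).ravel()
    if sp.size == 0 or sb.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([sp, sb]))
    r_pres = ranks[: sp.size].sum()
    u = r_pres - sp.size * (sp.size + 1) / 2.0
    return float(u / (sp.size * sb.size))


def split_sample(presences: PresenceSample, test_fraction: float = 0.25,
                 seed: int | None = None) -> tuple[PresenceSample, PresenceSample]:
    """Random disjoint, exhaustive train/test partition of the presences."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    if presences.m < 4:
        raise ValueError("need at least 4 presences to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(presences.m)
    n_test = int(round(presences.m * test_fraction))
    n_test = min(max(n_test, 1), presences.m - 1)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return presences.subset(train_idx), presences.subset(test_idx)
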