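"""Model evaluation: cross-validation replicates, jackknife, importances.

Variable-importance diagnostics follow the presence-only modelling
conventions:

* *jackknife*: regularized training gain of the model fitted with each
  variable alone and with each variable omitted, against the full model;
* *percent contribution*: each variable's share of the gain increments
  accumulated while fitting, normalized to sum to 100;
* *permutation importance*: normalized drop in training AUC after permuting
  one variable's values across the presence + background points;
* *factorial selection*: per-group models plus backward elimination of
  variables whose removal barely changes the gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureConfig, build_features
from .maxent import (
    DEFAULT_MAX_ITER,
    MaxentModel,
    PresenceSample,
    auc,
    fit,
    predict,
    sample_background,
)
from .raster import Layer, Stack

__all__ = [
    "EvaluationReport",
    "evaluate",
    "replicate_cv",
    "jackknife",
    "variable_importance",
    "factorial_selection",
]


@dataclass
class EvaluationReport:
    """Evaluation bundle for one fitted model."""

    training_auc: float
    test_auc: float | None
    gain: float
    percent_contribution: dict[str, float]
    permutation_importance: dict[str, float]
    jackknife_gains: pd.DataFrame | None = None  # variable, gain_alone, gain_without
    full_gain: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in self.percent_contribution:
            rows.append({
                "variable": v,
                "percent_contribution": self.percent_contribution[v],
                "permutation_importance": self.permutation_importance.get(v, np.nan),
            })
        return pd.DataFrame(rows)


def _model_auc(model: MaxentModel, stack: Stack, presences: PresenceSample,
               background: np.ndarray) -> float:
    F_p = model.expansion.transform_stack(stack, cells=presences.cells, clamp=True)
    F_b = model.expansion.transform_stack(stack, cells=background, clamp=True)
    return auc(model.linear_predictor(F_p), model.linear_predictor(F_b))


def evaluate(model: MaxentModel, stack: Stack, train: PresenceSample,
             background: np.ndarray, test: PresenceSample | None = None,
             seed: int | None = None,
             with_jackknife: bool = False, **fit_kw) -> EvaluationReport:
    """Training/test AUC plus the variable-importance diagnostics."""
    contrib, perm = variable_importance(model, train, background, stack, seed=seed)
    jk = None
    full_gain = model.gain
    if with_jackknife:
        jk = jackknife(train, stack, background=background,
                       config=model.expansion.config,
                       reg_multiplier=model.reg_multiplier, **fit_kw)
    return EvaluationReport(
        training_auc=_model_auc(model, stack, train, background),
        test_auc=(_model_auc(model, stack, test, background)
                  if test is not None and test.m else None),
        gain=model.gain,
        percent_contribution=contrib,
        permutation_importance=perm,
        jackknife_gains=jk,
        full_gain=full_gain,
    )


def replicate_cv(presences: PresenceSample, stack: Stack, k: int = 10,
                 max_iter: int = DEFAULT_MAX_ITER, seed: int | None = None,
                 config: FeatureConfig | None = None,
                 reg_multiplier: float = 1.0,
                 background: np.ndarray | None = None,
                 ) -> tuple[list[MaxentModel], list[Layer], Layer]:
    """k-fold replicate models, their logistic predictions, and the mean map.

    The presences are split into k equal-sized groups (seeded); each
    replicate trains on k−1 groups.  The cell-wise mean of the replicate
    predictions is the map used downstream in the impact analysis.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if presences.m < k:
        raise ValueError("fewer presences than folds")
    rng = np.random.default_rng(seed)
    if background is None:
        background = sample_background(stack.grid, seed=int(rng.integers(2**31)))
    expansion = build_features(stack, config, background_cells=background)
    folds = np.arange(presences.m) % k
    rng.shuffle(folds)
    models, layers = [], []
    for fold in range(k):
        train = presences.subset(np.nonzero(folds != fold)[0])
        models.append(fit(train, background, expansion, stack,
                          reg_multiplier=reg_multiplier, max_iter=max_iter))
        layers.append(predict(models[-1], stack, output="logistic", clamp=True))
    mean_vals = np.mean([l.values for l in layers], axis=0)
    mean_vals[stack.grid.mask] = 0.0
    mean_layer = Layer(grid=stack.grid, name="risk_mean", values=mean_vals,
                       units="probability")
    return models, layers, mean_layer


def jackknife(presences: PresenceSample, stack: Stack,
              background: np.ndarray | None = None,
              config: FeatureConfig | None = None,
              reg_multiplier: float = 1.0, max_iter: int = DEFAULT_MAX_ITER,
              seed: int | None = None) -> pd.DataFrame:
    """Gain with each variable alone and omitted, plus the full-model gain.

    Returns a DataFrame with columns ``variable``, ``gain_alone``,
    ``gain_without`` and attribute column ``gain_full`` repeated per row.
    With a single variable only the full-model gain is meaningful.
    """
    if background is None:
        background = sample_background(stack.grid, seed=seed)

    def gain_of(sub: Stack) -> float:
        expansion = build_features(sub, config, background_cells=background)
        model = fit(presences, background, expansion, sub,
                    reg_multiplier=reg_multiplier, max_iter=max_iter)
        return model.gain

    full_gain = gain_of(stack)
    names = stack.names
    rows = []
    if len(names) < 2:
        return pd.DataFrame(
            [{"variable": names[0], "gain_alone": full_gain,
              "gain_without": 0.0, "gain_full": full_gain}])
    for name in names:
        alone = Stack([stack[name]])
        without = Stack([l for l in stack if l.name != name])
        rows.append({
            "variable": name,
            "gain_alone": gain_of(alone),
            "gain_without": gain_of(without),
            "gain_full": full_gain,
        })
    return pd.DataFrame(rows)


def variable_importance(model: MaxentModel, presences: PresenceSample,
                        background: np.ndarray, stack: Stack,
                        seed: int | None = None,
                        ) -> tuple[dict[str, float], dict[str, float]]:
    """(percent contribution, permutation importance) per variable.

    Percent contribution allocates the solver's per-iteration gain increments
    to variables (product features split evenly between their parents) and
    normalizes to 100.  Permutation importance permutes one variable's raw
    values across the pooled presence + background points, re-evaluates the
    training AUC, and normalizes the drops to sum to 100.
    """
    expansion = model.expansion
    names = [n for n in expansion.variable_names]
    # --- percent contribution
    contrib = {n: 0.0 for n in names}
    fc = model.feature_contrib
    if fc is None:
        fc = np.abs(model.weights)
    for j, feat in enumerate(expansion.features):
        share = max(float(fc[j]), 0.0)
        for v in feat.variables:
            contrib[v] += share / len(feat.variables)
    total = sum(contrib.values())
    if total > 0:
        contrib = {v: 100.0 * c / total for v, c in contrib.items()}
    else:
        contrib = {v: 100.0 / len(names) for v in names}

    # --- permutation importance
    rng = np.random.default_rng(seed)
    pres_cols = expansion.stack_columns(stack, cells=presences.cells)
    bg_cols = expansion.stack_columns(stack, cells=np.asarray(background))
    n_p = presences.m

    def scores(cols_p, cols_b):
        F_p = expansion.transform_columns(cols_p, clamp=True)
        F_b = expansion.transform_columns(cols_b, clamp=True)
        return model.linear_predictor(F_p), model.linear_predictor(F_b)

    base_auc = auc(*scores(pres_cols, bg_cols))
    drops = {}
    for v in names:
        pooled = np.concatenate([pres_cols[v], bg_cols[v]])
        perm = rng.permutation(pooled)
        cp = dict(pres_cols)
        cb = dict(bg_cols)
        cp[v] = perm[:n_p]
        cb[v] = perm[n_p:]
        drops[v] = max(base_auc - auc(*scores(cp, cb)), 0.0)
    total = sum(drops.values())
    if total > 0:
        perm_imp = {v: 100.0 * d / total for v, d in drops.items()}
    else:
        perm_imp = {v: 0.0 for v in names}
    return contrib, perm_imp


def factorial_selection(presences: PresenceSample, stack: Stack,
                        groups: dict[str, list[str]],
                        tolerance: float = 0.01,
                        background: np.ndarray | None = None,
                        config: FeatureConfig | None = None,
                        reg_multiplier: float = 1.0,
                        max_iter: int = DEFAULT_MAX_ITER,
                        seed: int | None = None) -> dict:
    """Grouped model comparison plus parsimony pruning of the variable set.

    Fits one model per named group and one with all grouped variables, then
    iteratively removes variables whose omission changes the full gain by
    less than ``tolerance``.  Returns per-configuration gain/AUC and the
    retained variable set.
    """
    if not groups:
        raise ValueError("no variable groups given")
    for gname, vars_ in groups.items():
        if not vars_:
            raise ValueError(f"empty group {gname!r}")
        for v in vars_:
            if v not in stack:
                raise KeyError(f"group {gname!r} references unknown variable {v!r}")
    all_vars = [v for vs in groups.values() for v in vs]
    if len(set(all_vars)) != len(all_vars):
        raise ValueError("groups must not overlap")
    if background is None:
        background = sample_background(stack.grid, seed=seed)

    def fit_on(names: list[str]) -> tuple[MaxentModel, float]:
        sub = Stack([stack[n] for n in names])
        expansion = build_features(sub, config, background_cells=background)
        model = fit(presences, background, expansion, sub,
                    reg_multiplier=reg_multiplier, max_iter=max_iter)
        return model, _model_auc(model, sub, presences, background)

    report: dict = {"groups": {}, "tolerance": tolerance}
    for gname, vs in groups.items():
        model, a = fit_on(vs)
        report["groups"][gname] = {"variables": vs, "gain": model.gain, "auc": a}

    retained = list(all_vars)
    model, a = fit_on(retained)
    report["full"] = {"variables": list(retained), "gain": model.gain, "auc": a}
    history = []
    while len(retained) > 1:
        full_gain = fit_on(retained)[0].gain
        deltas = {}
        for v in retained:
            rest = [x for x in retained if x != v]
            deltas[v] = full_gain - fit_on(rest)[0].gain
        removable = [v for v, d in deltas.items() if d < tolerance]
        if not removable:
            break
        # drop the least informative variable first, then re-assess
        drop = min(removable, key=lambda v: deltas[v])
        retained.remove(drop)
        history.append({"removed": drop, "gain_delta": deltas[drop]})
    # a retained set can legitimately end empty when nothing is informative
    if len(retained) == 1:
        full_gain = fit_on(retained)[0].gain
        if full_gain < tolerance:
            history.append({"removed": retained[0], "gain_delta": full_gain})
            retained = []
    if retained:
        model, a = fit_on(retained)
        report["retained_model"] = {"gain": model.gain, "auc": a}
    report["retained"] = retained
    report["history"] = history
    return report
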