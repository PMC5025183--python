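"""Config-driven orchestration of the full fire-risk analysis.

``run_pipeline`` sequences covariate generation (or loading), train/test
splitting, model fitting, evaluation (AUC, jackknife, importances,
specificity), scenario projection and impact accounting, writing every
artifact plus a JSON manifest (inputs, seeds, settings, checksums) that
suffices to reproduce deterministic outputs bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import __version__
from .features import FeatureConfig, build_features
from .impact import AGBStack, agb_loss, classify_risk, high_risk_area, \
    hotspot_monthly_histogram, zonal_stats
from .importance import evaluate, replicate_cv
from .maxent import PresenceSample, fit, sample_background, split_sample
from .raster import Stack, read_raster, write_raster
from .scenarios import project_scenario, specificity_validation
from .synthetic import LandscapeConfig, generate_landscape, make_scenario_fixture, \
    sample_hotspots

log = logging.getLogger("firerisk")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Settings of one pipeline run (see docs/methods.md for parameters)."""

    seed: int = 0
    n_presences: int = 2000
    test_fraction: float = 0.25
    reg_multiplier: float = 1.0
    max_iter: int = 500
    prevalence: float = 0.5
    replicates: int = 10
    scenario_modes: tuple = ("A_like", "B_like", "C_like")
    scenario_climates: tuple = ("wet", "dry")
    alpha_low: float = 0.7084
    alpha_high: float = 0.90
    threshold: float = 0.5
    landscape: dict = field(default_factory=dict)
    features: dict = field(default_factory=dict)
    stack_dir: str | None = None  # load covariates instead of simulating
    presences_csv: str | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_stack(stack_dir: str) -> Stack:
    layers = []
    for fname in sorted(os.listdir(stack_dir)):
        if fname.endswith((".asc", ".tif", ".tiff")):
            kind = "categorical" if fname.startswith("protected") else "continuous"
            layers.append(read_raster(os.path.join(stack_dir, fname), kind=kind))
    if not layers:
        raise FileNotFoundError(f"no rasters in {stack_dir}")
    return Stack(layers)


def run_pipeline(config: RunConfig, out_dir: str) -> dict:
    """Execute the full analysis; returns the manifest dict."""
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages": {},
        "outputs": {},
        "failed_stage": None,
    }
    rng = np.random.default_rng(config.seed)
    seeds = {name: int(rng.integers(2**31))
             for name in ("landscape", "hotspots", "split", "cv", "eval", "background")}
    manifest["seeds"] = seeds

    def emit(name: str, path: str):
        manifest["outputs"][name] = {"path": os.path.relpath(path, out_dir),
                                     "sha256": _sha256(path)}

    stage = "covariates"
    try:
        log.info("stage %s", stage)
        if config.stack_dir:
            stack = _load_stack(config.stack_dir)
            landscape = None
        else:
            landscape = generate_landscape(
                LandscapeConfig(**config.landscape), seed=seeds["landscape"])
            stack = landscape.stack
        for layer in stack:
            path = os.path.join(out_dir, f"covariate_{layer.name}.tif")
            write_raster(layer, path)
            emit(f"covariate_{layer.name}", path)
        manifest["stages"][stage] = "ok"

        stage = "presences"
        if config.presences_csv:
            presences = PresenceSample.from_csv(config.presences_csv)
        else:
            presences = sample_hotspots(landscape.truth, config.n_presences,
                                        seed=seeds["hotspots"])
        path = os.path.join(out_dir, "presences.csv")
        presences.to_csv(path)
        emit("presences", path)
        hist = hotspot_monthly_histogram(presences)
        manifest["stages"][stage] = {
            "n": presences.m,
            "peak_months": hist["peak_months"],
            "top2_fraction": hist["top2_fraction"],
        }

        stage = "fit"
        train, test = split_sample(presences, config.test_fraction,
                                   seed=seeds["split"])
        background = sample_background(stack.grid, seed=seeds["background"])
        fconf = FeatureConfig(**config.features)
        expansion = build_features(stack, fconf, background_cells=background)
        model = fit(train, background, expansion, stack,
                    reg_multiplier=config.reg_multiplier,
                    max_iter=config.max_iter, prevalence=config.prevalence)
        path = os.path.join(out_dir, "model.json")
        model.to_json(path)
        emit("model", path)
        manifest["stages"][stage] = {"gain": model.gain,
                                     "converged": model.converged}

        stage = "evaluate"
        report = evaluate(model, stack, train, background, test=test,
                          seed=seeds["eval"], with_jackknife=True,
                          max_iter=config.max_iter)
        path = os.path.join(out_dir, "importance.csv")
        report.to_frame().to_csv(path, index=False)
        emit("importance", path)
        path = os.path.join(out_dir, "jackknife.csv")
        report.jackknife_gains.to_csv(path, index=False)
        emit("jackknife", path)
        manifest["stages"][stage] = {"training_auc": report.training_auc,
                                     "test_auc": report.test_auc}

        stage = "replicates"
        models, _, mean_risk = replicate_cv(
            presences, stack, k=config.replicates, max_iter=config.max_iter,
            seed=seeds["cv"], config=fconf, background=background,
            reg_multiplier=config.reg_multiplier)
        path = os.path.join(out_dir, "risk_mean.tif")
        write_raster(mean_risk, path)
        emit("risk_mean", path)
        spec_table = specificity_validation(mean_risk, test)
        path = os.path.join(out_dir, "specificity.csv")
        spec_table.to_csv(path, index=False)
        emit("specificity", path)
        manifest["stages"][stage] = {
            "k": config.replicates,
            "high_risk_area_km2": high_risk_area(mean_risk, config.threshold),
            "test_fraction_above_05": spec_table.attrs["fraction_above_05"],
        }

        stage = "scenarios"
        scen_summary = {}
        scen_results = {}
        if landscape is not None:
            for mode in config.scenario_modes:
                for climate in config.scenario_climates:
                    spec = make_scenario_fixture(landscape, mode, climate)
                    res = project_scenario(models, spec, stack)
                    scen_results[spec.name] = res
                    path = os.path.join(out_dir, f"risk_{spec.name}.tif")
                    write_raster(res.mean_risk, path)
                    emit(f"risk_{spec.name}", path)
                    scen_summary[spec.name] = {
                        "high_risk_area_km2": res.high_risk_area_km2,
                        "clamped_fraction": res.clamped_fraction,
                    }
        manifest["stages"][stage] = scen_summary

        stage = "impact"
        impact_summary = {}
        if landscape is not None:
            agb = AGBStack(landscape.agb_layers)
            zones = stack["protected_areas"]
            targets = {"baseline": mean_risk}
            targets.update({n: r.mean_risk for n, r in scen_results.items()})
            for name, risk in targets.items():
                rc = classify_risk(risk)
                rep = agb_loss(risk, agb, config.alpha_low, config.alpha_high,
                               threshold=config.threshold)
                path = os.path.join(out_dir, f"impact_{name}_bins.csv")
                rep.per_bin.to_csv(path, index=False)
                emit(f"impact_{name}_bins", path)
                zs = zonal_stats(risk, zones, threshold=config.threshold)
                path = os.path.join(out_dir, f"impact_{name}_zones.csv")
                zs.to_csv(path, index=False)
                emit(f"impact_{name}_zones", path)
                impact_summary[name] = {
                    "class_areas_km2": rc.areas_km2,
                    "total_loss_tg": rep.total_loss_tg,
                    "loss_envelope_tg": [rep.total_loss_low_tg,
                                         rep.total_loss_high_tg],
                    "high_risk_area_km2": rep.high_risk_area_km2,
                }
        manifest["stages"][stage] = impact_summary
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = repr(exc)
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    path = os.path.join(out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
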