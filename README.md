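# firerisk

Presence-only maximum-entropy modelling of landscape fire risk, scenario
projection under land-use and climate change, and impact accounting
(risk classes, aboveground-biomass loss, zonal statistics) — built as a
tested, reusable pipeline for tropical dry-forest regions where fire
observations come from satellite active-fire detections (hotspots) with no
reliable absences.

## Who this is for

Landscape ecologists and fire analysts who have: gridded covariates
(land-cover fractions, distance to roads, settlement density, protected-area
categories, climate anomalies), a presence-only sample of fire locations,
and who want a probability-of-fire map they can project under alternative
development and climate scenarios and translate into burned-biomass
estimates. A synthetic-landscape generator with known ground truth makes
every stage testable without any external data.

## The model

Given presence cells and a background sample characterising the landscape,
the method estimates the distribution of maximum entropy

q(x) ∝ exp(Σⱼ λⱼ fⱼ(x))

over background cells, subject to the constraint that each environmental
feature's expectation under *q* matches its empirical presence average to
within an L1 budget βⱼ — equivalently, maximizing the penalized presence
log-likelihood (1/m) Σ ln q(x) − Σⱼ βⱼ|λⱼ|. Features are linear, quadratic
and hinge transforms of continuous covariates and indicators of categorical
ones, scaled to [0, 1] over background. The mapped output is the logistic
transform p = τe^H q / (1 − τ + τe^H q) with τ = 0.5 prevalence and H the
entropy of the fitted distribution, read as a relative probability of fire
presence in [0, 1].

Around the fitted model the pipeline provides: presence-background ROC/AUC
with a 25% random test split, 10-replicate cross-validated prediction maps,
jackknife gain per variable (alone/omitted), percent contribution and
permutation importance, factorial variable-group comparison with parsimony
pruning, scenario stacks built by swapping the dynamic layers
(deforestation, roads, protected areas, temperature and MCWD anomalies),
and impact accounting: risk classes (low/moderate/high/extreme quarters of
[0, 1]), high-risk area (p > 0.5), and potential biomass loss
B_l = (1 − α)·B_i with α ∈ [0.7084, 0.90] giving a central loss factor
0.196 ± 0.096.

Covariate construction includes the maximum climatological water deficit,
accumulated monthly as WDₙ = min(0, WDₙ₋₁ + Pₙ − 100 mm) and reported as
the most negative deficit of the hydrological year.

## Worked example

```python
from firerisk import (LandscapeConfig, generate_landscape, sample_hotspots,
                      sample_background, split_sample, build_features, fit,
                      predict, auc, jackknife, high_risk_area, agb_loss, AGBStack)

ls = generate_landscape(LandscapeConfig(), seed=1)       # 200x200 km, 1 km cells
presences = sample_hotspots(ls.truth, 2000, seed=2)      # known suitability
train, test = split_sample(presences, 0.25, seed=3)
background = sample_background(ls.stack.grid, seed=4)
expansion = build_features(ls.stack, background_cells=background)
model = fit(train, background, expansion, ls.stack)

F_test = expansion.transform_stack(ls.stack, cells=test.cells)
F_bg = expansion.transform_stack(ls.stack, cells=background)
print(f"test AUC {auc(model.linear_predictor(F_test), model.linear_predictor(F_bg)):.3f}")

risk = predict(model, ls.stack, output="logistic")
print(f"high-risk area {high_risk_area(risk):.0f} km^2")
report = agb_loss(risk, AGBStack(ls.agb_layers))
print(f"potential loss {report.total_loss_tg:.2f} Tg")
```

prints

```
test AUC 0.764
high-risk area 7998 km^2
potential loss 17.71 Tg
```

i.e. the model discriminates fire cells well above the 0.5 random baseline
(the generator's dominant drivers are road proximity, recent deforestation
and settlement density), about a fifth of the valid landscape is at high
fire risk (p > 0.5), and burning all of it once would release ~18 Tg of
aboveground biomass at the central loss factor (the envelope
[9.0, 26.4] Tg spans the α range). `jackknife(train, ls.stack,
background=background)` ranks road distance and deforestation as the most
informative single variables, matching the truth behind the fixture.

The same analysis is scriptable from the shell:

```
firerisk run --seed 1 --out results/run1           # full pipeline + manifest
firerisk simulate --seed 1 --out fixture/          # write a fixture directory
```

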