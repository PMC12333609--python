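# coastsdm

Dual-engine **presence-only habitat suitability modelling** for small
coastal study areas, built for the kind of data a marine protected-area
survey actually produces: a few dozen validated sightings from dedicated
boat surveys plus opportunistic citizen-science reports, a handful of
environmental raster layers, and strong, structured sampling bias.

The package implements, end to end:

- a raster data model with the standard predictor derivations (slope and
  aspect by Horn's 8-neighbor method, Euclidean distance surfaces,
  temporal means, bilinear resampling, Pearson correlation screening);
- **bias-corrected background sampling**: a Gaussian-KDE sampling-effort
  surface, focal-smoothed and constrained to a buffer around the sightings
  and the protected-area boundary, from which background / pseudo-absence
  points are drawn with the same spatial bias as the presences;
- a from-scratch **penalized-spline binomial GAM** with shrinkage
  smoothers (P-splines with a double penalty so uninformative terms shrink
  to zero), GCV-selected smoothing parameters, analytic prediction
  standard errors, partial-response curves, and leave-one-out
  deviance-drop variable importance;
- a from-scratch **maximum-entropy (MaxEnt-style) presence-only model**
  with linear, quadratic and hinge features, L1 regularization with a
  tunable multiplier `beta`, gain accounting, logistic output, percent
  contribution, permutation importance, and bootstrap uncertainty rasters;
- evaluation and tuning: Mann–Whitney AUC, the true skill statistic (TSS),
  stratified k-fold cross-validation, the (k, background-count) and
  (beta, background-count) tuning loops, per-cell mean/SE/CV uncertainty
  maps, and a citizen-science **ablation experiment**;
- a **synthetic-landscape generator** with known true suitability, so the
  whole pipeline is testable without any external data download.

## The models

With presences and pseudo-absences coded `y ∈ {0, 1}`, the GAM is a
binomial-logit additive model

    logit P(y = 1 | x) = β₀ + Σⱼ fⱼ(xⱼ),

each `fⱼ` a cubic B-spline with basis dimension `k` and a second-order
difference penalty `λⱼ βᵀSⱼβ` plus a shrinkage penalty `εⱼ` on the penalty
null space; `λⱼ, εⱼ` are chosen by GCV. Deviance explained is
`1 − D/D₀`, and AIC uses the effective degrees of freedom (trace of the
hat matrix).

MaxEnt estimates a distribution over background cells,
`P(x) ∝ exp(λ·f(x))`, maximizing the regularized training gain

    G(λ) = mean_presence(λ·f) − log Z(λ) + log N − Σⱼ βⱼ|λⱼ|,

with features `f` scaled to [0, 1] on the background and
`βⱼ = beta · cⱼ · sⱼ/√m`. The logistic output is `eᴴr/(1 + eᴴr)` with `r`
the raw output and `H` the entropy of the fitted distribution, so a
typical background cell scores 0.5.

## Worked example

```python
from coastsdm import (simulate_study, build_bias_surface, draw_background,
                      subsample_pseudo_absences, extract_design, build_smooth,
                      fit_gam, deviance_importance, cross_validate, gam_recipe,
                      maxent_recipe, fit_maxent, make_features,
                      percent_contribution)

stack, truth, sb, cb, occ = simulate_study(seed=0)   # 20 survey + 49 citizen
ms = stack.subset(["chl", "sst_anom", "slope", "dist_aqua"])
bias = build_bias_surface(occ, truth.study_area, ms.reference)
pool = draw_background(bias, 30000, seed=1)

pa = subsample_pseudo_absences(pool, len(occ), 1.0, seed=2)   # 1:1 ratio
design = extract_design(ms, occ.xy, pa.xy)
specs = [build_smooth(design.table[n].to_numpy(), 5, n) for n in ms.names]
fit = fit_gam(design, specs)
cv = cross_validate(gam_recipe(k=5), design, 10, seed=3)
```

prints, with the importance and MaxEnt steps added:

```
occurrences: 69 {'citizen': 49, 'survey': 20}
GAM deviance explained: 0.532  AIC: 103.1
GAM 10-fold CV AUC: 0.847 +/- 0.069
predictor  deviance_explained_drop  proportion_of_total
dist_aqua                   13.847                0.260
      chl                   13.355                0.251
 sst_anom                    0.776                0.015
    slope                    0.248                0.005
MaxEnt gains (reg/unreg): 1.525 / 1.668
MaxEnt 10-fold CV AUC: 0.899
predictor  percent_contribution
      chl                  84.3
dist_aqua                  12.0
 sst_anom                   2.0
    slope                   1.6
```

Both engines discriminate presences from bias-matched background well
(AUC ≈ 0.85–0.90), and both attribute most of the signal to the
chlorophyll-a and distance-to-aquaculture drivers that generated the
landscape — the qualitative pattern a field analyst would look for before
trusting either map. The drop/contribution tables are not comparable
across engines; each is normalized within its own accounting.

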