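"""Discrimination metrics, cross-validation, tuning loops, uncertainty
maps, and the citizen-science ablation experiment."""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._rng import derive_seed
from .design import SdmDesign, extract_design
from .gam import build_smooth, fit_gam, predict_gam
from .grid import FeatureGeometry, InvalidInputError, PredictorStack, RasterGrid
from .maxent import bootstrap_predict, fit_maxent, make_features, predict_maxent
from .occurrences import (
    BackgroundSet,
    OccurrenceSet,
    build_bias_surface,
    draw_background,
    stratified_kfold,
    subsample_pseudo_absences,
)

__all__ = [
    "EvalResult",
    "TuningRecord",
    "UncertaintyMaps",
    "ModelSettings",
    "auc",
    "tss",
    "gam_recipe",
    "maxent_recipe",
    "cross_validate",
    "tune_gam",
    "tune_maxent",
    "uncertainty_maps",
    "ablation_citizen_science",
]


@dataclass
class EvalResult:
    auc: float
    tss: float
    tss_threshold: float
    n_pos: int
    n_neg: int


@dataclass
class UncertaintyMaps:
    mean: RasterGrid
    standard_error: RasterGrid
    coefficient_of_variation: RasterGrid  # percent
    mode: str  # "replicate" | "analytic"; CV values are not comparable across modes


@dataclass
class ModelSettings:
    """Fixed pipeline presets for the emulated survey design."""

    pool_size: int = 30000
    bandwidth: float = 6000.0
    buffer: float = 2000.0
    focal_window: int = 3
    gam_ratio: float = 1.0          # presences : pseudo-absences = 1 : ratio
    gam_k: int = 5
    maxent_background: int = 8000
    maxent_beta: float = 1.0
    maxent_iterations: int = 500
    n_hinge_knots: int = 30
    n_folds: int = 10
    bootstrap_replicates: int = 500
    predictors: list[str] | None = None   # None = all stack layers


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def auc(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """Mann-Whitney AUC: P(random positive outranks random negative), ties 0.5."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise InvalidInputError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def tss(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> tuple[float, float]:
    """Max over thresholds of sensitivity + specificity - 1.

    Candidate thresholds are midpoints between adjacent distinct pooled
    scores plus sentinels below/above all scores; "positive" means
    score >= threshold.  Returns (tss, smallest maximizing threshold).
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise InvalidInputError("both score lists must be non-empty")
    uniq = np.unique(np.concatenate([pos, neg]))
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cands = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    sens = (pos[:, None] >= cands[None, :]).mean(axis=0)
    spec = (neg[:, None] < cands[None, :]).mean(axis=0)
    scores = sens + spec - 1.0
    best = scores.max()
    thr = float(cands[np.flatnonzero(np.isclose(scores, best))[0]])
    return float(best), thr


# ---------------------------------------------------------------------------
# Model recipes + cross-validation
# ---------------------------------------------------------------------------

def gam_recipe(k: int = 5, **fit_kwargs) -> Callable:
    """A recipe fitting a shrinkage-smoother GAM on the training design."""

    def fit(train: SdmDesign) -> Callable[[pd.DataFrame], np.ndarray]:
        specs = []
        for name in train.predictor_names:
            vals = train.table[name].to_numpy(float)
            kk = min(k, np.unique(vals).size)
            if kk < 3:
                continue
            specs.append(build_smooth(vals, kk, name))
        model = fit_gam(train, specs, keep_design=False, **fit_kwargs)
        return model.predict_table

    return fit


def maxent_recipe(beta: float = 1.0, n_hinge_knots: int = 30,
                  iterations: int = 500) -> Callable:
    """A recipe fitting MaxEnt on the presences/background of the design."""

    def fit(train: SdmDesign) -> Callable[[pd.DataFrame], np.ndarray]:
        pres, bg = train.presences(), train.background()
        feats = make_features(pres, bg, n_hinge_knots)
        model = fit_maxent(pres, bg, feats, beta=beta, iterations=iterations)

        def score(table: pd.DataFrame) -> np.ndarray:
            return model.logistic(table)

        return score

    return fit


def cross_validate(model_recipe: Callable, design: SdmDesign, k: int, seed: int) -> dict:
    """k-fold stratified CV; returns mean/SE of AUC plus per-fold results.

    Folds whose test part lacks a class are skipped (logged in the report).
    """
    folds = stratified_kfold(design.labels, k, seed)
    results: list[EvalResult] = []
    skipped = 0
    for f in range(k):
        test_mask = folds.test_mask(f)
        test = design.subset_rows(test_mask)
        train = design.subset_rows(~test_mask)
        if len(np.unique(test.labels)) < 2 or len(np.unique(train.labels)) < 2:
            skipped += 1
            continue
        score = model_recipe(train)
        s = np.asarray(score(test.table), dtype=float)
        pos, neg = s[test.labels == 1], s[test.labels == 0]
        t, thr = tss(pos, neg)
        results.append(EvalResult(auc(pos, neg), t, thr, len(pos), len(neg)))
    if not results:
        raise InvalidInputError("every fold was degenerate")
    aucs = np.array([r.auc for r in results])
    return {
        "mean_auc": float(aucs.mean()),
        "se_auc": float(aucs.std(ddof=1) / np.sqrt(len(aucs))) if len(aucs) > 1 else 0.0,
        "mean_tss": float(np.mean([r.tss for r in results])),
        "folds": results,
        "skipped_folds": skipped,
    }


# ---------------------------------------------------------------------------
# Tuning loops
# ---------------------------------------------------------------------------

@dataclass
class TuningRecord:
    model: str
    setting: dict
    repeat: int
    auc: float
    tss: float


def _split_90_10(design: SdmDesign, seed: int) -> tuple[SdmDesign, SdmDesign]:
    folds = stratified_kfold(design.labels, 10, seed)
    test_mask = folds.test_mask(0)
    return design.subset_rows(~test_mask), design.subset_rows(test_mask)


def _tune(
    model_name: str,
    recipe_for: Callable[[dict], Callable],
    make_design: Callable[[dict, int], SdmDesign],
    settings: list[dict],
    repeats: int,
    seed: int,
) -> tuple[pd.DataFrame, dict]:
    records = []
    counter = 0
    for setting in settings:
        for rep in range(repeats):
            counter += 1
            rep_seed = derive_seed(seed, f"tune-{model_name}", counter)
            design = make_design(setting, rep_seed)
            train, test = _split_90_10(design, derive_seed(rep_seed, "split"))
            try:
                score = recipe_for(setting)(train)
                s = np.asarray(score(test.table), dtype=float)
                pos, neg = s[test.labels == 1], s[test.labels == 0]
                if pos.size == 0 or neg.size == 0:
                    continue
                t, _ = tss(pos, neg)
                records.append(TuningRecord(model_name, dict(setting), rep, auc(pos, neg), t))
            except InvalidInputError:
                continue
    table = pd.DataFrame(
        [{**r.setting, "model": r.model, "repeat": r.repeat, "auc": r.auc, "tss": r.tss}
         for r in records]
    )
    selected = _select_setting(table, list(settings[0].keys()))
    return table, selected


def _select_setting(table: pd.DataFrame, keys: list[str]) -> dict:
    """Max mean AUC subject to mean TSS within 0.02 of its maximum;
    ties break toward smaller setting values (k first, then count)."""
    means = table.groupby(keys, as_index=False).agg(auc=("auc", "mean"), tss=("tss", "mean"))
    eligible = means[means["tss"] >= means["tss"].max() - 0.02]
    if eligible.empty:
        eligible = means
    best_auc = eligible["auc"].max()
    top = eligible[np.isclose(eligible["auc"], best_auc)]
    top = top.sort_values(keys)
    return {k: top.iloc[0][k].item() if hasattr(top.iloc[0][k], "item") else top.iloc[0][k]
            for k in keys}


def tune_gam(
    presences_xy: tuple[np.ndarray, np.ndarray],
    pool: BackgroundSet,
    stack: PredictorStack,
    k_values: Sequence[int] = (3, 5, 10),
    bg_count_range: tuple[int, int] = (30, 250),
    n_bg_candidates: int = 30,
    repeats: int = 50,
    seed: int = 0,
    lambda_grid: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Grid of (k, pseudo-absence count) x repeats, scored by test AUC/TSS.

    Pseudo-absence counts are ``n_bg_candidates`` values sampled uniformly
    from ``bg_count_range``; each repeat redraws the pseudo-absences from
    the pool and makes a fresh 90/10 stratified split.
    """
    rng = np.random.default_rng(derive_seed(seed, "gam-bg-candidates"))
    bg_counts = np.sort(rng.integers(bg_count_range[0], bg_count_range[1] + 1,
                                     size=n_bg_candidates))
    settings = [{"k": int(k), "n_background": int(b)} for k in k_values for b in bg_counts]

    def make_design(setting: dict, rep_seed: int) -> SdmDesign:
        n = setting["n_background"]
        idx = np.random.default_rng(rep_seed).choice(len(pool), size=n, replace=False)
        bg = pool.points.iloc[idx]
        return extract_design(stack, presences_xy, (bg["x"].to_numpy(), bg["y"].to_numpy()))

    def recipe_for(setting: dict) -> Callable:
        return gam_recipe(k=setting["k"], lambda_grid=lambda_grid)

    return _tune("gam", recipe_for, make_design, settings, repeats, seed)


def tune_maxent(
    presences_xy: tuple[np.ndarray, np.ndarray],
    pool: BackgroundSet,
    stack: PredictorStack,
    bg_count_range: tuple[int, int] = (1000, 12000),
    n_bg_candidates: int = 30,
    beta_values: Sequence[float] = (1, 2, 3, 4, 5),
    repeats: int = 50,
    seed: int = 0,
    n_hinge_knots: int = 30,
    iterations: int = 500,
) -> tuple[pd.DataFrame, dict]:
    rng = np.random.default_rng(derive_seed(seed, "maxent-bg-candidates"))
    hi = min(bg_count_range[1], len(pool))
    bg_counts = np.sort(rng.integers(bg_count_range[0], hi + 1, size=n_bg_candidates))
    settings = [{"beta": float(b), "n_background": int(n)}
                for b in beta_values for n in bg_counts]

    def make_design(setting: dict, rep_seed: int) -> SdmDesign:
        n = setting["n_background"]
        idx = np.random.default_rng(rep_seed).choice(len(pool), size=n, replace=False)
        bg = pool.points.iloc[idx]
        return extract_design(stack, presences_xy, (bg["x"].to_numpy(), bg["y"].to_numpy()))

    def recipe_for(setting: dict) -> Callable:
        return maxent_recipe(beta=setting["beta"], n_hinge_knots=n_hinge_knots,
                             iterations=iterations)

    return _tune("maxent", recipe_for, make_design, settings, repeats, seed)


# ---------------------------------------------------------------------------
# Uncertainty maps
# ---------------------------------------------------------------------------

def uncertainty_maps(
    replicates: Sequence[RasterGrid] | None = None,
    analytic: tuple[RasterGrid, RasterGrid] | None = None,
) -> UncertaintyMaps:
    """Per-cell mean / SE / CV(%) from replicates or an analytic pair.

    Replicate mode: SE = sd/sqrt(R) but CV = 100*sd/mean, so CV describes
    prediction variability rather than uncertainty of the mean.  Analytic
    mode passes mean and SE through with CV = 100*SE/mean.  The two modes
    are labelled and are not comparable with each other.
    """
    if analytic is not None:
        mean_g, se_g = analytic
        dispersion = se_g.values
        mode = "analytic"
    else:
        reps = list(replicates or [])
        if len(reps) < 2:
            raise InvalidInputError("replicate mode needs at least two replicates")
        ref = reps[0]
        vals = np.stack([np.where(r.nodata_mask, np.nan, r.values) for r in reps])
        import warnings

        with warnings.catch_warnings():
            # all-NaN cells (outside every replicate) are masked below
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_v = np.nanmean(vals, axis=0)
            sd = np.nanstd(vals, axis=0, ddof=1)
        mask = np.all(np.isnan(vals), axis=0) | ref.nodata_mask
        mean_g = ref.with_values(np.where(mask, np.nan, mean_v), mask)
        se_g = ref.with_values(np.where(mask, np.nan, sd / np.sqrt(len(reps))), mask)
        dispersion = sd
        mode = "replicate"

    mean_v = mean_g.values
    cv = np.full(mean_g.shape, np.nan)
    ok = ~mean_g.nodata_mask & (mean_v > 1e-9)
    cv[ok] = 100.0 * dispersion[ok] / mean_v[ok]
    cv_mask = mean_g.nodata_mask | ~ok
    return UncertaintyMaps(mean_g, se_g, mean_g.with_values(cv, cv_mask), mode)


# ---------------------------------------------------------------------------
# End-to-end engine run + citizen-science ablation
# ---------------------------------------------------------------------------

def run_engines(
    occ: OccurrenceSet,
    stack: PredictorStack,
    sac: FeatureGeometry,
    settings: ModelSettings,
    seed: int,
) -> dict:
    """Bias surface -> background pool -> both engines -> CV + uncertainty."""
    names = settings.predictors or stack.names
    model_stack = stack.subset(names)
    ref = model_stack.reference

    bias = build_bias_surface(occ, sac, ref, settings.bandwidth,
                              settings.buffer, settings.focal_window)
    pool = draw_background(bias, settings.pool_size, derive_seed(seed, "pool"))

    out: dict = {"bias": bias, "pool_size": len(pool), "n_presences": len(occ)}
    px, py = occ.xy

    # --- GAM: 1:ratio pseudo-absences -------------------------------------
    pa = subsample_pseudo_absences(pool, len(occ), settings.gam_ratio,
                                   derive_seed(seed, "pseudo-absences"))
    gam_design = extract_design(model_stack, (px, py), pa.xy)
    specs = [build_smooth(gam_design.table[n].to_numpy(float), settings.gam_k, n)
             for n in gam_design.predictor_names]
    gam_fit = fit_gam(gam_design, specs)
    gam_cv = cross_validate(gam_recipe(k=settings.gam_k), gam_design,
                            settings.n_folds, derive_seed(seed, "gam-cv"))
    prob, se = predict_gam(gam_fit, model_stack)
    gam_unc = uncertainty_maps(analytic=(prob, se))
    out["gam"] = {"fit": gam_fit, "design": gam_design, "cv": gam_cv,
                  "prediction": prob, "uncertainty": gam_unc}

    # --- MaxEnt: large background, beta preset ----------------------------
    mx_bg = subsample_pseudo_absences(
        pool, settings.maxent_background, 1.0, derive_seed(seed, "maxent-bg")
    ) if settings.maxent_background < len(pool) else pool
    mx_design = extract_design(model_stack, (px, py), mx_bg.xy)
    pres, bg = mx_design.presences(), mx_design.background()
    feats = make_features(pres, bg, settings.n_hinge_knots)
    mx_fit = fit_maxent(pres, bg, feats, beta=settings.maxent_beta,
                        iterations=settings.maxent_iterations)
    mx_cv = cross_validate(
        maxent_recipe(settings.maxent_beta, settings.n_hinge_knots,
                      settings.maxent_iterations),
        mx_design, settings.n_folds, derive_seed(seed, "maxent-cv"))
    raw, logistic = predict_maxent(mx_fit, model_stack)
    reps = bootstrap_predict(pres, bg, feats, model_stack,
                             n_replicates=settings.bootstrap_replicates,
                             beta=settings.maxent_beta,
                             seed=derive_seed(seed, "maxent-boot"),
                             iterations=settings.maxent_iterations)
    mx_unc = uncertainty_maps(replicates=reps)
    out["maxent"] = {"fit": mx_fit, "design": mx_design, "cv": mx_cv,
                     "prediction": logistic, "raw": raw, "uncertainty": mx_unc}
    return out


def _summary(run: dict) -> dict:
    def mean_cv(unc: UncertaintyMaps) -> float:
        return float(np.nanmean(unc.coefficient_of_variation.values))

    return {
        engine: {
            "mean_auc": run[engine]["cv"]["mean_auc"],
            "mean_tss": run[engine]["cv"]["mean_tss"],
            "mean_cv_percent": mean_cv(run[engine]["uncertainty"]),
        }
        for engine in ("gam", "maxent")
    }


def ablation_citizen_science(
    full: OccurrenceSet,
    stack: PredictorStack,
    sac: FeatureGeometry,
    settings: ModelSettings,
    seed: int,
) -> dict:
    """Run the pipeline on all records and on survey-only records.

    Every model setting is held fixed between the two runs; the report
    carries per-run AUC/TSS/CV summaries and per-cell suitability
    difference rasters (full minus survey-only) for both engines.
    """
    survey_only = full.subset_source("survey")
    runs = {}
    for name, occ in (("full", full), ("survey_only", survey_only)):
        try:
            runs[name] = run_engines(occ, stack, sac, settings, seed)
        except InvalidInputError as err:
            runs[name] = {"failed": str(err)}
    report = {"runs": runs, "summaries": {}}
    for name, run in runs.items():
        if "failed" not in run:
            report["summaries"][name] = _summary(run)
    if all("failed" not in r for r in runs.values()):
        for engine in ("gam", "maxent"):
            a = runs["full"][engine]["prediction"]
            b = runs["survey_only"][engine]["prediction"]
            report[f"{engine}_difference"] = a.with_values(a.values - b.values)
    return report
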