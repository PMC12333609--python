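"""Predictor pruning: pairwise-correlation + single-variable-AIC rule,
and a post-fit concurvity diagnostic for the GAM."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .design import SdmDesign
from .gam import GamFit, build_smooth, fit_gam
from .grid import InvalidInputError, PredictorStack

__all__ = ["SelectionReport", "prune_collinear", "concurvity_index"]


@dataclass
class SelectionReport:
    retained: list[str]
    removed: list[dict] = field(default_factory=list)
    concurvity: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"retained": self.retained, "removed": self.removed,
             "concurvity": self.concurvity},
            indent=2,
        )

    def to_text(self) -> str:
        lines = ["Retained predictors: " + ", ".join(self.retained)]
        for r in self.removed:
            lines.append(
                f"removed {r['name']} (|r|={r['r']:.3f} with {r['partner']}; "
                f"AIC removed={r['aic_removed']:.2f} vs kept={r['aic_kept']:.2f}"
                + ("; lexicographic tie-break" if r.get("tie_break") else "")
                + ")"
            )
        for name, v in self.concurvity.items():
            lines.append(f"concurvity[{name}] = {v:.3f}")
        return "\n".join(lines)


def _single_variable_aic(design: SdmDesign, name: str, k: int) -> float:
    sub = design.subset_predictors([name])
    spec = build_smooth(sub.table[name].to_numpy(float), k=k, predictor=name)
    fit = fit_gam(sub, [spec], keep_design=False)
    return fit.aic


def prune_collinear(
    stack: PredictorStack,
    design: SdmDesign,
    threshold: float = 0.7,
    k: int = 5,
    aic_tol: float = 1e-6,
) -> SelectionReport:
    """Iteratively drop one of each |r| > threshold pair.

    Pairs are processed in descending |r|.  For the offending pair, two
    single-predictor binomial GAMs are fit on ``design`` and the predictor
    whose model has the higher AIC is removed; exact AIC ties (within
    ``aic_tol``) break lexicographically by predictor name.
    """
    from .grid import pairwise_correlation

    retained = [n for n in stack.names if n in design.predictor_names]
    if len(retained) < 2:
        raise InvalidInputError("need at least two predictors to prune")
    removed: list[dict] = []
    aic_cache: dict[str, float] = {}

    def aic_of(name: str) -> float:
        if name not in aic_cache:
            aic_cache[name] = _single_variable_aic(design, name, k)
        return aic_cache[name]

    while len(retained) >= 2:
        corr = pairwise_correlation(stack.subset(retained))
        r = corr.to_numpy()
        np.fill_diagonal(r, 0.0)
        absr = np.abs(np.nan_to_num(r, nan=0.0))
        if absr.max() <= threshold:
            break
        i, j = np.unravel_index(np.argmax(absr), absr.shape)
        a, b = retained[i], retained[j]
        aic_a, aic_b = aic_of(a), aic_of(b)
        tie = abs(aic_a - aic_b) <= aic_tol
        if tie:
            drop, keep = max(a, b), min(a, b)
        elif aic_a > aic_b:
            drop, keep = a, b
        else:
            drop, keep = b, a
        removed.append({
            "name": drop, "partner": keep, "r": float(r[i, j]),
            "aic_removed": float(aic_of(drop)), "aic_kept": float(aic_of(keep)),
            "tie_break": bool(tie),
        })
        retained.remove(drop)
    return SelectionReport(retained=retained, removed=removed)


def concurvity_index(fit: GamFit) -> dict[str, float]:
    """Per-term proportion of the fitted contribution explained by the rest.

    For each smooth, the fitted term contribution over the training rows is
    projected onto the column span of all other terms' (centered) bases plus
    the intercept; the index is ``||projection||^2 / ||contribution||^2``,
    in [0, 1].  A single-term model returns 0 for its term.
    """
    if fit.X_train is None:
        raise InvalidInputError("fit was built with keep_design=False")
    X = fit.X_train
    out: dict[str, float] = {}
    for spec, sl in zip(fit.specs, fit.term_slices):
        g = X[:, sl] @ fit.beta[sl]
        norm2 = float(g @ g)
        if len(fit.specs) == 1 or norm2 <= 1e-12:
            out[spec.predictor] = 0.0
            continue
        other_cols = [np.ones((X.shape[0], 1))]
        for sp2, sl2 in zip(fit.specs, fit.term_slices):
            if sp2.predictor != spec.predictor:
                other_cols.append(X[:, sl2])
        Z = np.column_stack(other_cols)
        coef, *_ = np.linalg.lstsq(Z, g, rcond=None)
        proj = Z @ coef
        out[spec.predictor] = float(np.clip((proj @ proj) / norm2, 0.0, 1.0))
    return out
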