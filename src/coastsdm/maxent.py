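"""Presence-only maximum-entropy habitat model (linear/quadratic/hinge).

The model estimates a probability distribution over background cells that
maximizes entropy subject to the fitted feature expectations staying close
to the presence-sample means; closeness is enforced softly through an L1
penalty, whose scale is the "beta" regularization multiplier.  Features
are min-max scaled to [0, 1] on the background: one linear and one
quadratic feature per predictor plus forward and reverse hinges at evenly
spaced background quantiles.  Product and threshold features are never
generated.  Optimization is cyclic coordinate ascent with exact 1-D
soft-threshold Newton steps and backtracking, so the regularized gain is
non-decreasing.

Outputs follow the conventional presence-only conventions: the *raw*
output is the fitted distribution over background; the *logistic* output
is ``e^H r / (1 + e^H r)`` with ``H`` the entropy of the fitted raw
distribution, which equals 0.5 at a typical background cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import SdmDesign
from .grid import InvalidInputError, PredictorStack, RasterGrid

__all__ = [
    "FeatureDef",
    "FeatureSet",
    "MaxentFit",
    "make_features",
    "fit_maxent",
    "predict_maxent",
    "percent_contribution",
    "permutation_importance",
    "bootstrap_predict",
]

_CLASS_CONST = {"linear": 1.0, "quadratic": 1.0, "hinge_forward": 0.5, "hinge_reverse": 0.5}


@dataclass(frozen=True)
class FeatureDef:
    """One scaled feature: maps a parent predictor into [0, 1]."""

    parent: str
    kind: str  # linear | quadratic | hinge_forward | hinge_reverse
    lo: float  # background min of the transformed quantity
    hi: float  # background max of the transformed quantity
    knot: float | None = None

    @property
    def name(self) -> str:
        if self.kind.startswith("hinge"):
            return f"{self.kind}({self.parent}@{self.knot:.6g})"
        return f"{self.kind}({self.parent})"

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), *self._clip_range())
        if self.kind == "linear":
            return (x - self.lo) / (self.hi - self.lo)
        if self.kind == "quadratic":
            return (x * x - self.lo) / (self.hi - self.lo)
        if self.kind == "hinge_forward":
            return np.maximum(0.0, (x - self.knot) / (self.hi - self.knot))
        if self.kind == "hinge_reverse":
            return np.maximum(0.0, (self.knot - x) / (self.knot - self.lo))
        raise InvalidInputError(f"unknown feature kind {self.kind!r}")

    def _clip_range(self) -> tuple[float, float]:
        if self.kind == "quadratic":
            # lo/hi are bounds of x^2; clamp x so x^2 lands inside them
            m = np.sqrt(self.hi)
            return (-m, m)
        return (self.lo, self.hi)


@dataclass
class FeatureSet:
    features: list[FeatureDef]
    parents: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.parents:
            seen = dict.fromkeys(f.parent for f in self.features)
            self.parents = list(seen)

    def __len__(self) -> int:
        return len(self.features)

    def matrix(self, table: pd.DataFrame) -> np.ndarray:
        cols = [f.transform(table[f.parent].to_numpy(float)) for f in self.features]
        return np.column_stack(cols) if cols else np.empty((len(table), 0))


def make_features(
    design: SdmDesign, background: SdmDesign, n_hinge_knots: int = 30
) -> FeatureSet:
    """Linear + quadratic + hinge features scaled on the background sample."""
    if len(background) == 0:
        raise InvalidInputError("background must be non-empty")
    feats: list[FeatureDef] = []
    for name in design.predictor_names:
        bg = background.table[name].to_numpy(float)
        lo, hi = float(bg.min()), float(bg.max())
        if hi - lo <= 1e-12:
            continue  # constant predictor: all its features are degenerate
        feats.append(FeatureDef(name, "linear", lo, hi))
        sq = bg * bg
        qlo, qhi = float(sq.min()), float(sq.max())
        if qhi - qlo > 1e-12:
            feats.append(FeatureDef(name, "quadratic", qlo, qhi))
        if n_hinge_knots > 0:
            qs = np.linspace(0, 1, n_hinge_knots + 2)[1:-1]
            for t in np.quantile(bg, qs):
                t = float(t)
                if hi - t > 1e-9 * (hi - lo):
                    feats.append(FeatureDef(name, "hinge_forward", lo, hi, knot=t))
                if t - lo > 1e-9 * (hi - lo):
                    feats.append(FeatureDef(name, "hinge_reverse", lo, hi, knot=t))
    # de-duplicate identical hinge knots arising from tied quantiles
    feats = list(dict.fromkeys(feats))
    return FeatureSet(feats, list(design.predictor_names))


@dataclass
class MaxentFit:
    feature_set: FeatureSet
    lambdas: np.ndarray
    beta_multiplier: float
    reg_amounts: np.ndarray          # per-feature L1 penalty scales beta_j
    log_partition: float             # log sum over background of exp(eta)
    entropy: float                   # H of the fitted raw distribution
    regularized_gain: float
    unregularized_gain: float
    n_presence: int
    n_background: int
    contribution_trace: list[tuple[int, float]]  # (feature index, gain change)
    converged: bool
    n_cycles: int
    cycle_gains: list[float] | None = None  # regularized gain after each cycle

    def eta(self, table: pd.DataFrame) -> np.ndarray:
        return self.feature_set.matrix(table) @ self.lambdas

    def raw(self, table: pd.DataFrame) -> np.ndarray:
        """Raw output: sums to 1 over the training background."""
        return np.exp(self.eta(table) - self.log_partition)

    def logistic(self, table: pd.DataFrame) -> np.ndarray:
        r = self.raw(table) * np.exp(self.entropy)
        return r / (1.0 + r)

    def to_lambdas_text(self) -> str:
        lines = [
            f"{f.name}, {lam:.10g}, {f.lo:.10g}, {f.hi:.10g}"
            for f, lam in zip(self.feature_set.features, self.lambdas)
        ]
        lines.append(f"entropy, {self.entropy:.10g}")
        lines.append(f"logPartition, {self.log_partition:.10g}")
        return "\n".join(lines)


def fit_maxent(
    presences: SdmDesign,
    background: SdmDesign,
    features: FeatureSet,
    beta: float = 1.0,
    iterations: int = 500,
    tol: float = 1e-7,
) -> MaxentFit:
    """Maximize the L1-regularized gain by cyclic coordinate ascent.

    The gain is ``mean_presence(eta) - log Z + log N - sum_j beta_j |lambda_j|``
    with ``Z`` the sum of ``exp(eta)`` over the N background points, so the
    uniform model scores 0.  Per-feature penalties are
    ``beta * c_class * max(s_j, 1e-3) / sqrt(m)`` with ``s_j`` the presence
    standard deviation of feature j and m the presence count.  ``iterations``
    caps the number of full coordinate cycles.
    """
    if beta < 0:
        raise InvalidInputError("beta must be non-negative")
    m, N = len(presences), len(background)
    if m < 1:
        raise InvalidInputError("need at least one presence")
    if N < 2:
        raise InvalidInputError("need at least two background points")

    Fp = features.matrix(presences.table)
    Fb = np.asfortranarray(features.matrix(background.table))
    J = len(features)
    pbar = Fp.mean(axis=0) if J else np.empty(0)
    s = Fp.std(axis=0, ddof=1) if m > 1 else np.zeros(J)
    cls = np.array([_CLASS_CONST[f.kind] for f in features.features]) if J else np.empty(0)
    beta_j = beta * cls * np.maximum(s, 1e-3) / np.sqrt(m)

    lam = np.zeros(J)
    eta = np.zeros(N)
    logN = np.log(N)

    def log_partition(e: np.ndarray) -> float:
        c = e.max() if e.size else 0.0
        return float(c + np.log(np.exp(e - c).sum()))

    logZ = log_partition(eta)

    def gain(lam_v: np.ndarray, logZ_v: float) -> float:
        return float(pbar @ lam_v - logZ_v + logN - beta_j @ np.abs(lam_v))

    G = gain(lam, logZ)
    trace: list[tuple[int, float]] = []
    cycle_gains: list[float] = []
    converged = False
    n_cycles = 0
    for n_cycles in range(1, max(1, iterations) + 1):
        G_start = G
        w = np.exp(eta - logZ)  # raw distribution over background
        for j in range(J):
            fj = Fb[:, j]
            m1 = float(w @ fj)
            m2 = float(w @ (fj * fj))
            curv = max(m2 - m1 * m1, 1e-12)
            grad = pbar[j] - m1
            # soft-threshold Newton step for the L1-penalized 1-D problem
            z = curv * lam[j] + grad
            target = np.sign(z) * max(abs(z) - beta_j[j], 0.0) / curv
            delta = float(np.clip(target - lam[j], -10.0, 10.0))  # trust region
            if abs(delta) < 1e-14:
                continue
            # exact 1-D gain change with backtracking to guarantee ascent
            accepted = False
            for _ in range(30):
                lam_new = lam[j] + delta
                dlogZ = float(np.log(w @ np.exp(delta * fj)))
                dG = pbar[j] * delta - dlogZ - beta_j[j] * (abs(lam_new) - abs(lam[j]))
                if dG >= 0.0:
                    accepted = True
                    break
                delta *= 0.5
                if abs(delta) < 1e-14:
                    break
            if not accepted or abs(delta) < 1e-14:
                continue
            lam[j] = lam[j] + delta
            eta = eta + delta * fj
            logZ = logZ + dlogZ
            w = np.exp(eta - logZ)
            G += dG
            if dG > 0:
                trace.append((j, dG))
        cycle_gains.append(G)
        if G - G_start < tol:
            converged = True
            break
        # periodic renormalization against floating-point drift
        logZ = log_partition(eta)
        G = gain(lam, logZ)

    logZ = log_partition(eta)
    w = np.exp(eta - logZ)
    entropy = float(-(w * np.log(np.clip(w, 1e-300, None))).sum())
    G = gain(lam, logZ)
    return MaxentFit(
        feature_set=features, lambdas=lam, beta_multiplier=beta,
        reg_amounts=beta_j, log_partition=logZ, entropy=entropy,
        regularized_gain=G, unregularized_gain=G + float(beta_j @ np.abs(lam)),
        n_presence=m, n_background=N, contribution_trace=trace,
        converged=converged, n_cycles=n_cycles, cycle_gains=cycle_gains,
    )


def predict_maxent(
    fit: MaxentFit, stack: PredictorStack
) -> tuple[RasterGrid, RasterGrid]:
    """Raw and logistic suitability rasters (inputs clamped to background range)."""
    parents = fit.feature_set.parents
    for name in parents:
        if name not in stack:
            raise InvalidInputError(f"stack is missing predictor {name!r}")
    sub = stack.subset(parents)
    ref = stack.reference
    valid = sub.joint_valid_mask()
    table = sub.table(valid)
    raw_v = fit.raw(table)
    log_v = fit.logistic(table)
    raw = np.full(ref.shape, np.nan)
    logi = np.full(ref.shape, np.nan)
    raw[valid] = raw_v
    logi[valid] = log_v
    nodata = ~valid
    return ref.with_values(raw, nodata), ref.with_values(logi, nodata)


def percent_contribution(fit: MaxentFit) -> pd.DataFrame:
    """Training-gain credit per parent predictor, normalized to 100."""
    credit = dict.fromkeys(fit.feature_set.parents, 0.0)
    for j, dg in fit.contribution_trace:
        if dg > 0:
            credit[fit.feature_set.features[j].parent] += dg
    total = sum(credit.values())
    rows = [
        {"predictor": p, "percent_contribution": (100.0 * c / total) if total > 0 else 0.0}
        for p, c in credit.items()
    ]
    return pd.DataFrame(rows).sort_values(
        "percent_contribution", ascending=False
    ).reset_index(drop=True)


def _auc_scores(pos: np.ndarray, neg: np.ndarray) -> float:
    from .evaluation import auc

    return auc(pos, neg)


def permutation_importance(
    fit: MaxentFit, presences: SdmDesign, background: SdmDesign, seed: int
) -> pd.DataFrame:
    """AUC drop (presence vs background) when each predictor is shuffled."""
    rng = np.random.default_rng(seed)
    m = len(presences)
    pooled = pd.concat([presences.table, background.table], ignore_index=True)
    base_scores = fit.eta(pooled)
    base_auc = _auc_scores(base_scores[:m], base_scores[m:])
    rows = []
    for name in fit.feature_set.parents:
        perm = pooled.copy()
        perm[name] = rng.permutation(perm[name].to_numpy())
        scores = fit.eta(perm)
        drop = max(base_auc - _auc_scores(scores[:m], scores[m:]), 0.0)
        rows.append({"predictor": name, "auc_drop": drop})
    df = pd.DataFrame(rows)
    total = df["auc_drop"].sum()
    df["permutation_importance"] = 100.0 * df["auc_drop"] / total if total > 0 else 0.0
    return df.sort_values("permutation_importance", ascending=False).reset_index(drop=True)


def bootstrap_predict(
    presences: SdmDesign,
    background: SdmDesign,
    features: FeatureSet,
    stack: PredictorStack,
    n_replicates: int = 500,
    beta: float = 1.0,
    seed: int = 0,
    iterations: int = 500,
) -> list[RasterGrid]:
    """Logistic prediction rasters from presence bootstrap replicates."""
    if n_replicates < 2:
        raise InvalidInputError("need at least two bootstrap replicates")
    m = len(presences)
    out: list[RasterGrid] = []
    dropped = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(rep,)))
        idx = rng.integers(0, m, size=m)
        boot = SdmDesign(presences.table.iloc[idx], list(presences.predictor_names))
        try:
            fit = fit_maxent(boot, background, features, beta=beta, iterations=iterations)
            out.append(predict_maxent(fit, stack)[1])
        except (InvalidInputError, FloatingPointError):
            dropped += 1
    if dropped > 0.1 * n_replicates:
        raise InvalidInputError(f"{dropped}/{n_replicates} bootstrap replicates failed")
    return out
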