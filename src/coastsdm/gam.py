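"""Penalized-spline binomial GAM with shrinkage smoothers.

The linear predictor is an intercept plus a sum of penalized cubic
B-spline smooths (P-splines): each term carries a second-order difference
penalty that controls wiggliness, plus a "double penalty" on the penalty
null space (the constant + linear part of the smooth) scaled by a
shrinkage parameter, so an uninformative term can be shrunk all the way
to zero — variable selection during fitting, in the spirit of shrinkage
smoothers.  Fitting is penalized IRLS; smoothing parameters are chosen by
minimizing GCV over a log-spaced grid, coordinate-wise per term.

Suitability probabilities come from the logit link; prediction standard
errors use the delta method with the penalized information matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.special import expit, logit

from .design import SdmDesign, extract_design  # re-export: design tables live here
from .grid import InvalidInputError, PredictorStack, RasterGrid

__all__ = [
    "SdmDesign",
    "SmoothSpec",
    "GamFit",
    "build_smooth",
    "fit_gam",
    "predict_gam",
    "deviance_importance",
    "partial_response",
]

_DEFAULT_GRID = np.logspace(-4, 4, 21)


@dataclass
class SmoothSpec:
    """Penalized B-spline basis for one predictor.

    ``k`` is the basis dimension ("wiggliness parameter"); the spline
    degree is ``min(3, k - 1)`` so that k basis functions always exist.
    """

    predictor: str
    k: int
    knots: np.ndarray
    degree: int
    penalty: np.ndarray          # second-order difference penalty, k x k
    null_projection: np.ndarray  # projector onto the penalty null space
    col_means: np.ndarray        # training means for sum-to-zero centering
    x_range: tuple[float, float]
    shrinkage_epsilon: float = 1e-4

    def basis(self, x: np.ndarray, extrapolate: str = "linear") -> tuple[np.ndarray, np.ndarray]:
        """Uncentered basis matrix at ``x`` plus an out-of-range flag.

        Outside the training range the basis is continued linearly from
        the boundary (value + first derivative), and the flag is set.
        """
        x = np.asarray(x, dtype=float)
        lo, hi = self.x_range
        out_of_range = (x < lo) | (x > hi)
        xc = np.clip(x, lo, hi)
        B = BSpline.design_matrix(xc, self.knots, self.degree, extrapolate=False).toarray()
        if extrapolate == "linear" and out_of_range.any():
            dbs = BSpline(self.knots, np.eye(self.k).T, self.degree).derivative()
            for bound in (lo, hi):
                sel = out_of_range & (xc == bound)
                if sel.any():
                    B[sel] += np.outer(x[sel] - bound, dbs(bound))
        return B, out_of_range

    def centered_basis(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        B, flag = self.basis(x)
        return B - self.col_means, flag


@dataclass
class GamFit:
    """Everything needed for prediction, importance, and uncertainty."""

    specs: list[SmoothSpec]
    beta: np.ndarray                 # [intercept, term coefs...]
    term_slices: list[slice]
    lambdas: np.ndarray              # per-term wiggliness penalties
    epsilons: np.ndarray             # per-term null-space (shrinkage) penalties
    covariance: np.ndarray           # (X'WX + P)^-1, the Bayesian posterior cov
    information: np.ndarray          # X'WX at convergence
    null_deviance: float
    residual_deviance: float
    aic: float
    edf: float
    converged: bool
    n_iterations: int
    X_train: np.ndarray | None = None

    @property
    def intercept(self) -> float:
        return float(self.beta[0])

    @property
    def deviance_explained(self) -> float:
        return 1.0 - self.residual_deviance / self.null_deviance

    @property
    def predictor_names(self) -> list[str]:
        return [s.predictor for s in self.specs]

    def linear_predictor(self, table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(eta, var_eta, out_of_range flag) for rows of predictor values."""
        n = len(table)
        X = np.ones((n, 1 + sum(s.k for s in self.specs)))
        flag = np.zeros(n, dtype=bool)
        for spec, sl in zip(self.specs, self.term_slices):
            B, f = spec.centered_basis(table[spec.predictor].to_numpy(float))
            X[:, sl] = B
            flag |= f
        eta = X @ self.beta
        var = np.einsum("ij,jk,ik->i", X, self.covariance, X)
        return eta, np.maximum(var, 0.0), flag

    def predict_table(self, table: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(table)[0])

    def to_json_dict(self) -> dict:
        return {
            "beta": self.beta.tolist(),
            "lambdas": self.lambdas.tolist(),
            "epsilons": self.epsilons.tolist(),
            "aic": self.aic,
            "edf": self.edf,
            "null_deviance": self.null_deviance,
            "residual_deviance": self.residual_deviance,
            "deviance_explained": self.deviance_explained,
            "converged": self.converged,
            "terms": [
                {"predictor": s.predictor, "k": s.k, "degree": s.degree,
                 "knots": s.knots.tolist(), "col_means": s.col_means.tolist(),
                 "x_range": list(s.x_range)}
                for s in self.specs
            ],
        }


def build_smooth(values: np.ndarray, k: int, predictor: str = "x") -> SmoothSpec:
    """P-spline basis with ``k`` functions on quantile-spaced interior knots."""
    values = np.asarray(values, dtype=float)
    if k < 3:
        raise InvalidInputError("k must be >= 3")
    uniq = np.unique(values)
    if uniq.size < k:
        raise InvalidInputError(f"need at least k={k} distinct values, got {uniq.size}")
    degree = min(3, k - 1)
    lo, hi = float(uniq[0]), float(uniq[-1])
    n_interior = k - degree - 1
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(uniq, qs)
        # quantile ties would create invalid knot multiplicities
        if np.unique(interior).size < n_interior or interior[0] <= lo or interior[-1] >= hi:
            interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    else:
        interior = np.empty(0)
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])

    D = np.diff(np.eye(k), n=2, axis=0)  # (k-2) x k second differences
    S = D.T @ D
    # Projector onto null(S): constant and linear coefficient sequences.
    U = np.linalg.qr(np.column_stack([np.ones(k), np.arange(k, dtype=float)]))[0]
    N = U @ U.T

    spec = SmoothSpec(predictor, k, knots, degree, S, N, np.zeros(k), (lo, hi))
    B, _ = spec.basis(values)
    spec.col_means = B.mean(axis=0)
    return spec


def _binomial_deviance(y: np.ndarray, mu: np.ndarray, w: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(w * (y * np.log(mu) + (1 - y) * np.log1p(-mu))))


class _PirlsWorkspace:
    """Shared matrices for repeated penalized IRLS solves on one design."""

    def __init__(self, design: SdmDesign, specs: list[SmoothSpec]):
        self.y = design.labels.astype(float)
        self.w = design.weights
        if not (np.any(self.y == 1) and np.any(self.y == 0)):
            raise InvalidInputError("both classes must be present to fit a GAM")
        n = len(design)
        ks = [s.k for s in specs]
        p = 1 + sum(ks)
        self.X = np.ones((n, p))
        self.term_slices = []
        pos = 1
        for spec, k in zip(specs, ks):
            sl = slice(pos, pos + k)
            B, _ = spec.centered_basis(design.table[spec.predictor].to_numpy(float))
            self.X[:, sl] = B
            self.term_slices.append(sl)
            pos += k
        self.specs = specs
        self.p = p

    def penalty(self, lambdas: np.ndarray, epsilons: np.ndarray) -> np.ndarray:
        P = np.zeros((self.p, self.p))
        for spec, sl, lam, eps in zip(self.specs, self.term_slices, lambdas, epsilons):
            P[sl, sl] = lam * spec.penalty + eps * spec.null_projection
        return P

    def pirls(self, P: np.ndarray, beta0: np.ndarray | None = None,
              tol: float = 1e-8, max_iter: int = 200):
        """Penalized IRLS; returns (beta, deviance, XtWX, iters, converged)."""
        y, w, X = self.y, self.w, self.X
        if beta0 is None:
            beta = np.zeros(self.p)
            pbar = np.clip(np.average(y, weights=w) if w.sum() else 0.5, 1e-3, 1 - 1e-3)
            beta[0] = logit(pbar)
        else:
            beta = beta0.copy()
        eta = X @ beta
        mu = expit(eta)
        dev = _binomial_deviance(y, mu, w)
        pdev = dev + beta @ P @ beta  # penalized deviance drives the line search
        XtWX = None
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            wirls = w * np.clip(mu * (1 - mu), 1e-10, None)
            z = eta + (y - mu) / np.clip(mu * (1 - mu), 1e-10, None)
            WX = X * wirls[:, None]
            XtWX = X.T @ WX
            rhs = WX.T @ z
            try:
                direction = np.linalg.solve(XtWX + P, rhs) - beta
            except np.linalg.LinAlgError:
                direction = np.linalg.lstsq(XtWX + P, rhs, rcond=None)[0] - beta
            # step halving guards against divergence near separation
            step = 1.0
            while True:
                beta_new = beta + step * direction
                eta_new = X @ beta_new
                mu_new = expit(eta_new)
                dev_new = _binomial_deviance(y, mu_new, w)
                pdev_new = dev_new + beta_new @ P @ beta_new
                if np.isfinite(pdev_new) and pdev_new <= pdev + 1e-9:
                    break
                step *= 0.5
                if step < 1e-8:
                    beta_new, eta_new, mu_new = beta, eta, mu
                    dev_new, pdev_new = dev, pdev
                    break
            delta = abs(pdev - pdev_new)
            beta, eta, mu, dev, pdev = beta_new, eta_new, mu_new, dev_new, pdev_new
            if delta < tol * (abs(pdev) + 0.1):
                converged = True
                break
        wirls = w * np.clip(mu * (1 - mu), 1e-10, None)
        XtWX = X.T @ (X * wirls[:, None])
        return beta, dev, XtWX, it, converged

    def gcv(self, P: np.ndarray, beta0: np.ndarray | None = None) -> tuple[float, np.ndarray]:
        beta, dev, XtWX, _, _ = self.pirls(P, beta0)
        edf = _edf(XtWX, P)
        n = len(self.y)
        denom = max(n - edf, 1e-6)
        return n * dev / denom**2, beta


def _edf(XtWX: np.ndarray, P: np.ndarray) -> float:
    try:
        F = np.linalg.solve(XtWX + P, XtWX)
    except np.linalg.LinAlgError:
        F = np.linalg.lstsq(XtWX + P, XtWX, rcond=None)[0]
    return float(np.trace(F))


def fit_gam(
    design: SdmDesign,
    specs: list[SmoothSpec],
    select: bool = True,
    lambda_grid: np.ndarray | None = None,
    fixed_lambda: float | np.ndarray | None = None,
    fixed_epsilon: float | np.ndarray | None = None,
    n_sweeps: int = 2,
    tol: float = 1e-8,
    max_iter: int = 200,
    keep_design: bool = True,
) -> GamFit:
    """Fit the penalized binomial GAM.

    With ``select=True`` (default) per-term smoothing and shrinkage
    parameters are chosen by coordinate-wise GCV minimization over a
    log-spaced grid, in ``n_sweeps`` sweeps.  ``fixed_lambda`` /
    ``fixed_epsilon`` bypass selection (scalars broadcast over terms).
    """
    ws = _PirlsWorkspace(design, specs)
    grid = _DEFAULT_GRID if lambda_grid is None else np.asarray(lambda_grid, float)
    nt = len(specs)

    lambdas = np.full(nt, 1.0)
    epsilons = np.full(nt, float(grid[0]) if nt else 1e-4)
    if fixed_lambda is not None:
        lambdas = np.broadcast_to(np.asarray(fixed_lambda, float), (nt,)).copy()
    if fixed_epsilon is not None:
        epsilons = np.broadcast_to(np.asarray(fixed_epsilon, float), (nt,)).copy()

    beta_warm = None
    if select and nt and fixed_lambda is None:
        for _ in range(n_sweeps):
            for j in range(nt):
                best = (np.inf, lambdas[j])
                for lam in grid:
                    lambdas[j] = lam
                    score, beta_w = ws.gcv(ws.penalty(lambdas, epsilons), beta_warm)
                    if score < best[0]:
                        best = (score, lam)
                        beta_warm = beta_w
                lambdas[j] = best[1]
                if fixed_epsilon is None:
                    best = (np.inf, epsilons[j])
                    for eps in grid:
                        epsilons[j] = eps
                        score, beta_w = ws.gcv(ws.penalty(lambdas, epsilons), beta_warm)
                        if score < best[0]:
                            best = (score, eps)
                            beta_warm = beta_w
                    epsilons[j] = best[1]

    P = ws.penalty(lambdas, epsilons)
    beta, dev, XtWX, n_iter, converged = ws.pirls(P, beta_warm, tol=tol, max_iter=max_iter)
    edf = _edf(XtWX, P)
    try:
        cov = np.linalg.inv(XtWX + P)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(XtWX + P)

    # Null deviance: intercept-only binomial MLE.
    y, w = ws.y, ws.w
    p0 = np.clip(np.average(y, weights=w), 1e-12, 1 - 1e-12)
    null_dev = _binomial_deviance(y, np.full_like(y, p0), w)
    aic = dev + 2.0 * edf

    return GamFit(
        specs=list(specs), beta=beta, term_slices=ws.term_slices,
        lambdas=lambdas, epsilons=epsilons, covariance=cov, information=XtWX,
        null_deviance=null_dev, residual_deviance=dev, aic=aic, edf=edf,
        converged=converged, n_iterations=n_iter,
        X_train=ws.X if keep_design else None,
    )


def predict_gam(
    fit: GamFit, stack: PredictorStack, return_coverage: bool = False
):
    """Per-cell suitability probability and delta-method standard error.

    Cells with any nodata predictor are nodata.  Cells where a predictor
    falls outside the training range are predicted by linear basis
    extrapolation and flagged in the optional coverage raster.
    """
    for name in fit.predictor_names:
        if name not in stack:
            raise InvalidInputError(f"stack is missing predictor {name!r}")
    ref = stack.reference
    sub = stack.subset(fit.predictor_names) if fit.predictor_names else stack
    valid = sub.joint_valid_mask()
    table = sub.table(valid)
    eta, var_eta, flag = fit.linear_predictor(table)
    mu = expit(eta)
    se = mu * (1 - mu) * np.sqrt(var_eta)

    prob = np.full(ref.shape, np.nan)
    serr = np.full(ref.shape, np.nan)
    cover = np.full(ref.shape, np.nan)
    prob[valid] = mu
    serr[valid] = se
    cover[valid] = flag.astype(float)
    nodata = ~valid
    out = (ref.with_values(prob, nodata), ref.with_values(serr, nodata))
    if return_coverage:
        return out + (ref.with_values(cover, nodata),)
    return out


def deviance_importance(
    design: SdmDesign, specs: list[SmoothSpec], **fit_kwargs
) -> pd.DataFrame:
    """Leave-one-predictor-out deviance-drop importance table.

    ``drop`` is the decrease in percent deviance explained when the
    predictor is removed; ``proportion_of_total`` divides by the full
    model's deviance explained.  Because every reduced model is refit
    (and re-penalized), proportions can sum above 1.
    """
    if not specs:
        raise InvalidInputError("need at least one smooth term")
    full = fit_gam(design, specs, **fit_kwargs)
    de_full = full.deviance_explained
    rows = []
    for spec in specs:
        reduced_specs = [s for s in specs if s.predictor != spec.predictor]
        red = fit_gam(design, reduced_specs, **fit_kwargs)
        drop = (de_full - red.deviance_explained) * 100.0
        rows.append({
            "predictor": spec.predictor,
            "deviance_explained_drop": drop,
            "proportion_of_total": (drop / 100.0) / de_full if de_full > 0 else np.nan,
            "converged": red.converged,
        })
    return pd.DataFrame(rows).sort_values(
        "deviance_explained_drop", ascending=False
    ).reset_index(drop=True)


def partial_response(fit: GamFit, predictor: str, n_points: int = 100) -> pd.DataFrame:
    """Centered smooth effect (logit scale) with pointwise SE on an x grid."""
    for spec, sl in zip(fit.specs, fit.term_slices):
        if spec.predictor == predictor:
            lo, hi = spec.x_range
            x = np.linspace(lo, hi, n_points)
            B, _ = spec.centered_basis(x)
            effect = B @ fit.beta[sl]
            V = fit.covariance[sl, sl]
            se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B, V, B), 0.0))
            return pd.DataFrame({"x": x, "effect": effect, "se": se})
    raise InvalidInputError(f"unknown predictor {predictor!r}")
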