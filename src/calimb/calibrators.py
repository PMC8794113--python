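"""Calibration maps: Platt scaling, beta calibration, spline calibration.

All three calibrators map a raw positive-class score ``z`` in [0, 1] to a
calibrated probability:

* **Platt** — ``p = logistic(alpha + beta * z)``, fitted by maximum
  likelihood against Platt's smoothed targets.
* **Beta** — ``p = 1 / (1 + exp(-c) * (1 - z)^b / z^a)``, i.e. a logistic
  model in the features ``(ln z, -ln(1 - z))``; ``(a, b, c) = (1, 1, 0)`` is
  the identity, and ``a, b >= 0`` is enforced by drop-and-refit.
* **Spline** — a cubic smoothing spline on the logit scale maximizing the
  penalized Bernoulli log-likelihood
  ``sum_i [y_i f(z_i) - log(1 + e^{f(z_i)})] - lam * int f''(z)^2 dz``,
  with the smoothing parameter chosen from a log-spaced grid by held-out
  likelihood under a fixed, seed-controlled 5-fold split.

An ``identity`` baseline (exact passthrough) completes the set.  Fitted maps
serialize to a small JSON document with bit-faithful parameters.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import BSpline
from scipy.special import expit, logit

from .exceptions import DegenerateInputError, DegenerateLabelsError, FitError

#: Symmetric probability clip applied before any logit/log transform.
EPS = 1e-6

_MAP_FORMAT = "calimb.map"
_MAP_VERSION = 1


@dataclass(frozen=True)
class PlattParams:
    """Intercept/slope of the two-parameter logistic calibration map."""

    alpha: float
    beta: float


@dataclass(frozen=True)
class BetaParams:
    """Three-parameter beta-calibration coefficients; ``a, b >= 0``."""

    a: float
    b: float
    c: float


@dataclass
class SplineParams:
    """Fitted natural-cubic smoothing spline on the logit scale.

    Both axes are logit-transformed: the spline ``f`` maps ``logit(z)`` to
    the logit of the calibrated probability (so the identity map is affine
    and the lambda -> infinity limit is affine in logit).  ``knots`` is the
    full (clamped) cubic B-spline knot vector on the logit-score axis;
    ``coefficients`` the basis coefficients of ``f``; ``lam`` the selected
    smoothing parameter and ``selection_trace`` the candidate grid with
    held-out log-likelihoods.
    """

    knots: np.ndarray
    coefficients: np.ndarray
    lam: float
    selection_trace: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)

    @property
    def lo(self) -> float:
        return float(self.knots[3])

    @property
    def hi(self) -> float:
        return float(self.knots[-4])


@dataclass
class CalibrationMap:
    """A fitted calibration map: method tag + parameters + fit sample count."""

    method: str  # identity | platt | beta | spline
    params: PlattParams | BetaParams | SplineParams | None = None
    fit_n: int = 0


# ---------------------------------------------------------------------------
# shared logistic-likelihood machinery


def _newton_logistic(
    X: np.ndarray, t: np.ndarray, max_iter: int = 100, tol: float = 1e-8
) -> np.ndarray:
    """Damped Newton for the Bernoulli log-likelihood of ``sigma(X @ w)``.

    ``t`` may be fractional (smoothed targets).  Raises ``FitError`` on
    non-convergence.
    """
    w = np.zeros(X.shape[1])
    eta = X @ w
    ll = np.sum(t * eta - np.logaddexp(0.0, eta))
    for _ in range(max_iter):
        mu = expit(eta)
        grad = X.T @ (t - mu)
        wts = np.clip(mu * (1.0 - mu), 1e-12, None)
        H = (X * wts[:, None]).T @ X
        H[np.diag_indices_from(H)] += 1e-12
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - ridge guards this
            raise FitError("singular Hessian in logistic fit") from exc
        scale = 1.0
        for _ in range(30):
            w_new = w + scale * step
            eta_new = X @ w_new
            ll_new = np.sum(t * eta_new - np.logaddexp(0.0, eta_new))
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            raise FitError(f"logistic fit: step halving failed at ll={ll:.6g}")
        done = np.max(np.abs(w_new - w)) < tol
        w, eta, ll = w_new, eta_new, ll_new
        if done:
            return w
    raise FitError(f"logistic fit did not converge in {max_iter} iterations (ll={ll:.6g})")


def _check_two_classes(labels: np.ndarray) -> tuple[int, int]:
    labels = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError(
            f"both classes required, got {n_pos} positives / {n_neg} negatives"
        )
    return n_pos, n_neg


def _smoothed_targets(labels: np.ndarray) -> np.ndarray:
    """Platt's out-of-sample targets t+ = (N+ + 1)/(N+ + 2), t- = 1/(N- + 2)."""
    labels = np.asarray(labels, dtype=int)
    n_pos, n_neg = _check_two_classes(labels)
    t_pos = (n_pos + 1.0) / (n_pos + 2.0)
    t_neg = 1.0 / (n_neg + 2.0)
    return np.where(labels == 1, t_pos, t_neg)


# ---------------------------------------------------------------------------
# Platt scaling


def fit_platt(scores: np.ndarray, labels: np.ndarray) -> PlattParams:
    """Maximum-likelihood Platt scaling with smoothed targets.

    Degenerate all-identical scores fall back to the intercept-only model, so
    the applied map outputs the smoothed prevalence for every input.
    """
    z = np.asarray(scores, dtype=float)
    if len(z) < 2:
        raise DegenerateInputError("fit_platt needs at least 2 samples")
    t = _smoothed_targets(labels)
    if np.ptp(z) == 0.0:
        warnings.warn("constant scores: fitting intercept-only Platt map", stacklevel=2)
        return PlattParams(alpha=float(logit(np.mean(t))), beta=0.0)
    X = np.column_stack([np.ones_like(z), z])
    w = _newton_logistic(X, t)
    if w[1] <= 0:
        warnings.warn(
            f"fitted Platt slope beta={w[1]:.4g} <= 0: scores are not positively "
            "oriented with the labels",
            stacklevel=2,
        )
    return PlattParams(alpha=float(w[0]), beta=float(w[1]))


def apply_platt(params: PlattParams, scores: np.ndarray) -> np.ndarray:
    """Elementwise ``logistic(alpha + beta * z)``; strictly increasing for beta > 0."""
    z = np.asarray(scores, dtype=float)
    return expit(params.alpha + params.beta * z)


# ---------------------------------------------------------------------------
# Beta calibration


def _is_separated(z: np.ndarray, labels: np.ndarray) -> bool:
    pos = z[labels == 1]
    neg = z[labels == 0]
    return bool(pos.min() > neg.max() or neg.min() > pos.max())


def fit_beta(scores: np.ndarray, labels: np.ndarray) -> BetaParams:
    """Fit beta calibration by logistic regression on ``(ln z, -ln(1-z))``.

    If a fitted coefficient comes out negative the offending feature is
    dropped and the reduced model refitted with that parameter pinned at 0
    (two-parameter sub-family).  Perfectly rank-separated inputs reuse
    Platt's smoothed-target safeguard.
    """
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    z = np.clip(np.asarray(scores, dtype=float), EPS, 1.0 - EPS)
    t = (
        _smoothed_targets(labels)
        if _is_separated(z, labels)
        else labels.astype(float)
    )
    f1 = np.log(z)
    f2 = -np.log1p(-z)
    ones = np.ones_like(z)

    if np.ptp(z) == 0.0:
        warnings.warn("constant scores: fitting intercept-only beta map", stacklevel=2)
        return BetaParams(a=0.0, b=0.0, c=float(logit(np.mean(t))))

    w = _newton_logistic(np.column_stack([ones, f1, f2]), t)
    a, b, c = float(w[1]), float(w[2]), float(w[0])
    if a < 0:
        w = _newton_logistic(np.column_stack([ones, f2]), t)
        a, b, c = 0.0, float(w[1]), float(w[0])
        if b < 0:
            a = b = 0.0
            c = float(logit(np.mean(t)))
    elif b < 0:
        w = _newton_logistic(np.column_stack([ones, f1]), t)
        a, b, c = float(w[1]), 0.0, float(w[0])
        if a < 0:
            a = b = 0.0
            c = float(logit(np.mean(t)))
    return BetaParams(a=a, b=b, c=c)


def apply_beta(params: BetaParams, scores: np.ndarray) -> np.ndarray:
    """Elementwise ``1 / (1 + exp(-c) (1-z)^b / z^a)``; non-decreasing for a, b >= 0."""
    z = np.clip(np.asarray(scores, dtype=float), EPS, 1.0 - EPS)
    return expit(params.c + params.a * np.log(z) - params.b * np.log1p(-z))


# ---------------------------------------------------------------------------
# Spline calibration


def _spline_knot_vector(z: np.ndarray, n_knots: int) -> np.ndarray:
    lo, hi = float(z.min()), float(z.max())
    quantiles = np.unique(np.quantile(z, np.linspace(0.0, 1.0, n_knots)))
    # thin clustered quantiles: tiny knot gaps make the curvature penalty
    # (which scales like 1/gap^3) numerically catastrophic
    min_gap = (hi - lo) / (2.0 * n_knots)
    interior = []
    last = lo
    for q in quantiles:
        if q - last >= min_gap and hi - q >= min_gap:
            interior.append(q)
            last = q
    return np.concatenate([[lo] * 4, interior, [hi] * 4])


def _second_derivative_penalty(t: np.ndarray) -> np.ndarray:
    """Exact Gram matrix of second derivatives of the cubic B-spline basis.

    Second derivatives of cubic B-splines are piecewise linear, so two-point
    Gauss-Legendre per knot interval integrates their products exactly.
    """
    nb = len(t) - 4
    d2 = BSpline(t, np.eye(nb), 3).derivative(2)
    breaks = np.unique(t)
    P = np.zeros((nb, nb))
    gl_nodes = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    for a, b in zip(breaks[:-1], breaks[1:]):
        half = 0.5 * (b - a)
        mid = 0.5 * (a + b)
        # keep evaluation inside the open interval so the piecewise form is unambiguous
        vals = d2(mid + half * gl_nodes)
        P += half * (vals.T @ vals)
    return P


def _penalized_irls(
    X: sp.csr_array,
    y: np.ndarray,
    lam_P: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    nb = X.shape[1]
    beta = np.zeros(nb) if x0 is None else x0.copy()
    eta = X @ beta
    pll = np.sum(y * eta - np.logaddexp(0.0, eta)) - beta @ lam_P @ beta
    for _ in range(max_iter):
        mu = expit(eta)
        wts = np.clip(mu * (1.0 - mu), 1e-10, None)
        H = (X.multiply(wts[:, None]).T @ X).toarray() + 2.0 * lam_P
        H[np.diag_indices_from(H)] += 1e-10
        grad = X.T @ (y - mu) - 2.0 * lam_P @ beta
        step = np.linalg.solve(H, grad)
        if np.max(np.abs(step)) < tol:
            return beta
        slack = 1e-9 * (1.0 + abs(pll))
        scale = 1.0
        for _ in range(40):
            beta_new = beta + scale * step
            eta_new = X @ beta_new
            pll_new = (
                np.sum(y * eta_new - np.logaddexp(0.0, eta_new))
                - beta_new @ lam_P @ beta_new
            )
            if pll_new >= pll - slack:
                break
            scale *= 0.5
        else:
            # rounding-dominated regime near the optimum
            return beta
        done = np.max(np.abs(beta_new - beta)) < tol
        beta, eta, pll = beta_new, eta_new, pll_new
        if done:
            return beta
    raise FitError(f"spline fit did not converge in {max_iter} iterations")


def default_lambda_grid() -> np.ndarray:
    """Default smoothing-parameter grid: 20 log-spaced points in [1e-4, 1e2]."""
    return np.logspace(-4.0, 2.0, 20)


def fit_spline(
    scores: np.ndarray,
    labels: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    n_knots: int = 40,
    n_folds: int = 5,
    seed: int = 0,
) -> SplineParams:
    """Penalized-likelihood cubic smoothing spline on the logit scale.

    The smoothing parameter is selected from ``lambda_grid`` by total
    held-out log-likelihood under a fixed ``n_folds``-fold split shuffled
    with ``seed``; the winning value is refitted on all data.  Deterministic
    given inputs and seed.
    """
    z = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if len(z) < 10:
        raise DegenerateInputError(f"fit_spline needs n >= 10, got {len(z)}")
    _check_two_classes(labels)
    if np.ptp(z) == 0.0:
        raise DegenerateInputError("fit_spline: all scores identical")
    grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, dtype=float)
    if len(grid) == 0 or (grid <= 0).any():
        raise FitError("lambda_grid must be non-empty and strictly positive")

    x = logit(np.clip(z, EPS, 1.0 - EPS))
    t = _spline_knot_vector(x, min(n_knots, len(np.unique(x))))
    P = _second_derivative_penalty(t)
    lo, hi = t[3], t[-4]
    X_all = BSpline.design_matrix(np.clip(x, lo, hi), t, 3)

    trace: list[tuple[float, float]] = []
    if len(grid) == 1:
        best_lam = float(grid[0])
    else:
        rng = np.random.default_rng(seed)
        folds = np.array_split(rng.permutation(len(z)), n_folds)
        order = np.argsort(grid)  # ascending lambda enables warm starts
        scores_by_lam = np.zeros(len(grid))
        for fold in folds:
            mask = np.ones(len(z), dtype=bool)
            mask[fold] = False
            X_tr = X_all[mask]
            y_tr = y[mask]
            X_te = X_all[~mask]
            y_te = y[~mask]
            if y_tr.min() == y_tr.max():  # pragma: no cover - needs tiny folds
                continue
            warm: np.ndarray | None = None
            for j in order:
                warm = _penalized_irls(X_tr, y_tr, grid[j] * P, x0=warm)
                f = X_te @ warm
                scores_by_lam[j] += float(np.sum(y_te * f - np.logaddexp(0.0, f)))
        best_lam = float(grid[int(np.argmax(scores_by_lam))])
        trace = [(float(l), float(s)) for l, s in zip(grid, scores_by_lam)]
    beta = _penalized_irls(X_all, y, best_lam * P)
    return SplineParams(knots=t, coefficients=beta, lam=best_lam, selection_trace=trace)


def apply_spline(params: SplineParams, scores: np.ndarray) -> np.ndarray:
    """Evaluate the fitted spline map, extrapolating linearly beyond the fit range.

    Linear extrapolation on the logit axis matches natural-spline boundary
    behaviour and keeps the map injective outside the fitted score range.
    """
    x = logit(np.clip(np.asarray(scores, dtype=float), EPS, 1.0 - EPS))
    bs = BSpline(params.knots, params.coefficients, 3)
    deriv = bs.derivative()
    lo, hi = params.lo, params.hi
    f = np.asarray(bs(np.clip(x, lo, hi)), dtype=float)
    below = x < lo
    above = x > hi
    if below.any():
        f[below] = bs(lo) + deriv(lo) * (x[below] - lo)
    if above.any():
        f[above] = bs(hi) + deriv(hi) * (x[above] - hi)
    return np.clip(expit(f), EPS, 1.0 - EPS)


# ---------------------------------------------------------------------------
# dispatch + fitting front-end


def fit_map(
    method: str,
    scores: np.ndarray,
    labels: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
) -> CalibrationMap:
    """Fit a calibration map of the requested method on a calibration split."""
    if method == "identity":
        return CalibrationMap(method="identity", params=None, fit_n=len(np.asarray(scores)))
    if method == "platt":
        params: PlattParams | BetaParams | SplineParams = fit_platt(scores, labels)
    elif method == "beta":
        params = fit_beta(scores, labels)
    elif method == "spline":
        params = fit_spline(scores, labels, lambda_grid=lambda_grid, seed=seed)
    else:
        raise ValueError(f"unknown calibration method {method!r}")
    return CalibrationMap(method=method, params=params, fit_n=len(np.asarray(scores)))


def apply_map(cmap: CalibrationMap, scores: np.ndarray) -> np.ndarray:
    """Apply a fitted map; outputs clipped to [0, 1], identity is exact passthrough."""
    z = np.asarray(scores, dtype=float)
    if z.size == 0:
        return z.copy()
    if cmap.method == "identity":
        return z.copy()
    if cmap.method == "platt":
        out = apply_platt(cmap.params, z)
    elif cmap.method == "beta":
        out = apply_beta(cmap.params, z)
    elif cmap.method == "spline":
        out = apply_spline(cmap.params, z)
    else:
        raise ValueError(f"unknown calibration method {cmap.method!r}")
    return np.clip(out, 0.0, 1.0)


def is_monotone(cmap: CalibrationMap, n_grid: int = 1001) -> bool:
    """Check non-decrease of the applied map on an evenly spaced grid in [0, 1]."""
    grid = np.linspace(0.0, 1.0, n_grid)
    out = apply_map(cmap, grid)
    return bool(np.all(np.diff(out) >= 0.0))


# ---------------------------------------------------------------------------
# serialization


def save_map(cmap: CalibrationMap, path: str | Path) -> None:
    """Serialize a fitted map to JSON; float parameters round-trip bit-faithfully."""
    doc: dict = {
        "format": _MAP_FORMAT,
        "version": _MAP_VERSION,
        "method": cmap.method,
        "fit_n": cmap.fit_n,
    }
    p = cmap.params
    if isinstance(p, PlattParams):
        doc["params"] = {"alpha": p.alpha, "beta": p.beta}
    elif isinstance(p, BetaParams):
        doc["params"] = {"a": p.a, "b": p.b, "c": p.c}
    elif isinstance(p, SplineParams):
        doc["params"] = {
            "knots": p.knots.tolist(),
            "coefficients": p.coefficients.tolist(),
            "lambda": p.lam,
            "selection_trace": [[l, s] for l, s in p.selection_trace],
        }
    elif p is not None:  # pragma: no cover
        raise ValueError(f"cannot serialize params of type {type(p).__name__}")
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def load_map(path: str | Path) -> CalibrationMap:
    """Inverse of :func:`save_map`."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("format") != _MAP_FORMAT:
        raise ValueError(f"{path}: not a {_MAP_FORMAT} file")
    method = doc["method"]
    raw = doc.get("params", {})
    params: PlattParams | BetaParams | SplineParams | None
    if method == "identity":
        params = None
    elif method == "platt":
        params = PlattParams(alpha=raw["alpha"], beta=raw["beta"])
    elif method == "beta":
        params = BetaParams(a=raw["a"], b=raw["b"], c=raw["c"])
    elif method == "spline":
        params = SplineParams(
            knots=np.asarray(raw["knots"], dtype=float),
            coefficients=np.asarray(raw["coefficients"], dtype=float),
            lam=raw["lambda"],
            selection_trace=[(float(l), float(s)) for l, s in raw["selection_trace"]],
        )
    else:
        raise ValueError(f"unknown calibration method {method!r}")
    return CalibrationMap(method=method, params=params, fit_n=int(doc.get("fit_n", 0)))
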