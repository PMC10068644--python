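"""Scaled elastic net with bootstrap model averaging.

The objective is the literal sum-of-squares form

    min_{b0, b}  sum_i (y*_i - b0 - sum_j b_j X_ij)^2
                 + lambda * sum_j ( (1 - alpha)/2 * b_j^2 + alpha * |b_j| )

(no 1/n or 1/(2n) factor; to move a penalty strength between conventions use
lambda_here = 2 n alpha_meansq for mean-squared-error solvers with the same
l1_ratio).  It is minimized by cyclic coordinate descent with
soft-thresholding on standardized predictors; the intercept is unpenalized.
The ridge weight is chosen by a log-scale grid search maximizing the
adjusted R^2 stopping criterion

    R_adj^2 = 1 - (n - i)(1 - R^2) / (n - p),   i = 1 with an intercept,

with p counting the estimated parameters (intercept + active coefficients).

Stability selection repeats the fit over N bootstrap draws (90% of the
sample as training data; by default whole families are drawn, since
observations are correlated within pedigrees), refits unpenalized least
squares on each draw's active set, and model-averages the coefficient
vectors including zeros (beta*_j = mean_i beta_j^(i)).  Metabolites selected
in strictly more than the threshold fraction (default 20%) of draws form the
reported set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import adjusted_r2

logger = logging.getLogger(__name__)


class ElasticNetError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass
class ElasticNetProblem:
    """Residualized trait y* plus a standardized metabolite design matrix."""

    y: np.ndarray
    X: np.ndarray
    metabolite_ids: list[str]
    family: np.ndarray | None = None   # family label per row, for cluster draws

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape[0] != len(self.y):
            raise ElasticNetError("X and y have different numbers of rows")
        if self.X.shape[1] != len(self.metabolite_ids):
            raise ElasticNetError("metabolite_ids length mismatch")
        if not (np.all(np.isfinite(self.y)) and np.all(np.isfinite(self.X))):
            raise ElasticNetError("non-finite entries in the problem")
        col_sd = self.X.std(axis=0, ddof=0)
        if np.any(col_sd <= 0):
            bad = [self.metabolite_ids[j] for j in np.where(col_sd <= 0)[0]]
            raise ElasticNetError(f"zero-variance columns: {bad[:5]}")
        if (np.max(np.abs(self.X.mean(axis=0))) > 1e-8
                or np.max(np.abs(col_sd - 1.0)) > 1e-8):
            raise ElasticNetError("X must be standardized (mean 0, SD 1)")

    @classmethod
    def from_matrix(cls, y_star: pd.Series, matrix_values: pd.DataFrame,
                    family: pd.Series | None = None) -> "ElasticNetProblem":
        common = y_star.index.intersection(matrix_values.index)
        X = matrix_values.loc[common].to_numpy(dtype=float)
        sd = X.std(axis=0, ddof=0)
        if np.any(sd <= 0):
            bad = [matrix_values.columns[j] for j in np.where(sd <= 0)[0]]
            raise ElasticNetError(f"zero-variance metabolites: {bad[:5]}")
        X = (X - X.mean(axis=0)) / sd
        fam = family.loc[common].to_numpy() if family is not None else None
        return cls(y_star.loc[common].to_numpy(dtype=float), X,
                   [str(c) for c in matrix_values.columns], fam)


@dataclass
class ElasticNetConfig:
    alpha: float = 0.5
    lambda_: float | None = None       # None: choose by select_l2_by_grid
    n_grid: int = 25
    grid_span: float = 1e-4            # lowest grid point = span * lambda_max
    max_active: int | None = None      # grid-search active-set cap (see select_l2_by_grid)
    n_bootstrap: int = 2000
    train_fraction: float = 0.9
    selection_threshold: float = 0.20
    refit: bool = True
    cluster_bootstrap: bool = True     # draw whole families
    with_replacement: bool = False     # classical resampling instead of 90% subsample
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ElasticNetError("alpha must be in [0, 1]")
        if self.lambda_ is not None and self.lambda_ < 0:
            raise ElasticNetError("lambda must be >= 0")
        if not 0.0 < self.train_fraction < 1.0:
            raise ElasticNetError("train_fraction must be in (0, 1)")


@dataclass
class ElasticNetFit:
    intercept: float
    beta: np.ndarray
    objective: float
    active: np.ndarray             # indices of nonzero coefficients
    r2: float
    adj_r2: float
    n: int
    p_effective: int
    n_sweeps: int


def objective_value(y, X, intercept, beta, alpha, lam) -> float:
    r = y - intercept - X @ beta
    pen = np.sum((1.0 - alpha) / 2.0 * beta ** 2 + alpha * np.abs(beta))
    return float(np.sum(r * r) + lam * pen)


def lambda_max(X: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Smallest lambda with an all-zero solution: max_j 2|x_j'(y - ybar)| / alpha.

    For alpha = 0 the lasso part vanishes and no finite lambda empties the
    active set; the alpha = 1 bound is used to anchor the grid.
    """
    yc = y - y.mean()
    g = 2.0 * np.max(np.abs(X.T @ yc))
    return g / alpha if alpha > 0 else g


def _soft(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


def _sweep_python(XT, r, beta, xx, denom, thresh, idx):
    """One cyclic pass over ``idx``; updates beta/r in place.

    Returns (max coefficient change, intercept shift).  Reference
    implementation; the numba kernel below is the hot path.
    """
    max_delta = 0.0
    for j in idx:
        bj = beta[j]
        rho = 2.0 * (XT[j] @ r) + 2.0 * xx[j] * bj
        new = _soft(rho, thresh) / denom[j]
        d = new - bj
        if d != 0.0:
            beta[j] = new
            r -= d * XT[j]
            if abs(d) > max_delta:
                max_delta = abs(d)
    mu = r.mean()
    r -= mu
    return max_delta, mu


try:
    from numba import njit

    @njit(cache=False, fastmath=False)
    def _sweep_numba(XT, r, beta, xx, denom, thresh, idx):  # pragma: no cover
        n = r.shape[0]
        max_delta = 0.0
        for k in range(idx.shape[0]):
            j = idx[k]
            bj = beta[j]
            rho = 0.0
            for i in range(n):
                rho += XT[j, i] * r[i]
            rho = 2.0 * rho + 2.0 * xx[j] * bj
            if rho > thresh:
                new = (rho - thresh) / denom[j]
            elif rho < -thresh:
                new = (rho + thresh) / denom[j]
            else:
                new = 0.0
            d = new - bj
            if d != 0.0:
                beta[j] = new
                for i in range(n):
                    r[i] -= d * XT[j, i]
                ad = abs(d)
                if ad > max_delta:
                    max_delta = ad
        mu = 0.0
        for i in range(n):
            mu += r[i]
        mu /= n
        for i in range(n):
            r[i] -= mu
        return max_delta, mu

    _SWEEP = _sweep_numba
except ImportError:  # pragma: no cover
    _SWEEP = _sweep_python


def fit_scaled_elastic_net(
    prob: ElasticNetProblem,
    alpha: float,
    lambda_: float,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    beta_init: np.ndarray | None = None,
    max_active: int | None = None,
) -> ElasticNetFit:
    """Cyclic coordinate descent on the literal sum-of-squares objective.

    The stationarity condition per coordinate gives the update
    b_j = S(2 x_j' r_(-j), lambda * alpha) / (2 x_j'x_j + lambda (1 - alpha));
    each update is an exact single-coordinate minimization, so the objective
    is non-increasing across sweeps (asserted).  After an initial full sweep,
    inner sweeps cycle over the active set only, with a full sweep to confirm
    convergence (the usual active-set strategy).
    """
    if lambda_ < 0:
        raise ElasticNetError("lambda must be >= 0")
    y, X = prob.y, prob.X
    n, p = X.shape
    xx = np.einsum("ij,ij->j", X, X)            # x_j'x_j per column
    denom = 2.0 * xx + lambda_ * (1.0 - alpha)
    thresh = lambda_ * alpha

    beta = np.zeros(p) if beta_init is None else np.asarray(beta_init, float).copy()
    intercept = float(y.mean() - X.mean(axis=0) @ beta)
    r = y - intercept - X @ beta
    obj = objective_value(y, X, intercept, beta, alpha, lambda_)

    XT = np.ascontiguousarray(X.T)

    def sweep(indices) -> float:
        nonlocal intercept
        max_delta, mu = _SWEEP(XT, r, beta, xx, denom, thresh,
                               np.asarray(indices, dtype=np.int64))
        intercept += mu
        return max_delta

    n_sweeps = 0
    full = np.arange(p, dtype=np.int64)
    converged = False
    while n_sweeps < max_iter:
        delta = sweep(full)
        n_sweeps += 1
        new_obj = objective_value(y, X, intercept, beta, alpha, lambda_)
        if new_obj > obj * (1 + 1e-9) + 1e-12:
            raise AssertionError("coordinate-descent objective increased")
        obj = new_obj
        if delta < tol:
            converged = True
            break
        active = np.where(beta != 0.0)[0]
        if max_active is not None and len(active) > max_active:
            raise ConvergenceError(
                f"active set grew to {len(active)} > max_active={max_active}")
        while n_sweeps < max_iter:
            d_in = sweep(active)
            n_sweeps += 1
            if d_in < tol:
                break
    if not converged and n_sweeps >= max_iter:
        # final full-sweep check before giving up
        if sweep(full) >= tol:
            raise ConvergenceError(
                f"coordinate descent not converged after {n_sweeps} sweeps "
                f"(last objective {obj:.6g})")

    obj = objective_value(y, X, intercept, beta, alpha, lambda_)
    active = np.where(beta != 0.0)[0]
    tss = float(np.sum((y - y.mean()) ** 2))
    rss = float(np.sum((y - intercept - X @ beta) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else math.nan
    p_eff = 1 + len(active)
    adj = adjusted_r2(r2, n, p_eff, i=1) if n > p_eff else math.nan
    return ElasticNetFit(intercept=intercept, beta=beta.copy(), objective=obj,
                         active=active, r2=r2, adj_r2=adj, n=n,
                         p_effective=p_eff, n_sweeps=n_sweeps)


def select_l2_by_grid(
    prob: ElasticNetProblem,
    alpha: float,
    grid: np.ndarray | None = None,
    n_grid: int = 25,
    grid_span: float = 1e-4,
    max_active: int | None = None,
) -> tuple[float, pd.DataFrame]:
    """Log-scale grid search for the penalty weight.

    Fits at every grid point (warm-started from large to small lambda) and
    returns the lambda maximizing the adjusted-R^2 criterion; ties break
    toward the larger (more parsimonious) lambda.  ``max_active`` optionally
    caps the admissible active-set size: with p comparable to n the in-sample
    R^2 of a selected model is inflated enough that the adjusted-R^2
    criterion otherwise drifts into the saturated corner of the path.
    """
    if grid is None:
        lmax = lambda_max(prob.X, prob.y, alpha)
        if lmax <= 0:
            raise ElasticNetError("degenerate problem: lambda_max = 0")
        grid = np.geomspace(grid_span * lmax, lmax, n_grid)
    grid = np.sort(np.asarray(grid, dtype=float))
    if len(grid) == 0:
        raise ElasticNetError("empty lambda grid")

    rows = []
    beta = None
    # fits whose active set reaches n-1 parameters have an undefined adjusted
    # R^2 and can never win; abort them early
    cap = prob.X.shape[0] - 2
    if max_active is not None:
        cap = min(cap, max_active)
    for lam in grid[::-1]:
        try:
            fit = fit_scaled_elastic_net(prob, alpha, lam, beta_init=beta,
                                         max_active=cap)
        except ConvergenceError as exc:
            rows.append({"lambda": lam, "adj_r2": -np.inf, "r2": np.nan,
                         "n_active": -1, "error": str(exc)})
            continue
        beta = fit.beta
        crit = fit.adj_r2 if np.isfinite(fit.adj_r2) else -np.inf
        rows.append({"lambda": lam, "adj_r2": crit, "r2": fit.r2,
                     "n_active": len(fit.active), "error": ""})
    diag = pd.DataFrame(rows).sort_values("lambda").reset_index(drop=True)
    if not np.isfinite(diag["adj_r2"]).any():
        raise ElasticNetError("every grid fit failed")
    best = diag["adj_r2"].max()
    chosen = float(diag.loc[np.isclose(diag["adj_r2"], best), "lambda"].max())
    return chosen, diag


def _path_warm_start(prob: ElasticNetProblem, alpha: float, lam: float,
                     n_steps: int = 8) -> np.ndarray:
    """Descend a short lambda path from lambda_max to ``lam`` with warm starts.

    Cold-start coordinate descent at a small penalty converges slowly when
    the design is ill-conditioned; a handful of warm-started path steps make
    the target fit cheap and reliable.
    """
    lmax = lambda_max(prob.X, prob.y, alpha if alpha > 0 else 1.0)
    beta = None
    if lam < lmax:
        for l in np.geomspace(lmax, max(lam, 1e-12), n_steps)[:-1]:
            try:
                beta = fit_scaled_elastic_net(prob, alpha, l, beta_init=beta).beta
            except ConvergenceError:
                continue   # keep the last successful warm point
    try:
        return fit_scaled_elastic_net(prob, alpha, lam, beta_init=beta).beta
    except ConvergenceError:
        logger.warning("full-data warm fit: relaxed tolerance")
        return fit_scaled_elastic_net(prob, alpha, lam, tol=1e-6,
                                      beta_init=beta).beta


@dataclass
class ModelAverageResult:
    table: pd.DataFrame            # per metabolite: counts, pct, quantiles, beta_star
    intercept_star: float
    n_bootstrap: int
    selection_threshold: float
    selected: list[str] = field(default_factory=list)
    lambda_: float = math.nan
    alpha: float = math.nan

    @property
    def beta_star(self) -> pd.Series:
        return self.table["beta_star"]


def _bootstrap_rows(rng, n, family, config) -> np.ndarray:
    if config.cluster_bootstrap and family is not None:
        fams = np.unique(family)
        if config.with_replacement:
            take = rng.choice(fams, size=len(fams), replace=True)
        else:
            k = max(1, int(math.ceil(config.train_fraction * len(fams))))
            take = rng.choice(fams, size=k, replace=False)
        rows = np.concatenate([np.where(family == f)[0] for f in take])
        return np.sort(rows)
    if config.with_replacement:
        return np.sort(rng.integers(0, n, size=n))
    k = max(1, int(math.ceil(config.train_fraction * n)))
    return np.sort(rng.choice(n, size=k, replace=False))


def bootstrap_model_average(
    prob: ElasticNetProblem,
    config: ElasticNetConfig,
) -> ModelAverageResult:
    """Bootstrap stability selection with refit and zero-inclusive averaging.

    Each draw trains the elastic net on 90% of the sample (whole families by
    default), refits unpenalized least squares on the draw's active set
    (zeros elsewhere; a rank-deficient refit falls back to the penalized
    coefficients, logged), and the N coefficient vectors are summarized by
    nonzero counts/percentages, 25/50/75% quantiles and the model-average
    coefficient beta* = mean including zeros.  Metabolites with selection
    percentage strictly above 100 * threshold form the selected set.
    """
    n, p = prob.X.shape
    alpha = config.alpha
    if config.lambda_ is not None:
        lam = float(config.lambda_)
    else:
        lam, _ = select_l2_by_grid(prob, alpha, n_grid=config.n_grid,
                                   grid_span=config.grid_span,
                                   max_active=config.max_active)
    rng = np.random.default_rng(config.seed)

    warm = _path_warm_start(prob, alpha, lam)
    coefs = np.zeros((config.n_bootstrap, p))
    intercepts = np.zeros(config.n_bootstrap)
    n_fallback = 0
    for b in range(config.n_bootstrap):
        rows = _bootstrap_rows(rng, n, prob.family, config)
        Xb, yb = prob.X[rows], prob.y[rows]
        sd = Xb.std(axis=0, ddof=0)
        keep = sd > 0
        sub = ElasticNetProblem.__new__(ElasticNetProblem)
        sub.y, sub.X = yb, Xb[:, keep]
        sub.metabolite_ids = [prob.metabolite_ids[j] for j in np.where(keep)[0]]
        sub.family = None
        try:
            fit = fit_scaled_elastic_net(sub, alpha, lam, beta_init=warm[keep])
        except ConvergenceError:
            # badly conditioned draw (e.g. p ~ n with a tiny penalty): accept
            # a slightly looser coefficient tolerance rather than aborting
            logger.warning("draw %d: retrying at relaxed tolerance", b)
            fit = fit_scaled_elastic_net(sub, alpha, lam, tol=1e-6,
                                         beta_init=warm[keep])
        beta_full = np.zeros(p)
        beta_full[np.where(keep)[0]] = fit.beta
        b0 = fit.intercept
        if config.refit:
            active = np.where(beta_full != 0.0)[0]
            if len(active) > 0:
                Xa = np.column_stack([np.ones(len(rows)), Xb[:, active]])
                if len(rows) > Xa.shape[1] and np.linalg.matrix_rank(Xa) == Xa.shape[1]:
                    coef, *_ = np.linalg.lstsq(Xa, yb, rcond=None)
                    b0 = float(coef[0])
                    beta_full = np.zeros(p)
                    beta_full[active] = coef[1:]
                else:
                    n_fallback += 1
                    logger.warning("draw %d: rank-deficient refit, keeping "
                                   "penalized coefficients", b)
            else:
                b0 = float(yb.mean())
        coefs[b] = beta_full
        intercepts[b] = b0
    if n_fallback:
        logger.info("%d/%d draws fell back to penalized coefficients",
                    n_fallback, config.n_bootstrap)

    nz = coefs != 0.0
    counts = nz.sum(axis=0)
    pct = 100.0 * counts / config.n_bootstrap
    q25, q50, q75 = np.percentile(coefs, [25, 50, 75], axis=0)
    beta_star = coefs.mean(axis=0)
    table = pd.DataFrame({
        "nonzero_count": counts,
        "nonzero_pct": pct,
        "q25": q25, "q50": q50, "q75": q75,
        "beta_star": beta_star,
        "selected": pct > 100.0 * config.selection_threshold,
    }, index=pd.Index(prob.metabolite_ids, name="metabolite_id"))
    selected = [m for m, s in zip(prob.metabolite_ids, table["selected"]) if s]
    return ModelAverageResult(table=table, intercept_star=float(intercepts.mean()),
                              n_bootstrap=config.n_bootstrap,
                              selection_threshold=config.selection_threshold,
                              selected=selected, lambda_=lam, alpha=alpha)


def predict_model_average(result: ModelAverageResult, X_new: np.ndarray) -> np.ndarray:
    """Score new (identically standardized) data with the averaged model."""
    X_new = np.asarray(X_new, dtype=float)
    beta = result.beta_star.to_numpy()
    if X_new.ndim != 2 or X_new.shape[1] != len(beta):
        raise ElasticNetError(
            f"X_new has {X_new.shape} but the model averages {len(beta)} coefficients")
    return result.intercept_star + X_new @ beta
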