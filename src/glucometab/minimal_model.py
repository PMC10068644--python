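"""Bergman minimal-model kinetics for the FSIGT.

The frequently sampled intravenous glucose tolerance test (FSIGT) delivers a
glucose bolus at t = 0-1 min and samples plasma glucose and insulin densely
afterwards.  Two coupled models describe the data:

Glucose disappearance (driven by a remote insulin-action state X):

    dG/dt = -(p1 + X(t)) * G(t) + p1 * Gb,      G(0) = G0
    dX/dt = -p2 * X(t) + p3 * (I(t) - Ib),      X(0) = 0

Insulin kinetics (glucose-stimulated secretion above a threshold h):

    dI/dt = -n * I(t) + gamma * (G(t) - h)+ * t,  I(0) = I0

where the secretion term is clamped at zero for G <= h by default
(``clamp_secretion=False`` integrates the literal unclamped form).

Derived traits:

* S_G = p1 (glucose effectiveness, per minute)
* S_I = p3 / p2 (insulin sensitivity, min^-1 per uU/mL; reported in 1e-4 units)
* AIR = mean incremental insulin over 2-8 min above basal
* DI  = AIR * S_I (S_I in 1e-4 units)
* HOMA-IR = G_mmol * I / 22.5, HOMA-B = 20 * I / (G_mmol - 3.5)
  (classic single-formula HOMA; glucose converted mg/dL -> mmol/L by / 18.016)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

MGDL_PER_MMOL = 18.016
SI_REPORT_SCALE = 1e4  # raw min^-1/(uU/mL) -> the conventional "x 10^-4" units


class NumericalModelError(RuntimeError):
    """Integrator produced non-finite state or the fit failed to converge."""


def mgdl_to_mmol(g: float | np.ndarray) -> float | np.ndarray:
    return np.asarray(g, dtype=float) / MGDL_PER_MMOL if isinstance(g, np.ndarray) else g / MGDL_PER_MMOL


def mmol_to_mgdl(g: float | np.ndarray) -> float | np.ndarray:
    return np.asarray(g, dtype=float) * MGDL_PER_MMOL if isinstance(g, np.ndarray) else g * MGDL_PER_MMOL


@dataclass(frozen=True)
class MinimalModelParams:
    """Full parameter set of the coupled glucose/insulin minimal model."""

    p1: float          # per minute; equals S_G
    p2: float          # per minute; decay of remote insulin action
    p3: float          # per minute^2 per (uU/mL)
    G0: float          # mg/dL, glucose at t=0 after the bolus
    n: float           # per minute; insulin clearance
    gamma: float       # secretion gain
    h: float           # mg/dL; glucose threshold for secretion
    I0: float          # uU/mL, insulin at t=0
    Gb: float          # mg/dL, basal glucose
    Ib: float          # uU/mL, basal insulin

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p3", "n"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.G0 <= 0 or self.Gb <= 0:
            raise ValueError("G0 and Gb must be positive")
        if self.I0 < 0 or self.Ib < 0:
            raise ValueError("I0 and Ib must be >= 0")

    @property
    def s_g(self) -> float:
        return self.p1

    @property
    def s_i_raw(self) -> float:
        """S_I in raw min^-1 per (uU/mL); NaN if p2 == 0 (undefined ratio)."""
        if self.p2 <= 0:
            return math.nan
        return self.p3 / self.p2

    @property
    def s_i(self) -> float:
        """S_I in the conventional x 10^-4 reporting units."""
        return self.s_i_raw * SI_REPORT_SCALE


@dataclass
class FSIGTRecord:
    """One individual's sampled FSIGT time course.

    Times are minutes relative to the glucose injection at [0, 1]; samples at
    t <= 0 are pre-injection and define the basal levels Gb and Ib.
    """

    individual_id: str
    times: np.ndarray
    glucose: np.ndarray
    insulin: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.glucose = np.asarray(self.glucose, dtype=float)
        self.insulin = np.asarray(self.insulin, dtype=float)
        if not (len(self.times) == len(self.glucose) == len(self.insulin)):
            raise ValueError("times, glucose and insulin must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.glucose <= 0):
            raise ValueError("glucose must be positive")
        if np.any(self.insulin < 0):
            raise ValueError("insulin must be nonnegative")

    @property
    def basal_glucose(self) -> float:
        pre = self.glucose[self.times <= 0]
        if len(pre) == 0:
            raise ValueError("no pre-injection samples for basal glucose")
        return float(np.mean(pre))

    @property
    def basal_insulin(self) -> float:
        pre = self.insulin[self.times <= 0]
        if len(pre) == 0:
            raise ValueError("no pre-injection samples for basal insulin")
        return float(np.mean(pre))


def _rhs_full(t, y, p: MinimalModelParams, clamp: bool):
    G, X, I = y
    dG = -(p.p1 + X) * G + p.p1 * p.Gb
    dX = -p.p2 * X + p.p3 * (I - p.Ib)
    drive = (G - p.h)
    if clamp:
        drive = max(drive, 0.0)
    dI = -p.n * I + p.gamma * drive * t
    return (dG, dX, dI)


def simulate_fsigt(
    params: MinimalModelParams,
    sample_times: np.ndarray,
    noise_cv: tuple[float, float] = (0.0, 0.0),
    seed: int | None = None,
    individual_id: str = "sim",
    clamp_secretion: bool = True,
    rtol: float = 1e-10,
    atol: float = 1e-8,
) -> FSIGTRecord:
    """Forward-simulate an FSIGT record from full minimal-model parameters.

    Samples at t <= 0 are reported at the basal values (Gb, Ib); samples at
    t > 0 come from integrating the coupled ODEs from (G0, 0, I0).
    Multiplicative log-normal noise is applied per the glucose/insulin CVs;
    the record is noiseless when both CVs are zero.
    """
    sample_times = np.asarray(sample_times, dtype=float)
    if np.any(np.diff(sample_times) <= 0):
        raise ValueError("sample_times must be strictly increasing")
    g_cv, i_cv = noise_cv
    if g_cv < 0 or i_cv < 0:
        raise ValueError("noise CVs must be >= 0")

    post = sample_times > 0
    glucose = np.full_like(sample_times, params.Gb)
    insulin = np.full_like(sample_times, params.Ib)
    if post.any():
        t_post = sample_times[post]
        sol = solve_ivp(
            _rhs_full,
            (0.0, float(t_post[-1])),
            (params.G0, 0.0, params.I0),
            t_eval=t_post,
            args=(params, clamp_secretion),
            method="LSODA",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise NumericalModelError(f"integration failed: {sol.message}")
        glucose[post] = sol.y[0]
        insulin[post] = sol.y[2]

    if g_cv > 0 or i_cv > 0:
        rng = np.random.default_rng(seed)
        if g_cv > 0:
            glucose = glucose * rng.lognormal(0.0, g_cv, size=len(glucose))
        if i_cv > 0:
            insulin = insulin * rng.lognormal(0.0, i_cv, size=len(insulin))
    insulin = np.maximum(insulin, 0.0)
    if np.any(glucose <= 0):
        raise NumericalModelError("simulated glucose became nonpositive")
    return FSIGTRecord(individual_id, sample_times, glucose, insulin)


def _forcing_interpolator(times: np.ndarray, values: np.ndarray):
    """Monotone cubic (PCHIP) interpolant of a sampled forcing input.

    Shape-preserving and far closer to the smooth underlying kinetics than a
    piecewise-linear chord, which systematically biases the fitted p2/p3.
    Extrapolates the end cubics outside the sampled range, floored at zero.
    """
    from scipy.interpolate import PchipInterpolator

    pch = PchipInterpolator(times, values, extrapolate=True)
    return lambda t: max(float(pch(t)), 0.0)


def _simulate_glucose_forced(p1, p2, p3, G0, Gb, Ib, t_grid, insulin_fn,
                             rtol=1e-8, atol=1e-6):
    """Integrate Eqs for (G, X) with observed insulin as the forcing input."""

    def rhs(t, y):
        G, X = y
        return (-(p1 + X) * G + p1 * Gb, -p2 * X + p3 * (insulin_fn(t) - Ib))

    sol = solve_ivp(rhs, (float(t_grid[0]), float(t_grid[-1])), (G0, 0.0),
                    t_eval=t_grid, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise NumericalModelError(f"glucose-model integration failed: {sol.message}")
    return sol.y[0]


@dataclass
class GlucoseFit:
    """Result of fitting the glucose disappearance model to one record."""

    p1: float
    p2: float
    p3: float
    G0: float
    s_g: float
    s_i: float                    # x 10^-4 units; NaN when unidentifiable
    se: dict = field(default_factory=dict)
    rss: float = math.nan
    n_points: int = 0
    converged: bool = False
    si_identifiable: bool = True
    message: str = ""


def fit_glucose_minimal_model(
    record: FSIGTRecord,
    fit_window_start: float = 8.0,
    n_starts: int = 8,
    seed: int = 0,
    x0: MinimalModelParams | None = None,
) -> GlucoseFit:
    """Fit (p1, p2, p3, G0) to the glucose samples of an FSIGT record.

    Observed insulin, linearly interpolated, is the forcing input (the
    decoupled two-stage MINMOD convention).  The sum of squared glucose
    residuals over samples with t >= ``fit_window_start`` is minimized with
    positivity enforced by log-parameterization; ``n_starts`` perturbed
    restarts guard against local minima.  When insulin never leaves its basal
    level the action state X is identically zero, S_I is unidentifiable and
    only (p1, G0) are fit (flagged via ``si_identifiable=False``).
    """
    Gb, Ib = record.basal_glucose, record.basal_insulin
    mask = record.times >= fit_window_start
    if mask.sum() < 4:
        raise ValueError("too few samples at t >= fit_window_start")
    t_fit = record.times[mask]
    g_obs = record.glucose[mask]
    # integration grid starts at 0 so X(0)=0 is honoured even when fitting later samples
    t_grid = np.unique(np.concatenate([[0.0], record.times[record.times > 0]]))
    fit_idx = np.searchsorted(t_grid, t_fit)
    # forcing input: post-injection insulin only -- the pre-injection basal
    # does not represent the immediate post-bolus insulin, so interpolating
    # across the injection would bias X
    post_sel = record.times > 0
    interp = _forcing_interpolator(record.times[post_sel], record.insulin[post_sel])

    flat_insulin = np.max(np.abs(record.insulin - Ib)) <= 1e-8 * max(1.0, Ib)

    if flat_insulin:
        # X == 0: G relaxes exponentially to Gb; fit (p1, G0) only.
        def resid_exp(theta):
            p1, G0 = np.exp(theta)
            return Gb + (G0 - Gb) * np.exp(-p1 * t_fit) - g_obs

        res = least_squares(resid_exp, np.log([0.02, max(g_obs[0], Gb + 1)]),
                            method="lm", xtol=1e-14, ftol=1e-14)
        p1, G0 = np.exp(res.x)
        return GlucoseFit(p1=p1, p2=math.nan, p3=math.nan, G0=G0, s_g=p1,
                          s_i=math.nan, rss=float(res.cost * 2),
                          n_points=int(mask.sum()), converged=res.success,
                          si_identifiable=False,
                          message="flat insulin: X=0, S_I unidentifiable")

    def resid(theta):
        p1, p2, p3, G0 = np.exp(theta)
        g_hat = _simulate_glucose_forced(p1, p2, p3, G0, Gb, Ib, t_grid, interp)
        return g_hat[fit_idx] - g_obs

    g_peak = float(np.max(record.glucose))
    if x0 is not None:
        base = np.log([max(x0.p1, 1e-6), max(x0.p2, 1e-6),
                       max(x0.p3, 1e-12), max(x0.G0, 1.0)])
    else:
        base = np.log([0.02, 0.025, 1e-5, max(g_peak, Gb + 50)])
    rng = np.random.default_rng(seed)
    best = None
    for k in range(max(1, n_starts)):
        start = base if k == 0 else base + rng.normal(0, 0.5, size=4)
        try:
            res = least_squares(resid, start, method="lm", diff_step=1e-4,
                                xtol=1e-12, ftol=1e-12, max_nfev=400)
        except NumericalModelError:
            continue
        if best is None or res.cost < best.cost:
            best = res
        if best.cost < 1e-12 * max(1.0, np.sum(g_obs**2)):
            break
    if best is None:
        raise NumericalModelError("glucose-model fit failed from every start")

    p1, p2, p3, G0 = np.exp(best.x)
    rss = float(2 * best.cost)
    dof = max(len(t_fit) - 4, 1)
    sigma2 = rss / dof
    # delta-method SEs on the natural scale from the log-scale Jacobian
    se = {}
    try:
        J = best.jac
        cov_log = sigma2 * np.linalg.inv(J.T @ J)
        se_log = np.sqrt(np.maximum(np.diag(cov_log), 0.0))
        for name, val, s in zip(("p1", "p2", "p3", "G0"), (p1, p2, p3, G0), se_log):
            se[name] = val * s
    except np.linalg.LinAlgError:
        pass

    si_raw = p3 / p2 if p2 > 1e-8 else math.nan
    identifiable = np.isfinite(si_raw)
    return GlucoseFit(p1=p1, p2=p2, p3=p3, G0=G0, s_g=p1,
                      s_i=si_raw * SI_REPORT_SCALE if identifiable else math.nan,
                      se=se, rss=rss, n_points=int(mask.sum()),
                      converged=bool(best.success), si_identifiable=identifiable,
                      message=best.message)


@dataclass
class InsulinFit:
    n: float
    gamma: float
    h: float
    I0: float
    rss: float = math.nan
    converged: bool = False
    message: str = ""


def fit_insulin_kinetics(
    record: FSIGTRecord,
    n_starts: int = 5,
    seed: int = 0,
    clamp_secretion: bool = True,
    x0: tuple[float, float, float, float] | None = None,
) -> InsulinFit:
    """Fit (n, gamma, h, I0) of the insulin-kinetics model to observed insulin.

    Observed glucose (linearly interpolated) is the secretion input; least
    squares over post-injection insulin samples, with n, gamma, I0 kept
    nonnegative by bounds and h bounded within the observed glucose range.
    """
    post = record.times > 0
    if post.sum() < 4:
        raise ValueError("too few post-injection insulin samples")
    t_obs = record.times[post]
    i_obs = record.insulin[post]
    if np.ptp(record.insulin) <= 1e-12 * max(1.0, float(np.max(record.insulin))):
        raise NumericalModelError("insulin has zero variance: kinetics unidentifiable")

    g_v = record.glucose
    gmin, gmax = float(np.min(g_v)), float(np.max(g_v))
    glucose_fn = _forcing_interpolator(record.times[post], record.glucose[post])

    def rhs(t, y, n_, gamma_, h_):
        drive = glucose_fn(t) - h_
        if clamp_secretion:
            drive = max(drive, 0.0)
        return -n_ * y[0] + gamma_ * drive * t

    def model(theta):
        n_, gamma_, h_, I0_ = theta
        sol = solve_ivp(rhs, (0.0, float(t_obs[-1])), (I0_,), t_eval=t_obs,
                        args=(n_, gamma_, h_), method="LSODA",
                        rtol=1e-9, atol=1e-8)
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise NumericalModelError("insulin-kinetics integration failed")
        return sol.y[0]

    def resid(theta):
        return model(theta) - i_obs

    lb = np.array([1e-6, 0.0, gmin, 0.0])
    ub = np.array([5.0, np.inf, gmax, np.inf])
    if x0 is not None:
        base = np.clip(np.asarray(x0, dtype=float), lb, ub)
    else:
        base = np.array([0.15, 1e-3, record.basal_glucose,
                         max(float(i_obs[0]), 1.0)])
        base = np.clip(base, lb, ub)
    rng = np.random.default_rng(seed)
    best = None
    for k in range(max(1, n_starts)):
        start = base if k == 0 else np.clip(
            base * rng.lognormal(0, 0.3, size=4), lb, ub)
        try:
            res = least_squares(resid, start, bounds=(lb, ub), diff_step=1e-4,
                                xtol=1e-12, ftol=1e-12, max_nfev=400)
        except NumericalModelError:
            continue
        if best is None or res.cost < best.cost:
            best = res
        if best.cost < 1e-16 * max(1.0, np.sum(i_obs**2)):
            break
    if best is None:
        raise NumericalModelError("insulin-kinetics fit failed from every start")
    n_, gamma_, h_, I0_ = best.x
    return InsulinFit(n=float(n_), gamma=float(gamma_), h=float(h_),
                      I0=float(I0_), rss=float(2 * best.cost),
                      converged=bool(best.success), message=best.message)


def compute_air(record: FSIGTRecord, window: tuple[float, float] = (2.0, 8.0)) -> float:
    """Acute insulin response: mean incremental insulin above basal in [2, 8] min.

    The sign is retained; a blunted first-phase response can be negative.
    """
    lo, hi = window
    in_win = (record.times >= lo) & (record.times <= hi)
    if not in_win.any():
        raise ValueError(f"no insulin samples in the [{lo}, {hi}] min window")
    return float(np.mean(record.insulin[in_win]) - record.basal_insulin)


def compute_di(air: float, si: float) -> float:
    """Disposition index: AIR x S_I (S_I in x 10^-4 units). NaN propagates."""
    if not np.isfinite(si) or not np.isfinite(air):
        return math.nan
    return air * si


def compute_homa(fasting_glucose_mgdl: float, fasting_insulin: float) -> tuple[float, float]:
    """Classic HOMA indices from fasting glucose (mg/dL) and insulin (uU/mL).

    Returns (HOMA-IR, HOMA-B); HOMA-B is NaN (with a logged reason) when
    fasting glucose is at or below 3.5 mmol/L, where its denominator vanishes.
    """
    if fasting_glucose_mgdl <= 0:
        raise ValueError("fasting glucose must be positive")
    if fasting_insulin < 0:
        raise ValueError("fasting insulin must be >= 0")
    g_mmol = fasting_glucose_mgdl / MGDL_PER_MMOL
    homa_ir = g_mmol * fasting_insulin / 22.5
    if g_mmol <= 3.5:
        logger.warning(
            "HOMA-B undefined: fasting glucose %.3f mmol/L <= 3.5", g_mmol)
        return homa_ir, math.nan
    if fasting_insulin == 0:
        return 0.0, 0.0
    return homa_ir, 20.0 * fasting_insulin / (g_mmol - 3.5)
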