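"""Per-metabolite linear mixed-model association with pedigree adjustment.

Each glucose-homeostasis trait is first transformed toward normality
(S_I, HOMA-IR, HOMA-B: natural log; AIR, DI: sign-retaining square root;
S_G: untransformed), then tested one metabolite at a time in

    y = intercept + age + sex + BMI + metabolite + g + e,
    g ~ N(0, sigma_g^2 K),  e ~ N(0, sigma_e^2 I)

where K encodes the pedigree: either a block of ones per family (a family
random intercept) or the additive relationship matrix (kinship mode).
Variance components are estimated by REML on the eigenbasis of K: with
K = U S U' and delta = sigma_g^2 / sigma_e^2, rotating by U' diagonalizes
the covariance to sigma_e^2 (delta S + I), so the profiled REML criterion
is a cheap one-dimensional optimization in log(delta).  Metabolites are
standardized (mean 0, SD 1) within the analyzed samples; the metabolite
coefficient is tested with a Wald statistic against the standard normal.

Significance in a scan uses the Bonferroni threshold 0.05 / M for M tested
metabolites (0.05/727 = 6.88e-5 at the full panel size).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .pedigree import build_relationship_matrix

TRAIT_TRANSFORMS = {
    "S_I": "natural_log",
    "HOMA_IR": "natural_log",
    "HOMA_B": "natural_log",
    "AIR": "signed_sqrt",
    "DI": "signed_sqrt",
    "S_G": "identity",
}

COVARIATE_COLUMNS = ["age", "sex", "bmi"]


class AssociationError(ValueError):
    pass


@dataclass
class TransformedTrait:
    trait_name: str
    transform: str
    values: pd.Series            # NaN where dropped or originally missing
    n_dropped_nonpositive: int = 0


def transform_trait(values: pd.Series, trait_name: str) -> TransformedTrait:
    """Apply the fixed per-trait normalizing transform.

    natural_log drops (records) nonpositive values; signed_sqrt(x) =
    sign(x) * sqrt(|x|) keeps the sign of negative AIR/DI.
    """
    if trait_name not in TRAIT_TRANSFORMS:
        raise AssociationError(f"unknown trait {trait_name!r}; known: {sorted(TRAIT_TRANSFORMS)}")
    kind = TRAIT_TRANSFORMS[trait_name]
    v = pd.Series(values, dtype=float)
    dropped = 0
    if kind == "natural_log":
        nonpos = v <= 0
        dropped = int((nonpos & v.notna()).sum())
        out = np.log(v.where(~nonpos))
    elif kind == "signed_sqrt":
        out = np.sign(v) * np.sqrt(np.abs(v))
    else:
        out = v.copy()
    return TransformedTrait(trait_name, kind, out, dropped)


@dataclass
class RelationshipModel:
    """Random-effect structure: family blocks or a kinship matrix."""

    mode: str                       # "family_intercept" | "kinship"
    family: pd.Series               # family id per individual id
    matrix: pd.DataFrame | None = None

    @classmethod
    def from_families(cls, family: pd.Series) -> "RelationshipModel":
        return cls("family_intercept", pd.Series(family))

    @classmethod
    def from_pedigree(cls, ped: pd.DataFrame) -> "RelationshipModel":
        A = build_relationship_matrix(ped)
        fam = pd.Series(ped["family_id"].values, index=ped["individual_id"].values)
        return cls("kinship", fam, A)

    def covariance(self, individual_ids) -> np.ndarray:
        ids = list(individual_ids)
        if self.mode == "kinship":
            if self.matrix is None:
                raise AssociationError("kinship mode requires a relationship matrix")
            return self.matrix.loc[ids, ids].to_numpy(dtype=float)
        fam = self.family.loc[ids].to_numpy()
        return (fam[:, None] == fam[None, :]).astype(float)


@dataclass
class LMMFit:
    beta: np.ndarray
    se: np.ndarray
    sigma_g2: float
    sigma_e2: float
    fitted_fixed: np.ndarray
    blup: np.ndarray
    n: int
    converged: bool = True


class LMMWorkspace:
    """Eigen-rotated REML solver for one covariance matrix K, reusable across fits."""

    def __init__(self, K: np.ndarray):
        K = np.asarray(K, dtype=float)
        s, U = np.linalg.eigh((K + K.T) / 2.0)
        self.s = np.maximum(s, 0.0)
        self.U = U
        self.n = K.shape[0]

    def rotate(self, M: np.ndarray) -> np.ndarray:
        return self.U.T @ M

    def _profile(self, log_delta: float, Xr: np.ndarray, yr: np.ndarray) -> float:
        delta = math.exp(log_delta)
        w = 1.0 / (delta * self.s + 1.0)
        XtW = Xr.T * w
        XtWX = XtW @ Xr
        try:
            beta = np.linalg.solve(XtWX, XtW @ yr)
        except np.linalg.LinAlgError:
            return np.inf
        r = yr - Xr @ beta
        rss_w = float(np.sum(w * r * r))
        n, p = Xr.shape
        if rss_w <= 0:
            return np.inf
        sign, logdet_xx = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        return ((n - p) * math.log(rss_w) + float(np.sum(np.log(delta * self.s + 1.0)))
                + logdet_xx)

    def fit(self, X: np.ndarray, y: np.ndarray) -> LMMFit:
        n, p = X.shape
        if n - p < 2:
            raise AssociationError("too few observations for REML")
        Xr, yr = self.rotate(X), self.rotate(y)

        # profiled REML over log(delta), with the delta -> 0 (OLS) boundary
        # checked explicitly
        res = minimize_scalar(self._profile, bounds=(-25.0, 12.0),
                              args=(Xr, yr), method="bounded",
                              options={"xatol": 1e-10})
        crit_interior = res.fun if res.success else np.inf
        # ordinary least squares limit: all weights 1
        w1 = np.ones_like(self.s)
        crit_zero = ((n - p) * math.log(max(float(np.sum(
            (yr - Xr @ np.linalg.lstsq(Xr, yr, rcond=None)[0]) ** 2)), 1e-300))
            + float(np.linalg.slogdet(Xr.T @ Xr)[1]))
        if crit_zero <= crit_interior:
            delta = 0.0
            w = w1
        else:
            delta = math.exp(res.x)
            w = 1.0 / (delta * self.s + 1.0)

        XtW = Xr.T * w
        XtWX = XtW @ Xr
        XtWX_inv = np.linalg.inv(XtWX)
        beta = XtWX_inv @ (XtW @ yr)
        r = yr - Xr @ beta
        sigma_e2 = float(np.sum(w * r * r)) / (n - p)
        cov_beta = sigma_e2 * XtWX_inv
        se = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))
        blup_rot = delta * self.s * w * r
        return LMMFit(beta=beta, se=se, sigma_g2=delta * sigma_e2,
                      sigma_e2=sigma_e2, fitted_fixed=X @ beta,
                      blup=self.U @ blup_rot, n=n,
                      converged=bool(res.success or delta == 0.0))


@dataclass
class AssociationResult:
    metabolite_id: str
    trait_name: str
    beta: float
    se: float
    p: float
    significant: bool
    n: int
    sigma_g2: float
    sigma_e2: float
    error: str = ""


def _design(covariates: pd.DataFrame, extra: np.ndarray | None = None) -> np.ndarray:
    cov = covariates.copy()
    if cov["sex"].dtype == object:
        cov["sex"] = (cov["sex"] == "female").astype(float)
    X = np.column_stack([np.ones(len(cov)), cov[COVARIATE_COLUMNS].to_numpy(dtype=float)])
    if extra is not None:
        X = np.column_stack([X, extra])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise AssociationError("singular fixed-effect design (collinear columns)")
    return X


def _complete_mask(y: pd.Series, covariates: pd.DataFrame,
                   metabolite: pd.Series | None = None) -> pd.Series:
    mask = y.notna() & covariates[COVARIATE_COLUMNS].notna().all(axis=1)
    if metabolite is not None:
        mask &= metabolite.notna()
    return mask


def standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd <= 0:
        raise AssociationError("zero-variance metabolite cannot be standardized")
    return (x - x.mean()) / sd


def fit_lmm_single(
    y: TransformedTrait,
    covariates: pd.DataFrame,
    metabolite: pd.Series,
    rel: RelationshipModel,
    threshold: float = 0.05,
    workspace: LMMWorkspace | None = None,
    mask: pd.Series | None = None,
) -> AssociationResult:
    """REML fit of one (trait, metabolite) pair; Wald test on the metabolite."""
    if mask is None:
        mask = _complete_mask(y.values, covariates, metabolite)
    ids = mask.index[mask]
    if len(ids) < 30:
        raise AssociationError(f"only {len(ids)} complete cases (< 30)")
    z = standardize(metabolite.loc[ids].to_numpy(dtype=float))
    X = _design(covariates.loc[ids], z)
    if workspace is None:
        workspace = LMMWorkspace(rel.covariance(ids))
    fit = workspace.fit(X, y.values.loc[ids].to_numpy(dtype=float))
    b, s = fit.beta[-1], fit.se[-1]
    p = 2.0 * float(norm.sf(abs(b / s))) if s > 0 else math.nan
    p = max(p, 5e-324)
    return AssociationResult(
        metabolite_id=str(metabolite.name), trait_name=y.trait_name,
        beta=float(b), se=float(s), p=p, significant=bool(p < threshold),
        n=fit.n, sigma_g2=fit.sigma_g2, sigma_e2=fit.sigma_e2)


def bonferroni_threshold(n_metabolites: int, alpha: float = 0.05) -> float:
    return alpha / n_metabolites


def association_scan(
    traits: dict[str, TransformedTrait],
    matrix,                       # MetaboliteMatrix (QC'd: no missing values)
    covariates: pd.DataFrame,
    rel: RelationshipModel,
) -> pd.DataFrame:
    """One REML fit per (trait, metabolite); Bonferroni threshold 0.05 / M.

    Per-fit failures are recorded in the ``error`` column and the scan
    continues.  Output rows are ordered by (trait, metabolite id).
    """
    M = matrix.n_metabolites
    threshold = bonferroni_threshold(M)
    rows = []
    for trait_name in sorted(traits):
        tt = traits[trait_name]
        mask = _complete_mask(tt.values, covariates)
        in_matrix = set(matrix.values.index)
        ids = pd.Index([i for i in mask.index[mask] if i in in_matrix])
        ws = LMMWorkspace(rel.covariance(ids))
        sub_mask = pd.Series(True, index=ids)
        for mid in matrix.values.columns:
            col = matrix.values[mid]
            try:
                res = fit_lmm_single(tt, covariates, col, rel,
                                     threshold=threshold, workspace=ws,
                                     mask=sub_mask)
            except AssociationError as exc:
                res = AssociationResult(str(mid), trait_name, math.nan, math.nan,
                                        math.nan, False, 0, math.nan, math.nan,
                                        error=str(exc))
            rows.append(res)
    df = pd.DataFrame([r.__dict__ for r in rows])
    df = df.sort_values(["trait_name", "metabolite_id"]).reset_index(drop=True)
    df.attrs["bonferroni_threshold"] = threshold
    df.attrs["n_metabolites_tested"] = M
    return df


def residualize_trait(
    y: TransformedTrait,
    covariates: pd.DataFrame,
    rel: RelationshipModel,
) -> pd.Series:
    """Trait residuals after fixed covariates and predicted (BLUP) random effects."""
    mask = _complete_mask(y.values, covariates)
    ids = mask.index[mask]
    X = _design(covariates.loc[ids])
    ws = LMMWorkspace(rel.covariance(ids))
    fit = ws.fit(X, y.values.loc[ids].to_numpy(dtype=float))
    resid = y.values.loc[ids].to_numpy(dtype=float) - fit.fitted_fixed - fit.blup
    return pd.Series(resid, index=ids, name=f"{y.trait_name}_residual")


def residual_variance_explained(y_star: pd.Series, X_selected: pd.DataFrame) -> float:
    """Adjusted R^2 of OLS of the residualized trait on the selected metabolites.

    Uses R_adj^2 = 1 - (n - i)(1 - R^2)/(n - p) with i = 1 (intercept) and
    p counting all estimated parameters (intercept + selected metabolites).
    An empty selection explains nothing and returns 0.
    """
    if X_selected.shape[1] == 0:
        return 0.0
    common = y_star.index.intersection(X_selected.index)
    y = y_star.loc[common].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(common)),
                         X_selected.loc[common].to_numpy(dtype=float)])
    n, p = X.shape
    if p >= n:
        raise AssociationError(f"p = {p} >= n = {n}: adjusted R^2 undefined")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 0:
        raise AssociationError("constant residualized trait")
    r2 = 1.0 - float(np.sum(resid ** 2)) / tss
    return adjusted_r2(r2, n, p, i=1)


def adjusted_r2(r2: float, n: int, p: int, i: int = 1) -> float:
    if n <= p:
        raise AssociationError(f"n = {n} <= p = {p}: adjusted R^2 undefined")
    return 1.0 - (n - i) * (1.0 - r2) / (n - p)
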