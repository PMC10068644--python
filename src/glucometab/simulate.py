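"""Synthetic family-structured cohorts with known glucose-homeostasis physiology.

No public FSIGT + metabolome dataset with pedigrees exists, so every
downstream stage is exercised on synthetic cohorts whose ground truth is
known.  The generator emulates:

* multi-generation families (two founder couples plus descendants) with
  configurable count and size;
* per-individual true minimal-model physiology (S_I, S_G, AIR drawn
  log-normal with Table-1-style location/scale defaults) with a shared
  family component of configurable intraclass correlation, so traits
  cluster within pedigrees;
* fasting glucose/insulin and a full FSIGT parameter set consistent with
  the drawn traits (p1 = S_G, p3 = S_I_raw * p2, first-phase insulin peak
  sized so the 2-8 min incremental mean reproduces the drawn AIR);
* a pathway-annotated metabolite matrix with log-normal (right-skewed)
  marginals, shared latent factors inducing within-block (sub-pathway)
  correlation, planted linear effects on the transformed traits,
  detection-limit (lowest-quantile) missingness with a configurable number
  of metabolites above 50% missing, and one designated individual carrying
  many +/- 4 SD outliers.

Everything is reproducible from (config, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .association import transform_trait
from .minimal_model import FSIGTRecord, MinimalModelParams, simulate_fsigt
from .qc import MetaboliteMatrix

SUPER_PATHWAYS = [
    "Amino Acid", "Lipid", "Carbohydrate", "Nucleotide",
    "Peptide", "Cofactors and Vitamins", "Energy", "Xenobiotics",
]

#: dense FSIGT sampling schedule (minutes; t <= 0 pre-injection): minute-by-
#: minute through the first-phase response, then progressively sparser
DEFAULT_FSIGT_TIMES = np.concatenate([
    [-15.0, -10.0, -5.0, 0.0],
    np.arange(1.0, 21.0, 1.0),
    np.arange(23.0, 62.0, 3.0),
    np.arange(65.0, 185.0, 5.0),
])


@dataclass
class CohortConfig:
    """Distributional targets for the synthetic cohort.

    Location/scale defaults follow the published clinical characteristics of
    the African American family cohort the package emulates (age 42.3 +/-
    13.7 y, BMI 30.0 +/- 6.8 kg/m^2, S_I 1.64 +/- 1.17 x 1e-4, S_G 0.021 +/-
    0.008 /min, AIR 1013 +/- 830).  ``family_icc`` is the intraclass
    correlation of the shared family component injected into each
    (log-scale) physiological trait.
    """

    age_mean: float = 42.3
    age_sd: float = 13.7
    bmi_mean: float = 30.0
    bmi_sd: float = 6.8
    fraction_female: float = 0.592
    si_mean: float = 1.64            # x 1e-4 min^-1 per uU/mL
    si_sd: float = 1.17
    sg_mean: float = 0.021           # per minute
    sg_sd: float = 0.008
    air_mean: float = 1013.0         # uU/mL incremental
    air_sd: float = 830.0
    fasting_glucose_mean: float = 88.0   # mg/dL
    fasting_glucose_sd: float = 7.0
    fasting_insulin_mean: float = 7.3    # uU/mL
    fasting_insulin_sd: float = 3.5
    p2_mean: float = 0.025
    p2_sd: float = 0.005
    insulin_clearance_mean: float = 0.15  # n, per minute
    insulin_clearance_sd: float = 0.03
    secretion_gain_mean: float = 5e-3     # gamma
    secretion_gain_sd: float = 1e-3
    bolus_increment_mean: float = 190.0   # G0 - Gb, mg/dL
    bolus_increment_sd: float = 15.0
    family_icc: float = 0.30
    glucose_cv: float = 0.02         # FSIGT sampling noise
    insulin_cv: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        for name, val in asdict(self).items():
            if name.endswith(("_sd", "_cv")) and val < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.fraction_female <= 1.0:
            raise ValueError("fraction_female must be in [0, 1]")
        if not 0.0 <= self.family_icc < 1.0:
            raise ValueError("family_icc must be in [0, 1)")


def _lognormal_family(rng, mean, sd, fam_idx, n_families, icc):
    """Log-normal draws with the stated mean/SD and a shared family component.

    The log-scale variance is split icc : (1 - icc) between a family-level
    and an individual-level normal deviate, so the marginal moments are
    preserved at any icc.
    """
    n = len(fam_idx)
    b = rng.standard_normal(n_families)
    e = rng.standard_normal(n)
    if mean <= 0:
        raise ValueError("log-normal mean must be positive")
    if sd == 0:
        return np.full(n, float(mean))
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    z = math.sqrt(icc) * b[fam_idx] + math.sqrt(1.0 - icc) * e
    return np.exp(mu + math.sqrt(sigma2) * z)


def generate_cohort(pedigree: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """One row per pedigree individual: covariates, fasting values, true physiology.

    True S_G and S_I are positive (log-normal); the stored minimal-model
    parameters are internally consistent (p1 = S_G, p3 = S_I_raw * p2) and
    the first-phase insulin peak I0 is sized so that the mean incremental
    insulin over 2-8 min under clearance n reproduces the drawn AIR.
    """
    rng = np.random.default_rng(config.seed)
    ids = pedigree["individual_id"].to_numpy()
    fams = pedigree["family_id"].to_numpy()
    fam_codes, fam_idx = np.unique(fams, return_inverse=True)
    nf, n = len(fam_codes), len(ids)

    age = config.age_mean + config.age_sd * rng.standard_normal(n)
    bmi = config.bmi_mean + config.bmi_sd * rng.standard_normal(n)
    si = _lognormal_family(rng, config.si_mean, config.si_sd, fam_idx, nf,
                           config.family_icc)
    sg = _lognormal_family(rng, config.sg_mean, config.sg_sd, fam_idx, nf,
                           config.family_icc)
    air = _lognormal_family(rng, config.air_mean, config.air_sd, fam_idx, nf,
                            config.family_icc)
    gb = _lognormal_family(rng, config.fasting_glucose_mean,
                           config.fasting_glucose_sd, fam_idx, nf, 0.0)
    ib = _lognormal_family(rng, config.fasting_insulin_mean,
                           config.fasting_insulin_sd, fam_idx, nf,
                           config.family_icc)
    p2 = _lognormal_family(rng, config.p2_mean, config.p2_sd, fam_idx, nf, 0.0)
    n_clear = _lognormal_family(rng, config.insulin_clearance_mean,
                                config.insulin_clearance_sd, fam_idx, nf, 0.0)
    gamma = _lognormal_family(rng, config.secretion_gain_mean,
                              config.secretion_gain_sd, fam_idx, nf, 0.0)
    bolus = np.maximum(
        config.bolus_increment_mean
        + config.bolus_increment_sd * rng.standard_normal(n), 50.0)

    p3 = si * 1e-4 * p2
    # mean of exp(-n t) over t in [2, 8]: scales the I0 spike so the 2-8 min
    # incremental mean equals the drawn AIR
    decay_mean = (np.exp(-2.0 * n_clear) - np.exp(-8.0 * n_clear)) / (6.0 * n_clear)
    i0 = ib + air / decay_mean

    return pd.DataFrame({
        "family_id": fams,
        "sex": pedigree["sex"].to_numpy(),
        "age": age,
        "bmi": bmi,
        "fasting_glucose": gb,
        "fasting_insulin": ib,
        "true_s_i": si,
        "true_s_g": sg,
        "true_air": air,
        "true_p1": sg,
        "true_p2": p2,
        "true_p3": p3,
        "true_n": n_clear,
        "true_gamma": gamma,
        "true_h": gb,
        "true_G0": gb + bolus,
        "true_I0": i0,
        "true_Gb": gb,
        "true_Ib": ib,
    }, index=pd.Index(ids, name="individual_id"))


def params_for(cohort: pd.DataFrame, individual_id: str) -> MinimalModelParams:
    r = cohort.loc[individual_id]
    return MinimalModelParams(
        p1=r["true_p1"], p2=r["true_p2"], p3=r["true_p3"], G0=r["true_G0"],
        n=r["true_n"], gamma=r["true_gamma"], h=r["true_h"], I0=r["true_I0"],
        Gb=r["true_Gb"], Ib=r["true_Ib"])


def generate_fsigt_records(
    cohort: pd.DataFrame,
    config: CohortConfig,
    sample_times: np.ndarray = DEFAULT_FSIGT_TIMES,
    seed: int | None = None,
) -> list[FSIGTRecord]:
    """Simulate one FSIGT time course per cohort individual."""
    base = config.seed if seed is None else seed
    records = []
    for k, iid in enumerate(cohort.index):
        records.append(simulate_fsigt(
            params_for(cohort, iid), sample_times,
            noise_cv=(config.glucose_cv, config.insulin_cv),
            seed=(base, k), individual_id=str(iid)))
    return records


def measure_traits(cohort: pd.DataFrame, trait_cv: float = 0.05,
                   seed: int = 0) -> pd.DataFrame:
    """Trait panel derived from the true physiology with measurement noise.

    Multiplicative log-normal noise of coefficient of variation ``trait_cv``
    is applied to S_I, S_G and AIR; DI is the product AIR x S_I of the noisy
    values; HOMA indices come from the fasting values via the classic
    formulas.  A fast stand-in for per-individual FSIGT simulate-and-fit.
    """
    from .minimal_model import compute_homa

    rng = np.random.default_rng(seed)
    n = len(cohort)

    def noisy(x):
        if trait_cv == 0:
            return x.to_numpy(dtype=float)
        return x.to_numpy(dtype=float) * rng.lognormal(0.0, trait_cv, n)

    si = noisy(cohort["true_s_i"])
    sg = noisy(cohort["true_s_g"])
    air = noisy(cohort["true_air"])
    homa = [compute_homa(g, i) for g, i in
            zip(cohort["fasting_glucose"], cohort["fasting_insulin"])]
    return pd.DataFrame({
        "S_I": si, "S_G": sg, "AIR": air, "DI": air * si,
        "HOMA_IR": [h[0] for h in homa], "HOMA_B": [h[1] for h in homa],
    }, index=cohort.index)


@dataclass
class MetabolomeSpec:
    """Structure and planted truth of the synthetic metabolome."""

    n_metabolites: int = 733
    n_high_missing: int = 6
    high_missing_range: tuple[float, float] = (0.55, 0.80)
    background_missing_max: float = 0.05
    block_size_range: tuple[int, int] = (4, 12)
    block_corr_range: tuple[float, float] = (0.2, 0.6)
    #: trait name -> {metabolite index -> effect}, effects on the correlation
    #: scale between the metabolite and the standardized transformed trait
    effects: dict = field(default_factory=dict)
    outlier_individual: int | None = None    # positional index into the cohort
    n_outlier_metabolites: int = 132
    outlier_z: float = 8.0
    sigma_range: tuple[float, float] = (0.3, 1.0)
    mu_range: tuple[float, float] = (-0.5, 0.5)

    def __post_init__(self) -> None:
        if self.n_metabolites < 1:
            raise ValueError("n_metabolites must be >= 1")
        active = {j for d in self.effects.values() for j in d}
        if len(active) > self.n_metabolites:
            raise ValueError("more active metabolites than n_metabolites")
        if any(j < 0 or j >= self.n_metabolites for j in active):
            raise ValueError("active metabolite index out of range")


@dataclass
class SyntheticTruth:
    metabolite_ids: list[str]
    effects: dict                  # trait -> {metabolite_id -> effect}
    blocks: dict                   # metabolite_id -> block index
    block_corr: dict               # block index -> target correlation
    high_missing: list[str]
    outlier_individual_id: str | None

    def to_json(self) -> str:
        return json.dumps({
            "metabolite_ids": self.metabolite_ids,
            "effects": self.effects,
            "blocks": self.blocks,
            "block_corr": self.block_corr,
            "high_missing": self.high_missing,
            "outlier_individual_id": self.outlier_individual_id,
        }, indent=2, sort_keys=True)


def _transformed_standardized_traits(cohort: pd.DataFrame,
                                     traits: pd.DataFrame | None) -> pd.DataFrame:
    if traits is None:
        from .minimal_model import compute_homa
        homa = [compute_homa(g, i) for g, i in
                zip(cohort["fasting_glucose"], cohort["fasting_insulin"])]
        traits = pd.DataFrame({
            "S_I": cohort["true_s_i"], "S_G": cohort["true_s_g"],
            "AIR": cohort["true_air"],
            "DI": cohort["true_air"] * cohort["true_s_i"],
            "HOMA_IR": [h[0] for h in homa], "HOMA_B": [h[1] for h in homa],
        }, index=cohort.index)
    out = {}
    for name in traits.columns:
        tt = transform_trait(traits[name], name).values
        sd = tt.std(ddof=0)
        z = (tt - tt.mean()) / sd if sd > 0 else tt * 0.0
        out[name] = z.fillna(0.0)
    return pd.DataFrame(out, index=traits.index)


def generate_metabolome(
    cohort: pd.DataFrame,
    spec: MetabolomeSpec,
    seed: int,
    traits: pd.DataFrame | None = None,
) -> tuple[MetaboliteMatrix, SyntheticTruth]:
    """Pathway-annotated log-normal metabolome with planted trait effects.

    Latent scale: metabolite j in block b is z_j = sqrt(rho_b) f_b +
    sqrt(1 - rho_b) eps_j with f_b shared within the block, so the expected
    within-block pairwise correlation is rho_b.  A metabolite with planted
    effects {beta_t} becomes z_j = sum_t beta_t T_t + sqrt(1 - sum beta^2) z_j
    with T_t the standardized transformed trait, so beta_t is the latent
    metabolite-trait correlation.  Abundance = exp(mu_j + sigma_j z_j) gives
    right-skewed marginals.  Missingness censors the lowest quantiles
    (detection-limit style); ``n_high_missing`` metabolites exceed 50%.
    The designated outlier individual is planted at z = ``outlier_z`` on
    ``n_outlier_metabolites`` columns.
    """
    rng = np.random.default_rng(seed)
    n = len(cohort)
    p = spec.n_metabolites
    ids = [f"M{j + 1:04d}" for j in range(p)]

    # blocks and annotations
    lo_b, hi_b = spec.block_size_range
    sizes = []
    while sum(sizes) < p:
        sizes.append(int(rng.integers(lo_b, hi_b + 1)))
    sizes[-1] -= sum(sizes) - p
    block_of = np.repeat(np.arange(len(sizes)), sizes)
    rho = rng.uniform(*spec.block_corr_range, size=len(sizes))
    annotations = pd.DataFrame({
        "super_pathway": [SUPER_PATHWAYS[b % len(SUPER_PATHWAYS)] for b in block_of],
        "sub_pathway": [f"{SUPER_PATHWAYS[b % len(SUPER_PATHWAYS)]}: block {b:03d}"
                        for b in block_of],
    }, index=pd.Index(ids, name="metabolite_id"))

    factors = rng.standard_normal((n, len(sizes)))
    eps = rng.standard_normal((n, p))
    z = (np.sqrt(rho)[block_of] * factors[:, block_of]
         + np.sqrt(1.0 - rho[block_of]) * eps)

    # planted effects on the (standardized, transformed) trait scale
    tstd = _transformed_standardized_traits(cohort, traits)
    per_met: dict[int, list[tuple[str, float]]] = {}
    for trait, d in spec.effects.items():
        if trait not in tstd.columns:
            raise ValueError(f"effects reference unknown trait {trait!r}")
        for j, b in d.items():
            per_met.setdefault(int(j), []).append((trait, float(b)))
    for j, lst in per_met.items():
        s2 = sum(b * b for _, b in lst)
        if s2 >= 1.0:
            raise ValueError(f"metabolite index {j}: sum of squared effects {s2:.3f} >= 1")
        signal = np.zeros(n)
        for trait, b in lst:
            signal += b * tstd[trait].to_numpy()
        z[:, j] = signal + math.sqrt(1.0 - s2) * z[:, j]
    truth_effects: dict[str, dict[str, float]] = {}
    for trait, d in spec.effects.items():
        truth_effects[trait] = {ids[int(j)]: float(b) for j, b in d.items()}

    mu = rng.uniform(*spec.mu_range, size=p)
    sigma = rng.uniform(*spec.sigma_range, size=p)
    values = np.exp(mu + sigma * z)

    # outlier individual, planted before censoring so the values survive
    active = set(per_met)
    outlier_id = None
    if spec.outlier_individual is not None:
        oi = int(spec.outlier_individual)
        outlier_id = str(cohort.index[oi])
        eligible = np.array([j for j in range(p) if j not in active])
        chosen = rng.choice(eligible, size=min(spec.n_outlier_metabolites,
                                               len(eligible)), replace=False)
        values[oi, chosen] = np.exp(mu[chosen] + sigma[chosen] * spec.outlier_z)

    # detection-limit missingness: mask the lowest-quantile entries
    high_idx = rng.choice(np.array([j for j in range(p) if j not in active]),
                          size=spec.n_high_missing, replace=False)
    frac = rng.uniform(0.0, spec.background_missing_max, size=p)
    frac[high_idx] = rng.uniform(*spec.high_missing_range,
                                 size=spec.n_high_missing)
    vals = pd.DataFrame(values, index=cohort.index,
                        columns=pd.Index(ids, name="metabolite_id"))
    arr = vals.to_numpy()
    for j in range(p):
        k = int(round(frac[j] * n))
        if k > 0:
            lowest = np.argsort(arr[:, j], kind="stable")[:k]
            arr[lowest, j] = np.nan
    vals = pd.DataFrame(arr, index=vals.index, columns=vals.columns)

    truth = SyntheticTruth(
        metabolite_ids=ids,
        effects=truth_effects,
        blocks={ids[j]: int(block_of[j]) for j in range(p)},
        block_corr={int(b): float(r) for b, r in enumerate(rho)},
        high_missing=[ids[j] for j in sorted(high_idx)],
        outlier_individual_id=outlier_id,
    )
    return MetaboliteMatrix(vals, annotations), truth
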