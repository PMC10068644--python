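"""Trait transforms, REML mixed-model association and residualization."""

import numpy as np
import pandas as pd
import pytest

from glucometab.association import (AssociationError, RelationshipModel,
                                    TransformedTrait, adjusted_r2,
                                    association_scan, bonferroni_threshold,
                                    fit_lmm_single, residual_variance_explained,
                                    residualize_trait, transform_trait)
from glucometab.qc import MetaboliteMatrix


def simulate_family_data(nfam=42, fsize=14, family_var=1.0, resid_var=1.0,
                         beta_met=0.0, seed=0):
    rng = np.random.default_rng(seed)
    n = nfam * fsize
    ids = pd.Index([f"I{k:04d}" for k in range(n)], name="individual_id")
    fam = pd.Series(np.repeat([f"F{j:03d}" for j in range(nfam)], fsize), index=ids)
    cov = pd.DataFrame({
        "age": rng.normal(42, 13, n),
        "sex": rng.choice(["male", "female"], n),
        "bmi": rng.normal(30, 7, n),
    }, index=ids)
    met = pd.Series(rng.normal(size=n), index=ids, name="M0001")
    b = np.repeat(rng.normal(0, np.sqrt(family_var), nfam), fsize)
    z = (met - met.mean()) / met.std(ddof=0)
    y = (0.01 * cov["age"] + 0.2 * (cov["sex"] == "female") + beta_met * z
         + b + rng.normal(0, np.sqrt(resid_var), n))
    return pd.Series(y, index=ids), cov, met, fam


class TestTransforms:
    @pytest.mark.parametrize("trait,value,expected", [
        ("AIR", -9.0, -3.0),
        ("DI", 16.0, 4.0),
        ("HOMA_IR", np.e, 1.0),
        ("S_G", 0.021, 0.021),
    ])
    def test_fixed_transform_map(self, trait, value, expected):
        out = transform_trait(pd.Series([value]), trait)
        assert out.values.iloc[0] == pytest.approx(expected)

    def test_log_drops_nonpositive_and_records(self):
        out = transform_trait(pd.Series([1.0, 0.0, -2.0, np.nan]), "S_I")
        assert out.n_dropped_nonpositive == 2
        assert out.values.isna().tolist() == [False, True, True, True]

    def test_unknown_trait_rejected(self):
        with pytest.raises(AssociationError, match="unknown trait"):
            transform_trait(pd.Series([1.0]), "WAIST")


class TestREML:
    def test_zero_family_variance_matches_ols(self):
        y, cov, met, fam = simulate_family_data(family_var=0.0, beta_met=0.3,
                                                seed=1)
        rel = RelationshipModel.from_families(fam)
        tt = TransformedTrait("S_G", "identity", y)
        res = fit_lmm_single(tt, cov, met, rel)

        z = (met - met.mean()) / met.std(ddof=0)
        X = np.column_stack([np.ones(len(y)), cov["age"],
                             (cov["sex"] == "female").astype(float),
                             cov["bmi"], z])
        beta = np.linalg.lstsq(X, y.to_numpy(), rcond=None)[0]
        resid = y.to_numpy() - X @ beta
        s2 = resid @ resid / (len(y) - X.shape[1])
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[-1, -1])
        assert res.beta == pytest.approx(beta[-1], rel=1e-6)
        assert res.se == pytest.approx(se, rel=1e-6)

    def test_matches_statsmodels_mixedlm(self):
        """Independent oracle: statsmodels MixedLM (family random intercept)."""
        import statsmodels.formula.api as smf

        y, cov, met, fam = simulate_family_data(beta_met=0.25, seed=2)
        rel = RelationshipModel.from_families(fam)
        res = fit_lmm_single(TransformedTrait("S_G", "identity", y), cov, met, rel)

        z = (met - met.mean()) / met.std(ddof=0)
        df = pd.DataFrame({"y": y, "age": cov["age"],
                           "sexf": (cov["sex"] == "female").astype(float),
                           "bmi": cov["bmi"], "met": z, "fam": fam})
        sm_fit = smf.mixedlm("y ~ age + sexf + bmi + met", df,
                             groups="fam").fit(reml=True)
        assert res.beta == pytest.approx(sm_fit.params["met"], rel=1e-4)
        assert res.se == pytest.approx(sm_fit.bse["met"], rel=1e-4)
        assert res.sigma_g2 == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]),
                                             rel=1e-3)
        assert res.sigma_e2 == pytest.approx(sm_fit.scale, rel=1e-3)

    def test_variance_ratio_recovery_over_replicates(self):
        ratios = []
        for s in range(40):
            y, cov, met, fam = simulate_family_data(family_var=1.0,
                                                    resid_var=1.0, seed=100 + s)
            rel = RelationshipModel.from_families(fam)
            res = fit_lmm_single(TransformedTrait("S_G", "identity", y),
                                 cov, met, rel)
            ratios.append(res.sigma_g2 / res.sigma_e2)
        assert 0.8 <= float(np.median(ratios)) <= 1.25

    def test_kinship_mode_reduces_to_family_blocks_for_founder_sibs(self):
        # two full sibs share A=0.5: kinship fit differs from the family
        # intercept but both detect a strong planted effect
        from glucometab.pedigree import generate_pedigree

        ped = generate_pedigree(20, (8, 12), seed=3)
        rel = RelationshipModel.from_pedigree(ped)
        n = len(ped)
        rng = np.random.default_rng(4)
        ids = pd.Index(ped["individual_id"], name="individual_id")
        cov = pd.DataFrame({"age": rng.normal(42, 13, n),
                            "sex": rng.choice(["male", "female"], n),
                            "bmi": rng.normal(30, 7, n)}, index=ids)
        met = pd.Series(rng.normal(size=n), index=ids, name="M1")
        z = (met - met.mean()) / met.std(ddof=0)
        y = pd.Series(0.5 * z + rng.normal(0, 1, n), index=ids)
        res = fit_lmm_single(TransformedTrait("S_G", "identity", y), cov, met, rel)
        assert res.p < 1e-6
        assert res.beta == pytest.approx(0.5, abs=0.15)

    def test_collinear_design_rejected(self):
        y, cov, met, fam = simulate_family_data(seed=5)
        cov["bmi"] = cov["age"] * 2.0 - 1.0
        rel = RelationshipModel.from_families(fam)
        with pytest.raises(AssociationError, match="singular"):
            fit_lmm_single(TransformedTrait("S_G", "identity", y), cov, met, rel)

    def test_effect_monotonicity_in_wald_statistic(self):
        stats = []
        for beta in [0.0, 0.1, 0.2, 0.3, 0.4]:
            y, cov, met, fam = simulate_family_data(beta_met=beta, seed=42)
            rel = RelationshipModel.from_families(fam)
            res = fit_lmm_single(TransformedTrait("S_G", "identity", y),
                                 cov, met, rel)
            stats.append(abs(res.beta / res.se))
        assert all(b >= a for a, b in zip(stats, stats[1:]))


class TestScan:
    def make_matrix(self, ids, p, seed=0, planted=None, y=None):
        rng = np.random.default_rng(seed)
        vals = np.exp(rng.normal(size=(len(ids), p)))
        mids = [f"M{j:04d}" for j in range(p)]
        if planted:
            z = ((y - y.mean()) / y.std(ddof=0)).to_numpy()
            for j, b in planted.items():
                vals[:, j] = np.exp(b * z + np.sqrt(1 - b * b) * rng.normal(size=len(ids)))
        ann = pd.DataFrame({"super_pathway": ["Amino Acid"] * p,
                            "sub_pathway": ["BCAA"] * p},
                           index=pd.Index(mids, name="metabolite_id"))
        return MetaboliteMatrix(pd.DataFrame(vals, index=ids, columns=mids), ann)

    def test_threshold_follows_tested_metabolite_count(self):
        assert bonferroni_threshold(727) == pytest.approx(6.88e-5, abs=1e-7)
        assert bonferroni_threshold(1) == 0.05

    def test_scan_flags_planted_effects_and_is_deterministic(self):
        y, cov, _, fam = simulate_family_data(nfam=30, fsize=12, seed=6)
        rel = RelationshipModel.from_families(fam)
        matrix = self.make_matrix(y.index, 30, seed=7,
                                  planted={0: 0.4, 5: -0.4}, y=y)
        traits = {"S_G": TransformedTrait("S_G", "identity", y)}
        r1 = association_scan(traits, matrix, cov, rel)
        r2 = association_scan(traits, matrix, cov, rel)
        pd.testing.assert_frame_equal(r1, r2)
        assert r1.attrs["bonferroni_threshold"] == pytest.approx(0.05 / 30)
        sig = set(r1[r1.significant]["metabolite_id"])
        assert {"M0000", "M0005"} <= sig

    def test_scan_continues_past_failing_metabolite(self):
        y, cov, _, fam = simulate_family_data(nfam=10, fsize=10, seed=8)
        rel = RelationshipModel.from_families(fam)
        matrix = self.make_matrix(y.index, 5, seed=9)
        matrix.values["M0002"] = 1.0    # zero variance
        traits = {"S_G": TransformedTrait("S_G", "identity", y)}
        res = association_scan(traits, matrix, cov, rel)
        bad = res[res["metabolite_id"] == "M0002"]
        assert bad["error"].str.contains("zero-variance").all()
        assert res[res["metabolite_id"] != "M0002"]["error"].eq("").all()


class TestResidualize:
    def test_residuals_orthogonal_to_covariates(self):
        y, cov, _, fam = simulate_family_data(seed=10)
        rel = RelationshipModel.from_families(fam)
        y_star = residualize_trait(TransformedTrait("S_G", "identity", y),
                                   cov, rel)
        assert abs(y_star.mean()) < 1e-8
        for col in ["age", "bmi"]:
            r = np.corrcoef(y_star, cov.loc[y_star.index, col])[0, 1]
            assert abs(r) < 1e-6

    def test_exact_linear_trait_leaves_no_residual(self):
        _, cov, _, fam = simulate_family_data(family_var=0.0, seed=11)
        y = pd.Series(1.0 + 0.5 * cov["age"] - 0.2 * cov["bmi"], index=cov.index)
        rel = RelationshipModel.from_families(fam)
        y_star = residualize_trait(TransformedTrait("S_G", "identity", y),
                                   cov, rel)
        assert np.max(np.abs(y_star)) < 1e-8


class TestAdjustedR2:
    def test_printed_arithmetic_case(self):
        assert adjusted_r2(0.5, 100, 10, i=1) == pytest.approx(0.45)

    def test_exact_fit_fixed_point_and_intercept_identity(self):
        assert adjusted_r2(1.0, 50, 7) == 1.0
        assert adjusted_r2(0.37, 80, 1, i=1) == pytest.approx(0.37)

    def test_empty_selection_explains_nothing(self):
        y = pd.Series(np.random.default_rng(0).normal(size=50),
                      index=[f"I{k}" for k in range(50)])
        assert residual_variance_explained(y, pd.DataFrame(index=y.index)) == 0.0

    def test_exact_linear_function_gives_one(self):
        idx = [f"I{k}" for k in range(40)]
        x = pd.DataFrame({"M1": np.linspace(0, 1, 40)}, index=idx)
        y = pd.Series(3.0 - 2.0 * x["M1"], index=idx)
        assert residual_variance_explained(y, x) == pytest.approx(1.0)

    def test_p_not_less_than_n_rejected(self):
        idx = [f"I{k}" for k in range(5)]
        x = pd.DataFrame(np.random.default_rng(1).normal(size=(5, 5)),
                         index=idx, columns=list("abcde"))
        y = pd.Series(np.random.default_rng(2).normal(size=5), index=idx)
        with pytest.raises(AssociationError):
            residual_variance_explained(y, x)
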