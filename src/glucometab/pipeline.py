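"""End-to-end orchestration: simulate -> traits -> QC -> associate -> select -> compare.

The pipeline reproduces the workflow of a family-based metabolomics study
of glucose homeostasis on synthetic data: a family cohort with known
physiology, a pathway-structured metabolome with planted effects, minimal-
model-derived traits, QC, per-metabolite mixed-model association with
Bonferroni control, elastic-net bootstrap stability selection, and a
second-cohort effect-size comparison.  Reporting mirrors the study's
surfaces: a cohort characteristics table, the top metabolite per
super-pathway, overlap counts between trait-significant sets, a Spearman
trait-correlation matrix, the cross-cohort comparison table and a residual
variance-explained table.

Determinism: the global seed is expanded through ``numpy.random.SeedSequence``
into per-stage seeds, and all floats are written at fixed precision, so the
same config yields byte-identical output directories.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .association import (RelationshipModel, TRAIT_TRANSFORMS,
                          association_scan, residual_variance_explained,
                          residualize_trait, transform_trait)
from .compare import comparison_scan
from .elastic_net import (ElasticNetConfig, ElasticNetProblem,
                          bootstrap_model_average)
from .minimal_model import compute_air, compute_di, fit_glucose_minimal_model
from .pedigree import generate_pedigree, write_ped
from .qc import run_qc
from .simulate import (CohortConfig, MetabolomeSpec, generate_cohort,
                       generate_fsigt_records, generate_metabolome,
                       measure_traits, params_for)

logger = logging.getLogger(__name__)

TRAITS = list(TRAIT_TRANSFORMS)


@dataclass
class PipelineConfig:
    """All stage parameters plus the global seed and output directory."""

    seed: int = 1
    outdir: str | None = None
    # cohort 1 (the primary cohort)
    n_families: int = 42
    family_size_range: tuple[int, int] = (10, 18)
    total_individuals: int = 572
    # cohort 2 (the comparison cohort); same machinery, larger n
    run_compare: bool = True
    n_families2: int = 80
    total_individuals2: int = 1112
    # metabolome
    n_metabolites: int = 733
    n_high_missing: int = 6
    n_active_per_trait: int = 5
    planted_effect: float = 0.30
    glutamate_like_effect: float = -0.35    # on transformed S_I, cohort 1
    glutamate_like_effect2: float = -0.12   # cohort 2
    # traits
    trait_mode: str = "true_params"         # or "fsigt_fit"
    trait_cv: float = 0.05
    fit_window_start: float = 8.0
    # QC
    max_missing_fraction: float = 0.5
    sd_bound: float = 4.0
    max_outlier_count: int = 100
    # association
    rel_mode: str = "family_intercept"      # or "kinship"
    # selection
    run_select: bool = True
    alpha: float = 0.5
    n_bootstrap: int = 200                  # desk-scale default (study used 2000)
    train_fraction: float = 0.9
    selection_threshold: float = 0.20
    n_grid: int = 25

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("family_size_range",):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d.pop("outdir", None)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass
class ReportBundle:
    cohort_summary: pd.DataFrame
    top_by_superpathway: pd.DataFrame
    overlaps: pd.DataFrame
    trait_correlations: pd.DataFrame
    comparison: pd.DataFrame | None
    residual_r2: pd.DataFrame | None
    association: pd.DataFrame = field(default=None, repr=False)
    selection: pd.DataFrame | None = field(default=None, repr=False)
    qc_report: object = field(default=None, repr=False)
    truth: object = field(default=None, repr=False)
    n_individuals: int = 0
    n_metabolites: int = 0
    bonferroni_threshold: float = float("nan")


def _stage_seeds(seed: int, n: int = 12) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s % (2 ** 31)) for s in ss.generate_state(n)]


def default_effects(cfg: PipelineConfig, cohort2: bool = False) -> dict:
    """Planted-truth layout used by the default synthetic study.

    ``n_active_per_trait`` metabolites per trait at +/- ``planted_effect``
    (alternating sign), laid out on disjoint index ranges, plus one
    designated glutamate-like metabolite (index 0) with a differential
    effect on transformed S_I between the two cohorts.
    """
    effects: dict[str, dict[int, float]] = {t: {} for t in TRAITS}
    # at tiny metabolome sizes, shrink the planted sets to fit
    per_trait = min(cfg.n_active_per_trait, (cfg.n_metabolites - 1) // len(TRAITS))
    nxt = 1  # index 0 is reserved for the glutamate-like metabolite
    for t in TRAITS:
        for k in range(per_trait):
            effects[t][nxt] = cfg.planted_effect * (1 if k % 2 == 0 else -1)
            nxt += 1
    glu = cfg.glutamate_like_effect2 if cohort2 else cfg.glutamate_like_effect
    effects["S_I"][0] = glu
    return effects


def _traits_from_fsigt(cohort, config: CohortConfig, seed: int,
                       fit_window_start: float) -> pd.DataFrame:
    """Trait panel via per-individual FSIGT simulation and minimal-model fitting."""
    from .minimal_model import compute_homa

    records = generate_fsigt_records(cohort, config, seed=seed)
    rows = {}
    for rec in records:
        truth = params_for(cohort, rec.individual_id)
        fit = fit_glucose_minimal_model(rec, fit_window_start=fit_window_start,
                                        n_starts=3, seed=seed, x0=truth)
        air = compute_air(rec)
        homa_ir, homa_b = compute_homa(cohort.loc[rec.individual_id, "fasting_glucose"],
                                       cohort.loc[rec.individual_id, "fasting_insulin"])
        rows[rec.individual_id] = {
            "S_I": fit.s_i, "S_G": fit.s_g, "AIR": air,
            "DI": compute_di(air, fit.s_i),
            "HOMA_IR": homa_ir, "HOMA_B": homa_b,
        }
    return pd.DataFrame.from_dict(rows, orient="index").loc[cohort.index]


def _simulate_cohort(cfg: PipelineConfig, seeds: list[int], cohort2: bool):
    if cohort2:
        nf, total = cfg.n_families2, cfg.total_individuals2
        s_ped, s_cohort, s_met, s_traits = seeds[6], seeds[7], seeds[8], seeds[9]
    else:
        nf, total = cfg.n_families, cfg.total_individuals
        s_ped, s_cohort, s_met, s_traits = seeds[0], seeds[1], seeds[2], seeds[3]
    ped = generate_pedigree(nf, cfg.family_size_range, seed=s_ped,
                            total_size=total)
    ccfg = CohortConfig(seed=s_cohort)
    cohort = generate_cohort(ped, ccfg)
    if cfg.trait_mode == "fsigt_fit":
        traits = _traits_from_fsigt(cohort, ccfg, s_traits, cfg.fit_window_start)
    else:
        traits = measure_traits(cohort, trait_cv=cfg.trait_cv, seed=s_traits)
    spec = MetabolomeSpec(
        n_metabolites=cfg.n_metabolites,
        n_high_missing=cfg.n_high_missing,
        effects=default_effects(cfg, cohort2=cohort2),
        outlier_individual=None if cohort2 else 0,
    )
    matrix, truth = generate_metabolome(cohort, spec, seed=s_met, traits=traits)
    return ped, cohort, traits, matrix, truth


def _associate(cfg: PipelineConfig, ped, cohort, traits, qc_matrix):
    if cfg.rel_mode == "kinship":
        rel = RelationshipModel.from_pedigree(ped)
    else:
        rel = RelationshipModel.from_families(cohort["family_id"])
    ids = qc_matrix.values.index
    covars = cohort.loc[ids, ["age", "sex", "bmi"]]
    transformed = {t: transform_trait(traits.loc[ids, t], t) for t in TRAITS}
    results = association_scan(transformed, qc_matrix, covars, rel)
    return results, rel, transformed, covars


def trait_correlations(traits: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise Spearman correlations with pairwise-complete observations."""
    corr = traits.corr(method="spearman", min_periods=min_pairs)
    for t in traits.columns:
        if traits[t].nunique(dropna=True) <= 1:
            logger.warning("trait %s is constant: correlation undefined", t)
            corr.loc[t, :] = np.nan
            corr.loc[:, t] = np.nan
    return corr


def summarize_top_by_superpathway(results: pd.DataFrame,
                                  annotations: pd.DataFrame,
                                  threshold: float) -> pd.DataFrame:
    """Per (trait, super-pathway): significant count + the minimum-P metabolite.

    Exact-P ties break to the lexicographically smaller metabolite id;
    super-pathways without significant metabolites are omitted; metabolites
    missing annotation are excluded with a warning.
    """
    sig = results[results["p"] < threshold].copy()
    unannotated = set(sig["metabolite_id"]) - set(annotations.index.astype(str))
    if unannotated:
        logger.warning("excluding %d unannotated metabolites from the summary",
                       len(unannotated))
        sig = sig[~sig["metabolite_id"].isin(unannotated)]
    if sig.empty:
        return pd.DataFrame(columns=["trait_name", "super_pathway",
                                     "n_significant", "metabolite_id",
                                     "sub_pathway", "beta", "se", "p"])
    ann = annotations.copy()
    ann.index = ann.index.astype(str)
    sig = sig.join(ann, on="metabolite_id")
    sig = sig.sort_values(["trait_name", "super_pathway", "p", "metabolite_id"])
    counts = (sig.groupby(["trait_name", "super_pathway"], sort=True)
              .size().rename("n_significant"))
    top = (sig.groupby(["trait_name", "super_pathway"], sort=True)
           .head(1).set_index(["trait_name", "super_pathway"]))
    out = counts.to_frame().join(
        top[["metabolite_id", "sub_pathway", "beta", "se", "p"]]).reset_index()
    return out


def overlap_summary(significant_sets: dict[str, set]) -> pd.DataFrame:
    """|A intersect B| for every trait pair plus per-set sizes."""
    names = sorted(significant_sets)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            rows.append({
                "trait_a": a, "trait_b": b,
                "size_a": len(significant_sets[a]),
                "size_b": len(significant_sets[b]),
                "overlap": len(significant_sets[a] & significant_sets[b]),
            })
    return pd.DataFrame(rows)


def _cohort_summary(cohort: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    panel = pd.concat([cohort[["age", "bmi"]], traits], axis=1)
    rows = []
    for col in panel.columns:
        v = panel[col].dropna()
        rows.append({"variable": col, "n": len(v), "mean": v.mean(),
                     "sd": v.std(ddof=1), "q25": v.quantile(0.25),
                     "q75": v.quantile(0.75)})
    rows.append({"variable": "percent_female", "n": len(cohort),
                 "mean": 100.0 * (cohort["sex"] == "female").mean(),
                 "sd": np.nan, "q25": np.nan, "q75": np.nan})
    return pd.DataFrame(rows)


def _select(cfg: PipelineConfig, transformed, covars, rel, qc_matrix, seeds):
    rows = []
    r2_rows = []
    for k, t in enumerate(sorted(transformed)):
        tt = transformed[t]
        y_star = residualize_trait(tt, covars, rel)
        try:
            prob = ElasticNetProblem.from_matrix(y_star, qc_matrix.values,
                                                 family=rel.family)
        except Exception as exc:   # zero-variance columns etc.
            logger.warning("selection skipped for %s: %s", t, exc)
            continue
        # cap the grid-search active set at ~n/8: with p comparable to n the
        # adjusted-R^2 criterion otherwise saturates the path, which both
        # defeats a stability selection and makes every draw nearly dense
        en_cfg = ElasticNetConfig(
            alpha=cfg.alpha, n_bootstrap=cfg.n_bootstrap,
            train_fraction=cfg.train_fraction,
            selection_threshold=cfg.selection_threshold,
            n_grid=cfg.n_grid, max_active=max(10, len(prob.y) // 8),
            seed=(seeds[10] + k) % (2 ** 31))
        result = bootstrap_model_average(prob, en_cfg)
        tab = result.table.reset_index()
        tab.insert(0, "trait_name", t)
        tab["lambda"] = result.lambda_
        rows.append(tab)
        r2_rows.append((t, result, y_star))
    selection = pd.concat(rows, ignore_index=True) if rows else None
    return selection, r2_rows


def _residual_r2_table(results: pd.DataFrame, threshold: float,
                       r2_rows, qc_matrix) -> pd.DataFrame:
    out = []
    for t, result, y_star in r2_rows:
        sig = results[(results["trait_name"] == t)
                      & (results["p"] < threshold)]["metabolite_id"]
        uni_ids = [m for m in sig if m in qc_matrix.values.columns]
        sel_ids = [m for m in result.selected if m in qc_matrix.values.columns]
        def safe_r2(ids):
            if len(ids) == 0:
                return 0.0
            if len(ids) + 1 >= len(y_star):
                return np.nan
            return residual_variance_explained(y_star, qc_matrix.values[ids])
        out.append({"trait_name": t,
                    "n_univariate_significant": len(uni_ids),
                    "r2_adj_univariate": safe_r2(uni_ids),
                    "n_selected": len(sel_ids),
                    "r2_adj_selected": safe_r2(sel_ids)})
    return pd.DataFrame(out)


def rebuild_reports(outdir) -> None:
    """Re-derive every report table from the persisted intermediates.

    Reads association.tsv, traits.tsv, metabolome_qc.tsv, annotations.tsv,
    cohort.tsv (and comparison.tsv when present) from a completed run
    directory and rewrites the report_*.tsv surfaces from them alone.
    """
    outdir = Path(outdir)
    assoc = pd.read_csv(outdir / "association.tsv", sep="\t").fillna({"error": ""})
    qc_vals = pd.read_csv(outdir / "metabolome_qc.tsv", sep="\t", index_col=0)
    annotations = pd.read_csv(outdir / "annotations.tsv", sep="\t", index_col=0)
    traits = pd.read_csv(outdir / "traits.tsv", sep="\t", index_col=0)
    cohort = pd.read_csv(outdir / "cohort.tsv", sep="\t", index_col=0)
    thr = 0.05 / qc_vals.shape[1]
    ids = qc_vals.index
    sig_sets = {t: set(assoc[(assoc.trait_name == t) & (assoc.p < thr)]
                       ["metabolite_id"]) for t in TRAITS}
    gio.write_table(_cohort_summary(cohort.loc[ids], traits.loc[ids]),
                    outdir / "report_cohort_summary.tsv", index=False)
    gio.write_table(summarize_top_by_superpathway(assoc, annotations, thr),
                    outdir / "report_top_by_superpathway.tsv", index=False)
    gio.write_table(overlap_summary(sig_sets),
                    outdir / "report_overlaps.tsv", index=False)
    gio.write_table(trait_correlations(traits.loc[ids]),
                    outdir / "report_trait_correlations.tsv")


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every enabled stage in order and assemble the report bundle.

    When ``config.outdir`` is set, every intermediate table is persisted as
    TSV (JSON twins for QC/truth/config) and a run log records parameters,
    seeds and per-stage shapes.  Identical config + seed reproduce the
    output directory byte for byte.
    """
    seeds = _stage_seeds(config.seed)
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    # outdir is excluded from the persisted config/log so that runs into
    # different directories remain byte-identical
    log: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in asdict(config).items() if k != "outdir"},
                 "stage_seeds": seeds, "stages": {}}
    log["config_hash"] = hashlib.sha256(
        json.dumps(log["config"], sort_keys=True).encode()).hexdigest()

    # --- simulate + traits -------------------------------------------------
    ped, cohort, traits, matrix, truth = _simulate_cohort(config, seeds, False)
    log["stages"]["simulate"] = {"n_individuals": len(cohort),
                                 "n_metabolites": matrix.n_metabolites}
    # --- QC ----------------------------------------------------------------
    qc_matrix, qc_report = run_qc(matrix, config.max_missing_fraction,
                                  config.sd_bound, config.max_outlier_count)
    log["stages"]["qc"] = {"n_individuals": qc_matrix.n_individuals,
                           "n_metabolites": qc_matrix.n_metabolites}
    # --- association -------------------------------------------------------
    results, rel, transformed, covars = _associate(config, ped, cohort,
                                                   traits, qc_matrix)
    threshold = results.attrs["bonferroni_threshold"]
    log["stages"]["associate"] = {"n_tests": len(results),
                                  "bonferroni_threshold": threshold}
    # --- selection ---------------------------------------------------------
    selection = residual_r2 = None
    if config.run_select:
        selection, r2_rows = _select(config, transformed, covars, rel,
                                     qc_matrix, seeds)
        residual_r2 = _residual_r2_table(results, threshold, r2_rows, qc_matrix)
        log["stages"]["select"] = {"n_rows": 0 if selection is None else len(selection)}
    # --- comparison cohort -------------------------------------------------
    comparison = None
    if config.run_compare:
        ped2, cohort2, traits2, matrix2, _ = _simulate_cohort(config, seeds, True)
        qc2, _ = run_qc(matrix2, config.max_missing_fraction,
                        config.sd_bound, config.max_outlier_count)
        results2, *_ = _associate(config, ped2, cohort2, traits2, qc2)
        comparison = comparison_scan(results, results2,
                                     threshold_m=qc_matrix.n_metabolites)
        log["stages"]["compare"] = {"n_rows": len(comparison)}
        if outdir:
            gio.write_table(results2, outdir / "association_cohort2.tsv", index=False)

    # --- reports -----------------------------------------------------------
    ids = qc_matrix.values.index
    sig_sets = {
        t: set(results[(results["trait_name"] == t)
                       & (results["p"] < threshold)]["metabolite_id"])
        for t in TRAITS
    }
    bundle = ReportBundle(
        cohort_summary=_cohort_summary(cohort.loc[ids], traits.loc[ids]),
        top_by_superpathway=summarize_top_by_superpathway(
            results, qc_matrix.annotations, threshold),
        overlaps=overlap_summary(sig_sets),
        trait_correlations=trait_correlations(traits.loc[ids]),
        comparison=comparison,
        residual_r2=residual_r2,
        association=results,
        selection=selection,
        qc_report=qc_report,
        truth=truth,
        n_individuals=qc_matrix.n_individuals,
        n_metabolites=qc_matrix.n_metabolites,
        bonferroni_threshold=threshold,
    )

    if outdir:
        write_ped(ped, outdir / "pedigree.ped")
        gio.write_table(cohort, outdir / "cohort.tsv")
        gio.write_table(traits, outdir / "traits.tsv")
        gio.write_matrix(matrix, outdir / "metabolome_raw.tsv",
                         outdir / "annotations.tsv")
        gio.write_matrix(qc_matrix, outdir / "metabolome_qc.tsv")
        (outdir / "qc_report.json").write_text(qc_report.to_json())
        (outdir / "truth.json").write_text(truth.to_json())
        gio.write_table(results, outdir / "association.tsv", index=False)
        if selection is not None:
            gio.write_table(selection, outdir / "selection.tsv", index=False)
        if comparison is not None:
            gio.write_table(comparison, outdir / "comparison.tsv", index=False)
        gio.write_table(bundle.cohort_summary, outdir / "report_cohort_summary.tsv", index=False)
        gio.write_table(bundle.top_by_superpathway, outdir / "report_top_by_superpathway.tsv", index=False)
        gio.write_table(bundle.overlaps, outdir / "report_overlaps.tsv", index=False)
        gio.write_table(bundle.trait_correlations, outdir / "report_trait_correlations.tsv")
        if bundle.residual_r2 is not None:
            gio.write_table(bundle.residual_r2, outdir / "report_residual_r2.tsv", index=False)
        config.to_yaml(outdir / "config.yaml")
        (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return bundle
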