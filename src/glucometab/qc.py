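"""Metabolite-matrix quality control.

The delivered relative-abundance matrix (individuals x metabolites, with
super-/sub-pathway annotations) is cleaned in a fixed order:

1. drop metabolites with > 50% missing values (strict inequality);
2. impute remaining missing entries to the per-metabolite observed minimum
   (detection-limit censoring);
3. rescale each metabolite so its median equals one;
4. drop individuals carrying more than ``max_outlier_count`` metabolites
   beyond +/- 4 SD (computed on the rescaled, pre-winsorization values --
   after 1%/99% capping no 4-SD outlier can exist, so detection must come
   first);
5. winsorize each metabolite at the 1st and 99th percentiles (type-7
   linearly interpolated quantiles).

Every removal is recorded in a QCReport whose per-step counts satisfy
before - removed = after.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = ["super_pathway", "sub_pathway"]


class QCError(ValueError):
    pass


@dataclass
class MetaboliteMatrix:
    """Individuals x metabolites relative abundances plus pathway annotations.

    ``values`` is a DataFrame indexed by individual id with metabolite-id
    columns; NaN marks a missing (non-detected) measurement.  ``annotations``
    is indexed by metabolite id with super_pathway / sub_pathway columns.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.empty:
            raise QCError("empty metabolite matrix")
        if (self.values < 0).any().any():
            raise QCError("negative abundances present")
        missing_ann = set(self.values.columns) - set(self.annotations.index)
        if missing_ann:
            raise QCError(f"metabolites without annotation: {sorted(missing_ann)[:5]} ...")
        for col in ANNOTATION_COLUMNS:
            if col not in self.annotations.columns:
                raise QCError(f"annotations missing column {col!r}")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def subset(self, individuals=None, metabolites=None) -> "MetaboliteMatrix":
        vals = self.values
        if individuals is not None:
            vals = vals.loc[individuals]
        if metabolites is not None:
            vals = vals[metabolites]
        return MetaboliteMatrix(vals, self.annotations.loc[vals.columns])


@dataclass
class QCReport:
    steps: list = field(default_factory=list)
    metabolites_removed: dict = field(default_factory=dict)   # id -> reason
    individuals_removed: dict = field(default_factory=dict)   # id -> outlier count
    thresholds: dict = field(default_factory=dict)

    def record(self, step: str, before: int, removed: int, details=None) -> None:
        self.steps.append({
            "step": step, "before": before,
            "removed": removed, "after": before - removed,
            "details": details or {},
        })

    def merged_with(self, other: "QCReport") -> "QCReport":
        out = QCReport(steps=self.steps + other.steps,
                       metabolites_removed={**self.metabolites_removed,
                                            **other.metabolites_removed},
                       individuals_removed={**self.individuals_removed,
                                            **other.individuals_removed},
                       thresholds={**self.thresholds, **other.thresholds})
        return out

    def to_json(self) -> str:
        return json.dumps({
            "steps": self.steps,
            "metabolites_removed": self.metabolites_removed,
            "individuals_removed": self.individuals_removed,
            "thresholds": self.thresholds,
        }, indent=2, sort_keys=True)

    def log_lines(self) -> list[str]:
        return [
            f"{s['step']}: {s['before']} -> {s['after']} (removed {s['removed']})"
            for s in self.steps
        ]


def filter_high_missingness(
    m: MetaboliteMatrix, max_missing_fraction: float = 0.5
) -> tuple[MetaboliteMatrix, QCReport]:
    """Drop metabolites whose missing fraction strictly exceeds the threshold."""
    frac = m.values.isna().mean(axis=0)
    drop = frac.index[frac > max_missing_fraction]
    report = QCReport(thresholds={"max_missing_fraction": max_missing_fraction})
    for mid in drop:
        report.metabolites_removed[mid] = f"missing fraction {frac[mid]:.3f} > {max_missing_fraction}"
    report.record("filter_high_missingness", m.n_metabolites, len(drop),
                  {"removed_metabolites": list(drop)})
    keep = [c for c in m.values.columns if c not in set(drop)]
    return m.subset(metabolites=keep), report


def impute_to_minimum(m: MetaboliteMatrix) -> MetaboliteMatrix:
    """Replace each missing entry by that metabolite's observed minimum."""
    all_missing = m.values.columns[m.values.isna().all(axis=0)]
    if len(all_missing) > 0:
        raise QCError(f"all-missing metabolites must be filtered first: {list(all_missing)[:5]}")
    filled = m.values.fillna(m.values.min(axis=0))
    return MetaboliteMatrix(filled, m.annotations)


def rescale_to_unit_median(m: MetaboliteMatrix) -> MetaboliteMatrix:
    """Divide each metabolite by its median so every column median is 1."""
    if m.values.isna().any().any():
        raise QCError("missing entries present: impute before rescaling")
    med = m.values.median(axis=0)
    zero = med.index[med <= 0]
    if len(zero) > 0:
        raise QCError(f"nonpositive median, cannot rescale: {list(zero)[:5]}")
    return MetaboliteMatrix(m.values / med, m.annotations)


def winsorize(
    m: MetaboliteMatrix, lower: float = 0.01, upper: float = 0.99
) -> MetaboliteMatrix:
    """Cap each metabolite at its ``lower``/``upper`` type-7 quantiles."""
    if lower >= upper:
        raise QCError(f"lower quantile {lower} must be < upper {upper}")
    if m.values.isna().any().any():
        raise QCError("missing entries present: impute before winsorizing")
    arr = m.values.to_numpy(dtype=float)
    lo = np.quantile(arr, lower, axis=0)  # linear interpolation (type 7)
    hi = np.quantile(arr, upper, axis=0)
    capped = np.clip(arr, lo, hi)
    return MetaboliteMatrix(
        pd.DataFrame(capped, index=m.values.index, columns=m.values.columns),
        m.annotations,
    )


def exclude_outlier_individuals(
    m: MetaboliteMatrix, sd_bound: float = 4.0, max_outlier_count: int = 100
) -> tuple[MetaboliteMatrix, QCReport]:
    """Drop individuals with more than ``max_outlier_count`` +/- ``sd_bound`` SD values.

    Computed per metabolite on the (rescaled, pre-winsorization) values with
    the individual under test included in the mean/SD.
    """
    if max_outlier_count < 0:
        raise QCError("max_outlier_count must be >= 0")
    if m.values.isna().any().any():
        raise QCError("missing entries present: impute before outlier screening")
    arr = m.values.to_numpy(dtype=float)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore"):
        flags = np.abs(arr - mean) > sd_bound * sd
    counts = pd.Series(flags.sum(axis=1), index=m.values.index)
    drop = counts.index[counts > max_outlier_count]
    report = QCReport(thresholds={"sd_bound": sd_bound,
                                  "max_outlier_count": max_outlier_count})
    for iid in drop:
        report.individuals_removed[iid] = int(counts[iid])
    report.record("exclude_outlier_individuals", m.n_individuals, len(drop),
                  {"outlier_counts": {i: int(counts[i]) for i in drop}})
    keep = [i for i in m.values.index if i not in set(drop)]
    return m.subset(individuals=keep), report


def run_qc(
    m: MetaboliteMatrix,
    max_missing_fraction: float = 0.5,
    sd_bound: float = 4.0,
    max_outlier_count: int = 100,
    winsor_lower: float = 0.01,
    winsor_upper: float = 0.99,
) -> tuple[MetaboliteMatrix, QCReport]:
    """Full QC: filter -> impute -> rescale -> outlier-exclude -> winsorize."""
    m1, rep1 = filter_high_missingness(m, max_missing_fraction)
    m2 = impute_to_minimum(m1)
    m3 = rescale_to_unit_median(m2)
    m4, rep2 = exclude_outlier_individuals(m3, sd_bound, max_outlier_count)
    m5 = winsorize(m4, winsor_lower, winsor_upper)
    report = rep1.merged_with(rep2)
    report.record("winsorize", m4.n_metabolites, 0,
                  {"lower": winsor_lower, "upper": winsor_upper})
    return m5, report
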