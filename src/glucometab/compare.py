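"""Cross-cohort effect-size heterogeneity tests.

Two disjoint cohorts (e.g. two ancestry groups profiled with the same
protocol) yield per-metabolite effect estimates (beta, SE) on each trait.
The difference is tested with the independent-samples Z statistic

    Z = (beta1 - beta2) / sqrt(SE1^2 + SE2^2),    P = 2 * (1 - Phi(|Z|)),

with Bonferroni control at 0.05 / M over the M metabolites tested.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)


class ComparisonError(ValueError):
    pass


def z_difference_test(beta1: float, se1: float, beta2: float, se2: float) -> tuple[float, float]:
    """Z and two-sided P for the difference of two independent effect estimates."""
    if se1 <= 0 or se2 <= 0:
        raise ComparisonError("standard errors must be positive")
    z = (beta1 - beta2) / np.sqrt(se1 ** 2 + se2 ** 2)
    p = 2.0 * float(norm.sf(abs(z)))
    return float(z), max(p, 5e-324)


def comparison_scan(
    results1: pd.DataFrame,
    results2: pd.DataFrame,
    threshold_m: int,
) -> pd.DataFrame:
    """Per-(metabolite, trait) heterogeneity Z tests between two cohorts.

    Inner-joins the two association tables on (metabolite_id, trait_name);
    unmatched rows are logged and dropped.  Significance at 0.05/threshold_m.
    """
    keys = ["metabolite_id", "trait_name"]
    cols = keys + ["beta", "se"]
    for df, name in ((results1, "results1"), (results2, "results2")):
        missing = set(cols) - set(df.columns)
        if missing:
            raise ComparisonError(f"{name} missing columns {sorted(missing)}")
    merged = results1[cols].merge(results2[cols], on=keys, suffixes=("1", "2"))
    n_lost = len(results1) + len(results2) - 2 * len(merged)
    if n_lost > 0:
        logger.warning("comparison join dropped %d unmatched rows", n_lost)
    if merged.empty:
        if len(results1) == 0 and len(results2) == 0:
            logger.warning("comparison of two empty tables")
            return pd.DataFrame(columns=keys + ["beta1", "se1", "beta2", "se2",
                                                "z", "p", "significant"])
        raise ComparisonError("no shared (metabolite, trait) keys between cohorts")

    ok = (merged["se1"] > 0) & (merged["se2"] > 0)
    if (~ok).any():
        logger.warning("dropping %d rows with nonpositive SE", int((~ok).sum()))
        merged = merged[ok]
    denom = np.sqrt(merged["se1"] ** 2 + merged["se2"] ** 2)
    z = (merged["beta1"] - merged["beta2"]) / denom
    p = 2.0 * norm.sf(np.abs(z))
    thr = 0.05 / threshold_m
    out = merged.assign(z=z, p=np.maximum(p, 5e-324), significant=p < thr)
    out = out.sort_values(keys).reset_index(drop=True)
    out.attrs["bonferroni_threshold"] = thr
    return out
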