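# glucometab

Metabolomics of glucose homeostasis in family cohorts: minimal-model trait
estimation from FSIGT data, metabolite quality control, pedigree-adjusted
mixed-model association, elastic-net stability selection, and cross-cohort
effect-size comparison — exercised end to end on synthetic family-structured
data with known ground truth.

## Who this is for

Quantitative geneticists and metabolomics analysts who work with dynamic
glucose-homeostasis phenotypes (frequently sampled intravenous glucose
tolerance tests, FSIGT) in related individuals, and who want a tested,
reproducible reference implementation of the full analysis chain — from raw
glucose/insulin time courses to per-metabolite effect sizes and
between-cohort heterogeneity tests. Because no public dataset couples FSIGT
physiology, pedigrees and an untargeted metabolome, the package ships a
synthetic-cohort generator whose planted truth makes every downstream stage
verifiable.

## The models

**Minimal model of glucose disappearance.** After a glucose bolus at t = 0,
plasma glucose G(t) and a remote insulin-action state X(t) follow

    dG/dt = -(p1 + X) G + p1 Gb,        G(0) = G0
    dX/dt = -p2 X + p3 (I(t) - Ib),     X(0) = 0

with observed insulin I(t) as the forcing input. Glucose effectiveness is
S_G = p1 and insulin sensitivity S_I = p3/p2 (reported in the conventional
x 10^-4 min^-1 per uU/mL units). Insulin kinetics follow
dI/dt = -n I + gamma (G - h)+ t from I(0) = I0. Derived indices: the acute
insulin response AIR (mean 2-8 min insulin increment above basal), the
disposition index DI = AIR x S_I, and the classic fasting surrogates
HOMA-IR = G I / 22.5 and HOMA-B = 20 I / (G - 3.5) with G in mmol/L.

**Association.** Each trait is transformed toward normality (log for S_I,
HOMA-IR, HOMA-B; sign-retaining square root for AIR and DI; S_G untouched)
and tested one metabolite at a time in a linear mixed model with age, sex,
BMI and a pedigree random effect (family intercept, or a kinship covariance
from the additive relationship matrix), REML-estimated on the eigenbasis of
the relationship structure. Significance uses the Bonferroni threshold
0.05/M over the M metabolites that pass QC.

**Selection.** The scaled elastic net minimizes the literal sum-of-squares
objective

    sum_i (y*_i - b0 - sum_j b_j X_ij)^2
        + lambda sum_j [ (1-alpha)/2 b_j^2 + alpha |b_j| ]

on residualized traits y* and standardized metabolites X, with the ridge
weight chosen by a log-grid search on the adjusted R^2 criterion
R_adj^2 = 1 - (n-i)(1-R^2)/(n-p). Stability selection refits the model on
bootstrap draws (90% of the sample, whole families by default), refits
unpenalized least squares on each draw's active set, reports metabolites
selected in more than 20% of draws, and model-averages coefficients
including zeros.

**Comparison.** Effect sizes from two cohorts are contrasted with the
independent-samples Z statistic, Z = (b1 - b2) / sqrt(SE1^2 + SE2^2).

## Worked example

`examples/05_ancestry_comparison.py` recomputes the between-cohort
heterogeneity of the glutamate effect on each trait from published
per-cohort coefficients:

```
threshold 0.05/727 = 6.88e-05
trait          Z          P  significant
S_I        -4.61   4.07e-06  True
AIR        -0.13   8.98e-01  False
DI         -3.85   1.20e-04  False
S_G        -3.01   2.60e-03  False
HOMA_IR     3.26   1.13e-03  False
HOMA_B      1.62   1.06e-01  False
```

Only insulin sensitivity is heterogeneous at the Bonferroni threshold: the
glutamate effect on log S_I (-0.352 per SD) in the first cohort is about
three times the second cohort's (-0.117), and the pooled-SE Z test puts
that difference at P ~ 4e-6 < 6.88e-5. Each other trait's printed P is
reproduced from its printed betas/SEs by the same formula.

`examples/01_minimal_model_fit.py` simulates one FSIGT at 2% sampling noise
and recovers the physiology by fitting:

```
true  S_G = 0.0200 /min   S_I = 4.00 x1e-4
fitted S_G = 0.0206 /min   S_I = 4.11 x1e-4
AIR = 692 uU/mL (mean 2-8 min increment above basal)
DI  = 2843 (AIR x S_I: beta-cell compensation)
HOMA-IR = 1.76, HOMA-B = 106% from fasting values
```

The remaining examples cover QC (`02`), the mixed-model scan (`03`),
stability selection (`04`) and the full pipeline (`06`). A thin CLI mirrors
the stages: `glucometab run-all --seed 1 --outdir out/`, plus `simulate`,
`traits`, `qc`, `associate`, `select` and `compare` subcommands.

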