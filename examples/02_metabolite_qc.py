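"""Quality-control a synthetic metabolite matrix the way the study panel is
cleaned: missingness filter, minimum imputation, unit-median rescaling,
outlier-individual screen, 1%/99% winsorization."""

from glucometab import CohortConfig, MetabolomeSpec, generate_cohort, run_qc
from glucometab.pedigree import generate_pedigree
from glucometab.simulate import generate_metabolome

ped = generate_pedigree(10, (10, 14), seed=3)
cohort = generate_cohort(ped, CohortConfig(seed=4))
spec = MetabolomeSpec(n_metabolites=200, n_high_missing=3,
                      outlier_individual=0, n_outlier_metabolites=60)
matrix, truth = generate_metabolome(cohort, spec, seed=5)

clean, report = run_qc(matrix, max_missing_fraction=0.5, sd_bound=4.0,
                       max_outlier_count=40)
for line in report.log_lines():
    print(line)
print(f"retained: {clean.n_individuals} individuals x "
      f"{clean.n_metabolites} metabolites")
print(f"planted outlier individual removed: "
      f"{truth.outlier_individual_id in report.individuals_removed}")
# the 3 metabolites above 50% missingness and the planted outlier individual
# are removed; every retained column has median 1 before capping.
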