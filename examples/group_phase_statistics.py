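"""Mixed-model comparison of heart-rate responses between groups.

Simulates an analysis cohort (17 venous / 24 control), pushes every
recording through the full HR pipeline (beat detection, 0.4 s tachogram,
artifact repair, rest-median normalization, per-phase medians), fits the
group x phase linear mixed model and prints the Holm-adjusted EMM
contrast table.
"""

from venoppg import CohortConfig, analyze_cohort, generate_cohort
from venoppg.pipeline import results_to_phase_summaries
from venoppg.stats import (build_long_table, emm_contrasts,
                           fit_group_phase_model)
from venoppg.synth import ANALYSIS_COHORT_COUNTS

config = CohortConfig(counts=ANALYSIS_COHORT_COUNTS, seed=3)
cohort = generate_cohort(config)
results = analyze_cohort([recording for recording, _ in cohort])
summaries, labels = results_to_phase_summaries(results)
table = build_long_table(summaries, labels)
fit = fit_group_phase_model(table)
contrasts = emm_contrasts(fit)

print("Estimated marginal means (bpm, median normalized HR):")
print(fit.emm.round(2).to_string())
print()
print(contrasts.round(3).to_string(index=False))
print()
print("The 'Su - Rest / V_group' row estimates the venous group's HR rise")
print("in the surrender position; 'V_group - C_group / Su' is the")
print("between-group difference there. p_holm controls the family-wise")
print("error rate within each contrast family.")
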