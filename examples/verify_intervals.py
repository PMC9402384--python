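"""Verify established intervals on an independent cohort.

Transference check: per analyte and age group, count how many of ~40 fresh
subjects fall outside the candidate interval; the interval passes when at
most 5% do. Note that even a perfectly calibrated interval fails a
40-subject check about a third of the time by sampling alone
(P[Binom(40, 0.05) > 2] ~ 0.32), so single red cells are expected.
"""

import lymphoref as lr

spec = lr.default_spec()
cohort, _ = lr.generate_cohort(spec, seed=1)
result = lr.establish(cohort)

# an independent verification cohort from the same population, scaled to
# roughly 40 children per age group
from dataclasses import replace

verif_spec = replace(spec, group_sizes={b: 40 for b in spec.scheme.labels})
verif, _ = lr.generate_cohort(verif_spec, seed=2)

report, all_pass = lr.verify(result.ri_table, verif)
print(report.round(1).to_string())
print(f"\nall cells >= 95% within: {all_pass}")
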