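"""Descriptive statistics of the evaluation cohort.

Loads the packaged 13-polyp / 9-patient cohort table and prints the
count-and-percentage / median-and-range summary such feasibility cohorts
are reported with.
"""

import coloct
from coloct.io import packaged_cohort

summary = coloct.summarize_cohort(packaged_cohort())
print(summary.to_markdown())
# Percentages use the variable's own denominator (patients for age/sex,
# polyps for technique/diagnosis/location; diameter was not reported for
# two polyps, so its n is 11), rounded half-up to one decimal.
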