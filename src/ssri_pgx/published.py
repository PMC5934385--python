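"""Published two-site summary values used as reference inputs.

The original two-cohort (NHRI / TVGH) SSRI-response study released only
summary tables, not raw data. Two of those tables serve as fixed inputs
here:

* the site-level single-marker p-values for the headline variants, used to
  validate the Fisher/inverse-Gamma combiner against the printed
  meta-analysis p-values, and
* the longitudinal missing-data pattern counts (N = 428), which both drive
  the synthetic missingness generator and anchor the bookkeeping checks.

Printed p-values carry two significant figures, so combined values can be
expected to agree only to that precision.
"""

from __future__ import annotations

import pandas as pd

#: Site-level p-values and the printed combined p for variants whose
#: meta-analysis row is arithmetically reproducible from the printed inputs.
TWO_SITE_META_RECORDS = pd.DataFrame(
    [
        # variant, outcome, p (site 1 = NHRI), p (site 2 = TVGH), printed meta p
        ("rs2564", "response_binary", 2.7e-2, 1.9e-2, 4.4e-3),
        ("rs7044702", "response_binary", 4.5e-2, 8.2e-3, 3.3e-3),
        ("rs2148252", "response_pct", 9.1e-2, 3.8e-3, 3.1e-3),
        ("chr11:27682769:D", "remitted", 4.9e-3, 8.5e-3, 4.7e-4),
    ],
    columns=["variant_id", "outcome", "p_site1", "p_site2", "printed_meta_p"],
)

#: Missing-data patterns over (baseline, week 2, week 4, week 8):
#: observed flags and the published subject count for each pattern.
#: Baseline is observed in every pattern; N sums to 428.
MISSINGNESS_PATTERN_COUNTS = [
    ((True, True, True, True), 394),
    ((True, False, True, True), 10),
    ((True, True, False, True), 10),
    ((True, True, True, False), 10),
    ((True, False, False, True), 1),
    ((True, False, True, False), 2),
    ((True, True, False, False), 0),
    ((True, False, False, False), 1),
]

#: Total subjects underlying the pattern table.
MISSINGNESS_N = sum(n for _, n in MISSINGNESS_PATTERN_COUNTS)

#: Cohort demographics used as simulator defaults: the retained sample had
#: mean age 43.7 y and 71.3% women; 268 subjects came from NHRI and 187
#: from TVGH.
SITE_SIZES = {"NHRI": 268, "TVGH": 187}
MEAN_AGE = 43.7
FEMALE_FRACTION = 0.713
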