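"""Birth-weight and covariate harmonization rules.

Multi-source birth weights arrive in pounds/ounces or repeated self-reports;
these deterministic rules convert, reconcile (10% discrepancy exclusion),
recode education, and standardize covariates within cohort, keeping the
grams-per-SD scaling for later effect-size translation.
"""

import vertexspan as vs
from vertexspan.phenotype import BWReport

print("7 lbs 8 oz ->", round(vs.lbs_oz_to_grams(7, 8), 2), "g")
print("6 lbs, ounces missing ->", round(vs.lbs_oz_to_grams(6, None), 2),
      "g (missing ounces count as zero)")

print("reports (3000, 3100) g ->", vs.reconcile_repeated_bw(BWReport((3000, 3100))),
      "g (3.3% discrepancy: averaged)")
print("reports (3000, 3500) g ->", vs.reconcile_repeated_bw(BWReport((3000, 3500))),
      "(15.4% discrepancy: participant excluded)")

print("education codes {3, 1} ->", vs.ukb_education_to_years([3, 1]),
      "years (highest qualification wins)")

table = vs.sample_design(vs.lcbc_like(500), seed=4)
kept = vs.apply_sensitivity_filters(table, "bw_range")
print(f"2.5-5.0 kg birth-weight window keeps {kept['subject_id'].nunique()} of "
      f"{table['subject_id'].nunique()} subjects")

std, scaling = vs.standardize_covariates(table, ["bw"])
print(f"1 SD of birth weight in this cohort = {scaling.bw_sd_grams('LCBC'):.0f} g")
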