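"""Methylation-stratified survival with a best-cutoff scan.

Simulates a 500-patient cohort whose death hazard triples once the
promoter methylation beta value exceeds 0.30, then recovers that
threshold with the best-cutoff scan and compares the five-year survival
of the two groups.
"""

from epimark.simulate import gen_cohort
from epimark.survival import (
    best_cutoff_scan,
    km_estimate,
    records_from_frame,
    survival_at,
)

cohort, truth = gen_cohort(seed=17, n=500, cutoff=0.30, hazard_ratio=3.0)
records = records_from_frame(cohort, covariate_col="beta", id_col="subject_id")

result = best_cutoff_scan(records)
print(f"planted cutoff {truth.truth['cutoff']:.2f} "
      f"(hazard ratio {truth.truth['hazard_ratio']:.1f})")
print(f"recovered threshold {result.threshold:.3f} "
      f"({result.threshold_percent:.1f}% methylation), "
      f"log-rank chi2 {result.statistic:.1f}, p {result.p_value:.2e} "
      f"(unadjusted over {result.n_thresholds_tested} thresholds)")

low = [r for r in records if r.covariate < result.threshold]
high = [r for r in records if r.covariate >= result.threshold]
for name, group in (("low methylation", low), ("high methylation", high)):
    s60 = survival_at(km_estimate(group), 60.0)
    print(f"  {name:<16} n={len(group):>3}  five-year survival "
          f"{100 * s60.probability:.0f}%")

# Hypermethylated patients die faster: their five-year survival is far
# below the unmethylated group's, and the scan pinpoints the planted
# 30% methylation cutoff.  The minimum p over many thresholds is
# reported unadjusted — treat it as descriptive, not confirmatory.
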