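"""In-silico CoBRA: methylation-dependent restriction fragments.

Builds the synthetic promoter assay locus (published bisulfite primer
pair, 186-bp product, TaqI cut after base 89), converts it under a fully
methylated and a fully unmethylated profile, amplifies, digests and
prints the fragment pattern a gel would show.
"""

from epimark.bisulfite import (
    TAQI,
    MethylationProfile,
    bisulfite_convert,
    cobra_digest,
    in_silico_pcr,
    validate_bisulfite_primer,
)
from epimark.synthetic_loci import COBRA_FWD, COBRA_REV, cobra_template

template = cobra_template()
for direction, primer in (("forward", COBRA_FWD), ("reverse", COBRA_REV)):
    report = validate_bisulfite_primer(primer, template, direction)
    print(f"{direction} primer {primer}: "
          f"{'binds both methylation states' if report.passed else report.failures}")

for name, methylated in (("methylated", True), ("unmethylated", False)):
    profile = MethylationProfile.uniform(template, methylated)
    converted = bisulfite_convert(template, profile)
    _, amplicon = in_silico_pcr(converted, COBRA_FWD, COBRA_REV)
    fragments = cobra_digest(amplicon, TAQI)
    print(f"{name:>12}: amplicon {len(amplicon)} bp -> TaqI fragments {fragments}")

# Methylation retains the CpG inside the TaqI site (TCGA), so the
# methylated amplicon cuts into 89 + 97 bp while the unmethylated one
# stays uncut at 186 bp — the readout principle of CoBRA.
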