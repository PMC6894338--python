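# epimark

A toolkit for promoter-methylation biomarker studies in cancer
epigenomics. It covers the desk-side computations such a study runs
around a candidate tumour-suppressor gene: locating the promoter CpG
island, designing and simulating the bisulfite/CoBRA methylation assay,
scanning mRNA 3'UTRs for the translation control sequence the gene
product binds, stratifying patient survival on methylation or expression,
and placing CRISPR guides for dCas9 epigenetic editing. Every analysis
can be exercised end-to-end on seeded synthetic data with machine-readable
planted truth.

## What it computes

**CpG islands.** An island is an interval with length > 200 bp, average
G+C > 50 % and observed/expected CpG ratio

&nbsp;&nbsp;&nbsp;&nbsp;O/E = (N<sub>CpG</sub> · L) / (N<sub>C</sub> · N<sub>G</sub>) > 0.6,

detected by 200-bp sliding windows with majority-coverage boundary
refinement (`epimark.cgi`).

**Bisulfite / CoBRA.** Bisulfite treatment converts unmethylated C → T
while 5-methylcytosine is retained, so a converted amplicon contains the
TaqI site TCGA at a locus iff the original reads [C|T]CGA with that CpG
methylated. `epimark.bisulfite` converts templates deterministically,
validates Y/R-degenerate bisulfite primers, predicts amplicons and
fragment patterns, and estimates per-CpG beta values
β = N<sub>C</sub>/(N<sub>C</sub>+N<sub>T</sub>) from simulated reads
(classification: β ≥ 0.20 → methylated).

**TCS motifs.** The translation control sequence consensus
(A/U)UU(A/G)UCU expands to four 7-mers; `epimark.motifs` scans 3'UTR sets
overlap-tolerantly, tabulates per-UTR counts and finds same-motif
duplicates inside a 200-nt window.

**Survival.** `epimark.survival` implements the Kaplan–Meier
product-limit estimator S(t) = Π<sub>t<sub>i</sub>≤t</sub>(1 −
d<sub>i</sub>/n<sub>i</sub>), the two-group log-rank test (χ² with 1 df,
optional seeded permutation p), and the two dichotomisation conventions
used by survival web tools: mean split and best-cutoff scan (minimum
unadjusted log-rank p over observed covariate values).

**Guides.** `epimark.guides` places 20-nt SpCas9 protospacers on both
strands, checks NGG PAMs and reports each guide's 5' offset relative to
the TSS (+1 convention, no zero).

**Synthetic data.** `epimark.simulate` provides seeded, bit-reproducible
generators for all input classes (planted CpG islands, UTR sets with
exact motif counts, bisulfite reads with a conversion-efficiency
parameter, right-censored cohorts whose hazard steps at a methylation
cutoff), each returning a planted-truth manifest.

## Worked example

```bash
python examples/04_survival_stratification.py
```

```
planted cutoff 0.30 (hazard ratio 3.0)
recovered threshold 0.301 (30.1% methylation), log-rank chi2 131.1, p 2.34e-30 (unadjusted over 400 thresholds)
  low methylation  n=198  five-year survival 56%
  high methylation n=302  five-year survival 12%
```

A 500-patient cohort is simulated with a bimodal methylation beta
distribution and a hazard that triples once beta exceeds 0.30. The
best-cutoff scan recovers the planted threshold to three decimals; the
five-year survival gap between the groups is what a Kaplan–Meier plot of
a methylation-stratified cohort shows. The p-value is the minimum over
400 candidate thresholds and is deliberately flagged unadjusted.

The other examples (`examples/01`–`06`) demonstrate island detection,
the CoBRA fragment readout (186 bp amplicon → 89 + 97 bp fragments when
methylated, uncut when not), TCS scanning of the WEE-family UTR maps,
guide placement at the published TSS offsets, and beta quantification
from reads. The same stages are reachable from a thin CLI:

```bash
epimark demo --seed 1 --outdir out/      # generator -> analysis -> report
epimark cgi --fasta genome.fa --out islands.bed
epimark survival --table cohort.tsv --mode best-cutoff --out km.tsv
```

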