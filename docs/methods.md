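# Methods

This note records the models, conventions and numerical choices behind
each analysis stage, what the synthetic-data generators do and do not
emulate, and the known limitations.

## Sequence model and coordinates

All sequences are normalised to the {A,C,G,T,N} alphabet (RNA U → T,
case raised, whitespace stripped) and tagged with their source alphabet,
so RNA motifs match DNA 3'UTRs directly and results can be rendered back
in the caller's letters. Degenerate IUPAC codes other than N are
rejected in sequence bodies; primers and motifs go through a separate
degenerate matcher in which pattern N matches any base but an N *in the
subject* matches nothing concrete. All user-facing coordinates are
1-based inclusive; the BED writer converts to 0-based half-open at the
boundary.

## CpG-island detection

Criteria: length > 200 bp, G+C > 50 %, observed/expected CpG
(N_CpG · L)/(N_C · N_G) > 0.6, all strict inequalities, evaluated with N
bases excluded from every count (an N also breaks a CpG dinucleotide).

The criteria define islands but not an algorithm. We slide a 200-bp
window at 1-bp steps and test each window. A plain union of qualifying
windows systematically over-extends: a window overlapping only ~46 % of
a 68 %-GC island already exceeds 50 % GC against a 35 %-GC background,
so union boundaries smear ~100 bp into flanking sequence per side.
Boundaries are therefore refined by **majority coverage**: a position is
in a candidate island iff at least half of the windows covering it
qualify. At a sharp composition change the qualifying fraction of
covering windows crosses 1/2 within a few bp of the true edge, giving
~±20-bp boundary accuracy (mean reciprocal overlap 0.955 against planted
600-bp islands over 100 generator seeds). Each candidate run is then
re-evaluated as a whole against all three criteria; a failing candidate
has up to one window trimmed per flank and is re-tested, otherwise it is
dropped. Every reported island therefore satisfies the criteria over
its exact reported interval. Raising a threshold never increases total
island length.

No attempt is made to match annotation-browser island boundaries
bp-for-bp; those annotations use related but distinct algorithms.

## Bisulfite conversion and CoBRA

The deterministic converter implements the chemistry's logical rule:
every cytosine outside a methylated CpG becomes T; the C of a methylated
CpG is retained. Only the top strand is modelled explicitly; the bottom
strand is obtained by reverse-complementing first and remapping CpG
positions (the bottom-strand C of a CpG pairs with the top-strand G).
The converter requires binary methylation states; fractional beta values
live in the read simulator only.

Bisulfite primers may carry Y (top strand) or R (bottom-strand product)
where a CpG falls under the primer; validation requires exactly one
perfect degenerate match on both the fully methylated and fully
unmethylated converted template, at the same locus. In-silico PCR
demands a unique product (forward match … reverse-complement of the
reverse primer) and reports distinct no-product/multi-product errors,
because CoBRA interpretation assumes a single amplicon.

TaqI is modelled as recognition TCGA with cut offset 1 (T^CGA). The
published assay geometry — a 186-bp product with the site "at 89" — is
realised as the cut falling after base 89, i.e. recognition starting at
position 89, yielding fragments 89 + 97 bp. This makes the printed 89
directly observable as a gel fragment length, which is how CoBRA results
are read; the alternative reading (cut position 89 with recognition at
88) would shift the fragments by 1 bp and cannot be distinguished from
the printed description alone.

Beta values are β = m/(m+u); classification uses β ≥ threshold (default
0.20) — the boundary is deliberately inclusive since the assay
literature quotes the threshold without boundary semantics. Per-CpG
quantification counts C (retained = methylated) versus T among covering
reads and flags zero-coverage CpGs instead of emitting a value.

## TCS motif scanning

The consensus grammar is concrete bases plus parenthesised alternative
sets; (A/U)UU(A/G)UCU expands to AUUAUCU, AUUGUCU, UUUAUCU, UUUGUCU.
Scanning is overlap-tolerant (no greedy consumption) and alphabet-
invariant. "Duplicate" means the *identical* 7-mer twice in one UTR
with both occurrences inside one 200-nt window — containment semantics,
i.e. start difference ≤ window − motif length (193 nt for 7-mers). The
looser reading (start difference ≤ window) is available via
`semantics="starts"`; both agree on the worked WEE-family examples.
Per-UTR totals sum hits over all four expansions; occurrence histograms
are reported both as exactly-k and at-least-k because published
genome-scale tallies rarely state which convention they use.

## Survival analysis

Kaplan–Meier, the log-rank test and the dichotomisation conventions are
implemented from first principles (this is the analytical core of the
biomarker claim); an established survival library is used in the test
suite only, as an independent oracle.

* Ties: events precede censorings at equal times (standard
  product-limit convention).
* Greenwood variance and 95 % bands are computed and reported but
  nothing downstream depends on them; the variance is undefined (NaN)
  once S reaches 0.
* Log-rank: observed minus hypergeometric-expected events accumulated
  over shared event times; χ² with 1 df. A seeded label-permutation p
  (with the +1 correction) is available for small samples. **Small-n
  caveat:** at n ≤ 10 the exact permutation distribution has at most a
  few hundred atoms, and the χ² tail can differ from the exact p by
  0.02–0.08; the permutation option exists precisely for that regime.
* Mean split: threshold = arithmetic mean, groups {< mean, ≥ mean}.
* Best-cutoff scan: every observed covariate value inside the
  [0.1, 0.9] quantile band is tried; the threshold minimising the
  log-rank p wins (ties toward the smaller threshold, deterministically).
  The returned p is the minimum over all thresholds and is reported
  unadjusted with an explicit flag; under a null cohort the scan rejects
  at 5 % far more often than 5 % — the suite demonstrates this selection
  bias rather than hiding it. Methylation thresholds are additionally
  rendered on the percent scale (0.175 → 17.5 %).

## Guide placement

Protospacers are located by exact 20-mer match on both strands; the PAM
is the 3 nt adjacent on the protospacer strand and must match NGG
(SpCas9; no NAG tolerance). Offsets use promoter-coordinate counting
(TSS = +1, first upstream base = −1, zero never occurs) and anchor the
guide's 5'-most base; `offset_anchor` can re-anchor to the 3' end or
PAM-proximal base for annotations that count differently. Unfound
guides are reported as unplaced, not raised.

## Synthetic-data generators

All generators are pure functions of (seed, parameters) using a single
PRNG stream; outputs are bit-reproducible. Truth manifests carry
everything recovery tests need, so no expected value is hard-coded
downstream.

* **Genomes** (`gen_cgi_genome`): iid AT-rich background (GC 35 %, at
  which a 200-bp window essentially never reaches 50 % GC by chance);
  islands drawn from a first-order Markov model whose P(G | previous C)
  is tilted by the O/E target (an iid draw has expected O/E ≈ 1), with
  rejection until realised composition is within ±2 GC points and ±0.1
  O/E. Default planted composition (68 % GC, O/E 0.98) mirrors a
  typical promoter island.
* **UTR sets** (`gen_utr_set`): uniform-random backgrounds, exact
  planted per-UTR totals (`{total: n_UTRs}`), a stated fraction of
  duplicate-positive UTRs (same motif twice within the window); every
  UTR is re-scanned after planting and redrawn on any unintended match,
  so planted truth is exact. Non-duplicate UTRs receive pairwise
  distinct motifs.
* **Bisulfite reads** (`gen_bisulfite_reads`): per-read CpG states ~
  Bernoulli(β); non-CpG and unmethylated-CpG cytosines independently
  fail conversion with probability 1 − efficiency (accepted range
  (0.8, 1.0]), inflating apparent β by (1 − β)(1 − efficiency). Reads
  carry true coordinates, so no aligner exists or is needed.
* **Cohorts** (`gen_cohort`): beta values from a two-component Beta
  mixture (defaults Beta(2,8)/Beta(8,2), π = 0.5 — the bimodal
  tumour/control pattern of methylation arrays); survival exponential
  with rate ln2/median (default median 60 months so the 5-year horizon
  sits at the distribution centre, maximising the sensitivity of S(60)
  checks) multiplied by the hazard ratio above the cutoff; exactly
  round(n · censor_fraction) randomly chosen subjects are censored at a
  uniform fraction of their event time, meeting the requested censoring
  fraction exactly.

What the generators do **not** emulate: 450k probe chemistry and batch
effects, annotation-version-specific UTR universes, non-exponential
baseline hazards, covariate-dependent censoring, sequencing error, or
real genomic repeat structure. Passing recovery tests therefore shows
the pipeline's logic is correct under its stated model, not that the
detectors are calibrated for real-genome compositional complexity.

## Synthetic assay loci

`epimark.synthetic_loci` builds deterministic stand-ins for the study's
assay loci from published coordinates: the CoBRA template (printed
primer pair, 186-bp product, CpG-dependent TaqI site cut after base 89,
C-free filler so conversion acts only on planted CpGs), WEE1/WEE2-like
UTRs carrying the published motif maps at the published positions, and
a promoter with the six published guides planted at their published TSS
offsets (plus strand, AGG PAMs). Backgrounds are generated; only the
planted features are real. Each constructor verifies its own plantings
and raises on accidental collisions. Analyses of these loci validate
the pipeline against the printed worked values; they do not reproduce
genomic context.

## Problem sizes

Default suite and reproduction sizes: 2-kb genomes with one 600-bp
island; 300–1000-UTR sets; 1000–10 000 reads per quantification;
cohorts of 100–500 with 200-replicate calibration runs; 50–100-replicate
power estimates. These sizes put Monte-Carlo noise well inside the
asserted tolerances (e.g. binomial SD at β = 0.7, n = 1000 is 0.014
against a ±0.05 check) while keeping a full run to seconds.

## Known limitations

* Island boundary accuracy is inherently limited by the 200-bp window;
  sub-window boundary features (shores, sharp partial islands) are not
  resolved.
* The log-rank χ² p is an asymptotic approximation; use the permutation
  option below ~20 events.
* Best-cutoff p-values are unadjusted by design (mirroring the web
  tools this convention comes from); no multiple-testing correction is
  offered.
* The in-silico PCR has no mismatch tolerance or melting-temperature
  model; primers either match degenerately or not at all.
* Published patient-level quantities (five-year survival percentages,
  cohort thresholds such as 17.5 %/15.4 %) depend on consortium patient
  data and are out of scope; the survival stage is validated by closed
  form and planted-truth recovery instead.
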