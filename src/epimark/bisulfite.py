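"""In-silico bisulfite conversion, bisulfite-primer validation, CoBRA
amplicon/fragment prediction and methylation quantification.

Bisulfite treatment converts every unmethylated cytosine to uracil (read
as T after PCR) while 5-methylcytosine is retained.  CoBRA (combined
bisulfite restriction analysis) exploits the methylation-dependent
retention or creation of restriction sites in the converted amplicon —
here TaqI (TCGA, cutting T^CGA): a converted amplicon carries TCGA at a
locus iff the original reads [C|T]CGA there with that CpG methylated, so
the fragment pattern on a gel reads out methylation state.

Only top-strand products are modelled explicitly; the bottom strand is
obtained by reverse-complementing before conversion.  Incomplete
conversion is a property of the stochastic read simulator
(:mod:`epimark.simulate`), never of the deterministic converter here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ContractError,
    MultipleProductError,
    NoProductError,
    UndefinedValueError,
)
from .seq import (
    GenomicInterval,
    NucleotideSequence,
    cpg_positions,
    find_iupac,
    reverse_complement,
)


@dataclass(frozen=True)
class MethylationProfile:
    """Per-CpG methylation states for one sequence.

    ``cpg_positions`` are 1-based positions of the C of each CpG, strictly
    increasing; ``states`` are parallel booleans (methylated flags) or beta
    values in [0,1].  The deterministic converter requires binary states.
    """

    seq_id: str
    cpg_positions: tuple[int, ...]
    states: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.cpg_positions) != len(self.states):
            raise ContractError("positions and states differ in length")
        if any(b <= a for a, b in zip(self.cpg_positions, self.cpg_positions[1:])):
            raise ContractError("cpg_positions must be strictly increasing")
        if any(not 0.0 <= float(s) <= 1.0 for s in self.states):
            raise ContractError("beta values must lie in [0,1]")

    def validate_against(self, seq: NucleotideSequence) -> None:
        if seq.id != self.seq_id:
            raise ContractError(
                f"profile for {self.seq_id!r} applied to sequence {seq.id!r}"
            )
        for p in self.cpg_positions:
            if not (1 <= p < len(seq)) or seq.residues[p - 1 : p + 1] != "CG":
                raise ContractError(f"position {p} is not the C of a CpG in {seq.id!r}")

    @property
    def methylated_set(self) -> frozenset[int]:
        for s in self.states:
            if float(s) not in (0.0, 1.0):
                raise ContractError(
                    "deterministic conversion needs binary methylation states"
                )
        return frozenset(p for p, s in zip(self.cpg_positions, self.states) if s)

    @classmethod
    def uniform(cls, seq: NucleotideSequence, methylated: bool) -> "MethylationProfile":
        pos = tuple(cpg_positions(seq))
        return cls(seq.id, pos, tuple(1.0 if methylated else 0.0 for _ in pos))

    @classmethod
    def fully_methylated(cls, seq: NucleotideSequence) -> "MethylationProfile":
        return cls.uniform(seq, True)

    @classmethod
    def fully_unmethylated(cls, seq: NucleotideSequence) -> "MethylationProfile":
        return cls.uniform(seq, False)


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme with a concrete recognition site.

    ``cut_offset`` is the number of recognition bases 5' of the top-strand
    cut: TaqI (T^CGA) has recognition TCGA and cut_offset 1.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ContractError("cut_offset outside recognition site")


TAQI = RestrictionEnzyme("TaqI", "TCGA", 1)


def bisulfite_convert(
    seq: NucleotideSequence,
    profile: MethylationProfile,
    strand: str = "top",
) -> NucleotideSequence:
    """Deterministic bisulfite conversion of one strand.

    Every C outside a methylated CpG becomes T; the C of each methylated
    CpG is retained.  ``strand='bottom'`` applies the same rule to the
    reverse complement (profile positions are remapped to the bottom-strand
    C of each CpG, which pairs with the top-strand G).
    """
    profile.validate_against(seq)
    if strand not in ("top", "bottom"):
        raise ContractError(f"strand must be top or bottom, got {strand!r}")
    methylated = profile.methylated_set
    if strand == "bottom":
        L = len(seq)
        seq = reverse_complement(seq)
        methylated = frozenset(L - p for p in methylated)
    out = [
        "C" if (c == "C" and i in methylated) else ("T" if c == "C" else c)
        for i, c in enumerate(seq.residues, start=1)
    ]
    return NucleotideSequence(seq.id, "".join(out), seq.source_alphabet)


@dataclass(frozen=True)
class PrimerValidation:
    """Outcome of checking one bisulfite primer against both extreme
    methylation profiles of a template."""

    primer: str
    direction: str
    match_loci: Mapping[str, tuple[int, ...]]  # profile name -> 1-based starts
    passed: bool
    failures: tuple[str, ...]


def validate_bisulfite_primer(
    primer: str,
    template: NucleotideSequence,
    direction: str = "forward",
) -> PrimerValidation:
    """Check that a (possibly Y/R-degenerate) primer binds the converted
    template uniquely, regardless of methylation state.

    Bisulfite primers are designed against fully converted DNA: Y positions
    absorb CpG cytosines on the top strand (C if methylated, T if not) and
    R positions do the same on the bottom-strand product.  The primer
    passes iff it has exactly one perfect degenerate match on both the
    fully methylated and the fully unmethylated converted template, at the
    same locus.  Zero or multiple loci are failure modes, not exceptions.
    """
    primer = primer.upper().replace("U", "T")
    if len(primer) < 15:
        raise ContractError("primer shorter than 15 nt")
    if direction not in ("forward", "reverse"):
        raise ContractError(f"direction must be forward or reverse, got {direction!r}")

    needle = primer if direction == "forward" else reverse_complement(primer)
    loci: dict[str, tuple[int, ...]] = {}
    for name, meth in (("methylated", True), ("unmethylated", False)):
        converted = bisulfite_convert(template, MethylationProfile.uniform(template, meth))
        loci[name] = tuple(find_iupac(needle, converted.residues))

    failures = []
    for name, hits in loci.items():
        if len(hits) == 0:
            failures.append(f"no match on the {name} converted template")
        elif len(hits) > 1:
            failures.append(f"{len(hits)} matches on the {name} converted template")
    if not failures and loci["methylated"] != loci["unmethylated"]:
        failures.append("match loci differ between methylation states")
    return PrimerValidation(primer, direction, loci, not failures, tuple(failures))


def in_silico_pcr(
    template: NucleotideSequence,
    fwd: str,
    rev: str,
) -> tuple[GenomicInterval, NucleotideSequence]:
    """Predict the unique PCR product of a degenerate primer pair.

    The product's top strand begins with the forward-primer match and ends
    with the reverse complement of the reverse primer; its length is the
    inclusive span.  Zero candidate products raise
    :class:`NoProductError`; more than one raise
    :class:`MultipleProductError` (CoBRA interpretation assumes a single
    amplicon, so multi-mapping is an error, not a warning).
    """
    fwd = fwd.upper().replace("U", "T")
    rev = rev.upper().replace("U", "T")
    f_starts = find_iupac(fwd, template.residues)
    r_starts = find_iupac(reverse_complement(rev), template.residues)
    if not f_starts:
        raise NoProductError("forward primer has no match on the template")
    if not r_starts:
        raise NoProductError("reverse primer has no match on the template")
    pairs = [
        (f, r + len(rev) - 1)
        for f in f_starts
        for r in r_starts
        if r >= f + len(fwd)
    ]
    if not pairs:
        raise NoProductError("primer matches do not face each other")
    if len(pairs) > 1:
        raise MultipleProductError(f"{len(pairs)} candidate products")
    start, end = pairs[0]
    interval = GenomicInterval(template.id, start, end)
    amplicon = NucleotideSequence(
        f"{template.id}|amplicon_{start}_{end}", template.slice(start, end)
    )
    return interval, amplicon


def cobra_digest(
    amplicon: NucleotideSequence, enzyme: RestrictionEnzyme = TAQI
) -> list[int]:
    """Ordered fragment lengths after digesting the amplicon.

    The top strand is cut after base (site_start + cut_offset - 1) at every
    occurrence of the recognition sequence; fragment lengths always sum to
    the amplicon length, and an uncut amplicon yields a single fragment.
    """
    if len(amplicon) == 0:
        raise ContractError("empty amplicon")
    sites = find_iupac(enzyme.recognition, amplicon.residues)
    cuts = sorted(
        s + enzyme.cut_offset - 1
        for s in sites
        if 0 < s + enzyme.cut_offset - 1 < len(amplicon)
    )
    bounds = [0, *cuts, len(amplicon)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def methylation_beta(methylated_read_count: int, unmethylated_read_count: int) -> float:
    """Beta value m/(m+u) from read counts."""
    m, u = methylated_read_count, unmethylated_read_count
    if m < 0 or u < 0:
        raise ContractError("read counts must be non-negative")
    if m + u == 0:
        raise UndefinedValueError("zero coverage: beta undefined")
    return m / (m + u)


def classify(beta: float, threshold: float = 0.20) -> str:
    """Dichotomise a beta value; beta >= threshold counts as methylated."""
    if not 0.0 <= beta <= 1.0:
        raise ContractError("beta outside [0,1]")
    return "methylated" if beta >= threshold else "unmethylated"


def quantify_from_reads(
    reads: pd.DataFrame, cpg_positions: Sequence[int]
) -> pd.DataFrame:
    """Per-CpG beta estimates from simulated bisulfite reads.

    ``reads`` needs columns ``start`` (1-based template position of the
    read's first base) and ``sequence``.  At each CpG, beta is the fraction
    of covering reads showing C (retained = methylated) among C+T calls.
    Zero-coverage CpGs are flagged and get no beta.
    """
    if not {"start", "sequence"} <= set(reads.columns):
        raise ContractError("reads table needs 'start' and 'sequence' columns")
    rows = []
    starts = reads["start"].to_numpy()
    seqs = reads["sequence"].to_numpy()
    for p in cpg_positions:
        n_c = n_t = 0
        for s, rseq in zip(starts, seqs):
            off = p - s
            if 0 <= off < len(rseq):
                base = rseq[off]
                if base == "C":
                    n_c += 1
                elif base == "T":
                    n_t += 1
        cov = n_c + n_t
        rows.append(
            {
                "position": p,
                "coverage": cov,
                "n_methylated": n_c,
                "n_unmethylated": n_t,
                "beta": (n_c / cov) if cov else np.nan,
                "flagged_no_coverage": cov == 0,
            }
        )
    return pd.DataFrame(rows)
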