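"""Synthetic stand-in loci built from the printed assay coordinates.

These constructors embed published assay facts — bisulfite primer
sequences, the CoBRA amplicon geometry (186 bp, TaqI cut after base 89),
the WEE1/WEE2 3'UTR motif positions and the six promoter guide 20-mers
with their TSS offsets — into deterministic synthetic sequences, so the
pipeline can be exercised end-to-end without fetching genomic sequence.
Every sequence produced here is synthetic: backgrounds are generated, and
only the planted features are real.  Each constructor verifies its own
plantings (unique primer loci, exact motif recovery, unique guide
placements) and raises on any accidental collision.
"""

from __future__ import annotations

import numpy as np

from .errors import GeneratorError
from .motifs import expand_consensus, scan_sequence, TCS_CONSENSUS
from .seq import NucleotideSequence, find_iupac, reverse_complement

#: Bisulfite CoBRA primer pair for the promoter assay (Y/R absorb the CpG
#: cytosines so the primers bind both methylation states of converted DNA).
COBRA_FWD = "GGAGAAGGAYGAAGAGGGGTTTTT"
COBRA_REV = "TCCCCCAAAACCRCCATAAAC"

#: Published amplicon geometry: product size and top-strand cut position.
COBRA_PRODUCT_BP = 186
COBRA_TAQI_CUT_AT = 89

#: The six SpCas9 guides tiling the promoter CpG island, with the
#: published offsets of each guide's 5'-most base relative to the TSS.
GUIDES = {
    "guide_1": "ACTTTCGCTCACTTAGCCAG",
    "guide_2": "TGGTTCCCTTACGGATCAGC",
    "guide_3": "GTAGGGAGAAGGACGAAGAG",
    "guide_4": "GTCGCCTATTTAGGGTGCGG",
    "guide_5": "CGCGGCCACCAAGGGCAAGG",
    "guide_6": "CCGCGGTACAGTGCTCGCTG",
}
GUIDE_OFFSETS = {
    "guide_1": -402,
    "guide_2": -230,
    "guide_3": -133,
    "guide_4": -3,
    "guide_5": +120,
    "guide_6": +386,
}

#: Published WEE-family 3'UTR motif maps: (UTR length, [(motif, start)]).
WEE1_UTR_LENGTH = 1164
WEE1_MOTIF_MAP = [("UUUGUCU", 559), ("UUUAUCU", 988),
                  ("AUUGUCU", 1043), ("AUUGUCU", 1156)]
WEE2_UTR_LENGTH = 951
WEE2_MOTIF_MAP = [("UUUAUCU", 525), ("UUUAUCU", 592)]


def cobra_template(flank: int = 40, seq_id: str = "synthetic_cobra_locus") -> NucleotideSequence:
    """Unconverted top-strand template for the CoBRA assay.

    The amplicon body is laid out so that the printed primers bind its
    converted ends (primer CpGs under the Y/R positions), with a single
    CpG-dependent TaqI site whose top-strand cut falls after base
    ``COBRA_TAQI_CUT_AT`` of the ``COBRA_PRODUCT_BP``-bp product when the
    template is methylated.  The interior and flanks are C-free (A/T/G),
    so bisulfite conversion only acts on the planted CpGs.
    """
    fwd_site = COBRA_FWD.replace("Y", "C")  # CpG under the Y
    rev_site = str(reverse_complement(COBRA_REV)).replace("Y", "C")
    for site, y_at in ((fwd_site, COBRA_FWD.index("Y")),
                       (rev_site, str(reverse_complement(COBRA_REV)).index("Y"))):
        assert site[y_at : y_at + 2] == "CG", "primer CpG not under the Y"

    rng = np.random.default_rng(20190414)
    atg = np.array(list("ATG"))

    def filler(n: int) -> str:
        return "".join(atg[rng.integers(0, 3, size=n)])

    # amplicon coordinates (1-based): fwd 1..len(fwd); TaqI TCGA at cut..cut+3
    # so the top-strand cut (T^CGA) falls after base `cut`; rev-site tail.
    cut = COBRA_TAQI_CUT_AT
    core = (
        fwd_site
        + filler(cut - 1 - len(fwd_site))
        + "TCGA"
        + filler(COBRA_PRODUCT_BP - len(rev_site) - (cut + 3))
        + rev_site
    )
    assert len(core) == COBRA_PRODUCT_BP
    assert core[cut - 1 : cut + 3] == "TCGA"
    template = NucleotideSequence(seq_id, filler(flank) + core + filler(flank))

    # self-check: the primers must be unique on both converted templates
    from .bisulfite import MethylationProfile, bisulfite_convert

    for meth in (True, False):
        conv = bisulfite_convert(template, MethylationProfile.uniform(template, meth))
        if len(find_iupac(COBRA_FWD, conv.residues)) != 1:
            raise GeneratorError("forward primer not unique on converted template")
        if len(find_iupac(str(reverse_complement(COBRA_REV)), conv.residues)) != 1:
            raise GeneratorError("reverse primer not unique on converted template")
    return template


def _planted_utr(seq_id: str, length: int, motif_map, rng_seed: int,
                 max_tries: int = 500) -> NucleotideSequence:
    """Random-background UTR carrying exactly the given motif placements."""
    motif = expand_consensus(TCS_CONSENSUS)
    bases = np.array(list("ACGT"))
    rng = np.random.default_rng(rng_seed)
    wanted = {(m, s) for m, s in motif_map}
    for _ in range(max_tries):
        residues = list("".join(bases[rng.integers(0, 4, size=length)]))
        for m, start in motif_map:
            residues[start - 1 : start - 1 + len(m)] = m.replace("U", "T")
        seq = NucleotideSequence(seq_id, "".join(residues))
        got = {(h.motif, h.start) for h in scan_sequence(seq, motif)}
        if got == wanted:
            return seq
    raise GeneratorError(f"could not build {seq_id} without collisions")


def wee1_like_utr() -> NucleotideSequence:
    """A 1164-nt synthetic 3'UTR with the published WEE1 motif map."""
    return _planted_utr("synthetic_wee1_3utr", WEE1_UTR_LENGTH, WEE1_MOTIF_MAP, 1164)


def wee2_like_utr() -> NucleotideSequence:
    """A 951-nt synthetic 3'UTR with the published WEE2 motif map."""
    return _planted_utr("synthetic_wee2_3utr", WEE2_UTR_LENGTH, WEE2_MOTIF_MAP, 951)


def guide_promoter(
    length: int = 1000, tss: int = 501, seq_id: str = "synthetic_promoter"
) -> tuple[NucleotideSequence, int]:
    """Synthetic promoter with the six guides planted at their published
    TSS offsets, each on the plus strand followed by an AGG PAM.

    Returns (region, tss_position).  The AT-only background cannot host a
    G/C-containing 20-mer, so each guide is verifiably unique.
    """
    rng = np.random.default_rng(1405)
    at = np.array(list("AT"))
    residues = list("".join(at[rng.integers(0, 2, size=length)]))
    for gid, guide in GUIDES.items():
        offset = GUIDE_OFFSETS[gid]
        p = tss + offset - 1 if offset > 0 else tss + offset  # no offset 0
        residues[p - 1 : p - 1 + 20] = guide
        residues[p + 19 : p + 22] = "AGG"
    region = NucleotideSequence(seq_id, "".join(residues))
    top = region.residues
    for gid, guide in GUIDES.items():
        if top.count(guide) != 1 or top.count(str(reverse_complement(guide))) != 0:
            raise GeneratorError(f"{gid} is not uniquely placed")
    return region, tss
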