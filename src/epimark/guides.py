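"""SpCas9 guide placement in a promoter region.

Locates 20-nt protospacers by exact match on both strands, checks the
adjacent 3-nt PAM against NGG (SpCas9; no NAG tolerance), and reports each
guide's offset relative to an annotated transcription start site.  Offsets
follow promoter-coordinate counting: the TSS base is +1, the base
immediately upstream is -1, and 0 never occurs.  The anchored base is the
guide's 5'-most base; alternative anchors (3' end, PAM-proximal base) are
available for re-anchoring against annotations that count differently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import AlphabetError, ContractError
from .seq import NucleotideSequence, reverse_complement


@dataclass(frozen=True)
class GuidePlacement:
    guide_id: str
    protospacer: str  # as supplied, 20 nt
    strand: str  # + | -
    start: int  # 1-based leftmost position of the match on the top strand
    offset: int  # signed TSS-relative position of the anchored base (no 0)
    pam: str  # 3-mer on the protospacer strand ('' if off the region edge)
    pam_valid: bool


def _tss_offset(position: int, tss: int) -> int:
    """Promoter coordinate of a 1-based region position: TSS = +1, no 0."""
    return position - tss + 1 if position >= tss else position - tss


def locate_guides(
    region: NucleotideSequence,
    tss_position: int,
    guides: Mapping[str, str] | Sequence[str],
    offset_anchor: str = "5prime",
) -> tuple[list[GuidePlacement], list[str]]:
    """Place guides in a promoter region and compute TSS offsets.

    Returns (placements, unplaced guide ids); a guide absent from the
    region is reported as unplaced, not an error, and a guide matching at
    several loci yields one placement per locus.  ``offset_anchor``
    selects which protospacer base the offset refers to: ``5prime``
    (default), ``3prime`` or ``pam`` (the base adjacent to the PAM, which
    equals the 3' end for SpCas9).
    """
    if len(region) < 23:
        raise ContractError("region shorter than a protospacer plus PAM")
    if not 1 <= tss_position <= len(region):
        raise ContractError("TSS outside the region")
    if offset_anchor not in ("5prime", "3prime", "pam"):
        raise ContractError(f"unknown offset anchor {offset_anchor!r}")
    if not isinstance(guides, Mapping):
        guides = {f"guide_{i + 1}": g for i, g in enumerate(guides)}

    top = region.residues
    placements: list[GuidePlacement] = []
    unplaced: list[str] = []
    for gid, raw in guides.items():
        guide = raw.upper().replace("U", "T")
        if len(guide) != 20:
            raise ContractError(f"guide {gid!r} is not 20 nt")
        if set(guide) - set("ACGT"):
            raise AlphabetError(f"guide {gid!r} contains non-ACGT characters")
        found = False
        # plus strand: protospacer read left->right, PAM 3' of it
        i = top.find(guide)
        while i != -1:
            start = i + 1
            five, three = start, start + 19
            pam = top[i + 20 : i + 23]
            placements.append(_placement(gid, raw, "+", start, five, three,
                                         pam, tss_position, offset_anchor))
            found = True
            i = top.find(guide, i + 1)
        # minus strand: the reverse complement appears on the top strand;
        # the guide's 5' base sits at the rightmost top-strand position
        rc = reverse_complement(guide)
        i = top.find(rc)
        while i != -1:
            start = i + 1
            five, three = start + 19, start
            pam = reverse_complement(top[max(i - 3, 0) : i]) if i >= 3 else ""
            placements.append(_placement(gid, raw, "-", start, five, three,
                                         pam, tss_position, offset_anchor))
            found = True
            i = top.find(rc, i + 1)
        if not found:
            unplaced.append(gid)
    placements.sort(key=lambda p: (p.start, p.guide_id))
    return placements, unplaced


def _placement(gid, raw, strand, start, five, three, pam, tss, anchor) -> GuidePlacement:
    anchored = {"5prime": five, "3prime": three, "pam": three}[anchor]
    return GuidePlacement(
        gid, raw, strand, start, _tss_offset(anchored, tss),
        pam, len(pam) == 3 and pam[1:] == "GG",
    )
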