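"""Place CRISPR guides in a promoter and report TSS offsets.

Uses the six published 20-nt guides tiling a promoter CpG island,
planted in a synthetic promoter at their published offsets, and places
them back: exact match on both strands, NGG PAM check, and the signed
offset of each guide's 5'-most base relative to the TSS (+1; no zero).
"""

from epimark.guides import locate_guides
from epimark.synthetic_loci import GUIDES, guide_promoter

region, tss = guide_promoter()
placements, unplaced = locate_guides(region, tss, GUIDES)

print(f"promoter {region.id}: {len(region)} bp, TSS at {tss}")
for p in placements:
    print(f"  {p.guide_id}: {p.protospacer} strand {p.strand} "
          f"offset {p.offset:+d} PAM {p.pam} "
          f"({'valid NGG' if p.pam_valid else 'invalid'})")
if unplaced:
    print("unplaced:", ", ".join(unplaced))

# Offsets -402..-3 sit upstream of the TSS (the region where guided
# epigenetic modifiers act most effectively), +120/+386 downstream.
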