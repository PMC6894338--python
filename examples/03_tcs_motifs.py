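"""Scan 3'UTRs for the translation control sequence (TCS).

Expands the degenerate consensus (A/U)UU(A/G)UCU, scans two synthetic
UTRs carrying the published WEE1/WEE2 motif maps, and reports duplicate
motifs falling inside a 200-nt window.
"""

from epimark.motifs import (
    TCS_CONSENSUS,
    expand_consensus,
    find_window_duplicates,
    scan_sequence,
)
from epimark.synthetic_loci import wee1_like_utr, wee2_like_utr

motif = expand_consensus(TCS_CONSENSUS)
print(f"consensus {TCS_CONSENSUS} -> {', '.join(motif.expansions)}")

for utr in (wee1_like_utr(), wee2_like_utr()):
    hits = scan_sequence(utr, motif)
    print(f"\n{utr.id} ({len(utr)} nt):")
    for h in hits:
        print(f"  {h.motif} at position {h.start}")
    for e in find_window_duplicates(hits, window=200):
        print(f"  duplicate {e.motif} at {e.first_start}/{e.second_start} "
              f"(span {e.window_span} nt <= 200)")

# Each UTR carries one same-motif duplicate within a 200-nt window —
# the configuration associated with strong TCS-mediated regulation.
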