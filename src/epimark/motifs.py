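"""Translation-control-sequence (TCS) motif scanning of 3'UTRs.

The TCS consensus bound by Zar1-family proteins is (A/U)UU(A/G)UCU; this
module expands such parenthesised consensi into their concrete 7-mers,
scans UTR sets overlap-tolerantly, tabulates per-UTR occurrence counts and
detects same-motif duplicates falling within a 200-nt sliding window.
Matching happens in the unified T-alphabet so RNA motifs hit DNA UTRs;
hits are reported in RNA letters with 1-based start positions.
"""

from __future__ import annotations

import itertools
import re
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ContractError
from .seq import NucleotideSequence

TCS_CONSENSUS = "(A/U)UU(A/G)UCU"


@dataclass(frozen=True)
class DegenerateMotif:
    """A consensus with parenthesised alternative sets and its concrete
    expansions (RNA letters, lexicographically sorted, deduplicated)."""

    consensus: str
    expansions: tuple[str, ...]


@dataclass(frozen=True, order=True)
class MotifHit:
    utr_id: str
    motif: str  # RNA alphabet
    start: int  # 1-based


@dataclass(frozen=True)
class DuplicateEvent:
    """Two occurrences of the same motif in one UTR inside one window."""

    utr_id: str
    motif: str
    first_start: int
    second_start: int
    window_span: int  # nt from first base of first hit to last base of second


_GROUP_RE = re.compile(r"\(([ACGUT](?:/[ACGUT])+)\)|([ACGUT])")


def expand_consensus(consensus: str) -> DegenerateMotif:
    """Expand e.g. "(A/U)UU(A/G)UCU" into {AUUAUCU, AUUGUCU, UUUAUCU, UUUGUCU}."""
    upper = consensus.upper()
    pos = 0
    sets: list[tuple[str, ...]] = []
    for m in _GROUP_RE.finditer(upper):
        if m.start() != pos:
            raise ContractError(f"malformed consensus near position {pos + 1}")
        alts = tuple(m.group(1).split("/")) if m.group(1) else (m.group(2),)
        sets.append(tuple(dict.fromkeys(alts)))
        pos = m.end()
    if pos != len(upper) or not sets:
        raise ContractError(f"malformed consensus {consensus!r}")
    expansions = sorted(
        {"".join(bases).replace("T", "U") for bases in itertools.product(*sets)}
    )
    return DegenerateMotif(consensus, tuple(expansions))


def scan_sequence(
    utr: NucleotideSequence, motifs: DegenerateMotif | Iterable[str]
) -> list[MotifHit]:
    """All (overlap-tolerant) occurrences of every expansion in one UTR,
    sorted by start then motif."""
    expansions = motifs.expansions if isinstance(motifs, DegenerateMotif) else tuple(motifs)
    subject = utr.residues
    hits: list[MotifHit] = []
    for motif in expansions:
        needle = motif.upper().replace("U", "T")
        i = subject.find(needle)
        while i != -1:
            hits.append(MotifHit(utr.id, motif.upper().replace("T", "U"), i + 1))
            i = subject.find(needle, i + 1)
    hits.sort(key=lambda h: (h.start, h.motif))
    return hits


def scan_set(
    utrs: Sequence[NucleotideSequence], motifs: DegenerateMotif | Iterable[str]
) -> list[MotifHit]:
    out: list[MotifHit] = []
    for utr in utrs:
        out.extend(scan_sequence(utr, motifs))
    return out


@dataclass(frozen=True)
class CountSummary:
    """Per-UTR hit totals plus exactly-k and at-least-k histograms (k >= 2).

    Both tallies are reported because genome-scale per-UTR occurrence
    tables are often ambiguous between the two conventions.
    """

    per_utr: Mapping[str, int]
    exactly_k: Mapping[int, int]
    at_least_k: Mapping[int, int]


def summarise_counts(
    hits: Sequence[MotifHit], utr_ids: Iterable[str] | None = None
) -> CountSummary:
    """Tabulate totals per UTR (zero-hit UTRs appear when ``utr_ids`` is
    given) and the k>=2 histograms over UTRs."""
    per_utr: dict[str, int] = {u: 0 for u in (utr_ids or [])}
    for h in hits:
        per_utr[h.utr_id] = per_utr.get(h.utr_id, 0) + 1
    exactly = Counter(c for c in per_utr.values() if c >= 2)
    at_least: dict[int, int] = {}
    for k in sorted(exactly):
        at_least[k] = sum(v for c, v in exactly.items() if c >= k)
    return CountSummary(per_utr, dict(sorted(exactly.items())), at_least)


def find_window_duplicates(
    hits: Sequence[MotifHit],
    window: int = 200,
    semantics: str = "containment",
) -> list[DuplicateEvent]:
    """Pairs of same-motif occurrences in one UTR within a sliding window.

    ``semantics='containment'`` (default) requires both occurrences to fit
    entirely inside one ``window``-nt window, i.e. start difference <=
    window - motif length; ``'starts'`` relaxes this to start difference <=
    window.  A duplicate needs the *identical* motif twice — two different
    TCS expansions close together are not a duplicate.
    """
    if semantics not in ("containment", "starts"):
        raise ContractError(f"unknown window semantics {semantics!r}")
    grouped: dict[tuple[str, str], list[int]] = defaultdict(list)
    for h in hits:
        grouped[(h.utr_id, h.motif)].append(h.start)
    events: list[DuplicateEvent] = []
    for (utr_id, motif), starts in grouped.items():
        starts = sorted(starts)
        k = len(motif)
        limit = window - k if semantics == "containment" else window
        for i, a in enumerate(starts):
            for b in starts[i + 1 :]:
                if b - a > limit:
                    break
                events.append(DuplicateEvent(utr_id, motif, a, b, b + k - 1 - a + 1))
    events.sort(key=lambda e: (e.utr_id, e.first_start, e.second_start, e.motif))
    return events


def duplicate_positive_utrs(events: Sequence[DuplicateEvent]) -> dict[str, set[str]]:
    """Map motif -> set of UTR ids with at least one duplicate event."""
    out: dict[str, set[str]] = defaultdict(set)
    for e in events:
        out[e.motif].add(e.utr_id)
    return dict(out)
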