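"""CpG-island detection under the classical composition criteria.

A CpG island (CGI) is operationally defined here as an interval of length
>200 bp with average G+C content >50% and an observed/expected CpG ratio
>0.6, where

    O/E = (#CpG dinucleotides * L) / (#C * #G)

over the interval, with L the number of non-N bases.  These are the
criteria of the classical sliding-window definition; no hidden-Markov or
clustering caller is provided.  N bases are excluded from all counts and
break CpG dinucleotides (CN/NG are not CpGs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ContractError, UndefinedValueError
from .seq import GenomicInterval, NucleotideSequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CpGIsland:
    """A detected island with its composition statistics."""

    interval: GenomicInterval
    length_bp: int
    gc_percent: float
    obs_exp_cpg: float


def _counts(residues: str) -> tuple[int, int, int, int, int]:
    """(#C, #G, #A+T, #CpG, non-N length) over a residue string."""
    c = residues.count("C")
    g = residues.count("G")
    at = residues.count("A") + residues.count("T")
    cpg = sum(
        1
        for i in range(len(residues) - 1)
        if residues[i] == "C" and residues[i + 1] == "G"
    )
    return c, g, at, cpg, c + g + at


def gc_content(seq: NucleotideSequence, interval: GenomicInterval | None = None) -> float:
    """G+C percentage over the interval (whole sequence if None).

    N bases are excluded from numerator and denominator; an interval of
    only N has no defined G+C content.
    """
    residues = seq.residues if interval is None else seq.slice(interval.start, interval.end)
    c, g, at, _, non_n = _counts(residues)
    if non_n == 0:
        raise UndefinedValueError("interval contains only N bases")
    return 100.0 * (c + g) / non_n

def obs_exp_cpg(seq: NucleotideSequence, interval: GenomicInterval | None = None) -> float:
    """Observed/expected CpG ratio (#CpG * L)/(#C * #G); 0 when #C*#G = 0."""
    residues = seq.residues if interval is None else seq.slice(interval.start, interval.end)
    c, g, _, cpg, non_n = _counts(residues)
    if c * g == 0:
        return 0.0
    return cpg * non_n / (c * g)


def _passes(seq: NucleotideSequence, start: int, end: int,
            min_length: int, min_gc: float, min_oe: float) -> bool:
    """Strict (>) evaluation of all three criteria over [start, end]."""
    if end - start + 1 <= min_length:
        return False
    residues = seq.slice(start, end)
    c, g, at, cpg, non_n = _counts(residues)
    if non_n == 0 or c * g == 0:
        return False
    gc = 100.0 * (c + g) / non_n
    oe = cpg * non_n / (c * g)
    return gc > min_gc and oe > min_oe


def find_cgis(
    seq: NucleotideSequence,
    min_length: int = 200,
    min_gc: float = 50.0,
    min_oe: float = 0.6,
    window: int = 200,
    step: int = 1,
) -> list[CpGIsland]:
    """Detect CpG islands by merging qualifying sliding windows.

    Windows of ``window`` bp are slid at ``step`` bp and strictly tested
    against the G+C and O/E thresholds.  A raw union of qualifying windows
    smears island boundaries by up to a window length into the flanking
    background (any window that overlaps enough of the island qualifies),
    so boundaries are refined by majority coverage: a position belongs to
    a candidate island iff at least half of the windows covering it
    qualify, which localises the boundary to roughly where the island
    composition actually changes.  Maximal flagged runs become candidate
    intervals; each is re-evaluated as a whole (all three criteria,
    strictly), and a failing candidate has up to one window trimmed from
    each flank and is re-tested, else dropped.  Returned islands are
    sorted by start and non-overlapping.
    """
    n = len(seq)
    if n < window:
        logger.info("sequence %s shorter than window (%d < %d); no islands",
                    seq.id, n, window)
        return []

    res = np.frombuffer(seq.residues.encode(), dtype=np.uint8)
    is_c = res == ord("C")
    is_g = res == ord("G")
    non_n = res != ord("N")
    is_cpg = np.zeros(n, dtype=bool)
    is_cpg[:-1] = is_c[:-1] & is_g[1:]

    def csum(a: np.ndarray) -> np.ndarray:
        out = np.zeros(n + 1, dtype=np.int64)
        np.cumsum(a, out=out[1:])
        return out

    cs_c, cs_g, cs_nn, cs_cpg = csum(is_c), csum(is_g), csum(non_n), csum(is_cpg)

    starts = np.arange(0, n - window + 1, step)
    ends = starts + window  # exclusive
    c = cs_c[ends] - cs_c[starts]
    g = cs_g[ends] - cs_g[starts]
    nn = cs_nn[ends] - cs_nn[starts]
    # a CpG straddling the window end is not inside the window
    cpg = cs_cpg[ends - 1] - cs_cpg[starts]
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = np.where(nn > 0, 100.0 * (c + g) / np.maximum(nn, 1), 0.0)
        oe = np.where(c * g > 0, cpg * nn / np.maximum(c * g, 1), 0.0)
    ok = (gc > min_gc) & (oe > min_oe)

    # majority-coverage smoothing: per-position counts of qualifying vs
    # all windows covering it, via difference arrays
    qual_cov = np.zeros(n + 1, dtype=np.int32)
    all_cov = np.zeros(n + 1, dtype=np.int32)
    np.add.at(qual_cov, starts[ok], 1)
    np.add.at(qual_cov, ends[ok], -1)
    np.add.at(all_cov, starts, 1)
    np.add.at(all_cov, ends, -1)
    qual_cov = np.cumsum(qual_cov[:-1])
    all_cov = np.cumsum(all_cov[:-1])
    flagged = (all_cov > 0) & (2 * qual_cov >= all_cov)

    islands: list[CpGIsland] = []
    pos = 0
    while pos < n:
        if not flagged[pos]:
            pos += 1
            continue
        run_end = pos
        while run_end + 1 < n and flagged[run_end + 1]:
            run_end += 1
        lo, hi = pos + 1, run_end + 1  # 1-based inclusive
        # re-test candidate as a whole; trim at most one window per flank
        for s, e in ((lo, hi), (lo + window, hi), (lo, hi - window),
                     (lo + window, hi - window)):
            if s <= e and _passes(seq, s, e, min_length, min_gc, min_oe):
                iv = GenomicInterval(seq.id, s, e)
                islands.append(
                    CpGIsland(iv, iv.length, gc_content(seq, iv), obs_exp_cpg(seq, iv))
                )
                break
        pos = run_end + 1
    return islands
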