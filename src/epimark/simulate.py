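"""Seeded synthetic-data generators with machine-readable planted truth.

Every generator is a pure function of (seed, parameters): the same call
reproduces its output bit-for-bit.  Each returns a
:class:`TruthManifest` alongside the data, recording everything a
downstream recovery test needs (island coordinates, motif placements,
per-CpG betas, the survival cutoff and hazard ratio) so that tests can
score the pipeline against planted truth without hard-coded values.

The generators emulate the input classes of a promoter-methylation
biomarker study: GC-/CpG-structured genomic segments with planted CpG
islands, 3'UTR sets carrying translation-control-sequence motifs at
controlled per-UTR rates, bisulfite reads drawn from per-CpG methylation
levels with a conversion-efficiency parameter, and right-censored
survival cohorts whose hazard steps at a planted methylation cutoff.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, GeneratorError
from .motifs import (
    TCS_CONSENSUS,
    expand_consensus,
    find_window_duplicates,
    scan_sequence,
)
from .seq import GenomicInterval, NucleotideSequence, cpg_positions

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class TruthManifest:
    """Planted ground truth for one generator run; JSON-serialisable."""

    seed: int
    generator: str
    params: Mapping[str, Any]
    truth: Mapping[str, Any]

    def to_json(self, **kwargs) -> str:
        return json.dumps(dataclasses.asdict(self), default=_jsonify, **kwargs)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json(indent=2))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


# ---------------------------------------------------------------------------
# CpG-island genomes


def _composition(segment: str) -> tuple[float, float]:
    """(gc percent, observed/expected CpG ratio) of a residue string."""
    c = segment.count("C")
    g = segment.count("G")
    L = len(segment)
    cpg = sum(1 for i in range(L - 1) if segment[i] == "C" and segment[i + 1] == "G")
    gc = 100.0 * (c + g) / L if L else 0.0
    oe = cpg * L / (c * g) if c * g else 0.0
    return gc, oe


def _iid_segment(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _island_segment(rng: np.random.Generator, length: int, gc: float, oe: float) -> str:
    """First-order Markov draw whose CpG rate is tilted by the O/E target.

    With iid bases the expected O/E is ~1; conditioning P(G | previous C)
    on oe * P(G) shifts the expectation to ~oe.
    """
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    pg_after_c = min(oe * p[2], 0.95)
    after_c = p.copy()
    after_c[2] = 0.0
    after_c *= (1.0 - pg_after_c) / after_c.sum()
    after_c[2] = pg_after_c
    out = []
    prev_c = False
    us = rng.random(length)
    cum = np.cumsum(p)
    cum_c = np.cumsum(after_c)
    for u in us:
        idx = int(np.searchsorted(cum_c if prev_c else cum, u))
        idx = min(idx, 3)
        base = "ACGT"[idx]
        out.append(base)
        prev_c = base == "C"
    return "".join(out)


def gen_cgi_genome(
    seed: int,
    length: int,
    island_specs: Sequence[tuple[int, int, float, float]],
    background_gc: float = 0.35,
    gc_tol: float = 2.0,
    oe_tol: float = 0.1,
    max_tries: int = 1000,
    seq_id: str = "synthetic_genome",
) -> tuple[NucleotideSequence, TruthManifest]:
    """A genomic segment with AT-rich background and planted CpG islands.

    ``island_specs`` is a list of (start, length, target_gc_percent,
    target_oe); islands must be non-overlapping and within bounds.  Each
    island is drawn by rejection sampling until its realised composition
    is within ``gc_tol`` percentage points and ``oe_tol`` of the targets.
    """
    rng = np.random.default_rng(seed)
    specs = sorted(island_specs)
    prev_end = 0
    for start, ilen, gc, oe in specs:
        if start <= prev_end:
            raise ContractError("island specs overlap or are unordered")
        if start + ilen - 1 > length:
            raise ContractError("island extends past the sequence end")
        if not (0 < gc < 100) or oe <= 0:
            raise ContractError("invalid composition target")
        prev_end = start + ilen - 1

    residues = list(_iid_segment(rng, length, background_gc))
    truth_islands = []
    for start, ilen, gc, oe in specs:
        for attempt in range(max_tries):
            seg = _island_segment(rng, ilen, gc / 100.0, oe)
            got_gc, got_oe = _composition(seg)
            if abs(got_gc - gc) <= gc_tol and abs(got_oe - oe) <= oe_tol:
                break
        else:
            raise GeneratorError(
                f"could not hit gc={gc}, oe={oe} within {max_tries} draws"
            )
        residues[start - 1 : start - 1 + ilen] = seg
        truth_islands.append(
            {"start": start, "end": start + ilen - 1, "target_gc": gc,
             "target_oe": oe, "realised_gc": got_gc, "realised_oe": got_oe}
        )
    seq = NucleotideSequence(seq_id, "".join(residues))
    manifest = TruthManifest(
        seed, "gen_cgi_genome",
        {"length": length, "island_specs": [list(s) for s in specs],
         "background_gc": background_gc},
        {"islands": truth_islands},
    )
    return seq, manifest


# ---------------------------------------------------------------------------
# 3'UTR sets with planted TCS motifs


def gen_utr_set(
    seed: int,
    n_utrs: int,
    length_range: tuple[int, int] = (300, 1500),
    occurrence_table: Mapping[int, int] | None = None,
    duplicate_fraction: float = 0.0,
    window: int = 200,
    consensus: str = TCS_CONSENSUS,
    max_tries: int = 500,
) -> tuple[list[NucleotideSequence], TruthManifest]:
    """A 3'UTR set with exactly the planted motif occurrences and a stated
    fraction of UTRs carrying same-motif duplicates inside the window.

    ``occurrence_table`` maps a per-UTR total hit count to the number of
    UTRs carrying it (e.g. {2: 80, 3: 15, 4: 5}); unassigned UTRs carry no
    hits.  Non-duplicate UTRs receive pairwise-distinct motifs (so their
    total is capped at the number of consensus expansions); duplicate
    UTRs receive one motif twice within the window plus distinct others.
    Every UTR is re-scanned after planting and redrawn on any unintended
    match, so the emitted truth is exact.
    """
    motif = expand_consensus(consensus)
    k_motifs = len(motif.expansions)
    mlen = len(motif.expansions[0])
    occurrence_table = dict(occurrence_table or {})
    if any(k < 0 for k in occurrence_table):
        raise ContractError("negative occurrence count")
    n_assigned = sum(occurrence_table.values())
    if n_assigned > n_utrs:
        raise ContractError("occurrence_table assigns more UTRs than exist")
    counts = [k for k, n in sorted(occurrence_table.items()) for _ in range(n)]
    counts += [0] * (n_utrs - n_assigned)

    n_dup = round(n_utrs * duplicate_fraction)
    eligible = [i for i, c in enumerate(counts) if c >= 2]
    if n_dup > len(eligible):
        raise GeneratorError(
            f"duplicate_fraction needs {n_dup} UTRs with >=2 hits, "
            f"only {len(eligible)} planned"
        )

    rng = np.random.default_rng(seed)
    rng.shuffle(counts)
    eligible = [i for i, c in enumerate(counts) if c >= 2]
    dup_idx = set(rng.choice(eligible, size=n_dup, replace=False)) if n_dup else set()

    utrs: list[NucleotideSequence] = []
    truth_hits: list[dict] = []
    dup_utrs: list[str] = []
    for i, k in enumerate(counts):
        utr_id = f"utr_{i + 1:04d}"
        is_dup = i in dup_idx
        max_distinct = k_motifs + (1 if is_dup else 0)
        if k > max_distinct:
            raise GeneratorError(
                f"cannot plant {k} hits without unintended duplicates"
            )
        for attempt in range(max_tries):
            L = int(rng.integers(length_range[0], length_range[1] + 1))
            if L < max(mlen, (2 * k + 1) * mlen):
                continue
            seq, planted = _plant_utr(rng, utr_id, L, k, is_dup, motif.expansions,
                                      mlen, window)
            if seq is None:
                continue
            got = {(h.motif, h.start) for h in scan_sequence(seq, motif)}
            if got != {(m, s) for m, s in planted}:
                continue
            ev = find_window_duplicates(scan_sequence(seq, motif), window=window)
            if bool(ev) != is_dup:
                continue
            break
        else:
            raise GeneratorError(f"could not pack {k} hits into {utr_id}")
        utrs.append(seq)
        truth_hits.extend(
            {"utr_id": utr_id, "motif": m, "start": s} for m, s in sorted(planted, key=lambda x: x[1])
        )
        if is_dup:
            dup_utrs.append(utr_id)

    manifest = TruthManifest(
        seed, "gen_utr_set",
        {"n_utrs": n_utrs, "length_range": list(length_range),
         "occurrence_table": {str(k): v for k, v in occurrence_table.items()},
         "duplicate_fraction": duplicate_fraction, "window": window,
         "consensus": consensus},
        {"hits": truth_hits, "duplicate_utrs": dup_utrs,
         "per_utr_counts": {u.id: c for u, c in zip(utrs, counts)}},
    )
    return utrs, manifest


def _plant_utr(rng, utr_id, L, k, is_dup, expansions, mlen, window):
    """One attempt at building a UTR with exactly k planted hits."""
    background = "".join(_BASES[rng.integers(0, 4, size=L)])
    if k == 0:
        seq = NucleotideSequence(utr_id, background)
        return (seq, []) if not scan_sequence(seq, expansions) else (None, None)

    starts: list[int] = []
    if is_dup:
        a = int(rng.integers(1, L - mlen + 1 - mlen))
        hi = min(a + (window - mlen), L - mlen + 1)
        if hi < a + mlen:
            return None, None
        b = int(rng.integers(a + mlen, hi + 1))
        starts = [a, b]
    for _ in range(200):
        if len(starts) == k:
            break
        c = int(rng.integers(1, L - mlen + 2))
        if all(abs(c - s) >= mlen for s in starts):
            starts.append(c)
    if len(starts) != k:
        return None, None

    motifs_t = [m.replace("U", "T") for m in expansions]
    if is_dup:
        dup_m = int(rng.integers(0, len(expansions)))
        others = [j for j in range(len(expansions)) if j != dup_m]
        rng.shuffle(others)
        assign = [dup_m, dup_m] + others[: k - 2]
    else:
        order = list(range(len(expansions)))
        rng.shuffle(order)
        assign = order[:k]

    residues = list(background)
    planted = []
    for s, mi in zip(starts, assign):
        residues[s - 1 : s - 1 + mlen] = motifs_t[mi]
        planted.append((expansions[mi], s))
    return NucleotideSequence(utr_id, "".join(residues)), planted


# ---------------------------------------------------------------------------
# Bisulfite reads


def gen_bisulfite_reads(
    seed: int,
    region: NucleotideSequence,
    per_cpg_beta: float | Mapping[int, float],
    n_reads: int,
    read_length: int | None = None,
    conversion_efficiency: float = 1.0,
) -> tuple[pd.DataFrame, TruthManifest]:
    """Simulated top-strand bisulfite reads over a region.

    Each read's CpG methylation states are drawn Bernoulli(beta); a
    methylated CpG C is retained, an unmethylated one converts to T.
    Non-CpG cytosines (and unmethylated CpG cytosines) fail to convert
    independently with probability 1 - ``conversion_efficiency``, which
    must lie in (0.8, 1.0] — lower efficiencies are outside the regime the
    assay tolerates.  Reads carry 1-based ``start`` coordinates, so no
    alignment step exists downstream.
    """
    if not 0.8 < conversion_efficiency <= 1.0:
        raise ContractError("conversion_efficiency must be in (0.8, 1.0]")
    if n_reads < 0:
        raise ContractError("n_reads must be non-negative")
    positions = cpg_positions(region)
    if isinstance(per_cpg_beta, Mapping):
        betas = {int(p): float(b) for p, b in per_cpg_beta.items()}
        unknown = set(betas) - set(positions)
        if unknown:
            raise ContractError(f"beta given for non-CpG positions {sorted(unknown)}")
        betas = {p: betas.get(p, 0.0) for p in positions}
    else:
        betas = {p: float(per_cpg_beta) for p in positions}
    if any(not 0.0 <= b <= 1.0 for b in betas.values()):
        raise ContractError("beta values must lie in [0,1]")

    L = len(region)
    rlen = L if read_length is None else min(read_length, L)
    fail_p = 1.0 - conversion_efficiency
    rng = np.random.default_rng(seed)
    rows = []
    drawn_meth = {p: 0 for p in positions}
    covered = {p: 0 for p in positions}
    for r in range(n_reads):
        start = 1 if rlen >= L else int(rng.integers(1, L - rlen + 2))
        chunk = list(region.residues[start - 1 : start - 1 + rlen])
        for j, base in enumerate(chunk):
            if base != "C":
                continue
            p = start + j
            if p in betas:
                covered[p] += 1
                if rng.random() < betas[p]:
                    drawn_meth[p] += 1  # methylated: retained as C
                elif rng.random() >= fail_p:
                    chunk[j] = "T"
            elif rng.random() >= fail_p:
                chunk[j] = "T"
        rows.append({"read_id": f"read_{r + 1:05d}", "start": start,
                     "sequence": "".join(chunk)})
    reads = pd.DataFrame(rows, columns=["read_id", "start", "sequence"])
    manifest = TruthManifest(
        seed, "gen_bisulfite_reads",
        {"region_id": region.id, "n_reads": n_reads, "read_length": rlen,
         "conversion_efficiency": conversion_efficiency},
        {"cpg_positions": positions,
         "per_cpg_beta": {str(p): betas[p] for p in positions},
         "drawn_methylated": {str(p): drawn_meth[p] for p in positions},
         "covering_reads": {str(p): covered[p] for p in positions}},
    )
    return reads, manifest


# ---------------------------------------------------------------------------
# Survival cohorts


def gen_cohort(
    seed: int,
    n: int,
    beta_mixture: tuple[float, float, float, float, float] = (2.0, 8.0, 8.0, 2.0, 0.5),
    cutoff: float = 0.30,
    hazard_ratio: float = 3.0,
    baseline_median_months: float = 60.0,
    censor_fraction: float = 0.2,
) -> tuple[pd.DataFrame, TruthManifest]:
    """A right-censored cohort whose hazard steps at a methylation cutoff.

    Betas are drawn from the two-component mixture
    pi * Beta(a1, b1) + (1 - pi) * Beta(a0, b0) with ``beta_mixture`` =
    (a0, b0, a1, b1, pi) — by default an unmethylated mode near 0.2 and a
    hypermethylated mode near 0.8, reflecting the bimodal beta
    distributions of tumour/control panels.  Survival times are
    exponential with rate ln2 / ``baseline_median_months``, multiplied by
    ``hazard_ratio`` for subjects with beta >= ``cutoff``.  Exactly
    round(n * ``censor_fraction``) randomly chosen subjects are censored
    at a uniform fraction of their event time.
    """
    if n < 2:
        raise ContractError("cohort needs at least 2 subjects")
    if hazard_ratio <= 0 or not 0.0 < cutoff < 1.0:
        raise ContractError("invalid hazard ratio or cutoff")
    if not 0.0 <= censor_fraction <= 1.0:
        raise ContractError("censor_fraction must be in [0,1]")
    a0, b0, a1, b1, pi = beta_mixture
    if not 0.0 <= pi <= 1.0:
        raise ContractError("mixture weight must be in [0,1]")
    rng = np.random.default_rng(seed)
    comp = rng.random(n) < pi
    betas = np.where(comp, rng.beta(a1, b1, size=n), rng.beta(a0, b0, size=n))
    high = betas >= cutoff
    if high.all() or (~high).all():
        raise GeneratorError(
            "degenerate mixture: all betas on one side of the cutoff"
        )
    rate = math.log(2) / baseline_median_months * np.where(high, hazard_ratio, 1.0)
    event_times = rng.exponential(1.0 / rate)
    event = np.ones(n, dtype=int)
    times = event_times.copy()
    n_cens = round(n * censor_fraction)
    if n_cens:
        idx = rng.choice(n, size=n_cens, replace=False)
        times[idx] = event_times[idx] * rng.random(n_cens)
        event[idx] = 0
    times = np.maximum(times, 1e-9)
    df = pd.DataFrame(
        {
            "subject_id": [f"subject_{i + 1:04d}" for i in range(n)],
            "time": times,
            "event": event,
            "beta": betas,
        }
    )
    manifest = TruthManifest(
        seed, "gen_cohort",
        {"n": n, "beta_mixture": list(beta_mixture), "cutoff": cutoff,
         "hazard_ratio": hazard_ratio,
         "baseline_median_months": baseline_median_months,
         "censor_fraction": censor_fraction},
        {"cutoff": cutoff, "hazard_ratio": hazard_ratio,
         "high_group": df["subject_id"][high].tolist(),
         "n_censored": int(n_cens)},
    )
    return df, manifest
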