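"""End-to-end demo pipeline: generate synthetic inputs, run every
analysis stage, write the reports and score recovery against the planted
truth."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import bisulfite, cgi, guides as guides_mod, motifs, simulate, survival as surv
from .seq import write_fasta
from .synthetic_loci import COBRA_FWD, COBRA_REV, cobra_template


def reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    """min(overlap/len(a), overlap/len(b)) for 1-based inclusive intervals."""
    inter = min(a_end, b_end) - max(a_start, b_start) + 1
    if inter <= 0:
        return 0.0
    return min(inter / (a_end - a_start + 1), inter / (b_end - b_start + 1))


def run_demo(seed: int, outdir: Path) -> list[str]:
    """Run generator -> analysis -> report for every stage; returns the
    printed recovery summary."""
    outdir = Path(outdir)
    summary: list[str] = []

    # CpG island: plant one island, recover it
    genome, g_truth = simulate.gen_cgi_genome(seed, 2000, [(701, 600, 68.0, 0.98)])
    write_fasta([genome], outdir / "genome.fa")
    islands = cgi.find_cgis(genome)
    with open(outdir / "islands.bed", "w") as fh:
        for isl in islands:
            iv = isl.interval
            fh.write(f"{iv.seq_id}\t{iv.start - 1}\t{iv.end}\tCGI\t0\t+\n")
    planted = g_truth.truth["islands"][0]
    best = max(
        (reciprocal_overlap(i.interval.start, i.interval.end,
                            planted["start"], planted["end"]) for i in islands),
        default=0.0,
    )
    summary.append(f"cgi: {len(islands)} island(s); best reciprocal overlap "
                   f"with planted island {best:.2f}")

    # TCS motifs: plant occurrences, recover hits and duplicates
    utrs, u_truth = simulate.gen_utr_set(
        seed, 60, occurrence_table={2: 15, 3: 4, 4: 1}, duplicate_fraction=0.1
    )
    write_fasta(utrs, outdir / "utrs.fa")
    motif = motifs.expand_consensus(motifs.TCS_CONSENSUS)
    hits = motifs.scan_set(utrs, motif)
    pd.DataFrame([h.__dict__ for h in hits]).to_csv(
        outdir / "hits.tsv", sep="\t", index=False)
    truth_hits = {(h["utr_id"], h["motif"], h["start"]) for h in u_truth.truth["hits"]}
    found = {(h.utr_id, h.motif, h.start) for h in hits}
    events = motifs.find_window_duplicates(hits)
    dup_found = {e.utr_id for e in events}
    summary.append(
        f"tcs: {len(found)} hit(s), truth recovery "
        f"{'exact' if found == truth_hits else 'MISMATCH'}; "
        f"{len(dup_found)}/{len(u_truth.truth['duplicate_utrs'])} duplicate UTR(s)"
    )

    # CoBRA: methylation-dependent fragment pattern on the synthetic locus
    template = cobra_template()
    rows = []
    for name, meth in (("methylated", True), ("unmethylated", False)):
        converted = bisulfite.bisulfite_convert(
            template, bisulfite.MethylationProfile.uniform(template, meth))
        _, amplicon = bisulfite.in_silico_pcr(converted, COBRA_FWD, COBRA_REV)
        frags = bisulfite.cobra_digest(amplicon)
        rows.append({"profile": name, "amplicon_length": len(amplicon),
                     "fragment_lengths": ",".join(map(str, frags))})
    pd.DataFrame(rows).to_csv(outdir / "cobra_report.tsv", sep="\t", index=False)
    summary.append(
        f"cobra: amplicon {rows[0]['amplicon_length']} bp; fragments "
        f"methylated {rows[0]['fragment_lengths']}, "
        f"unmethylated {rows[1]['fragment_lengths']}"
    )

    # Survival: planted hazard step, best-cutoff recovery
    cohort, c_truth = simulate.gen_cohort(seed, 500)
    cohort.to_csv(outdir / "cohort.tsv", sep="\t", index=False)
    records = surv.records_from_frame(cohort, covariate_col="beta",
                                      id_col="subject_id")
    result = surv.best_cutoff_scan(records)
    low = [r for r in records if r.covariate < result.threshold]
    high = [r for r in records if r.covariate >= result.threshold]
    km_rows = []
    for name, grp in (("low", low), ("high", high)):
        curve = surv.km_estimate(grp)
        for t, n_i, d_i, s in zip(curve.event_times, curve.at_risk,
                                  curve.events, curve.survival):
            km_rows.append({"group": name, "time": t, "at_risk": int(n_i),
                            "events": int(d_i), "survival": s})
    pd.DataFrame(km_rows).to_csv(outdir / "km.tsv", sep="\t", index=False)
    summary.append(
        f"survival: planted cutoff {c_truth.truth['cutoff']:.2f}, recovered "
        f"{result.threshold:.3f} (p={result.p_value:.2e}, unadjusted over "
        f"{result.n_thresholds_tested} thresholds)"
    )

    # Guides: recover planted placements (generator-style round trip)
    from .synthetic_loci import GUIDES, GUIDE_OFFSETS, guide_promoter

    region, tss = guide_promoter()
    placements, unplaced = guides_mod.locate_guides(region, tss, GUIDES)
    pd.DataFrame([p.__dict__ for p in placements]).to_csv(
        outdir / "placements.tsv", sep="\t", index=False)
    ok = all(p.offset == GUIDE_OFFSETS[p.guide_id] and p.pam_valid
             for p in placements) and not unplaced
    summary.append(f"guides: {len(placements)} placed, offsets "
                   f"{'match' if ok else 'MISMATCH'}")
    return summary
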