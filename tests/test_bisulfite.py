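import itertools

import numpy as np
import pandas as pd
import pytest

from epimark.bisulfite import (
    TAQI,
    MethylationProfile,
    bisulfite_convert,
    classify,
    cobra_digest,
    in_silico_pcr,
    methylation_beta,
    quantify_from_reads,
    validate_bisulfite_primer,
)
from epimark.errors import (
    ContractError,
    MultipleProductError,
    NoProductError,
    UndefinedValueError,
)
from epimark.seq import NucleotideSequence, cpg_positions
from epimark.synthetic_loci import COBRA_FWD, COBRA_REV, cobra_template

from conftest import make_seq


def profile(seq, states):
    pos = tuple(cpg_positions(seq))
    return MethylationProfile(seq.id, pos, tuple(states))


class TestConvert:
    def test_methylated_cpg_retained(self):
        seq = make_seq("ACGTCT")
        out = bisulfite_convert(seq, profile(seq, [1.0]))
        assert out.residues == "ACGTTT"

    def test_unmethylated_cpg_converted(self):
        seq = make_seq("ACGTCT")
        out = bisulfite_convert(seq, profile(seq, [0.0]))
        assert out.residues == "ATGTTT"

    def test_no_cytosine_unchanged(self):
        seq = make_seq("AGTAGT")
        assert bisulfite_convert(seq, profile(seq, [])).residues == "AGTAGT"

    def test_full_unmethylated_conversion_leaves_no_c(self):
        seq = make_seq("CCGCGACTG")
        out = bisulfite_convert(seq, MethylationProfile.fully_unmethylated(seq))
        assert "C" not in out.residues

    def test_c_appears_exactly_at_methylated_cpgs(self):
        seq = make_seq("CCGACGTC")
        pos = cpg_positions(seq)  # [2, 5]
        prof = MethylationProfile(seq.id, tuple(pos), (1.0, 0.0))
        out = bisulfite_convert(seq, prof)
        assert [i + 1 for i, b in enumerate(out.residues) if b == "C"] == [2]

    def test_bottom_strand_converts_reverse_complement(self):
        seq = make_seq("ACGT")
        out = bisulfite_convert(seq, MethylationProfile.fully_methylated(seq), "bottom")
        # bottom strand of ACGT is ACGT; its CpG C (pairing the top G) stays
        assert out.residues == "ACGT"
        out_u = bisulfite_convert(
            seq, MethylationProfile.fully_unmethylated(seq), "bottom"
        )
        assert out_u.residues == "ATGT"

    def test_profile_id_mismatch_rejected(self):
        seq = make_seq("ACGT")
        with pytest.raises(ContractError):
            bisulfite_convert(seq, MethylationProfile("other", (1,), (1.0,)))

    def test_non_cpg_position_rejected(self):
        seq = make_seq("ACGT")
        with pytest.raises(ContractError):
            MethylationProfile(seq.id, (2, 3), (1.0, 1.0)).validate_against(seq)


class TestSiteLogic:
    def test_taqi_site_creation_retention_exhaustive(self):
        """Converted amplicon has TCGA at i iff original has [C|T]CGA with
        that CpG methylated — checked over all 4-mers x methylation states."""
        for bases in itertools.product("ACGT", repeat=4):
            original = "".join(bases)
            seq = NucleotideSequence("x", original)
            pos = cpg_positions(seq)
            for states in itertools.product([0.0, 1.0], repeat=len(pos)):
                prof = MethylationProfile("x", tuple(pos), states)
                conv = bisulfite_convert(seq, prof)
                has_site = conv.residues == "TCGA"
                cpg_at_2_meth = (
                    original[1:4] == "CGA"
                    and original[0] in "CT"
                    and 2 in prof.methylated_set
                )
                # a C at position 1 also needs to convert (or be T already)
                if original[0] == "C" and 1 in prof.methylated_set:
                    cpg_at_2_meth = False
                assert has_site == cpg_at_2_meth, (original, states)


class TestPcrAndDigest:
    def test_planted_primer_geometry(self, rng):
        bases = np.array(list("ACGT"))
        fwd = "GATTACAGATTACAGATTAC"
        rev_rc = "CCTTGGAACCTTGGAACCTT"  # appears on top strand, ends at 300
        while True:
            backbone = "".join(bases[rng.integers(0, 4, size=500)])
            t = backbone[:100] + fwd + backbone[120:280] + rev_rc + backbone[300:]
            if t.count(fwd) == 1 and t.count(rev_rc) == 1:
                break
        template = NucleotideSequence("t", t)
        from epimark.seq import reverse_complement

        interval, amplicon = in_silico_pcr(template, fwd, reverse_complement(rev_rc))
        assert (interval.start, interval.end) == (101, 300)
        assert len(amplicon) == 200

    def test_absent_forward_primer_is_no_product(self):
        template = make_seq("A" * 200)
        with pytest.raises(NoProductError):
            in_silico_pcr(template, "GATTACAGATTACAGATTAC", "TTTTTTTTTTTTTTTTTTTT")

    def test_multi_mapping_is_an_error(self):
        fwd = "GATTACAGATTACAGATTAC"
        rev_rc = "CCTTGGAACCTTGGAACCTT"
        t = ("A" * 10 + fwd) * 2 + "A" * 50 + rev_rc + "A" * 10
        with pytest.raises(MultipleProductError):
            from epimark.seq import reverse_complement

            in_silico_pcr(NucleotideSequence("t", t), fwd, reverse_complement(rev_rc))

    def test_fragment_lengths_conserve_amplicon_length(self):
        amp = make_seq("AATCGATTTCGAAA")  # two TaqI sites
        frags = cobra_digest(amp, TAQI)
        assert len(frags) == 3
        assert sum(frags) == len(amp)

    def test_uncut_amplicon_single_fragment(self):
        amp = make_seq("AAAATTTT")
        assert cobra_digest(amp, TAQI) == [8]

    def test_cut_position_convention(self):
        # T^CGA: cut after the T, so TCGA at start yields a 1-bp fragment
        assert cobra_digest(make_seq("TCGAAAAA"), TAQI) == [1, 7]


class TestCobraLocus:
    """Methylation-dependent fragment pattern of the synthetic assay locus."""

    @pytest.mark.parametrize(
        "methylated,expected", [(True, [89, 97]), (False, [186])]
    )
    def test_amplicon_and_fragments(self, methylated, expected):
        template = cobra_template()
        conv = bisulfite_convert(
            template, MethylationProfile.uniform(template, methylated)
        )
        _, amplicon = in_silico_pcr(conv, COBRA_FWD, COBRA_REV)
        assert len(amplicon) == 186
        assert cobra_digest(amplicon, TAQI) == expected

    def test_printed_primers_validate_on_both_profiles(self):
        template = cobra_template()
        fwd = validate_bisulfite_primer(COBRA_FWD, template, "forward")
        rev = validate_bisulfite_primer(COBRA_REV, template, "reverse")
        assert fwd.passed and rev.passed

    def test_primer_with_concrete_non_cpg_c_fails(self):
        template = cobra_template()
        bad = COBRA_FWD.replace("Y", "C").replace("TTTTT", "CTTTT")
        report = validate_bisulfite_primer(bad, template, "forward")
        assert not report.passed


class TestQuantification:
    def test_beta_and_threshold_boundary(self):
        assert methylation_beta(50, 50) == 0.5
        assert classify(0.5) == "methylated"
        assert methylation_beta(0, 100) == 0.0
        assert classify(0.0) == "unmethylated"
        assert classify(methylation_beta(19, 81)) == "unmethylated"
        assert classify(methylation_beta(20, 80)) == "methylated"

    def test_zero_coverage_is_undefined(self):
        with pytest.raises(UndefinedValueError):
            methylation_beta(0, 0)

    def test_quantify_flags_uncovered_cpg(self):
        reads = pd.DataFrame({"start": [1], "sequence": ["ACGT"]})
        table = quantify_from_reads(reads, [2, 50])
        row = table.set_index("position").loc[50]
        assert bool(row["flagged_no_coverage"]) and np.isnan(row["beta"])

    def test_quantify_counts_c_vs_t(self):
        reads = pd.DataFrame(
            {"start": [1, 1, 1], "sequence": ["ACGA", "ATGA", "ACGA"]}
        )
        table = quantify_from_reads(reads, [2])
        assert table.loc[0, "beta"] == pytest.approx(2 / 3)
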