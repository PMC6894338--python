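import numpy as np
import pytest

from epimark.motifs import TCS_CONSENSUS, expand_consensus
from epimark.seq import NucleotideSequence
from epimark.survival import SurvivalRecord


@pytest.fixture(scope="session")
def tcs_motif():
    return expand_consensus(TCS_CONSENSUS)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_seq(residues: str, seq_id: str = "s", alphabet: str = "DNA") -> NucleotideSequence:
    return NucleotideSequence(seq_id, residues.upper().replace("U", "T"), alphabet)


def make_records(times, events, covariates=None):
    covariates = covariates if covariates is not None else [None] * len(times)
    return [
        SurvivalRecord(f"subj_{i}", float(t), int(e), c if c is None else float(c))
        for i, (t, e, c) in enumerate(zip(times, events, covariates))
    ]
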