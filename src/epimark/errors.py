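"""Exception hierarchy shared across the toolkit."""


class EpimarkError(Exception):
    """Base class for all toolkit errors."""


class AlphabetError(EpimarkError, ValueError):
    """A sequence contains characters outside the accepted alphabet."""


class FastaFormatError(EpimarkError, ValueError):
    """A FASTA file violates the format contract (empty, blank or duplicate ids)."""


class ContractError(EpimarkError, ValueError):
    """An operation was called with arguments violating its preconditions."""


class UndefinedValueError(EpimarkError, ValueError):
    """The requested quantity is undefined for this input (e.g. all-N interval)."""


class NoProductError(EpimarkError, RuntimeError):
    """In-silico PCR found no amplifiable product."""


class MultipleProductError(EpimarkError, RuntimeError):
    """In-silico PCR found more than one candidate product."""


class DegenerateSplitError(EpimarkError, ValueError):
    """A covariate split cannot produce two non-empty groups."""


class GeneratorError(EpimarkError, RuntimeError):
    """A synthetic-data generator could not satisfy its targets."""
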