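"""Exception hierarchy."""


class PocketGTError(Exception):
    """Base class for all package errors."""


class FormatError(PocketGTError):
    """Unreadable or malformed input file."""


class EmptyStructureError(PocketGTError):
    """A structure without the required polymer content."""


class EmptyPocketError(PocketGTError):
    """A pocket candidate that selects zero residues."""


class VocabularyError(PocketGTError):
    """An amino-acid token outside the 21-way vocabulary."""


class ConfigError(PocketGTError):
    """Inconsistent model or run configuration."""


class BalancingError(PocketGTError):
    """Label balancing requested on a single-class dataset."""


class GenerationError(PocketGTError):
    """Synthetic-fixture construction could not satisfy its constraints."""


class EnsembleError(PocketGTError):
    """Incompatible members in a model ensemble."""


class MetricError(PocketGTError):
    """An evaluation metric is undefined on the given input."""
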