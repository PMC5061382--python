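"""Exception hierarchy shared across the pipeline stages."""


class PlauscompError(Exception):
    """Base class for all package-specific errors."""


class InputError(PlauscompError):
    """A file or table could not be read or is malformed."""


class EmptyCorpusError(InputError):
    """No sentences survived parsing."""


class DegenerateInputError(PlauscompError):
    """An input is valid in type but carries no usable signal (e.g. all-zero counts)."""


class ConfigurationError(PlauscompError):
    """A parameter is incompatible with the data (e.g. rank larger than the matrix)."""


class UndefinedSimilarityError(PlauscompError):
    """Cosine requested for a zero-norm vector; the caller decides the fallback."""


class ConsistencyError(PlauscompError):
    """Two pipeline artefacts that must agree do not (e.g. missing bigram row)."""


class EstimationError(PlauscompError):
    """A model could not be estimated from the data provided."""
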